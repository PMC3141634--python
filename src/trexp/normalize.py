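"""Cross-library normalization of read-count matrices.

Raw tag/EST counts from independently sequenced cDNA libraries are not
directly comparable: library depth differs and the count distributions can
be distorted relative to one another. Two normalizations are provided:

* :func:`quantile_normalize` — full-quantile normalization, forcing every
  library onto the common reference distribution given by the across-library
  mean of the order statistics. This is the default used upstream of the
  differential-expression R test.
* :func:`library_total_scale` — the classical depth scaling (counts scaled
  so each library sums to a common total), kept as a baseline comparator.

Both operate on a genes x libraries :class:`pandas.DataFrame` and return a
new frame with the same labels; values become real-valued.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["quantile_normalize", "library_total_scale"]


def _validate_counts(matrix: pd.DataFrame) -> None:
    if matrix.ndim != 2 or matrix.shape[0] == 0:
        raise ValueError("count matrix must be a non-empty 2-D table")
    if not matrix.index.is_unique:
        raise ValueError("duplicate gene identifiers in count matrix")
    if not matrix.columns.is_unique:
        raise ValueError("duplicate library labels in count matrix")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("count matrix contains missing values")
    if (values < 0).any():
        raise ValueError("count matrix contains negative entries")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Full-quantile normalize all libraries onto a common distribution.

    For each rank r the reference value is the mean over libraries of their
    r-th smallest counts. Every entry is replaced by the reference value at
    its within-library rank; entries tied within a library receive the mean
    of the reference values over their tied ranks, so ties stay tied.

    Parameters
    ----------
    matrix
        Genes x libraries table of non-negative counts (>= 2 libraries).

    Returns
    -------
    pandas.DataFrame
        Same shape and labels; within-library rank order is preserved and
        (absent ties) every library ends up with an identical sorted value
        vector.
    """
    _validate_counts(matrix)
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least two libraries")
    values = matrix.to_numpy(dtype=float)
    n_genes, n_libs = values.shape

    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(values)
    for j in range(n_libs):
        col = values[:, j]
        idx = order[:, j]
        col_sorted = col[idx]
        assigned = reference.copy()
        # average reference values over runs of tied observations
        start = 0
        while start < n_genes:
            stop = start + 1
            while stop < n_genes and col_sorted[stop] == col_sorted[start]:
                stop += 1
            if stop - start > 1:
                assigned[start:stop] = reference[start:stop].mean()
            start = stop
        out[idx, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def library_total_scale(matrix: pd.DataFrame, target_total: float) -> pd.DataFrame:
    """Scale each library so its column sum equals ``target_total``."""
    _validate_counts(matrix)
    if target_total <= 0:
        raise ValueError("target_total must be positive")
    totals = matrix.sum(axis=0).to_numpy(dtype=float)
    if (totals <= 0).any():
        bad = list(matrix.columns[totals <= 0])
        raise ValueError(f"libraries with zero total counts: {bad}")
    return matrix.astype(float) * (target_total / totals)
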