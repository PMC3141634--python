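"""Differential expression across cDNA libraries via the log-likelihood R test.

For one gene with counts x_j in libraries of total size N_j, the R statistic
is the log-likelihood ratio between a model with library-specific expression
proportions and the common-proportion null:

    R = sum_j x_j * ln( x_j / (N_j * f) ),    f = sum_j x_j / sum_j N_j

with 0*ln(0) taken as 0. R is zero iff x_j/N_j is constant across libraries,
and 2R is asymptotically chi-square with (m - 1) degrees of freedom under
the null, which supplies p-values.

Gene calls built on top of R:

* preferentially expressed genes (PEGs): R >= r_min, the focal library is
  the unique count maximum, and its count is at least fold_min times the
  mean of the other libraries;
* ubiquitous genes: at least one read in every library and no significant
  pairwise R test;
* stress-responsive genes: R over all libraries >= r_min and a >= fold_min
  change of the stress library against the mean of the organ libraries, in
  either direction.

The qRT-PCR relative quantification helper (2^-ddCt) used to validate calls
lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PegThresholds",
    "r_statistic",
    "r_test_matrix",
    "fold_change",
    "call_pegs",
    "call_ubiquitous",
    "call_stress_responsive",
    "ddct",
]


@dataclass(frozen=True)
class PegThresholds:
    """Stringency settings for gene calls.

    r_min:  minimum R statistic (natural-log units) for PEG / stress calls.
    fold_min:  minimum fold change of the focal library against the mean of
        the others (changes in either direction count for stress calls).
    alpha_nonsignificant:  per-test level above which a pairwise R test is
        considered non-significant when calling ubiquitous genes.
    """

    r_min: float = 8.0
    fold_min: float = 2.0
    alpha_nonsignificant: float = 0.05

    def __post_init__(self) -> None:
        if self.r_min <= 0:
            raise ValueError("r_min must be positive")
        if self.fold_min < 1:
            raise ValueError("fold_min must be >= 1")
        if not 0 < self.alpha_nonsignificant < 1:
            raise ValueError("alpha_nonsignificant must lie in (0, 1)")


def r_statistic(x, n) -> float:
    """Log-likelihood ratio R for one gene's counts across libraries.

    Parameters
    ----------
    x
        Per-library expression values (non-negative; real-valued after
        normalization is fine).
    n
        Per-library totals (all positive).

    Returns
    -------
    float
        R in natural-log units; zero iff the proportions x_j / n_j agree.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if x.shape != n.shape or x.ndim != 1:
        raise ValueError("x and n must be 1-D arrays of the same length")
    if (x < 0).any():
        raise ValueError("negative expression value")
    if (n <= 0).any():
        raise ValueError("library totals must be positive")
    total = x.sum()
    if total <= 0:
        raise ValueError("R statistic undefined for an all-zero gene")
    f = total / n.sum()
    nz = x > 0
    return float(np.sum(x[nz] * np.log(x[nz] / (n[nz] * f))))


def _r_matrix(values: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Vectorized R over the rows of a genes x libraries array."""
    row_sums = values.sum(axis=1)
    f = row_sums / totals.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = values * np.log(values / (totals[None, :] * f[:, None]))
    terms[values == 0] = 0.0
    return terms.sum(axis=1)


def r_test_matrix(matrix: pd.DataFrame, totals=None) -> pd.DataFrame:
    """Apply the R test to every gene of a count matrix.

    The effective library totals default to the column sums of the (usually
    normalized) matrix. Genes with zero total expression are dropped.

    Returns a frame indexed by gene with columns ``R``, ``df`` and ``p``,
    where p is the upper tail of chi-square(df = m - 1) at 2R.
    """
    if matrix.shape[1] < 2:
        raise ValueError("the R test needs at least two libraries")
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("count matrix contains negative entries")
    totals = values.sum(axis=0) if totals is None else np.asarray(totals, dtype=float)
    if (totals <= 0).any():
        raise ValueError("library totals must be positive")
    keep = values.sum(axis=1) > 0
    r = _r_matrix(values[keep], totals)
    r = np.maximum(r, 0.0)  # guard tiny negative round-off at R ~ 0
    df = matrix.shape[1] - 1
    p = stats.chi2.sf(2.0 * r, df)
    return pd.DataFrame(
        {"R": r, "df": df, "p": p}, index=matrix.index[keep]
    )


def fold_change(x, libraries, focal: str) -> float:
    """Fold change of the focal library against the mean of the others.

    Returns ``x_focal / mean(x_others)``; +inf when the others average zero
    but the focal value is positive, and 0 when the focal value is zero.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("negative expression value")
    libraries = list(libraries)
    if focal not in libraries:
        raise KeyError(f"unknown focal library {focal!r}")
    i = libraries.index(focal)
    others = np.delete(x, i)
    denom = others.mean()
    if x[i] == 0:
        return 0.0
    if denom == 0:
        return float("inf")
    return float(x[i] / denom)


def _fold_table(values: np.ndarray) -> np.ndarray:
    """Fold change of every library vs the mean of the others, per gene."""
    m = values.shape[1]
    row_sums = values.sum(axis=1, keepdims=True)
    other_means = (row_sums - values) / (m - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        folds = values / other_means
    folds[values == 0] = 0.0
    folds[(other_means == 0) & (values > 0)] = np.inf
    return folds


def call_pegs(
    matrix: pd.DataFrame, thresholds: PegThresholds = PegThresholds()
) -> pd.DataFrame:
    """Call preferentially expressed genes (PEGs), one library per gene.

    A gene is a PEG of library L iff R >= r_min, L is the unique maximum of
    the gene's values, and the fold change of L against the mean of the
    other libraries is >= fold_min. The input should normally be a
    normalized matrix.

    Returns a frame indexed by the called genes with columns ``library``,
    ``R``, ``p`` and ``fold``.
    """
    res = r_test_matrix(matrix)
    values = matrix.loc[res.index].to_numpy(dtype=float)
    libraries = list(matrix.columns)
    folds = _fold_table(values)

    argmax = values.argmax(axis=1)
    maxima = values.max(axis=1)
    unique_max = (values == maxima[:, None]).sum(axis=1) == 1
    focal_fold = folds[np.arange(len(values)), argmax]
    is_peg = (
        (res["R"].to_numpy() >= thresholds.r_min)
        & unique_max
        & (focal_fold >= thresholds.fold_min)
    )
    out = pd.DataFrame(
        {
            "library": [libraries[i] for i in argmax],
            "R": res["R"].to_numpy(),
            "p": res["p"].to_numpy(),
            "fold": focal_fold,
        },
        index=res.index,
    )
    return out.loc[is_peg]


def call_ubiquitous(
    matrix: pd.DataFrame, thresholds: PegThresholds = PegThresholds()
) -> list[str]:
    """Genes expressed in every library with no significant pairwise R test.

    A gene qualifies iff it has value >= 1 in every library and all
    m(m-1)/2 two-library R tests (chi-square df 1 on 2R) have
    p >= alpha_nonsignificant.
    """
    values = matrix.to_numpy(dtype=float)
    totals = values.sum(axis=0)
    present = (values >= 1).all(axis=1)
    candidates = np.flatnonzero(present)
    crit = stats.chi2.isf(thresholds.alpha_nonsignificant, 1) / 2.0
    m = matrix.shape[1]
    keep = np.ones(candidates.size, dtype=bool)
    for a in range(m):
        for b in range(a + 1, m):
            pair = values[candidates][:, [a, b]]
            r = _r_matrix(pair, totals[[a, b]])
            keep &= r < crit
    return [matrix.index[i] for i in candidates[keep]]


def call_stress_responsive(
    matrix: pd.DataFrame,
    stress_library: str,
    thresholds: PegThresholds = PegThresholds(),
) -> pd.DataFrame:
    """Genes responding to stress in either direction.

    A gene qualifies iff its R statistic over all libraries is >= r_min and
    the fold change of the stress library against the mean of the organ
    libraries is >= fold_min or <= 1/fold_min.

    Returns a frame indexed by the called genes with columns ``R``, ``p``,
    ``fold`` and ``direction`` ('up' or 'down').
    """
    if stress_library not in matrix.columns:
        raise KeyError(f"unknown stress library {stress_library!r}")
    res = r_test_matrix(matrix)
    values = matrix.loc[res.index].to_numpy(dtype=float)
    libraries = list(matrix.columns)
    i = libraries.index(stress_library)
    folds = _fold_table(values)[:, i]
    up = folds >= thresholds.fold_min
    down = folds <= 1.0 / thresholds.fold_min
    hit = (res["R"].to_numpy() >= thresholds.r_min) & (up | down)
    out = pd.DataFrame(
        {
            "R": res["R"].to_numpy(),
            "p": res["p"].to_numpy(),
            "fold": folds,
            "direction": np.where(up, "up", "down"),
        },
        index=res.index,
    )
    return out.loc[hit]


def ddct(ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control):
    """Relative transcript quantity by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) in the sample minus the same
    difference in the control condition; the result is 2^-ddCt. Accepts
    scalars or equal-length arrays (one entry per assayed gene).
    """
    d = (np.asarray(ct_target_sample, dtype=float) - np.asarray(ct_ref_sample, dtype=float)) - (
        np.asarray(ct_target_control, dtype=float) - np.asarray(ct_ref_control, dtype=float)
    )
    result = np.power(2.0, -d)
    return float(result) if result.ndim == 0 else result
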