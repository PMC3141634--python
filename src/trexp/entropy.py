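"""Information-theoretic comparison of transcriptomes.

Each library j defines a frequency distribution p_ij over genes. From it we
compute, all in bits (base-2 logarithms):

* diversity H_j = -sum_i p_ij log2 p_ij — the Shannon entropy of the
  library's transcript-frequency distribution;
* gene specificity S_i = (1/t) sum_j (p_ij/pbar_i) log2 (p_ij/pbar_i),
  with pbar_i the across-library mean frequency of gene i — 0 for a gene
  expressed uniformly, log2 t for a gene private to one library;
* specialization delta_j = sum_i p_ij S_i — the expression-weighted mean
  specificity of the genes a library expresses.

A library of broadly shared housekeeping transcripts has high H and low
delta; a library dominated by private transcripts has high delta. Plotting
H_j against delta_j summarizes how similar the sampled transcriptomes are.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "expression_frequencies",
    "transcriptome_diversity",
    "gene_specificity",
    "transcriptome_specialization",
    "entropy_profile",
]


def expression_frequencies(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-library relative frequencies p_ij = x_ij / sum_i x_ij."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative expression value")
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        bad = list(matrix.columns[totals <= 0])
        raise ValueError(f"libraries with zero total expression: {bad}")
    return pd.DataFrame(values / totals, index=matrix.index, columns=matrix.columns)


def _check_freqs(freqs: pd.DataFrame) -> np.ndarray:
    p = freqs.to_numpy(dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("frequencies must lie in [0, 1]")
    if not np.allclose(p.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("every library's frequencies must sum to 1")
    return p


def transcriptome_diversity(freqs: pd.DataFrame) -> pd.Series:
    """Shannon entropy H_j (bits) of each library's frequency distribution."""
    p = _check_freqs(freqs)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p)
    terms[p == 0] = 0.0
    return pd.Series(-terms.sum(axis=0), index=freqs.columns, name="H")


def gene_specificity(freqs: pd.DataFrame) -> pd.Series:
    """Specificity S_i (bits) of each gene's expression pattern.

    Genes with zero total expression are excluded from the result.
    """
    p = _check_freqs(freqs)
    t = p.shape[1]
    pbar = p.mean(axis=1)
    expressed = pbar > 0
    ratio = p[expressed] / pbar[expressed, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = ratio * np.log2(ratio)
    terms[ratio == 0] = 0.0
    s = terms.sum(axis=1) / t
    return pd.Series(np.maximum(s, 0.0), index=freqs.index[expressed], name="S")


def transcriptome_specialization(freqs: pd.DataFrame) -> pd.Series:
    """Specialization delta_j = sum_i p_ij S_i (bits) per library."""
    s = gene_specificity(freqs)
    p = freqs.loc[s.index].to_numpy(dtype=float)
    delta = p.T @ s.to_numpy()
    return pd.Series(delta, index=freqs.columns, name="delta")


def entropy_profile(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full profile from a (normalized) count matrix.

    Returns ``(library_table, gene_table)``: per-library H and delta sorted
    descending by delta (the diversity-vs-specialization scatter layout),
    and per-gene mean frequency and specificity.
    """
    freqs = expression_frequencies(matrix)
    h = transcriptome_diversity(freqs)
    s = gene_specificity(freqs)
    delta = transcriptome_specialization(freqs)
    libs = pd.DataFrame({"H": h, "delta": delta}).sort_values(
        "delta", ascending=False
    )
    genes = pd.DataFrame(
        {"mean_frequency": freqs.loc[s.index].mean(axis=1), "S": s}
    )
    return libs, genes
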