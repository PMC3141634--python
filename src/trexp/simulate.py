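"""Synthetic data with known ground truth.

Every analysis stage in this package can be exercised without any external
sequencing data via two generators:

* :func:`simulate_count_matrix` — a gene x library count matrix sampled
  multinomially per library (library totals are fixed, mirroring the
  reads-per-library structure of tag/EST sequencing), with optional planted
  library-preferential genes at chosen fold changes and a truth table for
  benchmarking recovery. Baseline expression weights default to a
  log-normal with a heavy tail, the shape typical of transcript-abundance
  distributions.
* :func:`simulate_alignment` — nucleotide sequences evolved along a tree
  under the F81 model, optionally with one rate-accelerated terminal
  branch, for validating the distance / clustering / relative-rate chain.

Both are pure functions of their configuration (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .rates import Alignment

__all__ = [
    "CountSimConfig",
    "SeqSimConfig",
    "simulate_count_matrix",
    "simulate_alignment",
    "assign_categories",
    "random_ultrametric_tree",
]


@dataclass(frozen=True)
class CountSimConfig:
    """Settings for the multinomial count-matrix generator.

    n_genes:  number of genes (rows).
    library_labels:  distinct library names (>= 2).
    library_totals:  reads per library N_j (the multinomial totals).
    baseline_weights:  strictly positive per-gene expression weights; when
        omitted, drawn log-normally (meanlog 0, sdlog 1.5) to mimic the
        long-tailed abundance distribution of real transcriptomes.
    planted_pegs:  (gene index, focal library, fold > 1) triples; the
        gene's weight is multiplied by ``fold`` in the focal library only.
    seed:  all randomness derives from this integer.
    """

    n_genes: int
    library_labels: tuple[str, ...] = ("FlwL", "ShtL", "TrpL", "StsL")
    library_totals: tuple[int, ...] = (258_457, 234_963, 292_970, 140_507)
    baseline_weights: tuple[float, ...] | None = None
    planted_pegs: tuple[tuple[int, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.library_labels) < 2:
            raise ValueError("need at least two libraries")
        if len(set(self.library_labels)) != len(self.library_labels):
            raise ValueError("duplicate library labels")
        if len(self.library_totals) != len(self.library_labels):
            raise ValueError("one total per library required")
        if any(n < 1 for n in self.library_totals):
            raise ValueError("library totals must be positive")
        if self.baseline_weights is not None:
            if len(self.baseline_weights) != self.n_genes:
                raise ValueError("one baseline weight per gene required")
            if any(w <= 0 for w in self.baseline_weights):
                raise ValueError("baseline weights must be strictly positive")
        for gene, lib, fold in self.planted_pegs:
            if not 0 <= gene < self.n_genes:
                raise ValueError(f"planted gene index {gene} out of range")
            if lib not in self.library_labels:
                raise ValueError(f"planted library {lib!r} unknown")
            if fold <= 1:
                raise ValueError("planted folds must exceed 1")


def gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes - 1)))
    return [f"g{i:0{width}d}" for i in range(n_genes)]


def simulate_count_matrix(config: CountSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a count matrix and return it with its truth table.

    Library j is a multinomial draw of N_j reads from gene probabilities
    proportional to the baseline weights, with planted genes' weights
    multiplied by their fold in their focal library. Column sums therefore
    equal the configured totals exactly.

    Returns
    -------
    (counts, truth)
        ``counts``: genes x libraries integer frame. ``truth``: frame
        indexed like ``counts`` with columns ``label`` ('null' or
        'peg:<library>') and ``fold``.
    """
    rng = np.random.default_rng(config.seed)
    if config.baseline_weights is None:
        weights = rng.lognormal(mean=0.0, sigma=1.5, size=config.n_genes)
    else:
        weights = np.asarray(config.baseline_weights, dtype=float)

    labels = list(config.library_labels)
    probs = np.tile(weights[:, None], (1, len(labels))).astype(float)
    truth = pd.DataFrame(
        {"label": "null", "fold": 1.0}, index=gene_ids(config.n_genes)
    )
    for gene, lib, fold in config.planted_pegs:
        probs[gene, labels.index(lib)] *= fold
        truth.iloc[gene, truth.columns.get_loc("label")] = f"peg:{lib}"
        truth.iloc[gene, truth.columns.get_loc("fold")] = fold
    probs /= probs.sum(axis=0)

    counts = np.column_stack(
        [
            rng.multinomial(total, probs[:, j])
            for j, total in enumerate(config.library_totals)
        ]
    )
    matrix = pd.DataFrame(counts, index=truth.index, columns=labels)
    return matrix, truth


@dataclass(frozen=True)
class SeqSimConfig:
    """Settings for the F81 sequence simulator.

    tree:  newick string or dendropy.Tree with branch lengths in expected
        substitutions per site.
    equilibrium_frequencies:  stationary base frequencies (A, C, G, T).
    n_sites:  alignment length.
    focal_taxon / rate_scale:  multiply the focal taxon's terminal branch
        by rate_scale (>= 1) to emulate a rate-accelerated lineage.
    seed:  all randomness derives from this integer.
    """

    tree: object
    n_sites: int
    equilibrium_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    focal_taxon: str | None = None
    rate_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        pi = np.asarray(self.equilibrium_frequencies, dtype=float)
        if pi.shape != (4,) or (pi <= 0).any() or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("equilibrium frequencies must be 4 positive values summing to 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        if self.rate_scale < 1:
            raise ValueError("rate_scale must be >= 1")


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=str(tree), schema="newick", rooting="force-rooted")


def simulate_alignment(config: SeqSimConfig) -> Alignment:
    """Evolve sequences along a tree under F81.

    The root state at each site is drawn from the equilibrium frequencies;
    along each branch of length t a site keeps its parent state with
    probability exp(-beta t) and is otherwise redrawn from the equilibrium
    distribution (the exact F81 transition kernel). The focal taxon's
    terminal branch, if named, is stretched by rate_scale.
    """
    tree = _as_tree(config.tree)
    pi = np.asarray(config.equilibrium_frequencies, dtype=float)
    beta = 1.0 / (1.0 - np.sum(pi**2))
    rng = np.random.default_rng(config.seed)

    states: dict[int, np.ndarray] = {}
    leaves: list[tuple[str, np.ndarray]] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            s = rng.choice(4, size=config.n_sites, p=pi)
        else:
            t = node.edge.length
            if t is None:
                raise ValueError("every branch needs a length")
            if t < 0:
                raise ValueError("negative branch length")
            if (
                config.focal_taxon is not None
                and node.is_leaf()
                and node.taxon is not None
                and node.taxon.label == config.focal_taxon
            ):
                t = t * config.rate_scale
            s = states[id(node.parent_node)].copy()
            resample = rng.random(config.n_sites) >= np.exp(-beta * t)
            if resample.any():
                s[resample] = rng.choice(4, size=int(resample.sum()), p=pi)
        states[id(node)] = s
        if node.is_leaf():
            leaves.append((node.taxon.label, s))
    labels = [lab for lab, _ in leaves]
    codes = np.stack([s for _, s in leaves]).astype(np.uint8)
    return Alignment(labels, codes)


def random_ultrametric_tree(n_leaves: int, seed: int = 0) -> dendropy.Tree:
    """Random rooted ultrametric (clock-like) tree with distinct node heights.

    Built by successive random pair merges at strictly increasing heights,
    so all leaves are equidistant from the root and UPGMA can recover the
    tree exactly from its patristic distances.
    """
    if n_leaves < 2:
        raise ValueError("need at least two leaves")
    rng = np.random.default_rng(seed)
    labels = [f"t{i:02d}" for i in range(n_leaves)]
    clusters = [(lab, 0.0) for lab in labels]  # (newick fragment, height)
    height = 0.0
    while len(clusters) > 1:
        height += float(rng.uniform(0.05, 0.5))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (fa, ha) = clusters.pop(j)
        (fb, hb) = clusters.pop(i)
        merged = f"({fa}:{height - ha:.10f},{fb}:{height - hb:.10f})"
        clusters.append((merged, height))
    newick = clusters[0][0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")


def assign_categories(
    n_genes: int,
    categories: list[tuple[str, int]],
    enriched: tuple[str, set[str]] | None = None,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Randomly annotate genes with disjoint functional categories.

    Each category receives exactly its stated number of distinct genes.
    When ``enriched`` names a category and a gene set, those genes are
    forced into that category (a planted enrichment signal).

    Returns a gene id -> set-of-category mapping covering annotated genes.
    """
    rng = np.random.default_rng(seed)
    ids = gene_ids(n_genes)
    id_set = set(ids)
    sizes = dict(categories)
    if len(sizes) != len(categories):
        raise ValueError("duplicate category names")
    if any(s < 0 for s in sizes.values()):
        raise ValueError("category sizes must be non-negative")
    if sum(sizes.values()) > n_genes:
        raise ValueError("categories oversubscribe the gene universe")

    forced: dict[str, set[str]] = {}
    if enriched is not None:
        cat, gene_set = enriched
        if cat not in sizes:
            raise ValueError(f"enriched category {cat!r} not declared")
        unknown = sorted(set(gene_set) - id_set)
        if unknown:
            raise ValueError(f"enriched genes outside the universe: {unknown}")
        if len(gene_set) > sizes[cat]:
            raise ValueError("enriched gene set larger than its category")
        forced[cat] = set(gene_set)

    pool = [g for g in ids if not any(g in s for s in forced.values())]
    rng.shuffle(pool)
    annotation: dict[str, set[str]] = {}
    cursor = 0
    for cat, size in categories:
        members = set(forced.get(cat, set()))
        need = size - len(members)
        members.update(pool[cursor : cursor + need])
        cursor += need
        for g in members:
            annotation.setdefault(g, set()).add(cat)
    return annotation
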