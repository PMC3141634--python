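"""Lineage-specific substitution-rate analysis.

The question addressed here: does one taxon evolve measurably faster than
its relatives? The toolkit mirrors the classical diagnostic chain for
nucleotide data:

1. filter alignment columns of dubious positional homology
   (:func:`clean_alignment_blocks`, a conservation/gap block filter);
2. compute pairwise LogDet (paralinear) distances, which stay additive
   under base-composition drift between lineages
   (:func:`logdet_distance`, :func:`distance_matrix`);
3. cluster with UPGMA (:func:`upgma`). UPGMA assumes a molecular clock, so
   a rate-accelerated taxon shows up with an inflated terminal branch and
   possibly a misplaced position (:func:`terminal_branch_report`);
4. test the asymmetry formally with a likelihood relative-rate test on a
   (taxon A, taxon B, outgroup) triplet under the F81 substitution model
   (:func:`relative_rate_test`).

Sequences are held in a light :class:`Alignment` container (taxon labels +
an integer-coded site matrix); trees are `dendropy.Tree` objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Alignment",
    "DivergenceTable",
    "RelRateResult",
    "clean_alignment_blocks",
    "divergence_matrix",
    "logdet_distance",
    "distance_matrix",
    "upgma",
    "tree_to_newick",
    "terminal_branch_report",
    "f81_transition_matrix",
    "triplet_log_likelihood",
    "relative_rate_test",
]

# integer codes for alignment columns
_ALPHABET = "ACGT-N"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
GAP, AMBIG = 4, 5


class Alignment:
    """Equal-length nucleotide sequences over {A, C, G, T, -, N}.

    Stored as taxon labels plus a (taxa x sites) uint8 code matrix.
    """

    def __init__(self, labels, codes: np.ndarray):
        labels = list(labels)
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate taxon labels")
        codes = np.asarray(codes, dtype=np.uint8)
        if codes.ndim != 2 or codes.shape[0] != len(labels):
            raise ValueError("code matrix must be (n_taxa, n_sites)")
        if codes.size and codes.max() > AMBIG:
            raise ValueError("invalid residue code")
        self.labels = labels
        self.codes = codes

    @classmethod
    def from_sequences(cls, items) -> "Alignment":
        """Build from an iterable of (label, sequence-string) pairs.

        Sequences are uppercased and U is read as T; anything outside
        {A, C, G, T, -, N} is rejected.
        """
        labels, rows = [], []
        length = None
        for label, seq in items:
            seq = str(seq).upper().replace("U", "T")
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError(
                    f"sequence length mismatch for {label!r}: "
                    f"{len(seq)} != {length}"
                )
            try:
                rows.append([_CODE[c] for c in seq])
            except KeyError as exc:
                raise ValueError(
                    f"invalid character {exc.args[0]!r} in sequence {label!r}"
                ) from None
            labels.append(label)
        if not labels:
            raise ValueError("empty alignment")
        return cls(labels, np.array(rows, dtype=np.uint8))

    def sequence(self, label: str) -> str:
        i = self.labels.index(label)
        return "".join(_ALPHABET[c] for c in self.codes[i])

    def subset(self, labels) -> "Alignment":
        idx = [self.labels.index(x) for x in labels]
        return Alignment(list(labels), self.codes[idx])

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.labels == other.labels
            and np.array_equal(self.codes, other.codes)
        )


@dataclass(frozen=True)
class DivergenceTable:
    """Joint base-pair frequencies of two aligned sequences.

    F[x, y] is the fraction of (pairwise-complete) sites where the first
    sequence shows base x and the second base y; marginals are the row and
    column sums.
    """

    F: np.ndarray
    f_a: np.ndarray
    f_b: np.ndarray
    n_sites_used: int


def clean_alignment_blocks(
    aln: Alignment,
    max_gap_fraction: float = 0.0,
    min_conservation: float = 0.5,
    min_block_length: int = 10,
) -> Alignment:
    """Keep conserved, gap-poor column blocks; drop the rest.

    A column is kept when its fraction of gap/ambiguous residues is at most
    ``max_gap_fraction`` and its majority base accounts for at least
    ``min_conservation`` of the unambiguous residues. Runs of consecutive
    kept columns shorter than ``min_block_length`` are then discarded, so
    only contiguous well-aligned blocks survive. An empty result is legal
    (the caller is warned via an empty alignment, not an exception).
    """
    codes = aln.codes
    n_taxa, n_sites = codes.shape
    gapish = codes >= GAP
    gap_frac = gapish.mean(axis=0)
    base_counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])
    n_resolved = base_counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        conservation = np.where(
            n_resolved > 0, base_counts.max(axis=0) / n_resolved, 0.0
        )
    keep = (gap_frac <= max_gap_fraction) & (conservation >= min_conservation)

    # prune short runs of kept columns
    final = keep.copy()
    i = 0
    while i < n_sites:
        if keep[i]:
            j = i
            while j < n_sites and keep[j]:
                j += 1
            if j - i < min_block_length:
                final[i:j] = False
            i = j
        else:
            i += 1
    return Alignment(aln.labels, codes[:, final])


def divergence_matrix(seq_a, seq_b) -> DivergenceTable:
    """Joint base frequencies of two equal-length sequences.

    Accepts strings or uint8 code vectors. Sites where either sequence has
    a gap or N are excluded (pairwise deletion).
    """
    a = _as_codes(seq_a)
    b = _as_codes(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    ok = (a < GAP) & (b < GAP)
    n_used = int(ok.sum())
    if n_used == 0:
        raise ValueError("no pairwise-complete sites between the sequences")
    joint = np.bincount(4 * a[ok].astype(int) + b[ok].astype(int), minlength=16)
    F = joint.reshape(4, 4) / n_used
    return DivergenceTable(F=F, f_a=F.sum(axis=1), f_b=F.sum(axis=0), n_sites_used=n_used)


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return Alignment.from_sequences([("x", seq)]).codes[0]
    return np.asarray(seq, dtype=np.uint8)


def logdet_distance(table: DivergenceTable) -> float:
    """LogDet (paralinear) distance from a joint-frequency table.

    d = -(1/4) [ ln det F - (1/2) sum_x ( ln f_a(x) + ln f_b(x) ) ]

    Zero for identical sequences; robust to base-composition differences
    between the two lineages. A non-positive determinant means the pair is
    saturated and no finite distance exists.
    """
    F = table.F
    sign, logdet = np.linalg.slogdet(F)
    if sign <= 0:
        raise ValueError("saturated sequence pair: det F <= 0, LogDet undefined")
    if (table.f_a <= 0).any() or (table.f_b <= 0).any():
        raise ValueError("zero marginal base frequency, LogDet undefined")
    marg = np.log(table.f_a).sum() + np.log(table.f_b).sum()
    return float(-0.25 * (logdet - 0.5 * marg))


def distance_matrix(aln: Alignment, method: str = "logdet") -> pd.DataFrame:
    """All pairwise distances of an alignment as a labelled symmetric frame."""
    if method != "logdet":
        raise ValueError(f"unknown distance method {method!r}")
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = logdet_distance(
                    divergence_matrix(aln.codes[i], aln.codes[j])
                )
            except ValueError as exc:
                raise ValueError(
                    f"distance undefined for pair "
                    f"({aln.labels[i]!r}, {aln.labels[j]!r}): {exc}"
                ) from exc
    return pd.DataFrame(d, index=aln.labels, columns=aln.labels)


# ---------------------------------------------------------------------------
# UPGMA


def upgma(d: pd.DataFrame) -> dendropy.Tree:
    """Average-linkage (UPGMA) clustering into a rooted ultrametric tree.

    Node heights equal half the between-cluster average distance, so every
    root-to-tip path has the same length. Ties in the minimum distance are
    broken by the lexicographically smallest pair of cluster labels (a
    cluster is labelled by its smallest member), making the output
    deterministic.
    """
    labels = list(d.index)
    if list(d.columns) != labels:
        raise ValueError("distance matrix rows and columns must match")
    dist = d.to_numpy(dtype=float)
    if len(labels) < 2:
        raise ValueError("UPGMA needs at least two taxa")
    if np.isnan(dist).any() or (dist < 0).any():
        raise ValueError("distances must be finite and non-negative")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")

    # cluster state: label (smallest member), size, height, newick fragment
    clusters: dict[int, dict] = {
        i: {"label": lab, "size": 1, "height": 0.0, "newick": None, "leaf": lab}
        for i, lab in enumerate(labels)
    }
    D = {
        (i, j): dist[i, j]
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    next_id = len(labels)
    while len(clusters) > 1:
        best = min(
            D.items(),
            key=lambda kv: (
                kv[1],
                tuple(sorted((clusters[kv[0][0]]["label"], clusters[kv[0][1]]["label"]))),
            ),
        )
        (i, j), dij = best
        height = dij / 2.0
        ci, cj = clusters.pop(i), clusters.pop(j)
        children = sorted((ci, cj), key=lambda c: c["label"])
        parts = []
        for child in children:
            frag = (
                _quote_label(child["leaf"])
                if child["newick"] is None
                else child["newick"]
            )
            parts.append(f"{frag}:{float(height - child['height']):.17g}")
        merged = {
            "label": children[0]["label"],
            "size": ci["size"] + cj["size"],
            "height": height,
            "newick": "(" + ",".join(parts) + ")",
            "leaf": None,
        }
        new_D = {}
        for (a, b), val in D.items():
            if {a, b} & {i, j}:
                continue
            new_D[(a, b)] = val
        for k, ck in clusters.items():
            dik = D.get((min(i, k), max(i, k)))
            djk = D.get((min(j, k), max(j, k)))
            new_D[(min(k, next_id), max(k, next_id))] = (
                ci["size"] * dik + cj["size"] * djk
            ) / (ci["size"] + cj["size"])
        clusters[next_id] = merged
        D = new_D
        next_id += 1

    root = next(iter(clusters.values()))
    newick = (root["newick"] or _quote_label(root["leaf"])) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    return tree


def _quote_label(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def tree_to_newick(tree: dendropy.Tree, precision: int = 6) -> str:
    """Deterministic newick string: lexicographic child order, fixed-width
    branch lengths, quoted labels where needed."""

    def min_leaf(node) -> str:
        if node.is_leaf():
            return node.taxon.label if node.taxon else (node.label or "")
        return min(min_leaf(c) for c in node.child_nodes())

    def render(node) -> str:
        if node.is_leaf():
            body = _quote_label(node.taxon.label if node.taxon else (node.label or ""))
        else:
            kids = sorted(node.child_nodes(), key=min_leaf)
            body = "(" + ",".join(render(c) for c in kids) + ")"
        if node.edge.length is not None and node.parent_node is not None:
            body += f":{node.edge.length:.{precision}f}"
        return body

    return render(tree.seed_node) + ";"


def terminal_branch_report(tree: dendropy.Tree) -> pd.DataFrame:
    """Rank taxa by terminal branch length (and root-to-tip distance).

    Long terminal branches on a clock tree flag rate-accelerated lineages.
    Returns a frame indexed by taxon, sorted by descending terminal branch
    length with the taxon label as tie-break.
    """
    rows = []
    for leaf in tree.leaf_node_iter():
        if leaf.edge.length is None:
            raise ValueError(f"missing branch length above {leaf.taxon.label!r}")
        depth = 0.0
        node = leaf
        while node.parent_node is not None:
            if node.edge.length is None:
                raise ValueError("missing internal branch length")
            depth += node.edge.length
            node = node.parent_node
        rows.append((leaf.taxon.label, float(leaf.edge.length), depth))
    out = pd.DataFrame(
        rows, columns=["taxon", "terminal_branch", "root_to_tip"]
    ).set_index("taxon")
    # tie-break on taxon label: sort labels first, then stable-sort lengths
    out = out.sort_index()
    return out.sort_values("terminal_branch", ascending=False, kind="stable")


# ---------------------------------------------------------------------------
# F81 likelihood machinery


def f81_transition_matrix(t: float, pi) -> np.ndarray:
    """F81 transition probabilities P(t) for branch length t (subst/site).

    With beta = 1 / (1 - sum pi^2), P_xy(t) = exp(-beta t) [x == y]
    + (1 - exp(-beta t)) pi_y. Branch lengths are in expected
    substitutions per site.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (4,) or (pi <= 0).any() or abs(pi.sum() - 1) > 1e-8:
        raise ValueError("pi must be four positive frequencies summing to 1")
    if t < 0:
        raise ValueError("branch length must be non-negative")
    beta = 1.0 / (1.0 - np.sum(pi**2))
    decay = np.exp(-beta * t)
    return decay * np.eye(4) + (1.0 - decay) * pi[None, :]


def _pattern_counts(aln: Alignment) -> np.ndarray:
    """64-bin counts of ungapped 3-taxon site patterns."""
    if aln.n_taxa != 3:
        raise ValueError("triplet likelihood needs exactly three sequences")
    c = aln.codes.astype(int)
    ok = (c < GAP).all(axis=0)
    if not ok.any():
        raise ValueError("no ungapped sites in the triplet alignment")
    idx = 16 * c[0, ok] + 4 * c[1, ok] + c[2, ok]
    return np.bincount(idx, minlength=64)


def triplet_log_likelihood(
    aln: Alignment, a: float, b: float, c: float, pi
) -> float:
    """Log-likelihood of a 3-taxon star tree under F81.

    The three sequences hang off a single internal node with branch
    lengths (a, b, c) in the alignment's taxon order; the internal state
    is summed out against the stationary distribution pi. Sites containing
    gaps or N are excluded.
    """
    counts = _pattern_counts(aln)
    Pa = f81_transition_matrix(a, pi)
    Pb = f81_transition_matrix(b, pi)
    Pc = f81_transition_matrix(c, pi)
    pi = np.asarray(pi, dtype=float)
    site_lik = np.einsum("s,si,sj,sk->ijk", pi, Pa, Pb, Pc).reshape(64)
    nz = counts > 0
    return float(np.sum(counts[nz] * np.log(site_lik[nz])))


@dataclass(frozen=True)
class RelRateResult:
    """Outcome of a likelihood relative-rate test.

    a_hat/b_hat/c_hat are the freely estimated branch lengths to taxon A,
    taxon B and the outgroup; shared_hat/c_constrained_hat the clock fit
    with a = b. The LRT statistic 2(lnL_free - lnL_constrained) is referred
    to chi-square with 1 df; rate_ratio = a_hat / b_hat.
    """

    taxon_a: str
    taxon_b: str
    outgroup: str
    a_hat: float
    b_hat: float
    c_hat: float
    shared_hat: float
    c_constrained_hat: float
    lnl_free: float
    lnl_constrained: float
    lrt: float
    p_value: float
    rate_ratio: float


_BOUNDS = (0.0, 10.0)
_STARTS_FREE = [(0.05, 0.05, 0.05), (0.2, 0.2, 0.2), (0.5, 0.5, 0.5), (0.1, 0.1, 0.4)]
_STARTS_CONSTRAINED = [(0.05, 0.05), (0.2, 0.2), (0.5, 0.5), (0.1, 0.4)]


def _maximize(counts_aln: Alignment, pi, constrained: bool) -> tuple[np.ndarray, float]:
    counts = _pattern_counts(counts_aln)
    pi = np.asarray(pi, dtype=float)

    def neg_lnl(params):
        if constrained:
            a = b = params[0]
            c = params[1]
        else:
            a, b, c = params
        Pa = f81_transition_matrix(a, pi)
        Pb = f81_transition_matrix(b, pi)
        Pc = f81_transition_matrix(c, pi)
        site_lik = np.einsum("s,si,sj,sk->ijk", pi, Pa, Pb, Pc).reshape(64)
        nz = counts > 0
        return -float(np.sum(counts[nz] * np.log(np.maximum(site_lik[nz], 1e-300))))

    starts = _STARTS_CONSTRAINED if constrained else _STARTS_FREE
    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg_lnl,
            np.array(x0),
            method="L-BFGS-B",
            bounds=[_BOUNDS] * len(x0),
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("branch-length optimization failed to converge")
    return best.x, -best.fun


def empirical_base_frequencies(aln: Alignment) -> np.ndarray:
    """Mean A/C/G/T frequencies over all sequences, ignoring gaps and N."""
    c = aln.codes
    counts = np.stack([(c == b).sum(axis=1) for b in range(4)], axis=1).astype(float)
    per_seq = counts / counts.sum(axis=1, keepdims=True)
    pi = per_seq.mean(axis=0)
    # keep strictly positive frequencies for the F81 machinery
    pi = np.maximum(pi, 1e-6)
    return pi / pi.sum()


def relative_rate_test(
    aln: Alignment, taxon_a: str, taxon_b: str, outgroup: str
) -> RelRateResult:
    """Likelihood relative-rate test of taxon A vs taxon B given an outgroup.

    Fits the 3-taxon F81 star tree freely and under the clock constraint
    a = b (equal root-to-tip paths for the two ingroup taxa); twice the
    log-likelihood difference is referred to chi-square with one degree of
    freedom. Equilibrium frequencies are fixed at the empirical mean base
    composition of the three sequences.
    """
    for name in (taxon_a, taxon_b, outgroup):
        if name not in aln.labels:
            raise KeyError(f"taxon {name!r} not in alignment")
    trip = aln.subset([taxon_a, taxon_b, outgroup])
    pi = empirical_base_frequencies(trip)
    free_x, lnl_free = _maximize(trip, pi, constrained=False)
    con_x, lnl_con = _maximize(trip, pi, constrained=True)
    lrt = 2.0 * (lnl_free - lnl_con)
    if lrt < -1e-6:
        raise RuntimeError(
            f"constrained likelihood exceeded free likelihood (LRT={lrt:.3g})"
        )
    lrt = max(lrt, 0.0)
    a_hat, b_hat, c_hat = (float(v) for v in free_x)
    ratio = float("inf") if b_hat == 0 else a_hat / b_hat
    return RelRateResult(
        taxon_a=taxon_a,
        taxon_b=taxon_b,
        outgroup=outgroup,
        a_hat=a_hat,
        b_hat=b_hat,
        c_hat=c_hat,
        shared_hat=float(con_x[0]),
        c_constrained_hat=float(con_x[1]),
        lnl_free=lnl_free,
        lnl_constrained=lnl_con,
        lrt=lrt,
        p_value=float(stats.chi2.sf(lrt, 1)),
        rate_ratio=ratio,
    )
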