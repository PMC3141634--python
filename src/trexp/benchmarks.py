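"""Seeded validation benchmarks on synthetic data with known truth.

Each function runs one end-to-end check of a pipeline stage under the
package's reference study conditions — four libraries at tag-sequencing
scale for the count analyses, F81 simulations for the rate analyses — and
returns the measured quantity (an error rate, a sensitivity, a recovery
fraction). They are used by the test suite and by ``scripts/acceptance.py``;
all randomness derives from the ``seed`` argument.

Study conditions, chosen once:

* null calibration: 2,000 null multinomial genes, 4 libraries of 10^4 reads;
* PEG recovery: 2,000 genes at an expected baseline of 25 reads/library
  (4 libraries of 5x10^4 reads), 100 planted 4-fold preferential genes;
  library totals are equal by construction, so the R test runs on the raw
  draws (depth normalization would be an exact no-op);
* LogDet consistency: sequence pairs at t = 0.1 substitutions/site,
  10^5 sites;
* relative-rate calibration: 10 kb triplets with a = b = 0.05, c = 0.1
  (clock) and a = 0.15 (3x acceleration);
* end-to-end rate pipeline: a 5-taxon clock tree, 5 kb alignments, one
  terminal branch accelerated 3x;
* specialization: 100 of 2,000 genes planted with a 50-fold preference in
  one library, making them nearly private to it.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import hypergeom_tail
from .entropy import entropy_profile, expression_frequencies, transcriptome_specialization
from .normalize import quantile_normalize
from .rates import (
    Alignment,
    distance_matrix,
    divergence_matrix,
    f81_transition_matrix,
    logdet_distance,
    relative_rate_test,
    terminal_branch_report,
    triplet_log_likelihood,
    upgma,
)
from .rtest import call_pegs, r_test_matrix
from .simulate import (
    CountSimConfig,
    SeqSimConfig,
    random_ultrametric_tree,
    simulate_alignment,
    simulate_count_matrix,
)

__all__ = [
    "null_type_one_rate",
    "peg_recovery",
    "quantile_normalization_check",
    "entropy_oracle_deviation",
    "hypergeometric_enumeration_error",
    "logdet_hand_example",
    "logdet_f81_consistency",
    "upgma_recovery_rate",
    "triplet_likelihood_oracle_error",
    "relrate_type_one_rate",
    "relrate_power",
    "specialized_library_top_rate",
    "accelerated_taxon_detection",
]

_FOUR_LIBS = ("FlwL", "ShtL", "TrpL", "StsL")


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def null_type_one_rate(
    seed: int, n_genes: int = 2000, library_total: int = 10_000
) -> dict:
    """Fraction of null genes with 2R above the chi-square(3) 0.95 quantile.

    Genes draw their baseline abundance from the generator's default
    log-normal, but every gene keeps the same expected proportion in all
    four libraries, so rejections are pure type-I errors; the fraction
    should sit near 0.05. Genes sampled to zero in every library carry no
    information and are dropped by the R test.
    """
    cfg = CountSimConfig(
        n_genes=n_genes,
        library_labels=_FOUR_LIBS,
        library_totals=(library_total,) * 4,
        seed=seed,
    )
    matrix, _ = simulate_count_matrix(cfg)
    res = r_test_matrix(matrix.astype(float))
    crit = stats.chi2.ppf(0.95, 3)
    return {"rate": float((2.0 * res["R"] > crit).mean()), "n": len(res)}


def peg_recovery(
    seed: int,
    n_genes: int = 2000,
    n_planted: int = 100,
    fold: float = 4.0,
    baseline_expected: float = 25.0,
) -> dict:
    """Sensitivity and false-positive rate of PEG calling on planted truth."""
    total = int(n_genes * baseline_expected)
    cfg = CountSimConfig(
        n_genes=n_genes,
        library_labels=_FOUR_LIBS,
        library_totals=(total,) * 4,
        baseline_weights=(1.0,) * n_genes,
        planted_pegs=tuple((i, "TrpL", fold) for i in range(n_planted)),
        seed=seed,
    )
    matrix, truth = simulate_count_matrix(cfg)
    pegs = call_pegs(matrix.astype(float))
    planted = set(truth.index[truth["label"] == "peg:TrpL"])
    called_focal = set(pegs.index[pegs["library"] == "TrpL"])
    sensitivity = len(planted & called_focal) / n_planted
    false_pos = len(set(pegs.index) - planted) / (n_genes - n_planted)
    return {"sensitivity": sensitivity, "false_positive_rate": false_pos, "n": n_genes}


def quantile_normalization_check(seed: int, n_genes: int = 500) -> dict:
    """Distribution equality and idempotence on a tie-free random matrix.

    Returns the largest deviation between sorted library columns after
    normalization and the largest change a second normalization pass makes.
    """
    rng = np.random.default_rng(seed)
    matrix = pd.DataFrame(
        rng.lognormal(0.0, 1.5, size=(n_genes, 4)),
        index=[f"g{i:04d}" for i in range(n_genes)],
        columns=_FOUR_LIBS,
    )
    once = quantile_normalize(matrix)
    sorted_cols = np.sort(once.to_numpy(), axis=0)
    dist_dev = float(np.abs(sorted_cols - sorted_cols[:, [0]]).max())
    twice = quantile_normalize(once)
    idem_dev = float(np.abs(twice.to_numpy() - once.to_numpy()).max())
    return {"sorted_column_deviation": dist_dev, "idempotence_deviation": idem_dev, "n": n_genes}


def entropy_oracle_deviation(seed: int, n_matrices: int = 100) -> dict:
    """Max |delta_j - brute-force double loop| over random small matrices."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        n_genes = int(rng.integers(5, 50))
        t = int(rng.integers(2, 6))
        matrix = pd.DataFrame(
            rng.lognormal(0.0, 1.0, size=(n_genes, t)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"L{j}" for j in range(t)],
        )
        freqs = expression_frequencies(matrix)
        got = transcriptome_specialization(freqs).to_numpy()
        p = freqs.to_numpy()
        s = np.zeros(n_genes)
        for i in range(n_genes):
            pbar = p[i].mean()
            for j in range(t):
                r = p[i, j] / pbar
                if r > 0:
                    s[i] += r * math.log2(r) / t
        want = np.array(
            [sum(p[i, j] * s[i] for i in range(n_genes)) for j in range(t)]
        )
        worst = max(worst, float(np.abs(got - want).max()))
    return {"max_abs_deviation": worst, "n": n_matrices}


def hypergeometric_enumeration_error(max_N: int = 60) -> dict:
    """Worst relative error of the tail against exact integer enumeration.

    Every (N, K, n, k) with N <= max_N is checked; the enumeration sums
    binomial products in exact integer arithmetic.
    """
    worst = 0.0
    checked = 0
    for N in range(1, max_N + 1):
        comb_total = math.comb
        for K in range(0, N + 1):
            for n in range(0, N + 1):
                total = comb_total(N, n)
                upper = min(K, n)
                lo = max(0, n - (N - K))
                # suffix sums of the exact point masses (integer arithmetic)
                tail_int = 0
                tails = [0] * (upper + 1)
                for j in range(upper, lo - 1, -1):
                    tail_int += comb_total(K, j) * comb_total(N - K, n - j)
                    tails[j] = tail_int
                for j in range(lo - 1, -1, -1):
                    tails[j] = tail_int  # below the support the tail is 1
                for k in range(0, upper + 1):
                    exact = tails[k] / total
                    got = hypergeom_tail(N, K, n, k)
                    checked += 1
                    if exact > 0:
                        worst = max(worst, abs(got - exact) / exact)
    return {"max_relative_error": worst, "n": checked}


def logdet_hand_example() -> dict:
    """LogDet of the joint table with diagonal 0.22 and off-diagonal 0.01."""
    from .rates import DivergenceTable

    F = np.full((4, 4), 0.01)
    np.fill_diagonal(F, 0.22)
    table = DivergenceTable(F=F, f_a=F.sum(1), f_b=F.sum(0), n_sites_used=10_000)
    return {"distance": logdet_distance(table), "n": 1}


def logdet_f81_consistency(
    seed: int, n_reps: int = 100, t: float = 0.1, n_sites: int = 100_000
) -> dict:
    """Mean estimated LogDet distance over F81 pairs at true separation t."""
    estimates = []
    for s in _child_seeds(seed, n_reps):
        aln = simulate_alignment(
            SeqSimConfig(tree=f"(A:{t / 2},B:{t / 2});", n_sites=n_sites, seed=int(s))
        )
        estimates.append(
            logdet_distance(divergence_matrix(aln.codes[0], aln.codes[1]))
        )
    return {
        "mean_distance": float(np.mean(estimates)),
        "true_distance": t,
        "n": n_reps,
    }


def _patristic(tree) -> pd.DataFrame:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda x: x.label)
    labels = [x.label for x in taxa]
    d = np.array([[pdm.patristic_distance(a, b) for b in taxa] for a in taxa])
    return pd.DataFrame(d, index=labels, columns=labels)


def upgma_recovery_rate(seed: int, n_trees: int = 100, max_leaves: int = 16) -> dict:
    """Fraction of random ultrametric trees recovered exactly by UPGMA.

    Recovery = patristic distance matrices agree to 1e-8 (equivalent to
    identical topology and node heights for ultrametric trees).
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for s in _child_seeds(seed, n_trees):
        n_leaves = int(rng.integers(4, max_leaves + 1))
        tree = random_ultrametric_tree(n_leaves, seed=int(s))
        d = _patristic(tree)
        recovered = upgma(d)
        d2 = _patristic(recovered).loc[d.index, d.columns]
        hits += bool(np.allclose(d2.to_numpy(), d.to_numpy(), atol=1e-8))
    return {"recovery_rate": hits / n_trees, "n": n_trees}


def triplet_likelihood_oracle_error(seed: int, n_cases: int = 20) -> dict:
    """Max |lnL - brute-force internal-state enumeration| on random triplets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        codes = rng.integers(0, 4, (3, 50)).astype(np.uint8)
        aln = Alignment(["x", "y", "z"], codes)
        pi = rng.dirichlet([5.0] * 4)
        a, b, c = rng.uniform(0.01, 0.5, 3)
        got = triplet_log_likelihood(aln, a, b, c, pi)
        Ps = [f81_transition_matrix(x, pi) for x in (a, b, c)]
        want = 0.0
        for site in range(50):
            lik = sum(
                pi[s]
                * Ps[0][s, codes[0, site]]
                * Ps[1][s, codes[1, site]]
                * Ps[2][s, codes[2, site]]
                for s in range(4)
            )
            want += math.log(lik)
        worst = max(worst, abs(got - want))
    return {"max_abs_error": worst, "n": n_cases}


def _relrate_replicate(a: float, b: float, c: float, n_sites: int, seed: int):
    aln = simulate_alignment(
        SeqSimConfig(
            tree=f"((A:{a},B:{b}):0.0,O:{c});", n_sites=n_sites, seed=seed
        )
    )
    return relative_rate_test(aln, "A", "B", "O")


def relrate_type_one_rate(
    seed: int, n_reps: int = 200, rate: float = 0.05, out: float = 0.1, n_sites: int = 10_000
) -> dict:
    """Rejection rate at alpha = 0.05 under a strict clock (a = b)."""
    hits = 0
    for s in _child_seeds(seed, n_reps):
        hits += _relrate_replicate(rate, rate, out, n_sites, int(s)).p_value < 0.05
    return {"rate": hits / n_reps, "n": n_reps}


def relrate_power(
    seed: int,
    n_reps: int = 100,
    a: float = 0.15,
    b: float = 0.05,
    c: float = 0.1,
    n_sites: int = 10_000,
) -> dict:
    """Power at the strict p < 0.001 level and mean rate-ratio recovery
    under a 3x terminal acceleration."""
    hits = 0
    ratios = []
    for s in _child_seeds(seed, n_reps):
        res = _relrate_replicate(a, b, c, n_sites, int(s))
        hits += res.p_value < 0.001
        ratios.append(res.rate_ratio)
    return {
        "power": hits / n_reps,
        "mean_rate_ratio": float(np.mean(ratios)),
        "true_rate_ratio": a / b,
        "n": n_reps,
    }


def specialized_library_top_rate(
    seed: int, n_runs: int = 100, n_genes: int = 2000, n_private: int = 100
) -> dict:
    """How often a library with planted near-private genes tops delta_j."""
    hits = 0
    for s in _child_seeds(seed, n_runs):
        cfg = CountSimConfig(
            n_genes=n_genes,
            library_labels=_FOUR_LIBS,
            library_totals=(100_000,) * 4,
            planted_pegs=tuple((i, "TrpL", 50.0) for i in range(n_private)),
            seed=int(s),
        )
        matrix, _ = simulate_count_matrix(cfg)
        libs, _ = entropy_profile(matrix.astype(float))
        hits += libs.index[0] == "TrpL"
    return {"rate": hits / n_runs, "n": n_runs}


# clock tree for the accelerated-taxon pipeline: the focal lineage branches
# alone below the outgroup split, so once accelerated it clusters last and
# its UPGMA terminal branch exceeds everyone's
_ACCEL_TREE = "(((Sis:0.03,Cou:0.03):0.03,Acc:0.06):0.04,Out:0.10);"


def accelerated_taxon_detection(
    seed: int, n_runs: int = 100, rate_scale: float = 3.0, n_sites: int = 5000
) -> dict:
    """Detection rates for a 3x-accelerated taxon on a 5-taxon clock tree.

    Measures how often the accelerated taxon (a) carries the longest
    terminal branch of the LogDet/UPGMA tree and (b) is flagged at
    p < 0.05 by the relative-rate test against its sister with a close
    outgroup.
    """
    upgma_hits = 0
    relrate_hits = 0
    for s in _child_seeds(seed, n_runs):
        aln = simulate_alignment(
            SeqSimConfig(
                tree=_ACCEL_TREE,
                n_sites=n_sites,
                focal_taxon="Acc",
                rate_scale=rate_scale,
                seed=int(s),
            )
        )
        tree = upgma(distance_matrix(aln))
        upgma_hits += terminal_branch_report(tree).index[0] == "Acc"
        res = relative_rate_test(aln, "Acc", "Sis", "Cou")
        relrate_hits += res.p_value < 0.05
    return {
        "upgma_longest_branch_rate": upgma_hits / n_runs,
        "relrate_detection_rate": relrate_hits / n_runs,
        "n": n_runs,
    }
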