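import math

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from trexp import (
    Alignment,
    SeqSimConfig,
    clean_alignment_blocks,
    distance_matrix,
    divergence_matrix,
    f81_transition_matrix,
    logdet_distance,
    random_ultrametric_tree,
    relative_rate_test,
    simulate_alignment,
    terminal_branch_report,
    tree_to_newick,
    triplet_log_likelihood,
    upgma,
)
from trexp.rates import DivergenceTable


def aln(*pairs):
    return Alignment.from_sequences(pairs)


def patristic_frame(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    d = np.array([[pdm.patristic_distance(a, b) for b in taxa] for a in taxa])
    return pd.DataFrame(d, index=labels, columns=labels)


class TestAlignment:
    def test_mixed_case_and_rna_normalized(self):
        a = aln(("x", "acgu"), ("y", "ACGT"))
        assert a.sequence("x") == "ACGT"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            aln(("x", "ACGT"), ("y", "ACG"))

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError, match="invalid character"):
            aln(("x", "ACGX"))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            aln(("x", "ACGT"), ("x", "ACGT"))


class TestCleanAlignmentBlocks:
    def test_conserved_gapfree_alignment_unchanged(self):
        a = aln(("x", "ACGT" * 5), ("y", "ACGT" * 5), ("z", "ACGT" * 5))
        out = clean_alignment_blocks(a, min_block_length=1)
        assert out == a

    def test_any_gap_column_removed_at_zero_tolerance(self):
        a = aln(("x", "A-AAAAAAAAAA"), ("y", "AAAAAAAAAAAA"))
        out = clean_alignment_blocks(a, max_gap_fraction=0.0, min_block_length=1)
        assert out.n_sites == 11

    def test_short_kept_runs_dropped(self):
        # 9 clean columns between two gap columns vanish at block length 10
        seq_x = "A" * 9 + "-" + "A" * 9 + "-" + "A" * 12
        seq_y = "A" * 9 + "A" + "A" * 9 + "A" + "A" * 12
        a = aln(("x", seq_x), ("y", seq_y))
        out = clean_alignment_blocks(a, min_block_length=10)
        assert out.n_sites == 12

    def test_unconserved_columns_removed(self):
        cols = ["AAAA", "ACGT", "AAAA"]  # middle column: majority 1/4 < 0.5
        seqs = ["".join(c[i] for c in cols) * 10 for i in range(4)]
        a = Alignment.from_sequences([(f"s{i}", s) for i, s in enumerate(seqs)])
        out = clean_alignment_blocks(a, min_block_length=1)
        assert out.n_sites == 20

    def test_empty_result_is_legal(self):
        a = aln(("x", "----"), ("y", "AAAA"))
        out = clean_alignment_blocks(a)
        assert out.n_sites == 0


class TestDivergence:
    def test_identical_sequences_diagonal(self):
        t = divergence_matrix("ACGT", "ACGT")
        np.testing.assert_allclose(np.diag(t.F), 0.25)
        assert t.F.sum() == pytest.approx(1.0)

    def test_single_mismatch_counts(self):
        t = divergence_matrix("AAAA", "AAAC")
        assert t.F[0, 0] == pytest.approx(0.75)
        assert t.F[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion(self):
        t = divergence_matrix("AA-A", "AAAA")
        assert t.n_sites_used == 3

    def test_no_shared_sites_rejected(self):
        with pytest.raises(ValueError, match="pairwise-complete"):
            divergence_matrix("--", "AA")


class TestLogDet:
    def test_zero_on_identical_equal_composition(self):
        assert logdet_distance(divergence_matrix("ACGT" * 10, "ACGT" * 10)) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_hand_computed_table(self):
        F = np.full((4, 4), 0.01)
        np.fill_diagonal(F, 0.22)
        t = DivergenceTable(F=F, f_a=F.sum(1), f_b=F.sum(0), n_sites_used=10000)
        # det F = 0.25 * 0.21^3; marginals all 0.25
        expected = -0.25 * (
            math.log(0.25 * 0.21**3) - 0.5 * 8 * math.log(0.25)
        )
        assert logdet_distance(t) == pytest.approx(expected, rel=1e-12)
        assert logdet_distance(t) == pytest.approx(0.13075, abs=1e-4)

    def test_consistency_on_f81_simulation(self):
        cfg = SeqSimConfig(tree="(A:0.05,B:0.05);", n_sites=100_000, seed=42)
        a = simulate_alignment(cfg)
        d = logdet_distance(divergence_matrix(a.codes[0], a.codes[1]))
        assert d == pytest.approx(0.1, abs=0.01)

    def test_saturation_rejected(self):
        F = np.full((4, 4), 1 / 16)  # rank-one: det = 0
        t = DivergenceTable(F=F, f_a=F.sum(1), f_b=F.sum(0), n_sites_used=100)
        with pytest.raises(ValueError, match="saturated"):
            logdet_distance(t)


class TestDistanceMatrix:
    def test_identical_triplicates_zero(self):
        a = aln(("x", "ACGT" * 5), ("y", "ACGT" * 5), ("z", "ACGT" * 5))
        d = distance_matrix(a)
        np.testing.assert_allclose(d.to_numpy(), 0.0, atol=1e-12)

    def test_symmetric_on_simulated_alignment(self):
        tree = "(((A:0.04,B:0.04):0.04,(C:0.05,D:0.03):0.05):0.02,(E:0.06,F:0.06):0.04);"
        a = simulate_alignment(SeqSimConfig(tree=tree, n_sites=4000, seed=2))
        d = distance_matrix(a)
        np.testing.assert_allclose(d.to_numpy(), d.to_numpy().T, atol=1e-12)
        assert (np.diag(d.to_numpy()) == 0).all()

    def test_saturated_pair_named(self):
        # two maximally divergent "sequences" force a saturation error
        a = aln(("pp", "AAAACCCCGGGGTTTT"), ("qq", "CCCCGGGGTTTTAAAA"))
        with pytest.raises(ValueError, match="pp.*qq"):
            distance_matrix(a)


class TestUpgma:
    def test_three_taxon_hand_example(self):
        d = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]],
            index=list("ABC"),
            columns=list("ABC"),
            dtype=float,
        )
        assert tree_to_newick(upgma(d)) == "((A:1.000000,B:1.000000):1.000000,C:2.000000);"

    def test_ultrametric_input_recovered_exactly(self):
        for seed in range(5):
            tree = random_ultrametric_tree(int(5 + 2 * seed), seed=seed)
            d = patristic_frame(tree)
            recovered = upgma(d)
            d2 = patristic_frame(recovered)
            np.testing.assert_allclose(
                d2.loc[d.index, d.columns].to_numpy(), d.to_numpy(), atol=1e-8
            )

    def test_matches_scipy_average_linkage_heights(self, rng):
        # independent oracle: cophenetic distances of scipy's UPGMA
        n = 7
        coords = rng.normal(size=(n, 3))
        dist = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(n)]
        d = pd.DataFrame(dist, index=labels, columns=labels)
        tree = upgma(d)
        mine = patristic_frame(tree)
        Z = hierarchy.average(squareform(dist, checks=False))
        coph = squareform(hierarchy.cophenet(Z))
        ref = pd.DataFrame(coph, index=labels, columns=labels)
        np.testing.assert_allclose(
            mine.loc[labels, labels].to_numpy(), ref.to_numpy(), atol=1e-9
        )

    def test_equal_distances_tie_break_is_deterministic(self):
        labels = list("DCBA")
        d = pd.DataFrame(1.0 - np.eye(4), index=labels, columns=labels)
        newick = tree_to_newick(upgma(d))
        assert newick == tree_to_newick(upgma(d))
        # first merge is the lexicographically smallest pair (A, B)
        assert "(A:0.500000,B:0.500000)" in newick

    def test_ultrametric_output(self, rng):
        n = 8
        dist = rng.uniform(1, 5, size=(n, n))
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0.0)
        labels = [f"t{i}" for i in range(n)]
        tree = upgma(pd.DataFrame(dist, index=labels, columns=labels))
        report = terminal_branch_report(tree)
        depths = report["root_to_tip"]
        np.testing.assert_allclose(depths, depths.iloc[0], atol=1e-9)

    def test_invalid_distances_rejected(self):
        d = pd.DataFrame(
            [[0, np.nan], [np.nan, 0]], index=list("AB"), columns=list("AB")
        )
        with pytest.raises(ValueError):
            upgma(d)


class TestTerminalBranchReport:
    def test_scaled_branch_ranks_first(self):
        tree = dendropy.Tree.get(
            data="((A:0.3,B:0.1):0.1,(C:0.1,D:0.1):0.1);", schema="newick"
        )
        report = terminal_branch_report(tree)
        assert report.index[0] == "A"
        assert report.loc["A", "terminal_branch"] == pytest.approx(0.3)

    def test_stable_under_relabeling(self):
        t1 = dendropy.Tree.get(data="((A:0.3,B:0.1):0.1,C:0.2);", schema="newick")
        t2 = dendropy.Tree.get(data="((Z:0.3,B:0.1):0.1,C:0.2);", schema="newick")
        r1 = terminal_branch_report(t1)
        r2 = terminal_branch_report(t2)
        assert list(r1["terminal_branch"]) == list(r2["terminal_branch"])

    def test_missing_length_rejected(self):
        tree = dendropy.Tree.get(data="((A:0.3,B),C:0.2);", schema="newick")
        with pytest.raises(ValueError):
            terminal_branch_report(tree)


class TestF81:
    def test_zero_time_is_identity(self):
        np.testing.assert_allclose(
            f81_transition_matrix(0.0, [0.1, 0.2, 0.3, 0.4]), np.eye(4), atol=1e-15
        )

    def test_long_time_reaches_stationarity(self):
        pi = np.array([0.1, 0.2, 0.3, 0.4])
        P = f81_transition_matrix(100.0, pi)
        np.testing.assert_allclose(P, np.tile(pi, (4, 1)), atol=1e-12)

    def test_uniform_pi_closed_form(self):
        P = f81_transition_matrix(0.1, [0.25] * 4)
        decay = math.exp(-4 / 3 * 0.1)
        assert P[0, 0] == pytest.approx(decay + (1 - decay) / 4, rel=1e-12)
        assert P[0, 1] == pytest.approx((1 - decay) / 4, rel=1e-12)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            f81_transition_matrix(-0.1, [0.25] * 4)


class TestTripletLikelihood:
    def brute_force(self, a3, a, b, c, pi):
        Ps = [f81_transition_matrix(t, pi) for t in (a, b, c)]
        total = 0.0
        for s in range(a3.n_sites):
            lik = sum(
                pi[x]
                * Ps[0][x, a3.codes[0, s]]
                * Ps[1][x, a3.codes[1, s]]
                * Ps[2][x, a3.codes[2, s]]
                for x in range(4)
            )
            total += math.log(lik)
        return total

    def test_degenerate_zero_lengths(self):
        a3 = aln(("x", "ACGT"), ("y", "ACGT"), ("z", "ACGT"))
        pi = [0.1, 0.2, 0.3, 0.4]
        expected = sum(math.log(pi[c]) for c in (0, 1, 2, 3))
        assert triplet_log_likelihood(a3, 0, 0, 0, pi) == pytest.approx(expected)

    def test_label_permutation_symmetry(self, rng):
        codes = rng.integers(0, 4, (3, 80)).astype(np.uint8)
        pi = [0.3, 0.2, 0.2, 0.3]
        a3 = Alignment(list("xyz"), codes)
        swapped = Alignment(list("xyz"), codes[[1, 0, 2]])
        assert triplet_log_likelihood(a3, 0.1, 0.2, 0.3, pi) == pytest.approx(
            triplet_log_likelihood(swapped, 0.2, 0.1, 0.3, pi), rel=1e-12
        )

    def test_matches_enumeration_oracle(self, rng):
        pi = [0.15, 0.35, 0.3, 0.2]
        for _ in range(5):
            codes = rng.integers(0, 4, (3, 50)).astype(np.uint8)
            a3 = Alignment(list("xyz"), codes)
            a, b, c = rng.uniform(0.01, 0.5, 3)
            assert triplet_log_likelihood(a3, a, b, c, pi) == pytest.approx(
                self.brute_force(a3, a, b, c, pi), abs=1e-10
            )

    def test_gapped_sites_excluded(self):
        a3 = aln(("x", "AC-T"), ("y", "ACGT"), ("z", "ACNT"))
        full = aln(("x", "ACT"), ("y", "ACT"), ("z", "ACT"))
        pi = [0.25] * 4
        assert triplet_log_likelihood(a3, 0.1, 0.1, 0.1, pi) == pytest.approx(
            triplet_log_likelihood(full, 0.1, 0.1, 0.1, pi)
        )


class TestRelativeRate:
    def test_identical_ingroup_sequences_give_null_result(self):
        seq = "ACGTTGCAACGT" * 20
        other = "ACGTTGCAACGT" * 10 + "TGCAACGTACGT" * 10
        a3 = aln(("A", seq), ("B", seq), ("O", other))
        res = relative_rate_test(a3, "A", "B", "O")
        assert res.lrt == pytest.approx(0.0, abs=1e-6)
        assert res.p_value > 0.99

    def test_branch_length_recovery_on_long_alignment(self):
        cfg = SeqSimConfig(
            tree="((A:0.15,B:0.05):0.0,O:0.1);", n_sites=100_000, seed=7
        )
        a3 = simulate_alignment(cfg)
        res = relative_rate_test(a3, "A", "B", "O")
        assert res.a_hat == pytest.approx(0.15, abs=0.01)
        assert res.b_hat == pytest.approx(0.05, abs=0.01)
        assert res.c_hat == pytest.approx(0.1, abs=0.01)
        assert res.p_value < 1e-6

    def test_missing_taxon_rejected(self):
        a3 = aln(("A", "ACGT"), ("B", "ACGT"), ("O", "ACGT"))
        with pytest.raises(KeyError):
            relative_rate_test(a3, "A", "Z", "O")
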