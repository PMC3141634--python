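"""Detect a rate-accelerated lineage from sequence data.

Evolves a 5 kb alignment on a clock tree with the terminal branch of one
taxon ("Acc") stretched 3x, then runs the full diagnostic chain: LogDet
distances -> UPGMA tree -> terminal-branch ranking -> likelihood
relative-rate test under F81.
"""

from trexp import (
    SeqSimConfig,
    distance_matrix,
    relative_rate_test,
    simulate_alignment,
    terminal_branch_report,
    tree_to_newick,
    upgma,
)

clock_tree = "(((Sis:0.03,Cou:0.03):0.03,Acc:0.06):0.04,Out:0.10);"
aln = simulate_alignment(
    SeqSimConfig(
        tree=clock_tree, n_sites=5000, focal_taxon="Acc", rate_scale=3.0, seed=5
    )
)

d = distance_matrix(aln)
print("LogDet distance matrix (substitutions/site):")
print(d.round(4).to_string())

tree = upgma(d)
print("\nUPGMA tree:", tree_to_newick(tree, precision=4))
report = terminal_branch_report(tree)
print("\nterminal branch ranking:")
print(report.round(4).to_string())
print(f"longest terminal branch: {report.index[0]} (expected: Acc)")

res = relative_rate_test(aln, "Acc", "Sis", "Cou")
print(
    f"\nrelative-rate test Acc vs Sis (outgroup Cou):"
    f"\n  branch estimates a={res.a_hat:.4f}, b={res.b_hat:.4f}, c={res.c_hat:.4f}"
    f"\n  LRT = {res.lrt:.2f}, p = {res.p_value:.3g},"
    f" rate ratio a/b = {res.rate_ratio:.2f}"
)
print(
    "\nUPGMA assumes a molecular clock, so the accelerated taxon surfaces"
    "\nwith an inflated terminal branch; the likelihood test makes the"
    "\nasymmetry formal (clock fit a = b rejected when p < 0.05)."
)
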