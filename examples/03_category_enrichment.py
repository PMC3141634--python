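"""Hypergeometric over-representation of functional categories.

Builds a 1,000-gene universe annotated with five categories, plants 25 of
a 30-gene query into the "energy" category and tests every category with
the one-sided hypergeometric tail, Bonferroni-corrected at cutoff 0.01.
"""

from trexp import assign_categories, category_overrepresentation

universe_size = 1000
annotation = assign_categories(
    universe_size,
    categories=[
        ("energy", 120),
        ("metabolism", 200),
        ("transport", 150),
        ("signalling", 100),
        ("unknown", 430),
    ],
    enriched=("energy", {f"g{i:04d}" for i in range(25)}),
    seed=11,
)

query = [f"g{i:04d}" for i in range(30)]  # 25 planted + 5 background genes
result = category_overrepresentation(annotation, query, cutoff=0.01)

print(result.round(6).to_string())
sig = result.index[result["significant"]].tolist()
print(f"\nsignificant categories at Bonferroni-corrected p < 0.01: {sig}")
print(
    "\nk of n query genes fall in a category covering K of N universe"
    "\ngenes; p_raw = P(X >= k) under random draws, corrected for the"
    "\nnumber of categories tested."
)
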