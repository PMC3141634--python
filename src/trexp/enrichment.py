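"""Functional-category over-representation by the hypergeometric test.

Given an annotation mapping genes to categories (FunCat/GO-style, possibly
several per gene), a gene universe of size N and a query set of size n
(e.g. the PEGs of one library), a category containing K universe genes and
k query genes is scored with the one-sided hypergeometric tail

    p = P(X >= k),  X ~ Hypergeometric(N, K, n),

Bonferroni-corrected over the number of categories represented in the
universe, with significance declared below a corrected cutoff (default
0.01).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import pandas as pd
from scipy import stats

__all__ = ["hypergeom_tail", "category_overrepresentation"]


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) of Hypergeometric(N, K, n).

    N: universe size, K: category size, n: query size, k: overlap.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(
            f"inconsistent hypergeometric parameters N={N} K={K} n={n} k={k}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _categories_of(annotation: Mapping[str, Iterable[str]], genes) -> dict[str, set]:
    members: dict[str, set] = {}
    for g in genes:
        for c in annotation.get(g, ()):
            members.setdefault(c, set()).add(g)
    return members


def category_overrepresentation(
    annotation: Mapping[str, Iterable[str]],
    query: Iterable[str],
    universe: Iterable[str] | None = None,
    cutoff: float = 0.01,
    report_all: bool = False,
) -> pd.DataFrame:
    """Test every category for over-representation in a query gene set.

    Parameters
    ----------
    annotation
        Mapping gene id -> iterable of category ids; genes may carry several
        categories and are counted once per category.
    query
        The gene set of interest; must be a subset of the universe.
    universe
        Background gene set; defaults to all annotated genes.
    cutoff
        Significance cutoff applied to the Bonferroni-corrected p-value.
    report_all
        Also report categories absent from the query (k = 0); such
        categories still count toward the Bonferroni denominator either way.

    Returns
    -------
    pandas.DataFrame
        One row per category, columns ``N, K, n, k, p_raw, p_bonferroni,
        significant``, sorted by ascending raw p with category label as the
        tie-break.
    """
    universe_set = set(annotation) if universe is None else set(universe)
    query_set = set(query)
    missing = sorted(query_set - universe_set)
    if missing:
        raise ValueError(f"query genes absent from the universe: {missing}")

    cat_universe = _categories_of(annotation, universe_set)
    cat_query = _categories_of(annotation, query_set)
    n_tests = len(cat_universe)  # categories with K >= 1 in the universe
    N, n = len(universe_set), len(query_set)

    rows = []
    for cat, members in sorted(cat_universe.items()):
        K = len(members)
        k = len(cat_query.get(cat, ()))
        if k == 0 and not report_all:
            continue
        p_raw = hypergeom_tail(N, K, n, k)
        p_bonf = min(1.0, p_raw * n_tests)
        rows.append((cat, N, K, n, k, p_raw, p_bonf, p_bonf < cutoff))
    out = pd.DataFrame(
        rows,
        columns=["category", "N", "K", "n", "k", "p_raw", "p_bonferroni", "significant"],
    ).set_index("category")
    # rows were built in sorted category order; a stable sort on p_raw
    # therefore breaks ties by category label
    return out.sort_values("p_raw", kind="stable")
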