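"""Gene-set overrepresentation analysis and list algebra.

The fold-change-gated differential mRNA list is tested for overrepresentation
in each gene set with the hypergeometric upper tail (one-sided Fisher), BH
adjusted across sets; curated categories are selected by rank + keyword, their
member genes pooled, and the pool intersected with a disease gene list.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .types import GeneSetCollection

__all__ = [
    "overrepresentation_test",
    "select_categories",
    "pool_unique_genes",
    "intersect_gene_lists",
]


def overrepresentation_test(query, sets: GeneSetCollection, universe,
                            binomial: bool = False) -> pd.DataFrame:
    """Hypergeometric overrepresentation p per set, BH-adjusted across sets.

    p = P(X ≥ k) with population N = |universe|, K = |set ∩ universe| marked,
    draws n = |query|, observed overlap k.  Query genes outside the universe
    are dropped with a warning.  ``binomial=True`` switches to the binomial
    approximation some GO tools use.  Result is sorted by adjusted p ascending
    (ties by raw p, then set name).
    """
    universe = list(dict.fromkeys(str(g) for g in universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    query = list(dict.fromkeys(str(g) for g in query))
    if not query:
        raise ValueError("empty query gene list")
    outside = [g for g in query if g not in uni]
    if outside:
        warnings.warn(f"{len(outside)} query genes outside universe dropped")
        query = [g for g in query if g in uni]
        if not query:
            raise ValueError("no query genes remain inside the universe")
    qset = set(query)
    n_uni, n_query = len(uni), len(qset)

    rows = []
    for name, (desc, members) in sets.sets.items():
        k_set = uni.intersection(members)
        overlap = sorted(qset.intersection(k_set))
        k = len(overlap)
        if binomial:
            p = float(stats.binom.sf(k - 1, n_query, len(k_set) / n_uni)) if k_set else 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, n_uni, len(k_set), n_query))
        rows.append({
            "set_name": name,
            "description": desc,
            "set_size": len(k_set),
            "query_size": n_query,
            "universe_size": n_uni,
            "overlap_count": k,
            "overlap_members": ",".join(overlap),
            "p_raw": min(p, 1.0),
        })
    res = pd.DataFrame(rows)
    res["p_adj"] = bh_adjust(res["p_raw"].to_numpy())
    res = res.sort_values(["p_adj", "p_raw", "set_name"],
                          kind="mergesort").reset_index(drop=True)
    return res


def select_categories(results: pd.DataFrame, top_n: int = 15,
                      keywords=None, explicit_names=None) -> list[str]:
    """Curate categories: take the ``top_n`` by adjusted p, keep keyword hits.

    ``explicit_names`` bypasses the keyword filter entirely (exact names).
    Keywords match case-insensitively as substrings of set name or description.
    """
    if explicit_names is not None:
        names = [n for n in explicit_names if n in set(results["set_name"])]
        return names
    if not keywords:
        raise ValueError(
            "category selection needs keywords or an explicit name list "
            "(this is a curation step — it is never automated)")
    # results arrive sorted by (p_adj, p_raw, name); top_n is a prefix
    top = results.iloc[:top_n]
    kws = [k.lower() for k in keywords]
    selected = []
    for _, row in top.iterrows():
        text = f"{row['set_name']} {row.get('description', '')}".lower()
        if any(k in text for k in kws):
            selected.append(row["set_name"])
    if not selected:
        warnings.warn("no categories matched the curation keywords")
    return selected


def pool_unique_genes(sets: GeneSetCollection, selected_names,
                      query) -> list[str]:
    """Union over selected sets of (set ∩ query), deduplicated and sorted."""
    if not selected_names:
        raise ValueError("no categories selected to pool")
    qset = {str(g) for g in query}
    pooled: set[str] = set()
    for name in selected_names:
        pooled |= sets.members(name) & qset
    return sorted(pooled)


def intersect_gene_lists(a, b) -> list[str]:
    """Sorted case-sensitive exact-ID intersection."""
    return sorted(set(map(str, a)) & set(map(str, b)))
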