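"""Local over-representation analysis against supplied gene sets.

A query list (e.g. the up-regulated significant proteins of one comparison)
is tested against every gene set of a collection with the one-sided
hypergeometric upper tail P[X >= k], where k is the query/set overlap, the
universe is the quantified background, and sets are intersected with the
universe before testing (sets with empty intersection are skipped, so they
do not enter the Benjamini-Hochberg denominator). q-values are BH across the
tested sets of one run; rows sort by q, then p, then set name.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import ComparisonResult, GeneSetCollection
from .errors import InputError


def enrich(query, universe, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` within ``universe``.

    Returns a DataFrame with one row per tested set: set_name,
    n_query_in_set, n_query, n_set_in_universe, n_universe, p_value, q_value
    and the ";"-joined overlap members.
    """
    query = {str(g).upper() for g in query}
    universe = {str(g).upper() for g in universe}
    if not query or not universe:
        raise InputError("query and universe must be non-empty")
    if len(collection) == 0:
        raise InputError("gene-set collection is empty")
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise InputError(f"query not contained in universe (e.g. {extra})")

    M, n = len(universe), len(query)
    rows = []
    for name, members in collection:
        in_universe = members & universe
        if not in_universe:
            continue
        overlap = sorted(in_universe & query)
        K, k = len(in_universe), len(overlap)
        p = float(hypergeom.sf(k - 1, M, K, n))
        rows.append({
            "set_name": name, "n_query_in_set": k, "n_query": n,
            "n_set_in_universe": K, "n_universe": M,
            "p_value": min(p, 1.0), "overlap": ";".join(overlap),
        })
    if not rows:
        return pd.DataFrame(columns=["set_name", "n_query_in_set", "n_query",
                                     "n_set_in_universe", "n_universe",
                                     "p_value", "q_value", "overlap"])
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out = out.sort_values(["q_value", "p_value", "set_name"],
                          kind="stable").reset_index(drop=True)
    return out[["set_name", "n_query_in_set", "n_query", "n_set_in_universe",
                "n_universe", "p_value", "q_value", "overlap"]]


def top_k_report(rows: pd.DataFrame, k: int = 5,
                 q_cutoff: float = 0.05) -> pd.DataFrame:
    """At most ``k`` sets with q below the cutoff; may be fewer or empty."""
    if rows.empty:
        return rows
    sig = rows[rows["q_value"] < q_cutoff]
    return sig.head(k).reset_index(drop=True)


def enrich_comparison(result: ComparisonResult, universe,
                      collection: GeneSetCollection, k: int = 5,
                      q_cutoff: float = 0.05) -> dict:
    """Up- and down-regulated lists tested separately (split-bar style).

    Returns ``{"up": (full table, top-k), "down": (full table, top-k)}``;
    directions with no significant genes produce empty tables.
    """
    out = {}
    sig = result.significant
    for direction in ("up", "down"):
        genes = {str(g).upper() for g in
                 sig.loc[sig["direction"] == direction, "gene_name"] if g}
        if not genes:
            empty = pd.DataFrame(columns=["set_name", "n_query_in_set",
                                          "n_query", "n_set_in_universe",
                                          "n_universe", "p_value", "q_value",
                                          "overlap"])
            out[direction] = (empty, empty)
            continue
        table = enrich(genes, universe, collection)
        out[direction] = (table, top_k_report(table, k=k, q_cutoff=q_cutoff))
    return out
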