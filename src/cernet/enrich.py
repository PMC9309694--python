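"""Gene-set over-representation analysis for network-linked mRNAs.

One-sided Fisher exact test per set: with a universe of U genes, a set of m
and a query of q, the probability of k or more hits is the hypergeometric
upper tail P[X >= k] — the same tail statistic as the ceRNA sponge test, and
deliberately the same implementation.  Results carry BH-adjusted p-values and
are ranked ascending by p (ties broken by set id) with top-K reporting
(default 20, the usual panel size).
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._hypergeom import hypergeom_upper_tail
from .seqio import GeneSetCollection, ValidationError

ENRICH_COLUMNS = [
    "set_id",
    "description",
    "k",
    "m",
    "q",
    "U",
    "p",
    "fdr",
    "hits",
]


def enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    top: int | None = 20,
) -> pd.DataFrame:
    """Rank gene sets by over-representation of ``query`` within ``universe``.

    The query must be a subset of the universe; each gene set is intersected
    with the universe before testing.  Returns the ``top`` best sets (all if
    None), sorted by (p, set id).
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValidationError("empty universe")
    if not query:
        raise ValidationError("empty query")
    stray = query - universe
    if stray:
        raise ValidationError(f"query genes outside the universe: {sorted(stray)[:5]}")
    U, q = len(universe), len(query)
    rows = []
    for sid in sorted(sets.sets):
        members = sets.members(sid) & universe
        if not members:
            continue
        m = len(members)
        hits = sorted(query & members)
        k = len(hits)
        rows.append(
            {
                "set_id": sid,
                "description": sets.description(sid),
                "k": k,
                "m": m,
                "q": q,
                "U": U,
                "p": hypergeom_upper_tail(k, U, m, q),
                "fdr": None,
                "hits": ",".join(hits),
            }
        )
    df = pd.DataFrame(rows, columns=ENRICH_COLUMNS)
    if len(df):
        df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
    if top is not None:
        df = df.head(top)
    return df
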