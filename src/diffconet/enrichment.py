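"""Hypergeometric over-representation analysis against a GMT collection.

For a query gene set (e.g. a network's genes) and a collection of named
sets, each set's overlap with the query is scored by the upper tail of the
hypergeometric distribution — the probability of drawing at least k set
members in n draws from a universe of N genes containing K members — and
the per-set p-values are BH-adjusted.  The universe defaults to the genes
on the expression platform rather than the genome: genes that could never
have been observed should not inflate significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from diffconet.diffexpr import bh_adjust
from diffconet.io import GeneSetCollection


@dataclass
class EnrichmentRecord:
    set_name: str
    overlap: int  # k
    set_size: int  # K (within the universe)
    query_size: int  # n
    universe_size: int  # N
    p_value: float
    adjusted_p: float = float("nan")


def hypergeometric_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_ora(
    query: set[str] | list[str],
    collection: GeneSetCollection,
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """One-sided over-representation of ``query`` in every collection set.

    ``query`` must be contained in ``universe``; each gene set is first
    intersected with the universe.  Returns a DataFrame sorted by p with
    columns set_name, overlap, set_size, query_size, universe_size, p_value,
    adjusted_p.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        missing = sorted(query - universe)
        raise ValueError(f"query genes outside the universe: {missing[:5]}")
    N, n = len(universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        members_in = members & universe
        if not members_in:
            continue
        K = len(members_in)
        k = len(members_in & query)
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p_value": hypergeometric_tail(k, N, K, n),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "set_name", "overlap", "set_size", "query_size", "universe_size",
            "p_value",
        ],
    )
    if len(frame):
        frame["adjusted_p"] = bh_adjust(frame["p_value"].to_numpy())
        frame = frame.sort_values(["p_value", "set_name"]).reset_index(drop=True)
    else:
        frame["adjusted_p"] = []
    return frame
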