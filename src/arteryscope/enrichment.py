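"""Gene-set enrichment by the EASE score (conservative modified Fisher test).

For a query list of n genes from a universe of N, overlapping a gene set of
size K in k genes, the Fisher p is the one-sided hypergeometric tail
P(X >= k). The EASE score penalizes the overlap by one gene — the same tail
evaluated with k-1 successes out of a list of n-1 — yielding a conservative
p that is always >= the Fisher p; k <= 1 gives EASE p = 1. Sets with
EASE p < 0.05 are reported as enriched by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust


def _tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def ease_score(k: int, n: int, K: int, N: int) -> Tuple[float, float]:
    """Return (ease_p, fisher_p) for an overlap of k.

    k = overlap, n = query-list size, K = gene-set size, N = universe size.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N) or n < 1 or K < 1:
        raise ValueError(
            f"inconsistent enrichment table: k={k}, n={n}, K={K}, N={N}")
    fisher_p = _tail(k, n, K, N)
    ease_p = 1.0 if k <= 1 else _tail(k - 1, n - 1, K, N)
    return ease_p, fisher_p


@dataclass
class EnrichmentResult:
    table: pd.DataFrame
    n_dropped_from_query: int


def enrich(
    query: Sequence[str],
    sets: Dict[str, List[str]],
    universe: Sequence[str],
    alpha: float = 0.05,
    adjust: bool = False,
) -> EnrichmentResult:
    """Test every gene set against the query list.

    Query genes outside the universe are dropped (their count is reported);
    set members outside the universe do not count toward K. Rows are sorted
    by ease_p ascending (ties by set name); the ``enriched`` flag applies
    ``alpha`` to the raw EASE p. ``adjust`` adds a BH column over EASE p.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("enrichment universe is empty")
    query_set = set(query)
    dropped = len(query_set - universe_set)
    query_set &= universe_set
    N, n = len(universe_set), len(query_set)

    rows = []
    for name, members in sets.items():
        members_in = set(members) & universe_set
        K = len(members_in)
        if K == 0:
            continue
        k = len(members_in & query_set)
        ease_p, fisher_p = ease_score(k, max(n, 1), K, N)
        rows.append(
            {"set": name, "k": k, "n": n, "K": K, "N": N,
             "ease_p": ease_p, "fisher_p": fisher_p}
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["enriched"] = table["ease_p"] < alpha
        if adjust:
            table["ease_p_bh"] = bh_adjust(table["ease_p"])
        table = table.sort_values(["ease_p", "set"]).reset_index(drop=True)
    return EnrichmentResult(table=table, n_dropped_from_query=dropped)
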