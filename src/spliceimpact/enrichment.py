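"""One-sided Fisher's exact (hypergeometric) pathway over-representation.

For a universe of N genes containing a pathway of size K and a query of size
n with k query genes in the pathway, the enrichment p-value is the upper-tail
hypergeometric probability P(X >= k), X ~ Hypergeom(N, K, n).  Significance
defaults to p <= 0.01 with no multiple-testing correction; Benjamini–Hochberg
adjusted values are available behind a flag.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Set

import numpy as np
from scipy import stats

from .models import EnrichmentResult, PathwayCollection, normalize_symbol

log = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 0.01


def fisher_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N and N >= 0):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # survival function computed in log space internally by scipy
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(pvals: Iterable[float]) -> List[float]:
    p = np.asarray(list(pvals), dtype=float)
    m = len(p)
    if m == 0:
        return []
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj.tolist()


def enrich(
    query_genes: Iterable[str],
    pathways: PathwayCollection,
    universe: Iterable[str],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    bh_correct: bool = False,
) -> List[EnrichmentResult]:
    """Score every pathway against the query; sorted by ascending p-value.

    Ties are broken by descending k, then pathway id; the "most affected"
    pathway is the first element.  Query genes outside the universe are
    dropped with a warning; pathway gene sets are intersected with the
    universe before counting.
    """
    universe_set: Set[str] = {normalize_symbol(g) for g in universe}
    query_raw = {normalize_symbol(g) for g in query_genes}
    if not query_raw:
        raise ValueError("empty query gene set")
    if not universe_set:
        raise ValueError("empty universe")
    query = query_raw & universe_set
    dropped = query_raw - universe_set
    if dropped:
        log.warning("%d query gene(s) outside the universe dropped", len(dropped))
    if not query:
        raise ValueError("no query genes remain inside the universe")

    N = len(universe_set)
    n = len(query)
    results = []
    for pid, (name, genes) in pathways.items():
        in_universe = genes & universe_set
        members = sorted(in_universe & query)
        k, K = len(members), len(in_universe)
        p = fisher_p(k, K, n, N)
        results.append(
            EnrichmentResult(
                pathway_id=pid,
                name=name,
                k=k,
                K=K,
                n=n,
                N=N,
                p_value=p,
                significant=p <= p_threshold,
                members=members,
            )
        )
    if bh_correct:
        adjusted = benjamini_hochberg([r.p_value for r in results])
        for r, q in zip(results, adjusted):
            r.p_value = q
            r.significant = q <= p_threshold
    results.sort(key=lambda r: (r.p_value, -r.k, r.pathway_id))
    return results
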