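"""Gene-list overlap statistics against curated sets, and generic ORA.

Symbols are compared case-insensitively (uppercased, whitespace stripped) so
that differently cased orthologous symbols from the two species still match
the curated lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .conserved_expression import hypergeometric_tail
from .io_core import GeneSet
from .motif_enrichment import bh_adjust

__all__ = ["OverlapReport", "normalize_symbol", "overlap_report", "ora"]


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: whitespace-stripped, uppercase. Idempotent."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class OverlapReport:
    """Overlap of a query gene list with one reference set.

    ``percent`` is 100 * k / n rounded to two decimals; ``p`` is the
    upper-tail hypergeometric probability of seeing >= k overlaps.
    """

    query_id: str
    set_id: str
    k: int
    n: int
    K: int
    N: int
    percent: float
    p: float
    q: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) <= self.N):
            raise ValueError(
                f"invalid counts k={self.k}, K={self.K}, n={self.n}, N={self.N}"
            )
        if not (0.0 <= self.percent <= 100.0):
            raise ValueError("percent must be within [0, 100]")


def overlap_report(
    query: Iterable[str],
    reference: GeneSet,
    universe: Iterable[str],
    query_id: str = "query",
) -> OverlapReport:
    """Hypergeometric overlap of a query list with a reference set.

    The reference is intersected with the universe before sizing; the query
    must be a subset of the universe (after symbol normalization).
    """
    universe_set = {normalize_symbol(g) for g in universe}
    if not universe_set:
        raise ValueError("universe must be non-empty")
    query_set = {normalize_symbol(g) for g in query}
    outside = query_set - universe_set
    if outside:
        raise ValueError(
            f"query genes outside the universe: {sorted(outside)[:5]}"
        )
    ref_set = {normalize_symbol(g) for g in reference.members} & universe_set
    k = len(query_set & ref_set)
    n = len(query_set)
    K = len(ref_set)
    N = len(universe_set)
    percent = round(100.0 * k / n, 2) if n else 0.0
    p = hypergeometric_tail(k, K, n, N) if K else 1.0
    return OverlapReport(
        query_id=query_id,
        set_id=reference.set_id,
        k=k,
        n=n,
        K=K,
        N=N,
        percent=percent,
        p=p,
    )


def ora(
    query: Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str],
    alpha: float = 0.05,
    query_id: str = "query",
) -> list[OverlapReport]:
    """Over-representation analysis of a query list against a GMT collection.

    One report per set, BH-adjusted across sets, sorted ascending by (q, p,
    set_id).  Sets with no universe members produce a k = K = 0, p = 1 report.
    """
    if not sets:
        raise ValueError("at least one gene set required")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    query = list(query)
    universe = list(universe)
    reports = [
        overlap_report(query, s, universe, query_id=query_id) for s in sets
    ]
    qvalues = bh_adjust([r.p for r in reports])
    from dataclasses import replace

    adjusted = [replace(r, q=float(q)) for r, q in zip(reports, qvalues)]
    return sorted(adjusted, key=lambda r: (r.q, r.p, r.set_id))
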