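"""Differentiation-state gene classification and cross-species conservation tests.

Genes are labelled from their fiber/epithelial differential-expression
statistics (negative log2FC at q below alpha means epithelial-preferred,
positive means fiber-preferred), orthologs with matching labels in both
species form the conserved sets, and the four class pairings are tested for
association with an upper-tail hypergeometric computed in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .io_core import DeRecord, OrthologPair

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionClass",
    "ConservedGeneSets",
    "OverlapTestResult",
    "classify_expression",
    "intersect_conserved",
    "hypergeometric_tail",
    "overlap_association_matrix",
]


class ExpressionClass(str, Enum):
    EPITHELIAL = "EPITHELIAL"
    FIBER = "FIBER"
    NS = "NS"


@dataclass(frozen=True)
class OverlapTestResult:
    """Counts and upper-tail hypergeometric p for a two-list overlap.

    ``k`` of the ``n`` query genes fall in the ``K``-sized reference set,
    within a universe of ``N`` genes.
    """

    k: int
    K: int
    n: int
    N: int
    p: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) <= self.N):
            raise ValueError(
                f"invalid counts k={self.k}, K={self.K}, n={self.n}, N={self.N}"
            )
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p must be in (0, 1], got {self.p}")


@dataclass
class ConservedGeneSets:
    """Ortholog pairs sharing an expression class in both species.

    ``cross_matrix`` counts the four class pairings (rows: species-A class,
    columns: species-B class, order EPITHELIAL then FIBER) over ortholog pairs
    significant in both species.  Marginal counts and the universe size are
    retained for the association tests.
    """

    conserved_epithelial: list[OrthologPair] = field(default_factory=list)
    conserved_fiber: list[OrthologPair] = field(default_factory=list)
    cross_matrix: np.ndarray = field(default_factory=lambda: np.zeros((2, 2), dtype=int))
    n_a_epithelial: int = 0
    n_a_fiber: int = 0
    n_b_epithelial: int = 0
    n_b_fiber: int = 0
    universe_size: int = 0
    n_skipped: int = 0


def classify_expression(
    records: Iterable[DeRecord], alpha: float = 0.05
) -> dict[str, ExpressionClass]:
    """Assign each gene exactly one of EPITHELIAL / FIBER / NS.

    EPITHELIAL iff log2fc < 0 and q < alpha; FIBER iff log2fc > 0 and
    q < alpha; NS otherwise (including log2fc exactly 0).  Inequalities are
    strict.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    labels: dict[str, ExpressionClass] = {}
    for rec in records:
        if rec.qvalue < alpha and rec.log2fc < 0:
            label = ExpressionClass.EPITHELIAL
        elif rec.qvalue < alpha and rec.log2fc > 0:
            label = ExpressionClass.FIBER
        else:
            label = ExpressionClass.NS
        labels[rec.gene_id] = label
    return labels


def intersect_conserved(
    labels_a: Mapping[str, ExpressionClass],
    labels_b: Mapping[str, ExpressionClass],
    orthologs: Sequence[OrthologPair],
) -> ConservedGeneSets:
    """Intersect per-species labels over one-to-one ortholog pairs.

    A pair is conserved-epithelial iff both members are EPITHELIAL, and
    conserved-fiber iff both are FIBER.  Pairs referencing a gene absent from
    either label set are skipped (and counted).  The universe is the set of
    ortholog pairs present in both label sets.
    """
    out = ConservedGeneSets()
    idx = {ExpressionClass.EPITHELIAL: 0, ExpressionClass.FIBER: 1}
    for pair in orthologs:
        la = labels_a.get(pair.gene_a)
        lb = labels_b.get(pair.gene_b)
        if la is None or lb is None:
            out.n_skipped += 1
            continue
        out.universe_size += 1
        if la is ExpressionClass.EPITHELIAL:
            out.n_a_epithelial += 1
        elif la is ExpressionClass.FIBER:
            out.n_a_fiber += 1
        if lb is ExpressionClass.EPITHELIAL:
            out.n_b_epithelial += 1
        elif lb is ExpressionClass.FIBER:
            out.n_b_fiber += 1
        if la in idx and lb in idx:
            out.cross_matrix[idx[la], idx[lb]] += 1
        if la is ExpressionClass.EPITHELIAL and lb is ExpressionClass.EPITHELIAL:
            out.conserved_epithelial.append(pair)
        elif la is ExpressionClass.FIBER and lb is ExpressionClass.FIBER:
            out.conserved_fiber.append(pair)
    if out.n_skipped:
        logger.info(
            "intersect_conserved: skipped %d ortholog pairs with missing labels",
            out.n_skipped,
        )
    return out


def _log_hypergeom_pmf(i: np.ndarray, K: int, n: int, N: int) -> np.ndarray:
    # log C(K, i) + log C(N-K, n-i) - log C(N, n)
    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logc(K, i) + logc(N - K, n - i) - logc(N, n)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    ``k`` successes observed when drawing ``n`` from a universe of ``N``
    containing ``K`` successes.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"invalid counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    lo = max(k, n - (N - K))
    hi = min(K, n)
    i = np.arange(lo, hi + 1)
    # clamp: the log-space sum can overshoot 1 by a few ulp
    return min(1.0, float(np.exp(logsumexp(_log_hypergeom_pmf(i, K, n, N)))))


def overlap_association_matrix(
    conserved: ConservedGeneSets, universe_size: int | None = None
) -> dict[tuple[ExpressionClass, ExpressionClass], OverlapTestResult]:
    """The four cross-species class association tests.

    For each (species-A class, species-B class) pairing the overlap of the two
    marginal gene lists is tested with an upper-tail hypergeometric over the
    ortholog universe.
    """
    N = conserved.universe_size if universe_size is None else universe_size
    marg_a = {
        ExpressionClass.EPITHELIAL: conserved.n_a_epithelial,
        ExpressionClass.FIBER: conserved.n_a_fiber,
    }
    marg_b = {
        ExpressionClass.EPITHELIAL: conserved.n_b_epithelial,
        ExpressionClass.FIBER: conserved.n_b_fiber,
    }
    idx = {ExpressionClass.EPITHELIAL: 0, ExpressionClass.FIBER: 1}
    results: dict[tuple[ExpressionClass, ExpressionClass], OverlapTestResult] = {}
    for ca, na in marg_a.items():
        for cb, kb in marg_b.items():
            if na > N or kb > N:
                raise ValueError(
                    f"universe ({N}) smaller than class set ({ca.value}: {na}, "
                    f"{cb.value}: {kb})"
                )
            k = int(conserved.cross_matrix[idx[ca], idx[cb]])
            p = hypergeometric_tail(k, kb, na, N)
            results[(ca, cb)] = OverlapTestResult(k=k, K=kb, n=na, N=N, p=p)
    return results
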