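"""PWM motif scanning and hit-count enrichment over peak sequence sets.

Each PFM is turned into a log-odds matrix, scanned over both strands of each
sequence, and a sequence counts as a hit when its best placement reaches a
fixed fraction of the motif's maximum achievable score.  Hits in a foreground
set are compared against a dinucleotide-shuffled (or cross-class) background
with a one-sided Fisher exact test, BH-adjusted per test family, and the four
test families are combined into a six-way motif partition with an
expressed-TF filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .conserved_expression import hypergeometric_tail
from .io_core import DeRecord, PositionFrequencyMatrix

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_FRACTION = 0.75
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
# complement of index: A<->T, C<->G, unknown (4) stays unknown
_COMPLEMENT = np.array([3, 2, 1, 0, 4])

__all__ = [
    "DEFAULT_THRESHOLD_FRACTION",
    "PwmModel",
    "MotifEnrichmentResult",
    "MotifPartition",
    "pfm_to_pwm",
    "max_achievable_score",
    "best_hit_score",
    "count_hits",
    "shuffle_control",
    "dinucleotide_shuffle",
    "fisher_motif_test",
    "bh_adjust",
    "run_enrichment",
    "partition_motifs",
    "combine_species_labels",
    "expression_filter",
]


@dataclass(frozen=True)
class PwmModel:
    """Log2-odds matrix (4 x W, rows A/C/G/T) against a base background."""

    motif_id: str
    tf_name: str
    logodds: np.ndarray
    background: np.ndarray

    @property
    def width(self) -> int:
        return self.logodds.shape[1]


@dataclass(frozen=True)
class MotifEnrichmentResult:
    motif_id: str
    tf_name: str
    fg_hits: int
    fg_n: int
    bg_hits: int
    bg_n: int
    p: float
    q: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.fg_hits <= self.fg_n and 0 <= self.bg_hits <= self.bg_n):
            raise ValueError(f"{self.motif_id}: hit counts exceed sequence counts")


class MotifPartition(str, Enum):
    EPI_ONLY = "EPI_ONLY"
    EPI_PREFERRED = "EPI_PREFERRED"
    FIBER_ONLY = "FIBER_ONLY"
    FIBER_PREFERRED = "FIBER_PREFERRED"
    SHARED = "SHARED"
    NONE = "NONE"


# ---------------------------------------------------------------------------
# PWM construction and scanning
# ---------------------------------------------------------------------------

def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
) -> PwmModel:
    """Convert counts to log2-odds with a background-weighted pseudocount.

    Per column: p_b = (count_b + pseudocount * bg_b) / (colsum + pseudocount),
    logodds_b = log2(p_b / bg_b).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    bg = (
        np.full(4, 0.25)
        if background is None
        else np.asarray(background, dtype=float)
    )
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or np.any(bg < 0):
        raise ValueError("background must be 4 non-negative values summing to 1")
    zero_bg = bg == 0
    if np.any(zero_bg & (pfm.counts.sum(axis=1) > 0)):
        raise ValueError(
            f"{pfm.motif_id}: zero background for a base with nonzero counts"
        )
    colsums = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pseudocount * bg[:, None]) / (colsums + pseudocount)
    with np.errstate(divide="ignore"):
        logodds = np.log2(probs / np.where(zero_bg, np.nan, bg)[:, None])
    logodds = np.where(zero_bg[:, None], -np.inf, logodds)
    return PwmModel(
        motif_id=pfm.motif_id, tf_name=pfm.tf_name, logodds=logodds, background=bg
    )


def max_achievable_score(pwm: PwmModel) -> float:
    """Best possible placement score: sum of per-column maxima."""
    return float(pwm.logodds.max(axis=0).sum())


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a DNA string to indices 0-3 (A/C/G/T); anything else (e.g. N) -> 4."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        lut[ord(base)] = idx
    return lut[arr].astype(np.intp)


def _strand_scores(idx: np.ndarray, scan: np.ndarray, width: int) -> np.ndarray:
    n_placements = idx.size - width + 1
    scores = np.zeros(n_placements)
    for j in range(width):
        scores += scan[idx[j : j + n_placements], j]
    return scores


def best_hit_score(sequence: str, pwm: PwmModel) -> float:
    """Maximum placement score over both strands.

    Placements covering a non-ACGT base score -inf; sequences shorter than
    the motif return -inf with a warning.
    """
    width = pwm.width
    if len(sequence) < width:
        warnings.warn(
            f"sequence shorter than motif {pwm.motif_id} (len {len(sequence)} < {width})",
            stacklevel=2,
        )
        return -np.inf
    # row 4 catches N / unknown bases with -inf at every column
    scan = np.vstack([pwm.logodds, np.full((1, width), -np.inf)])
    idx = encode_sequence(sequence)
    fwd = _strand_scores(idx, scan, width)
    rev = _strand_scores(_COMPLEMENT[idx][::-1], scan, width)
    return float(max(fwd.max(), rev.max()))


def count_hits(
    sequences: Iterable[str],
    pwm: PwmModel,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> int:
    """Number of sequences whose best score reaches
    ``threshold_fraction * max_achievable_score``."""
    if not (0.0 < threshold_fraction <= 1.0):
        raise ValueError("threshold_fraction must be in (0, 1]")
    threshold = threshold_fraction * max_achievable_score(pwm)
    return sum(1 for seq in sequences if best_hit_score(seq, pwm) >= threshold)


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (Altschul-Erickson)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide count multiset.

    Random Eulerian-walk construction: each symbol's outgoing edge multiset is
    kept, a terminal edge per symbol is drawn so that terminal edges form an
    arborescence into the last symbol, remaining edges are permuted, and the
    walk is read off from the first symbol.
    """
    if len(sequence) < 3:
        return sequence
    chars = list(sequence)
    last = chars[-1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(chars, chars[1:]):
        edges.setdefault(a, []).append(b)
    vertices = list(edges)

    def _connected_to_last(terminal: dict[str, str]) -> bool:
        for v in vertices:
            seen = set()
            node = v
            while node != last and node in terminal and node not in seen:
                seen.add(node)
                node = terminal[node]
            if node != last:
                return False
        return True

    while True:
        terminal = {
            v: edges[v][rng.integers(len(edges[v]))] for v in vertices if v != last
        }
        if _connected_to_last(terminal):
            break

    shuffled_edges: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v != last:
            pool.remove(terminal[v])
        order = rng.permutation(len(pool))
        out = [pool[i] for i in order]
        if v != last:
            out.append(terminal[v])
        shuffled_edges[v] = out

    result = [chars[0]]
    cursors = {v: 0 for v in vertices}
    node = chars[0]
    for _ in range(len(chars) - 1):
        nxt = shuffled_edges[node][cursors[node]]
        cursors[node] += 1
        result.append(nxt)
        node = nxt
    return "".join(result)


def shuffle_control(sequences: Sequence[str], seed: int) -> list[str]:
    """Deterministic dinucleotide-preserving shuffle of every sequence."""
    if not sequences:
        raise ValueError("sequences must be non-empty")
    rng = np.random.default_rng(seed)
    return [dinucleotide_shuffle(seq, rng) for seq in sequences]


# ---------------------------------------------------------------------------
# enrichment statistics
# ---------------------------------------------------------------------------

def fisher_motif_test(fg_hits: int, fg_n: int, bg_hits: int, bg_n: int) -> float:
    """One-sided Fisher exact upper tail on per-sequence hit indicators."""
    if not (0 <= fg_hits <= fg_n and 0 <= bg_hits <= bg_n):
        raise ValueError("hit counts must not exceed sequence counts")
    return hypergeometric_tail(
        k=fg_hits, K=fg_hits + bg_hits, n=fg_n, N=fg_n + bg_n
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def run_enrichment(
    fg_sequences: Sequence[str],
    bg_sequences: Sequence[str],
    pwms: Sequence[PwmModel],
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> dict[str, MotifEnrichmentResult]:
    """Hit-count Fisher enrichment of every motif, BH-adjusted across the
    library (one test family per call)."""
    results = []
    for pwm in pwms:
        fg_hits = count_hits(fg_sequences, pwm, threshold_fraction)
        bg_hits = count_hits(bg_sequences, pwm, threshold_fraction)
        p = fisher_motif_test(fg_hits, len(fg_sequences), bg_hits, len(bg_sequences))
        results.append(
            MotifEnrichmentResult(
                motif_id=pwm.motif_id,
                tf_name=pwm.tf_name,
                fg_hits=fg_hits,
                fg_n=len(fg_sequences),
                bg_hits=bg_hits,
                bg_n=len(bg_sequences),
                p=p,
            )
        )
    qvalues = bh_adjust([r.p for r in results])
    return {
        r.motif_id: replace(r, q=float(q)) for r, q in zip(results, qvalues)
    }


# ---------------------------------------------------------------------------
# four-way partition and expressed-TF filter
# ---------------------------------------------------------------------------

def partition_motifs(
    epi_results: Mapping[str, MotifEnrichmentResult],
    fiber_results: Mapping[str, MotifEnrichmentResult],
    epi_vs_fiber_results: Mapping[str, MotifEnrichmentResult],
    fiber_vs_epi_results: Mapping[str, MotifEnrichmentResult],
    alpha: float = 0.05,
) -> dict[str, MotifPartition]:
    """Combine the four test families into one label per motif.

    With E/F = significance against the shuffled control of each class and
    D_E/D_F = significance of the cross-class tests: EPI_ONLY = E and not F;
    FIBER_ONLY = F and not E; when both E and F hold, D_E gives
    EPI_PREFERRED (taking precedence over D_F, logged), D_F alone gives
    FIBER_PREFERRED, neither gives SHARED; otherwise NONE.
    """
    motifs = set(epi_results)
    for name, coll in (
        ("fiber", fiber_results),
        ("epi-vs-fiber", epi_vs_fiber_results),
        ("fiber-vs-epi", fiber_vs_epi_results),
    ):
        missing = motifs.symmetric_difference(coll)
        if missing:
            raise ValueError(
                f"motif(s) missing from {name} results: {sorted(missing)}"
            )
    labels: dict[str, MotifPartition] = {}
    for motif_id in sorted(motifs):
        E = epi_results[motif_id].q <= alpha
        F = fiber_results[motif_id].q <= alpha
        D_E = epi_vs_fiber_results[motif_id].q <= alpha
        D_F = fiber_vs_epi_results[motif_id].q <= alpha
        if E and not F:
            label = MotifPartition.EPI_ONLY
        elif F and not E:
            label = MotifPartition.FIBER_ONLY
        elif E and F:
            if D_E:
                if D_F:
                    logger.info(
                        "motif %s: both cross-tests significant, EPI_PREFERRED "
                        "takes precedence",
                        motif_id,
                    )
                label = MotifPartition.EPI_PREFERRED
            elif D_F:
                label = MotifPartition.FIBER_PREFERRED
            else:
                label = MotifPartition.SHARED
        else:
            label = MotifPartition.NONE
        labels[motif_id] = label
    return labels


_EPI_LABELS = {MotifPartition.EPI_ONLY, MotifPartition.EPI_PREFERRED}
_FIBER_LABELS = {MotifPartition.FIBER_ONLY, MotifPartition.FIBER_PREFERRED}


def combine_species_labels(
    labels_a: Mapping[str, MotifPartition],
    labels_b: Mapping[str, MotifPartition],
) -> dict[str, MotifPartition]:
    """Require a motif to pass in both species.

    Identical labels are kept; labels agreeing on direction (ONLY vs
    PREFERRED within the epithelial or fiber family) fall back to the weaker
    PREFERRED claim; anything else is NONE.
    """
    if set(labels_a) != set(labels_b):
        raise ValueError("species label sets cover different motifs")
    combined: dict[str, MotifPartition] = {}
    for motif_id in sorted(labels_a):
        la, lb = labels_a[motif_id], labels_b[motif_id]
        if la is lb:
            combined[motif_id] = la
        elif la in _EPI_LABELS and lb in _EPI_LABELS:
            combined[motif_id] = MotifPartition.EPI_PREFERRED
        elif la in _FIBER_LABELS and lb in _FIBER_LABELS:
            combined[motif_id] = MotifPartition.FIBER_PREFERRED
        else:
            combined[motif_id] = MotifPartition.NONE
    return combined


def expression_filter(
    labels: Mapping[str, MotifPartition],
    motif_tf_map: Mapping[str, str],
    de_a: Iterable[DeRecord],
    de_b: Iterable[DeRecord],
) -> dict[str, MotifPartition]:
    """Keep only motifs whose TF gene is detected in both species' DE tables.

    Gene symbols are matched case-insensitively; unmapped motifs are dropped
    with a log entry.
    """
    genes_a = {r.gene_id.strip().upper() for r in de_a}
    genes_b = {r.gene_id.strip().upper() for r in de_b}
    kept: dict[str, MotifPartition] = {}
    for motif_id, label in labels.items():
        tf = motif_tf_map.get(motif_id)
        if tf is None:
            logger.warning("motif %s: no TF mapping, dropped", motif_id)
            continue
        tf_norm = tf.strip().upper()
        if tf_norm in genes_a and tf_norm in genes_b:
            kept[motif_id] = label
    return kept
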