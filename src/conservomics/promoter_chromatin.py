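"""Strand-aware promoter windows and the promoter chromatin-state rule.

A gene's promoter window spans 7.5 kb upstream to 2.5 kb downstream of its
TSS.  Differential ATAC peaks are labelled epithelial- or fiber-specific by
sign and significance, and a promoter is epithelial-preferred iff it holds at
least one epithelial-specific peak and zero fiber-specific peaks (and the
mirror for fiber-preferred); windows with peaks of both labels are BOTH, and
windows without differential peaks are NONE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .io_core import DiffPeak, GenomicInterval, OrthologPair, TssRecord

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM_BP = 7500
DEFAULT_DOWNSTREAM_BP = 2500

__all__ = [
    "DEFAULT_UPSTREAM_BP",
    "DEFAULT_DOWNSTREAM_BP",
    "PeakClass",
    "PromoterStateLabel",
    "PromoterWindow",
    "PromoterState",
    "build_promoter_window",
    "classify_diff_peaks",
    "classify_promoter_state",
    "cross_species_promoter_states",
]


class PeakClass(str, Enum):
    EPI_SPECIFIC = "EPI_SPECIFIC"
    FIBER_SPECIFIC = "FIBER_SPECIFIC"
    NS = "NS"


class PromoterStateLabel(str, Enum):
    EPI_PREFERRED = "EPI_PREFERRED"
    FIBER_PREFERRED = "FIBER_PREFERRED"
    BOTH = "BOTH"
    NONE = "NONE"


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    interval: GenomicInterval
    upstream_bp: int = DEFAULT_UPSTREAM_BP
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP

    def __post_init__(self) -> None:
        if len(self.interval) > self.upstream_bp + self.downstream_bp:
            raise ValueError(
                f"{self.gene_id}: window longer than upstream + downstream"
            )


@dataclass(frozen=True)
class PromoterState:
    gene_id: str
    state: PromoterStateLabel
    n_epi_peaks: int
    n_fiber_peaks: int


def build_promoter_window(
    tss: TssRecord,
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
    chrom_length: int | None = None,
) -> PromoterWindow:
    """TSS-anchored window with ``upstream_bp`` upstream and ``downstream_bp``
    downstream bases (TSS base included on the downstream side).

    Minus-strand windows mirror plus-strand ones about the TSS base.  The
    window is clamped to ``[0, chrom_length)`` when a length is given.
    """
    if upstream_bp < 0 or downstream_bp < 0 or (upstream_bp == 0 and downstream_bp == 0):
        raise ValueError("window lengths must be >= 0 and not both 0")
    if tss.strand == "+":
        start = tss.pos - upstream_bp
        end = tss.pos + downstream_bp
    else:
        start = tss.pos - downstream_bp + 1
        end = tss.pos + upstream_bp + 1
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return PromoterWindow(
        gene_id=tss.gene_id,
        interval=GenomicInterval(tss.chrom, start, end, tss.strand),
        upstream_bp=upstream_bp,
        downstream_bp=downstream_bp,
    )


def classify_diff_peaks(
    peaks: Iterable[DiffPeak], alpha: float = 0.05
) -> list[tuple[DiffPeak, PeakClass]]:
    """EPI_SPECIFIC iff log2fc < 0, q < alpha; FIBER_SPECIFIC iff log2fc > 0,
    q < alpha; NS otherwise."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    labelled = []
    for peak in peaks:
        if peak.qvalue < alpha and peak.log2fc < 0:
            cls = PeakClass.EPI_SPECIFIC
        elif peak.qvalue < alpha and peak.log2fc > 0:
            cls = PeakClass.FIBER_SPECIFIC
        else:
            cls = PeakClass.NS
        labelled.append((peak, cls))
    return labelled


def classify_promoter_state(
    window: PromoterWindow,
    labelled_peaks: Iterable[tuple[DiffPeak, PeakClass]],
) -> PromoterState:
    """Apply the promoter-state rule to peaks overlapping the window >= 1 bp."""
    n_epi = 0
    n_fiber = 0
    for peak, cls in labelled_peaks:
        if not peak.interval.overlaps(window.interval):
            continue
        if cls is PeakClass.EPI_SPECIFIC:
            n_epi += 1
        elif cls is PeakClass.FIBER_SPECIFIC:
            n_fiber += 1
    if n_epi >= 1 and n_fiber == 0:
        state = PromoterStateLabel.EPI_PREFERRED
    elif n_fiber >= 1 and n_epi == 0:
        state = PromoterStateLabel.FIBER_PREFERRED
    elif n_epi >= 1 and n_fiber >= 1:
        state = PromoterStateLabel.BOTH
    else:
        state = PromoterStateLabel.NONE
    return PromoterState(
        gene_id=window.gene_id, state=state, n_epi_peaks=n_epi, n_fiber_peaks=n_fiber
    )


def cross_species_promoter_states(
    states_a: Mapping[str, PromoterState],
    states_b: Mapping[str, PromoterState],
    orthologs: Sequence[OrthologPair],
) -> tuple[list[OrthologPair], list[OrthologPair]]:
    """Ortholog pairs whose promoters share the EPI_PREFERRED (first list) or
    FIBER_PREFERRED (second list) state in both species."""
    epi_pairs: list[OrthologPair] = []
    fiber_pairs: list[OrthologPair] = []
    skipped = 0
    for pair in orthologs:
        sa = states_a.get(pair.gene_a)
        sb = states_b.get(pair.gene_b)
        if sa is None or sb is None:
            skipped += 1
            continue
        if (
            sa.state is PromoterStateLabel.EPI_PREFERRED
            and sb.state is PromoterStateLabel.EPI_PREFERRED
        ):
            epi_pairs.append(pair)
        elif (
            sa.state is PromoterStateLabel.FIBER_PREFERRED
            and sb.state is PromoterStateLabel.FIBER_PREFERRED
        ):
            fiber_pairs.append(pair)
    if skipped:
        logger.info(
            "cross_species_promoter_states: skipped %d pairs with missing states",
            skipped,
        )
    return epi_pairs, fiber_pairs
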