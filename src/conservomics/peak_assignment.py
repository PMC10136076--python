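"""Nearest-TSS assignment of open-chromatin regions and class partitioning.

Each peak is assigned to the gene whose TSS is closest to the peak midpoint
(ties broken by lexicographically smallest gene_id), then peaks are split by
whether their nearest gene belongs to the conserved epithelial or conserved
fiber set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .conserved_expression import ConservedGeneSets
from .io_core import DiffPeak, TssRecord

logger = logging.getLogger(__name__)

__all__ = ["PeakAssignment", "nearest_tss", "assign_peaks", "partition_peaks_by_class"]


@dataclass(frozen=True)
class PeakAssignment:
    peak_id: str
    gene_id: str
    distance: int

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


def nearest_tss(
    peak: DiffPeak, tss_records: Sequence[TssRecord]
) -> PeakAssignment | None:
    """Assign a peak to the TSS nearest its midpoint on the same chromosome.

    Distance is ``|midpoint - tss.pos|`` with midpoint
    ``floor((start + end - 1) / 2)``; ties go to the lexicographically
    smallest gene_id.  Returns None (logged) if the chromosome has no TSS.
    """
    mid = peak.interval.midpoint
    best: tuple[int, str] | None = None
    for tss in tss_records:
        if tss.chrom != peak.interval.chrom:
            continue
        cand = (abs(mid - tss.pos), tss.gene_id)
        if best is None or cand < best:
            best = cand
    if best is None:
        logger.warning(
            "peak %s: no TSS on chromosome %s, left unassigned",
            peak.peak_id,
            peak.interval.chrom,
        )
        return None
    return PeakAssignment(peak_id=peak.peak_id, gene_id=best[1], distance=best[0])


def assign_peaks(
    peaks: Iterable[DiffPeak], tss_records: Sequence[TssRecord]
) -> list[PeakAssignment]:
    """Nearest-TSS assignment for a peak collection; unassignable peaks are
    dropped (logged by :func:`nearest_tss`)."""
    out = []
    for peak in peaks:
        assignment = nearest_tss(peak, tss_records)
        if assignment is not None:
            out.append(assignment)
    return out


def partition_peaks_by_class(
    assignments: Iterable[PeakAssignment],
    conserved: ConservedGeneSets,
    species: Literal["a", "b"] = "a",
) -> tuple[list[PeakAssignment], list[PeakAssignment]]:
    """Split assignments by conserved class of the nearest gene.

    Returns ``(epi_peaks, fiber_peaks)``; peaks nearest genes in neither
    conserved set are excluded.  ``species`` selects which side of the
    ortholog pairs the assignments' gene_ids refer to.
    """
    attr = "gene_a" if species == "a" else "gene_b"
    epi_genes = {getattr(p, attr) for p in conserved.conserved_epithelial}
    fiber_genes = {getattr(p, attr) for p in conserved.conserved_fiber}
    overlap = epi_genes & fiber_genes
    if overlap:
        raise ValueError(f"conserved sets not disjoint: {sorted(overlap)[:5]}")
    epi_peaks = []
    fiber_peaks = []
    for a in assignments:
        if a.gene_id in epi_genes:
            epi_peaks.append(a)
        elif a.gene_id in fiber_genes:
            fiber_peaks.append(a)
    return epi_peaks, fiber_peaks
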