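"""Domain types and readers/writers for the plain-text formats the pipeline consumes.

Coordinate convention is uniformly 0-based half-open (BED style).  Sequences
are always returned on the forward strand, uppercased; strand handling is the
responsibility of downstream consumers (the motif scanner scans both strands).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pyfaidx

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "DeRecord",
    "DiffPeak",
    "TssRecord",
    "OrthologPair",
    "PositionFrequencyMatrix",
    "GeneSet",
    "read_de_table",
    "write_de_table",
    "read_diff_peaks",
    "write_diff_peaks",
    "read_tss_bed",
    "write_tss_bed",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "read_gmt",
    "write_gmt",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_fasta",
    "write_fasta",
    "extract_sequences",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Midpoint base, ``floor((start + end - 1) / 2)``."""
        return (self.start + self.end - 1) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class DeRecord:
    """One gene's differential-expression evidence (fiber / epithelial)."""

    gene_id: str
    log2fc: float
    qvalue: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2fc):
            raise ValueError(f"{self.gene_id}: log2fc must be finite")
        if not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"{self.gene_id}: qvalue must be in [0, 1]")


@dataclass(frozen=True)
class DiffPeak:
    """A differential-accessibility interval with its test statistics."""

    interval: GenomicInterval
    peak_id: str
    log2fc: float
    qvalue: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"{self.peak_id}: qvalue must be in [0, 1]")


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site; ``pos`` is a 0-based coordinate."""

    gene_id: str
    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"{self.gene_id}: TSS position must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Base counts per motif position; rows are A, C, G, T."""

    motif_id: str
    tf_name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(f"{self.motif_id}: counts must be 4 x W with W >= 1")
        if np.any(counts < 0):
            raise ValueError(f"{self.motif_id}: counts must be non-negative")
        if np.any(counts.sum(axis=0) <= 0):
            raise ValueError(f"{self.motif_id}: every column sum must be > 0")

    @property
    def width(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"{self.set_id}: gene set must be non-empty")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"line {lineno}: non-numeric {what}: {text!r}") from None


def _data_lines(path: Union[str, Path]) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line:
                yield lineno, line


# ---------------------------------------------------------------------------
# differential-expression tables
# ---------------------------------------------------------------------------

def read_de_table(path: Union[str, Path]) -> list[DeRecord]:
    """Read a TSV with header columns gene_id, log2fc, qvalue.

    Row order is preserved.  Duplicate gene_ids and non-numeric fields are
    rejected with informative errors.
    """
    records: list[DeRecord] = []
    seen: set[str] = set()
    header: dict[str, int] | None = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = {name: i for i, name in enumerate(fields)}
            for required in ("gene_id", "log2fc", "qvalue"):
                if required not in header:
                    raise ValueError(f"{path}: missing column {required!r}")
            continue
        gene_id = fields[header["gene_id"]]
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r} at line {lineno}")
        seen.add(gene_id)
        records.append(
            DeRecord(
                gene_id=gene_id,
                log2fc=_parse_float(fields[header["log2fc"]], "log2fc", lineno),
                qvalue=_parse_float(fields[header["qvalue"]], "qvalue", lineno),
            )
        )
    if header is None:
        raise ValueError(f"{path}: empty file (header required)")
    return records


def write_de_table(records: Iterable[DeRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2fc\tqvalue\n")
        for rec in records:
            fh.write(f"{rec.gene_id}\t{rec.log2fc:g}\t{rec.qvalue:g}\n")


# ---------------------------------------------------------------------------
# differential ATAC peaks (BED6+2: chrom start end name score strand log2fc q)
# ---------------------------------------------------------------------------

def read_diff_peaks(path: Union[str, Path]) -> list[DiffPeak]:
    peaks: list[DiffPeak] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 8:
            raise ValueError(f"line {lineno}: expected 8 BED6+2 columns, got {len(fields)}")
        chrom, start_s, end_s, peak_id, _score, strand = fields[:6]
        start = int(_parse_float(start_s, "start", lineno))
        end = int(_parse_float(end_s, "end", lineno))
        if start >= end:
            raise ValueError(f"line {lineno}: start >= end ({start} >= {end})")
        peaks.append(
            DiffPeak(
                interval=GenomicInterval(chrom, start, end, strand),
                peak_id=peak_id,
                log2fc=_parse_float(fields[6], "log2fc", lineno),
                qvalue=_parse_float(fields[7], "qvalue", lineno),
            )
        )
    return peaks


def write_diff_peaks(peaks: Iterable[DiffPeak], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peak_id}\t0\t{iv.strand}"
                f"\t{p.log2fc:g}\t{p.qvalue:g}\n"
            )


# ---------------------------------------------------------------------------
# TSS annotation (BED6; + strand TSS = start, - strand TSS = end - 1)
# ---------------------------------------------------------------------------

def read_tss_bed(path: Union[str, Path]) -> list[TssRecord]:
    records: list[TssRecord] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"line {lineno}: expected 6 BED columns, got {len(fields)}")
        chrom, start_s, end_s, gene_id, _score, strand = fields[:6]
        if strand == ".":
            raise ValueError(
                f"line {lineno}: strand '.' not allowed (required for promoter windows)"
            )
        start, end = int(start_s), int(end_s)
        if start >= end:
            raise ValueError(f"line {lineno}: start >= end ({start} >= {end})")
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r} at line {lineno}")
        seen.add(gene_id)
        pos = start if strand == "+" else end - 1
        records.append(TssRecord(gene_id=gene_id, chrom=chrom, pos=pos, strand=strand))
    return records


def write_tss_bed(records: Iterable[TssRecord], path: Union[str, Path]) -> None:
    # 1-bp features: both strand conventions then recover the same pos.
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.gene_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# JASPAR PFM text format
# ---------------------------------------------------------------------------

def _parse_jaspar_row(line: str) -> list[float]:
    body = line.split("[", 1)[-1].rsplit("]", 1)[0] if "[" in line else line[1:]
    return [float(tok) for tok in body.split()]


def read_jaspar_pfm(path: Union[str, Path]) -> list[PositionFrequencyMatrix]:
    """Parse JASPAR 2016+ text: ``>ID NAME`` then bracketed A, C, G, T rows."""
    pfms: list[PositionFrequencyMatrix] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected '>' header, got {lines[i]!r}")
        header = lines[i][1:].split(None, 1)
        motif_id = header[0]
        tf_name = header[1].strip() if len(header) > 1 else motif_id
        rows = []
        for j, base in enumerate("ACGT"):
            if i + 1 + j >= len(lines):
                raise ValueError(f"{motif_id}: truncated record")
            row_line = lines[i + 1 + j]
            if not row_line.lstrip().upper().startswith(base):
                raise ValueError(
                    f"{motif_id}: expected row for base {base}, got {row_line!r}"
                )
            rows.append(_parse_jaspar_row(row_line.lstrip()))
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"{motif_id}: rows of unequal width {sorted(widths)}")
        pfms.append(PositionFrequencyMatrix(motif_id, tf_name, np.array(rows)))
        i += 5
    return pfms


def write_jaspar_pfm(
    pfms: Iterable[PositionFrequencyMatrix], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.motif_id} {pfm.tf_name}\n")
            for base, row in zip("ACGT", pfm.counts):
                cells = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base} [ {cells} ]\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: Union[str, Path]) -> list[GeneSet]:
    sets: list[GeneSet] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: GMT requires >= 3 tab-separated fields")
        set_id, description, members = fields[0], fields[1], fields[2:]
        unique = list(dict.fromkeys(members))
        if len(unique) != len(members):
            logger.warning(
                "gene set %s: %d duplicate members removed",
                set_id,
                len(members) - len(unique),
            )
        sets.append(GeneSet(set_id=set_id, description=description, members=unique))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for s in sets:
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.set_id}\t{s.description}\t{members}\n")


# ---------------------------------------------------------------------------
# ortholog map
# ---------------------------------------------------------------------------

def read_ortholog_map(path: Union[str, Path]) -> list[OrthologPair]:
    """Read a two-column TSV; only one-to-one pairs are retained.

    Pairs where either gene participates in more than one pair are dropped and
    the number of drops logged.
    """
    raw: list[OrthologPair] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise ValueError(f"line {lineno}: expected two non-empty columns")
        raw.append(OrthologPair(gene_a=fields[0], gene_b=fields[1]))
    from collections import Counter

    count_a = Counter(p.gene_a for p in raw)
    count_b = Counter(p.gene_b for p in raw)
    kept = [p for p in raw if count_a[p.gene_a] == 1 and count_b[p.gene_b] == 1]
    dropped = len(raw) - len(kept)
    if dropped:
        logger.info("ortholog map: dropped %d non-one-to-one pairs", dropped)
    return kept


def write_ortholog_map(pairs: Iterable[OrthologPair], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: Union[str, Path], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: Union[str, Path]) -> pyfaidx.Fasta:
    """Open a FASTA with a sidecar ``.fai`` index (created if absent)."""
    return pyfaidx.Fasta(str(path), sequence_always_upper=True)


GenomeLike = Union[pyfaidx.Fasta, Mapping[str, str]]


def extract_sequences(
    genome: GenomeLike,
    intervals: Sequence[GenomicInterval],
) -> list[tuple[GenomicInterval, str]]:
    """Extract forward-strand, uppercased sequences for the given intervals.

    ``genome`` may be an open :func:`read_fasta` handle or a plain mapping of
    chromosome name to sequence string.  Intervals extending beyond their
    chromosome are rejected.
    """
    out: list[tuple[GenomicInterval, str]] = []
    for iv in intervals:
        try:
            chrom = genome[iv.chrom]
        except KeyError:
            raise KeyError(f"chromosome {iv.chrom!r} absent from genome") from None
        if iv.end > len(chrom):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end "
                f"({len(chrom)} bp)"
            )
        seq = str(chrom[iv.start : iv.end]).upper()
        out.append((iv, seq))
    return out
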