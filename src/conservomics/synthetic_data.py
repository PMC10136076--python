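"""Self-contained two-species fixture generator with a ground-truth manifest.

Generates genomes, TSS annotations, a one-to-one ortholog map, DE tables with
planted conserved epithelial/fiber ortholog pairs, differential ATAC peaks
placed inside the planted genes' promoter windows (fiber peaks carry planted
motif instances), a motif library with decoys, and curated gene sets — all
from a single seed, so every pipeline stage's expected output is derivable
from the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .io_core import (
    DeRecord,
    DiffPeak,
    GeneSet,
    GenomicInterval,
    OrthologPair,
    PositionFrequencyMatrix,
    TssRecord,
    write_de_table,
    write_diff_peaks,
    write_fasta,
    write_gmt,
    write_jaspar_pfm,
    write_ortholog_map,
    write_tss_bed,
)
from .motif_enrichment import (
    DEFAULT_THRESHOLD_FRACTION,
    best_hit_score,
    max_achievable_score,
    pfm_to_pwm,
)

logger = logging.getLogger(__name__)

SPECIES = ("a", "b")
CHROM = {"a": "chrA", "b": "chrB"}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: the nine per-species/shared data files emitted by :func:`write_fixture`
DATA_FILES = (
    "genome_a.fa",
    "genome_b.fa",
    "tss_a.bed",
    "tss_b.bed",
    "orthologs.tsv",
    "de_a.tsv",
    "de_b.tsv",
    "peaks_a.bed",
    "peaks_b.bed",
)
EXTRA_FILES = ("motifs.jaspar", "gene_sets.gmt")
MANIFEST_FILE = "manifest.json"

__all__ = [
    "SimulationConfig",
    "GroundTruthManifest",
    "Fixture",
    "default_motif_library",
    "simulate_genome",
    "simulate_annotation_and_orthologs",
    "simulate_expression",
    "simulate_peaks_and_motifs",
    "generate_fixture",
    "write_fixture",
    "DATA_FILES",
    "EXTRA_FILES",
    "MANIFEST_FILE",
]


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 1
    n_genes_per_species: int = 150
    n_orthologs: int = 120
    n_conserved_epi: int = 25
    n_conserved_fiber: int = 25
    # 150 genes at >= 20 kb spacing need > 3 Mb, hence 4 Mb per chromosome
    chrom_length: int = 4_000_000
    de_effect_loc: float = 2.0
    de_effect_scale: float = 0.5
    de_q_planted: float = 1e-3
    peak_width: int = 400
    n_ns_peaks: int = 50
    motif_copies_per_peak: int = 2
    planted_motif_ids: tuple = ("MP001",)
    planted_epi_motif_ids: tuple = ()  # symmetric-planting mode when non-empty
    decoy_motif_ids: tuple = ("MD001", "MD002", "MD003", "MD004", "MD005")
    min_gene_spacing: int = 20_000

    def __post_init__(self) -> None:
        if not (
            self.n_conserved_epi + self.n_conserved_fiber
            <= self.n_orthologs
            <= self.n_genes_per_species
        ):
            raise ValueError("require planted <= orthologs <= genes")
        if self.spacing < self.min_gene_spacing:
            raise ValueError(
                f"{self.n_genes_per_species} genes do not fit in "
                f"{self.chrom_length} bp at >= {self.min_gene_spacing} bp spacing"
            )

    @property
    def spacing(self) -> int:
        return self.chrom_length // (self.n_genes_per_species + 1)


@dataclass
class GroundTruthManifest:
    """Everything needed to verify pipeline recovery, JSON round-trippable."""

    seed: int
    expression_class: dict = field(default_factory=dict)  # species -> gene -> label
    promoter_state: dict = field(default_factory=dict)  # species -> gene -> label
    ortholog_pairs: list = field(default_factory=list)  # [[gene_a, gene_b], ...]
    conserved_epithelial: list = field(default_factory=list)
    conserved_fiber: list = field(default_factory=list)
    peaks: dict = field(default_factory=dict)  # peak_id -> truth record
    planted_motif_ids: list = field(default_factory=list)
    decoy_motif_ids: list = field(default_factory=list)
    motif_tf_map: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)  # filename -> sha256

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        return cls(**json.loads(text))


@dataclass
class Fixture:
    """In-memory fixture; :func:`write_fixture` serializes it to a directory."""

    config: SimulationConfig
    genomes: dict  # species -> {chrom: str}
    tss: dict  # species -> list[TssRecord]
    orthologs: list
    de: dict  # species -> list[DeRecord]
    peaks: dict  # species -> list[DiffPeak]
    pfms: list
    gene_sets: list
    manifest: GroundTruthManifest


# ---------------------------------------------------------------------------
# motif library
# ---------------------------------------------------------------------------

_CONSENSUS = {
    "MP001": "TGACGTCATTCC",
    "MP002": "CCATAGGATGTA",
    "MD001": "GATTACAGGCA",
    "MD002": "CACGTGACCTAT",
    "MD003": "TTGCCAAGTCG",
    "MD004": "AGGTCAAGGTCA",
    "MD005": "CTTCGAACGGAT",
}


def default_motif_library(
    motif_ids: tuple | None = None, majority: float = 0.97
) -> list[PositionFrequencyMatrix]:
    """Deterministic strong-consensus PFMs (counts sum to 100 per column)."""
    base_idx = {b: i for i, b in enumerate("ACGT")}
    pfms = []
    for motif_id in motif_ids or tuple(_CONSENSUS):
        consensus = _CONSENSUS[motif_id]
        counts = np.full((4, len(consensus)), 100 * (1 - majority) / 3)
        for j, base in enumerate(consensus):
            counts[base_idx[base], j] = 100 * majority
        pfms.append(
            PositionFrequencyMatrix(motif_id, f"TF_{motif_id}", counts)
        )
    return pfms


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------

def _rng_for(config: SimulationConfig, stage: str) -> np.random.Generator:
    # independent, seed-derived stream per stage so stages compose freely
    return np.random.default_rng([config.seed, int.from_bytes(stage.encode(), "big")])


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """One chromosome per species, i.i.d. uniform A/C/G/T, as byte-code arrays."""
    rng = rng or _rng_for(config, "genome")
    return {
        sp: _BASES[rng.integers(0, 4, config.chrom_length)].copy() for sp in SPECIES
    }


def decode_genome(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _gene_symbol(species: str, index: int, n_orthologs: int) -> str:
    # orthologous genes share a symbol up to case (exercises case-insensitive
    # matching downstream); species-private genes get private prefixes
    if index < n_orthologs:
        stem = f"GENE{index + 1:04d}"
        return stem if species == "a" else stem.capitalize()
    return (f"GA{index + 1:04d}" if species == "a" else f"Gb{index + 1:04d}")


def simulate_annotation_and_orthologs(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, list[TssRecord]], list[OrthologPair]]:
    """Evenly spaced, jittered, strand-alternating TSS plus index-matched
    one-to-one orthologs."""
    rng = rng or _rng_for(config, "annotation")
    spacing = config.spacing
    jitter_max = spacing // 5
    tss: dict[str, list[TssRecord]] = {}
    for sp in SPECIES:
        records = []
        for i in range(config.n_genes_per_species):
            jitter = int(rng.integers(-jitter_max, jitter_max + 1))
            pos = (i + 1) * spacing + jitter
            records.append(
                TssRecord(
                    gene_id=_gene_symbol(sp, i, config.n_orthologs),
                    chrom=CHROM[sp],
                    pos=pos,
                    strand="+" if i % 2 == 0 else "-",
                )
            )
        tss[sp] = records
    orthologs = [
        OrthologPair(tss["a"][i].gene_id, tss["b"][i].gene_id)
        for i in range(config.n_orthologs)
    ]
    return tss, orthologs


def _true_class(config: SimulationConfig, index: int) -> str:
    if index < config.n_conserved_epi:
        return "EPITHELIAL"
    if index < config.n_conserved_epi + config.n_conserved_fiber:
        return "FIBER"
    return "NS"


def simulate_expression(
    config: SimulationConfig,
    tss: dict[str, list[TssRecord]],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[DeRecord]], dict[str, dict[str, str]]]:
    """DE tables with planted conserved classes.

    Planted genes draw |log2FC| ~ Normal(effect loc/scale) with the class sign
    and q ~ Uniform(1e-8, de_q_planted); all other genes draw log2FC ~
    Normal(0, 0.3) and q ~ Uniform(0.05, 1), so no null gene can reach
    significance at alpha = 0.05.
    """
    rng = rng or _rng_for(config, "expression")
    de: dict[str, list[DeRecord]] = {}
    truth: dict[str, dict[str, str]] = {}
    for sp in SPECIES:
        records = []
        truth[sp] = {}
        for i, record in enumerate(tss[sp]):
            cls = _true_class(config, i) if i < config.n_orthologs else "NS"
            if cls == "NS":
                log2fc = float(rng.normal(0.0, 0.3))
                q = float(rng.uniform(0.05, 1.0))
            else:
                effect = 0.0
                while effect == 0.0:
                    effect = abs(rng.normal(config.de_effect_loc, config.de_effect_scale))
                log2fc = -effect if cls == "EPITHELIAL" else effect
                q = float(rng.uniform(1e-8, config.de_q_planted))
            records.append(DeRecord(record.gene_id, log2fc, q))
            truth[sp][record.gene_id] = cls
        de[sp] = records
    return de, truth


def _sample_motif_instance(
    pfm: PositionFrequencyMatrix, rng: np.random.Generator
) -> str:
    """Column-wise sample from the PFM, redrawn until it scores at least the
    default hit threshold (so planted peaks are guaranteed hits); falls back
    to the consensus after 50 draws."""
    pwm = pfm_to_pwm(pfm)
    threshold = DEFAULT_THRESHOLD_FRACTION * max_achievable_score(pwm)
    probs = pfm.counts / pfm.counts.sum(axis=0)
    for attempt in range(50):
        instance = "".join(
            "ACGT"[rng.choice(4, p=probs[:, j])] for j in range(pfm.width)
        )
        if best_hit_score(instance, pwm) >= threshold:
            if attempt:
                logger.debug(
                    "%s: instance accepted after %d redraws", pfm.motif_id, attempt
                )
            return instance
    logger.info("%s: sampling failed 50 draws, using consensus", pfm.motif_id)
    return "".join("ACGT"[i] for i in pfm.counts.argmax(axis=0))


def _plant_instances(
    genome: np.ndarray,
    interval: GenomicInterval,
    pfms: list[PositionFrequencyMatrix],
    copies: int,
    rng: np.random.Generator,
) -> list[dict]:
    """Write sampled motif instances into the genome at non-overlapping
    offsets inside the peak; collisions are re-drawn (retry count logged)."""
    placed: list[tuple[int, int]] = []
    records = []
    retries = 0
    for pfm in pfms:
        for _ in range(copies):
            width = pfm.width
            while True:
                offset = int(rng.integers(0, len(interval) - width + 1))
                if all(
                    offset + width <= s or offset >= e for s, e in placed
                ):
                    break
                retries += 1
            placed.append((offset, offset + width))
            instance = _sample_motif_instance(pfm, rng)
            start = interval.start + offset
            genome[start : start + width] = np.frombuffer(
                instance.encode("ascii"), dtype=np.uint8
            )
            records.append(
                {"motif_id": pfm.motif_id, "offset": offset, "instance": instance}
            )
    if retries:
        logger.debug("motif placement: %d collision redraws", retries)
    return records


def simulate_peaks_and_motifs(
    config: SimulationConfig,
    pfms: list[PositionFrequencyMatrix],
    genomes: dict[str, np.ndarray],
    tss: dict[str, list[TssRecord]],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[DiffPeak]], dict[str, dict]]:
    """Differential peaks in planted promoter windows plus NS decoy peaks.

    Fiber peaks (log2FC +2, q 1e-4) sit 1 kb upstream of each planted
    conserved-fiber gene's TSS and carry planted motif instances; epithelial
    peaks mirror them (no motifs unless symmetric planting is configured);
    NS peaks land at random TSS-distal positions.  Genomes are modified in
    place by motif planting.
    """
    rng = rng or _rng_for(config, "peaks")
    by_id = {m.motif_id: m for m in pfms}
    fiber_pfms = [by_id[i] for i in config.planted_motif_ids]
    epi_pfms = [by_id[i] for i in config.planted_epi_motif_ids]
    half = config.peak_width // 2
    peaks: dict[str, list[DiffPeak]] = {}
    truth: dict[str, dict] = {}
    for sp in SPECIES:
        peaks[sp] = []
        counter = 0

        def _add(interval, log2fc, q, label, gene_id=None, motifs=()):
            nonlocal counter
            counter += 1
            peak_id = f"{sp}_peak{counter:03d}"
            peaks[sp].append(DiffPeak(interval, peak_id, log2fc, q))
            truth[peak_id] = {
                "species": sp,
                "label": label,
                "gene_id": gene_id,
                "motifs": list(motifs),
            }

        for i, record in enumerate(tss[sp][: config.n_orthologs]):
            cls = _true_class(config, i)
            if cls == "NS":
                continue
            center = record.pos + (-1000 if record.strand == "+" else 1000)
            interval = GenomicInterval(
                record.chrom, center - half, center + half, "."
            )
            if cls == "FIBER":
                motifs = _plant_instances(
                    genomes[sp], interval, fiber_pfms, config.motif_copies_per_peak, rng
                )
                _add(interval, 2.0, 1e-4, "FIBER_SPECIFIC", record.gene_id, motifs)
            else:
                motifs = (
                    _plant_instances(
                        genomes[sp], interval, epi_pfms,
                        config.motif_copies_per_peak, rng,
                    )
                    if epi_pfms
                    else []
                )
                _add(interval, -2.0, 1e-4, "EPI_SPECIFIC", record.gene_id, motifs)

        tss_pos = np.array([t.pos for t in tss[sp]])
        margin = 8_000 + half
        for _ in range(config.n_ns_peaks):
            while True:
                center = int(rng.integers(half, config.chrom_length - half))
                if np.min(np.abs(tss_pos - center)) > margin:
                    break
            interval = GenomicInterval(CHROM[sp], center - half, center + half, ".")
            _add(
                interval,
                float(rng.normal(0.0, 0.3)),
                float(rng.uniform(0.05, 1.0)),
                "NS",
            )
    return peaks, truth


# ---------------------------------------------------------------------------
# whole-fixture assembly
# ---------------------------------------------------------------------------

def _gene_sets(
    config: SimulationConfig,
    tss: dict[str, list[TssRecord]],
    rng: np.random.Generator,
) -> list[GeneSet]:
    symbols = [t.gene_id.upper() for t in tss["a"][: config.n_orthologs]]
    epi = symbols[: config.n_conserved_epi]
    fiber = symbols[
        config.n_conserved_epi : config.n_conserved_epi + config.n_conserved_fiber
    ]
    sets = [
        GeneSet("PLANTED_EPI", "planted conserved epithelial genes", epi),
        GeneSet("PLANTED_FIBER", "planted conserved fiber genes", fiber),
    ]
    size = max(1, min(25, config.n_orthologs))
    for i in range(3):
        members = [symbols[j] for j in rng.choice(len(symbols), size, replace=False)]
        sets.append(GeneSet(f"DECOY{i + 1}", "random ortholog genes", members))
    return sets


def generate_fixture(config: SimulationConfig) -> Fixture:
    """Generate the complete in-memory fixture for one seed."""
    genomes = simulate_genome(config)
    tss, orthologs = simulate_annotation_and_orthologs(config)
    de, expression_truth = simulate_expression(config, tss)
    all_ids = config.planted_motif_ids + config.planted_epi_motif_ids + config.decoy_motif_ids
    # tf_name carries the TF gene symbol (as in JASPAR); point every motif at
    # a planted fiber gene so the expressed-TF filter keeps the whole library
    tf_gene = tss["a"][config.n_conserved_epi].gene_id
    pfms = [
        dataclasses.replace(m, tf_name=tf_gene) for m in default_motif_library(all_ids)
    ]
    peaks, peak_truth = simulate_peaks_and_motifs(config, pfms, genomes, tss)
    gene_sets = _gene_sets(config, tss, _rng_for(config, "genesets"))

    promoter_truth: dict[str, dict[str, str]] = {}
    for sp in SPECIES:
        promoter_truth[sp] = {}
        for i, record in enumerate(tss[sp]):
            cls = expression_truth[sp][record.gene_id]
            promoter_truth[sp][record.gene_id] = {
                "EPITHELIAL": "EPI_PREFERRED",
                "FIBER": "FIBER_PREFERRED",
                "NS": "NONE",
            }[cls]

    motif_tf_map = {m.motif_id: m.tf_name for m in pfms}

    conserved_epi = [
        [orthologs[i].gene_a, orthologs[i].gene_b]
        for i in range(config.n_conserved_epi)
    ]
    conserved_fiber = [
        [orthologs[i].gene_a, orthologs[i].gene_b]
        for i in range(
            config.n_conserved_epi, config.n_conserved_epi + config.n_conserved_fiber
        )
    ]
    manifest = GroundTruthManifest(
        seed=config.seed,
        expression_class=expression_truth,
        promoter_state=promoter_truth,
        ortholog_pairs=[[p.gene_a, p.gene_b] for p in orthologs],
        conserved_epithelial=conserved_epi,
        conserved_fiber=conserved_fiber,
        peaks=peak_truth,
        planted_motif_ids=list(config.planted_motif_ids),
        decoy_motif_ids=list(config.decoy_motif_ids),
        motif_tf_map=motif_tf_map,
    )
    genome_strs = {sp: {CHROM[sp]: decode_genome(genomes[sp])} for sp in SPECIES}
    return Fixture(
        config=config,
        genomes=genome_strs,
        tss=tss,
        orthologs=orthologs,
        de=de,
        peaks=peaks,
        pfms=pfms,
        gene_sets=gene_sets,
        manifest=manifest,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture(
    fixture: Fixture, out_dir: Union[str, Path], force: bool = False
) -> GroundTruthManifest:
    """Serialize a fixture to a directory; manifest checksums cover every file.

    Refuses an existing non-empty directory unless ``force`` is set.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)

    for sp in SPECIES:
        write_fasta(fixture.genomes[sp], out / f"genome_{sp}.fa")
        write_tss_bed(fixture.tss[sp], out / f"tss_{sp}.bed")
        write_de_table(fixture.de[sp], out / f"de_{sp}.tsv")
        write_diff_peaks(fixture.peaks[sp], out / f"peaks_{sp}.bed")
    write_ortholog_map(fixture.orthologs, out / "orthologs.tsv")
    write_jaspar_pfm(fixture.pfms, out / "motifs.jaspar")
    write_gmt(fixture.gene_sets, out / "gene_sets.gmt")

    manifest = fixture.manifest
    manifest.files = {
        name: _sha256(out / name) for name in DATA_FILES + EXTRA_FILES
    }
    (out / MANIFEST_FILE).write_text(manifest.to_json())
    return manifest
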