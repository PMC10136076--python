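"""End-to-end orchestration: fixture directory in, result tables out.

The analysis itself is side-effect free (:func:`analyze` works on in-memory
inputs); :func:`run_pipeline` wraps it with file IO and deterministic TSV
serialization so that two same-seed runs produce byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

from . import (
    conserved_expression as ce,
    geneset_overlap as go,
    motif_enrichment as me,
    peak_assignment as pa,
    promoter_chromatin as pc,
)
from .io_core import (
    DeRecord,
    DiffPeak,
    GeneSet,
    OrthologPair,
    PositionFrequencyMatrix,
    TssRecord,
    extract_sequences,
    read_de_table,
    read_diff_peaks,
    read_fasta,
    read_gmt,
    read_jaspar_pfm,
    read_ortholog_map,
    read_tss_bed,
)

logger = logging.getLogger(__name__)

SPECIES = ("a", "b")
FAMILIES = ("epi", "fiber", "epi_vs_fiber", "fiber_vs_epi")

__all__ = ["PipelineInputs", "PipelineResult", "analyze", "load_inputs", "run_pipeline"]


@dataclass
class PipelineInputs:
    de: dict  # species -> list[DeRecord]
    tss: dict  # species -> list[TssRecord]
    peaks: dict  # species -> list[DiffPeak]
    orthologs: list
    genomes: dict  # species -> genome mapping (chrom -> sequence-like)
    pfms: list
    gene_sets: list = field(default_factory=list)

    @classmethod
    def from_fixture(cls, fixture) -> "PipelineInputs":
        """Wrap an in-memory :class:`~conservomics.synthetic_data.Fixture`."""
        return cls(
            de=fixture.de,
            tss=fixture.tss,
            peaks=fixture.peaks,
            orthologs=fixture.orthologs,
            genomes=fixture.genomes,
            pfms=fixture.pfms,
            gene_sets=fixture.gene_sets,
        )


@dataclass
class PipelineResult:
    labels: dict
    conserved: ce.ConservedGeneSets
    association: dict
    promoter_states: dict  # species -> {gene_id: PromoterState}
    conserved_promoters: tuple
    assignments: dict  # species -> list[PeakAssignment]
    partitions: dict  # species -> (epi assignments, fiber assignments)
    motif_results: dict  # (species, family) -> {motif_id: MotifEnrichmentResult}
    motif_labels: dict  # species -> {motif_id: MotifPartition}
    combined_motif_labels: dict
    filtered_motif_labels: dict
    ora: dict  # query name -> list[OverlapReport]


def load_inputs(fixture_dir: Union[str, Path]) -> PipelineInputs:
    d = Path(fixture_dir)
    return PipelineInputs(
        de={sp: read_de_table(d / f"de_{sp}.tsv") for sp in SPECIES},
        tss={sp: read_tss_bed(d / f"tss_{sp}.bed") for sp in SPECIES},
        peaks={sp: read_diff_peaks(d / f"peaks_{sp}.bed") for sp in SPECIES},
        orthologs=read_ortholog_map(d / "orthologs.tsv"),
        genomes={sp: read_fasta(d / f"genome_{sp}.fa") for sp in SPECIES},
        pfms=read_jaspar_pfm(d / "motifs.jaspar"),
        gene_sets=read_gmt(d / "gene_sets.gmt") if (d / "gene_sets.gmt").exists() else [],
    )


def _peak_sequences(
    genome, peaks_by_id: Mapping[str, DiffPeak], assignments: Sequence
) -> list[str]:
    intervals = [peaks_by_id[a.peak_id].interval for a in assignments]
    return [seq for _, seq in extract_sequences(genome, intervals)]


def analyze(
    inputs: PipelineInputs,
    alpha: float = 0.05,
    threshold_fraction: float = me.DEFAULT_THRESHOLD_FRACTION,
    seed: int = 17,
) -> PipelineResult:
    """Run every stage on in-memory inputs."""
    labels = {
        sp: ce.classify_expression(inputs.de[sp], alpha=alpha) for sp in SPECIES
    }
    conserved = ce.intersect_conserved(labels["a"], labels["b"], inputs.orthologs)
    association = ce.overlap_association_matrix(conserved)

    labelled_peaks = {
        sp: pc.classify_diff_peaks(inputs.peaks[sp], alpha=alpha) for sp in SPECIES
    }
    promoter_states = {}
    for sp in SPECIES:
        states = {}
        for tss in inputs.tss[sp]:
            chrom_length = (
                len(inputs.genomes[sp][tss.chrom]) if inputs.genomes else None
            )
            window = pc.build_promoter_window(tss, chrom_length=chrom_length)
            states[tss.gene_id] = pc.classify_promoter_state(
                window, labelled_peaks[sp]
            )
        promoter_states[sp] = states
    conserved_promoters = pc.cross_species_promoter_states(
        promoter_states["a"], promoter_states["b"], inputs.orthologs
    )

    assignments = {
        sp: pa.assign_peaks(inputs.peaks[sp], inputs.tss[sp]) for sp in SPECIES
    }
    partitions = {
        sp: pa.partition_peaks_by_class(assignments[sp], conserved, species=sp)
        for sp in SPECIES
    }

    pwms = [me.pfm_to_pwm(pfm) for pfm in inputs.pfms]
    motif_results: dict = {}
    motif_labels: dict = {}
    for i, sp in enumerate(SPECIES):
        peaks_by_id = {p.peak_id: p for p in inputs.peaks[sp]}
        epi_seqs = _peak_sequences(inputs.genomes[sp], peaks_by_id, partitions[sp][0])
        fiber_seqs = _peak_sequences(inputs.genomes[sp], peaks_by_id, partitions[sp][1])
        if not epi_seqs or not fiber_seqs:
            logger.warning(
                "species %s: empty peak class (%d epi, %d fiber), motif stage skipped",
                sp,
                len(epi_seqs),
                len(fiber_seqs),
            )
            for family in FAMILIES:
                motif_results[(sp, family)] = {
                    pwm.motif_id: me.MotifEnrichmentResult(
                        pwm.motif_id, pwm.tf_name, 0, 0, 0, 0, 1.0, 1.0
                    )
                    for pwm in pwms
                }
            motif_labels[sp] = {
                pwm.motif_id: me.MotifPartition.NONE for pwm in pwms
            }
            continue
        shuf_epi = me.shuffle_control(epi_seqs, seed=seed + 2 * i)
        shuf_fiber = me.shuffle_control(fiber_seqs, seed=seed + 2 * i + 1)
        fam_inputs = {
            "epi": (epi_seqs, shuf_epi),
            "fiber": (fiber_seqs, shuf_fiber),
            "epi_vs_fiber": (epi_seqs, fiber_seqs),
            "fiber_vs_epi": (fiber_seqs, epi_seqs),
        }
        for family, (fg, bg) in fam_inputs.items():
            motif_results[(sp, family)] = me.run_enrichment(
                fg, bg, pwms, threshold_fraction
            )
        motif_labels[sp] = me.partition_motifs(
            motif_results[(sp, "epi")],
            motif_results[(sp, "fiber")],
            motif_results[(sp, "epi_vs_fiber")],
            motif_results[(sp, "fiber_vs_epi")],
            alpha=alpha,
        )
    combined = me.combine_species_labels(motif_labels["a"], motif_labels["b"])
    motif_tf_map = {pfm.motif_id: pfm.tf_name for pfm in inputs.pfms}
    filtered = me.expression_filter(
        combined, motif_tf_map, inputs.de["a"], inputs.de["b"]
    )

    ora_results: dict = {}
    if inputs.gene_sets:
        universe_pairs = [
            p
            for p in inputs.orthologs
            if p.gene_a in labels["a"] and p.gene_b in labels["b"]
        ]
        universe = [p.gene_a for p in universe_pairs]
        for name, pairs in (
            ("conserved_epithelial", conserved.conserved_epithelial),
            ("conserved_fiber", conserved.conserved_fiber),
        ):
            query = [p.gene_a for p in pairs]
            if query:
                ora_results[name] = go.ora(
                    query, inputs.gene_sets, universe, alpha=alpha, query_id=name
                )

    return PipelineResult(
        labels=labels,
        conserved=conserved,
        association=association,
        promoter_states=promoter_states,
        conserved_promoters=conserved_promoters,
        assignments=assignments,
        partitions=partitions,
        motif_results=motif_results,
        motif_labels=motif_labels,
        combined_motif_labels=combined,
        filtered_motif_labels=filtered,
        ora=ora_results,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _write_tsv(path: Path, header: Sequence[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def write_result_tables(result: PipelineResult, out_dir: Union[str, Path]) -> list[str]:
    """Write every stage's output as deterministic TSV tables; returns the
    list of file names written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def emit(name, header, rows):
        _write_tsv(out / name, header, rows)
        written.append(name)

    for sp in SPECIES:
        emit(
            f"expression_classes_{sp}.tsv",
            ["gene_id", "label"],
            sorted((g, lab.value) for g, lab in result.labels[sp].items()),
        )
        emit(
            f"promoter_states_{sp}.tsv",
            ["gene_id", "state", "n_epi_peaks", "n_fiber_peaks"],
            sorted(
                (s.gene_id, s.state.value, s.n_epi_peaks, s.n_fiber_peaks)
                for s in result.promoter_states[sp].values()
            ),
        )
        emit(
            f"peak_assignments_{sp}.tsv",
            ["peak_id", "gene_id", "distance"],
            sorted((a.peak_id, a.gene_id, a.distance) for a in result.assignments[sp]),
        )

    emit(
        "conserved_genes.tsv",
        ["conserved_class", "gene_a", "gene_b"],
        sorted(
            [("EPITHELIAL", p.gene_a, p.gene_b) for p in result.conserved.conserved_epithelial]
            + [("FIBER", p.gene_a, p.gene_b) for p in result.conserved.conserved_fiber]
        ),
    )
    emit(
        "association_tests.tsv",
        ["class_a", "class_b", "k", "K", "n", "N", "p"],
        [
            (ca.value, cb.value, r.k, r.K, r.n, r.N, f"{r.p:.6g}")
            for (ca, cb), r in sorted(
                result.association.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
            )
        ],
    )
    epi_pairs, fiber_pairs = result.conserved_promoters
    emit(
        "conserved_promoters.tsv",
        ["promoter_state", "gene_a", "gene_b"],
        sorted(
            [("EPI_PREFERRED", p.gene_a, p.gene_b) for p in epi_pairs]
            + [("FIBER_PREFERRED", p.gene_a, p.gene_b) for p in fiber_pairs]
        ),
    )
    for (sp, family), results in sorted(result.motif_results.items()):
        emit(
            f"motif_results_{sp}_{family}.tsv",
            ["motif_id", "tf_name", "fg_hits", "fg_n", "bg_hits", "bg_n", "p", "q"],
            [
                (
                    r.motif_id,
                    r.tf_name,
                    r.fg_hits,
                    r.fg_n,
                    r.bg_hits,
                    r.bg_n,
                    f"{r.p:.6g}",
                    f"{r.q:.6g}",
                )
                for r in sorted(results.values(), key=lambda r: r.motif_id)
            ],
        )
    emit(
        "motif_partition.tsv",
        ["motif_id", "label_a", "label_b", "combined", "expressed_tf"],
        [
            (
                m,
                result.motif_labels["a"][m].value,
                result.motif_labels["b"][m].value,
                result.combined_motif_labels[m].value,
                "yes" if m in result.filtered_motif_labels else "no",
            )
            for m in sorted(result.combined_motif_labels)
        ],
    )
    for name, reports in sorted(result.ora.items()):
        emit(
            f"ora_{name}.tsv",
            ["query_id", "set_id", "k", "n", "K", "N", "percent", "p", "q"],
            [
                (
                    r.query_id,
                    r.set_id,
                    r.k,
                    r.n,
                    r.K,
                    r.N,
                    f"{r.percent:.2f}",
                    f"{r.p:.6g}",
                    f"{r.q:.6g}",
                )
                for r in reports
            ],
        )
    return written


def run_pipeline(
    fixture_dir: Union[str, Path],
    out_dir: Union[str, Path],
    alpha: float = 0.05,
    threshold_fraction: float = me.DEFAULT_THRESHOLD_FRACTION,
    seed: int = 17,
) -> PipelineResult:
    """Load a fixture directory, analyze it, and write result tables."""
    inputs = load_inputs(fixture_dir)
    result = analyze(
        inputs, alpha=alpha, threshold_fraction=threshold_fraction, seed=seed
    )
    write_result_tables(result, out_dir)
    return result
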