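import hashlib
import json

import numpy as np
import pytest

from conservomics.conserved_expression import classify_expression
from conservomics.synthetic_data import (
    DATA_FILES,
    EXTRA_FILES,
    MANIFEST_FILE,
    GroundTruthManifest,
    SimulationConfig,
    decode_genome,
    default_motif_library,
    generate_fixture,
    simulate_annotation_and_orthologs,
    simulate_expression,
    simulate_genome,
    write_fixture,
)


class TestSimulationConfig:
    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="planted"):
            SimulationConfig(n_orthologs=200, n_genes_per_species=150)

    def test_genes_must_fit(self):
        with pytest.raises(ValueError, match="do not fit"):
            SimulationConfig(chrom_length=1_000_000)


class TestSimulateGenome:
    def test_length(self, small_config):
        genomes = simulate_genome(small_config)
        for arr in genomes.values():
            assert arr.size == small_config.chrom_length

    def test_determinism(self, small_config):
        a = simulate_genome(small_config)
        b = simulate_genome(small_config)
        for sp in a:
            assert a[sp].tobytes() == b[sp].tobytes()

    def test_base_frequencies(self):
        cfg = SimulationConfig(seed=2)
        genomes = simulate_genome(cfg)
        seq = decode_genome(genomes["a"])
        for base in "ACGT":
            assert abs(seq.count(base) / len(seq) - 0.25) < 0.01


class TestAnnotationAndOrthologs:
    def test_counts(self, small_config):
        tss, orthologs = simulate_annotation_and_orthologs(small_config)
        assert len(tss["a"]) == small_config.n_genes_per_species
        assert len(orthologs) == small_config.n_orthologs

    def test_spacing_bound(self, small_config):
        tss, _ = simulate_annotation_and_orthologs(small_config)
        for sp in ("a", "b"):
            positions = [t.pos for t in tss[sp]]
            gaps = np.diff(positions)
            assert gaps.min() >= 10_000

    def test_strand_alternation(self, small_config):
        tss, _ = simulate_annotation_and_orthologs(small_config)
        strands = [t.strand for t in tss["a"]]
        assert strands.count("+") == strands.count("-")
        assert strands[:2] == ["+", "-"]


class TestSimulateExpression:
    def test_planted_labels_recovered(self, small_config):
        tss, _ = simulate_annotation_and_orthologs(small_config)
        de, truth = simulate_expression(small_config, tss)
        for sp in ("a", "b"):
            labels = classify_expression(de[sp])
            for gene, cls in truth[sp].items():
                assert labels[gene].value == cls

    def test_no_null_gene_significant(self, small_config):
        tss, _ = simulate_annotation_and_orthologs(small_config)
        de, truth = simulate_expression(small_config, tss)
        for sp in ("a", "b"):
            for rec in de[sp]:
                if truth[sp][rec.gene_id] == "NS":
                    assert rec.qvalue >= 0.05

    def test_determinism(self, small_config):
        tss, _ = simulate_annotation_and_orthologs(small_config)
        de1, _ = simulate_expression(small_config, tss)
        de2, _ = simulate_expression(small_config, tss)
        assert de1 == de2


class TestPeaksAndMotifs:
    def test_planted_peaks_in_promoter_windows(self, small_fixture):
        from conservomics.promoter_chromatin import build_promoter_window

        fx = small_fixture
        for sp in ("a", "b"):
            tss_by_gene = {t.gene_id: t for t in fx.tss[sp]}
            peaks_by_id = {p.peak_id: p for p in fx.peaks[sp]}
            for pid, rec in fx.manifest.peaks.items():
                if rec["species"] != sp or not rec["gene_id"]:
                    continue
                window = build_promoter_window(tss_by_gene[rec["gene_id"]])
                assert peaks_by_id[pid].interval.overlaps(window.interval)

    def test_motif_instances_within_peaks_and_genome(self, small_fixture):
        fx = small_fixture
        for pid, rec in fx.manifest.peaks.items():
            sp = rec["species"]
            peak = next(p for p in fx.peaks[sp] if p.peak_id == pid)
            chrom_seq = fx.genomes[sp][peak.interval.chrom]
            for m in rec["motifs"]:
                offset, instance = m["offset"], m["instance"]
                assert 0 <= offset <= len(peak.interval) - len(instance)
                start = peak.interval.start + offset
                assert chrom_seq[start : start + len(instance)] == instance

    def test_fiber_peaks_carry_motifs_epi_do_not(self, small_fixture):
        for rec in small_fixture.manifest.peaks.values():
            if rec["label"] == "FIBER_SPECIFIC":
                assert len(rec["motifs"]) > 0
            else:
                assert rec["motifs"] == []

    def test_symmetric_planting_mode(self):
        cfg = SimulationConfig(
            seed=5,
            n_genes_per_species=20,
            n_orthologs=16,
            n_conserved_epi=4,
            n_conserved_fiber=4,
            chrom_length=500_000,
            n_ns_peaks=4,
            planted_epi_motif_ids=("MP002",),
        )
        fx = generate_fixture(cfg)
        epi_recs = [
            r for r in fx.manifest.peaks.values() if r["label"] == "EPI_SPECIFIC"
        ]
        assert epi_recs and all(
            m["motif_id"] == "MP002" for r in epi_recs for m in r["motifs"]
        )


class TestDefaultMotifLibrary:
    def test_column_majority(self):
        for pfm in default_motif_library():
            probs = pfm.counts / pfm.counts.sum(axis=0)
            assert np.all(probs.max(axis=0) >= 0.9)

    def test_ids_unique(self):
        ids = [m.motif_id for m in default_motif_library()]
        assert len(ids) == len(set(ids))


class TestWriteFixture:
    def test_emits_data_files_and_manifest(self, small_fixture, tmp_path):
        out = tmp_path / "fx"
        write_fixture(small_fixture, out)
        names = {p.name for p in out.iterdir()}
        assert set(DATA_FILES) <= names
        assert set(EXTRA_FILES) <= names
        assert MANIFEST_FILE in names
        assert len(DATA_FILES) == 9

    def test_checksums_match_disk(self, small_fixture, tmp_path):
        out = tmp_path / "fx"
        manifest = write_fixture(small_fixture, out)
        for name, digest in manifest.files.items():
            assert hashlib.sha256((out / name).read_bytes()).hexdigest() == digest

    def test_same_seed_identical_checksums(self, small_config, tmp_path):
        m1 = write_fixture(generate_fixture(small_config), tmp_path / "fx1")
        m2 = write_fixture(generate_fixture(small_config), tmp_path / "fx2")
        assert m1.files == m2.files

    def test_nonempty_dir_requires_force(self, small_fixture, tmp_path):
        out = tmp_path / "fx"
        out.mkdir()
        (out / "existing.txt").write_text("x")
        with pytest.raises(FileExistsError):
            write_fixture(small_fixture, out)
        write_fixture(small_fixture, out, force=True)

    def test_manifest_roundtrip(self, small_fixture, tmp_path):
        out = tmp_path / "fx"
        manifest = write_fixture(small_fixture, out)
        text = (out / MANIFEST_FILE).read_text()
        back = GroundTruthManifest.from_json(text)
        assert back == manifest
        assert json.loads(back.to_json()) == json.loads(text)
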