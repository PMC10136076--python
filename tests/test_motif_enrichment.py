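import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conservomics.io_core import DeRecord, PositionFrequencyMatrix
from conservomics.motif_enrichment import (
    MotifEnrichmentResult,
    MotifPartition,
    best_hit_score,
    bh_adjust,
    combine_species_labels,
    count_hits,
    dinucleotide_shuffle,
    expression_filter,
    fisher_motif_test,
    max_achievable_score,
    partition_motifs,
    pfm_to_pwm,
    shuffle_control,
)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_best(seq: str, pwm) -> float:
    """Placement-enumeration oracle, independent of the vectorized scanner."""
    width = pwm.width
    if len(seq) < width:
        return -math.inf
    best = -math.inf
    for s in (seq, revcomp(seq)):
        for i in range(len(s) - width + 1):
            total = 0.0
            for j in range(width):
                base = s[i + j]
                if base in "ACGT":
                    total += pwm.logodds["ACGT".index(base), j]
                else:
                    total = -math.inf
            best = max(best, total)
    return best


def _pfm(counts, motif_id="M1", tf_name="TF1"):
    return PositionFrequencyMatrix(motif_id, tf_name, np.array(counts, dtype=float))


@pytest.fixture()
def strong_pwm():
    # consensus ACGT with strong columns
    counts = np.full((4, 4), 1.0)
    for j, base in enumerate("ACGT"):
        counts["ACGT".index(base), j] = 97.0
    return pfm_to_pwm(_pfm(counts))


class TestPfmToPwm:
    def test_hand_arithmetic(self):
        pwm = pfm_to_pwm(_pfm([[2], [0], [0], [2]]), pseudocount=1.0)
        assert pwm.logodds[0, 0] == pytest.approx(math.log2(0.45 / 0.25), abs=1e-12)
        assert pwm.logodds[0, 0] == pytest.approx(0.8480, abs=1e-4)

    def test_uniform_column_zero_logodds(self):
        pwm = pfm_to_pwm(_pfm([[5], [5], [5], [5]]))
        np.testing.assert_allclose(pwm.logodds, 0.0, atol=1e-12)

    def test_probability_columns_sum_to_one(self):
        pwm = pfm_to_pwm(_pfm([[2, 8], [1, 0], [0, 1], [5, 3]]))
        probs = np.exp2(pwm.logodds) * pwm.background[:, None]
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-9)

    def test_zero_pseudocount_gives_neg_inf(self):
        pwm = pfm_to_pwm(_pfm([[2], [0], [0], [2]]), pseudocount=0.0)
        assert pwm.logodds[1, 0] == -np.inf

    def test_zero_background_with_count_rejected(self):
        with pytest.raises(ValueError):
            pfm_to_pwm(_pfm([[2], [1], [1], [1]]), background=[0.5, 0.25, 0.0, 0.25])

    def test_zero_background_with_zero_count_permitted(self):
        pwm = pfm_to_pwm(
            _pfm([[2], [1], [0], [1]]), background=[0.5, 0.25, 0.0, 0.25]
        )
        assert pwm.logodds[2, 0] == -np.inf


class TestBestHitScore:
    def test_consensus_achieves_max(self, strong_pwm):
        assert best_hit_score("ACGT", strong_pwm) == pytest.approx(
            max_achievable_score(strong_pwm)
        )

    def test_strand_symmetry_consensus(self, strong_pwm):
        assert best_hit_score(revcomp("ACGT"), strong_pwm) == best_hit_score(
            "ACGT", strong_pwm
        )

    def test_strand_symmetry_random(self, strong_pwm, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGTN"), size=60))
            assert best_hit_score(seq, strong_pwm) == best_hit_score(
                revcomp(seq), strong_pwm
            )

    def test_matches_brute_force(self, rng):
        pfms = [
            _pfm(rng.integers(0, 20, size=(4, w)) + 1, motif_id=f"M{w}")
            for w in (4, 7, 11)
        ]
        pwms = [pfm_to_pwm(p) for p in pfms]
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            for pwm in pwms:
                assert best_hit_score(seq, pwm) == brute_force_best(seq, pwm)

    def test_n_scores_neg_inf(self, strong_pwm):
        assert best_hit_score("NNNN", strong_pwm) == -np.inf

    def test_short_sequence_warns(self, strong_pwm):
        with pytest.warns(UserWarning, match="shorter"):
            assert best_hit_score("AC", strong_pwm) == -np.inf


class TestCountHits:
    def test_consensus_containing_sequence_hits(self, strong_pwm, rng):
        seq = "".join(rng.choice(list("ACGT"), size=50)) + "ACGT"
        assert count_hits([seq], strong_pwm, 0.75) == 1

    def test_all_n_not_hit(self, strong_pwm):
        assert count_hits(["N" * 50], strong_pwm, 0.75) == 0

    def test_bad_fraction(self, strong_pwm):
        with pytest.raises(ValueError):
            count_hits([], strong_pwm, 0.0)

    def test_planted_fixture_hit_rate_one(self, default_fixture):
        from conservomics.io_core import extract_sequences
        from conservomics.motif_enrichment import pfm_to_pwm

        fx = default_fixture
        pwm = pfm_to_pwm(next(m for m in fx.pfms if m.motif_id == "MP001"))
        for sp in ("a", "b"):
            planted = [
                p
                for p in fx.peaks[sp]
                if fx.manifest.peaks[p.peak_id]["label"] == "FIBER_SPECIFIC"
            ]
            seqs = [
                s
                for _, s in extract_sequences(
                    fx.genomes[sp], [p.interval for p in planted]
                )
            ]
            assert count_hits(seqs, pwm, 0.75) == len(seqs)


class TestDinucleotideShuffle:
    def test_single_symbol_fixed_point(self, rng):
        assert dinucleotide_shuffle("AAAA", rng) == "AAAA"

    def test_dinucleotide_counts_preserved(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGTN"), size=80))
            shuf = dinucleotide_shuffle(seq, rng)
            assert len(shuf) == len(seq)
            assert Counter(zip(seq, seq[1:])) == Counter(zip(shuf, shuf[1:]))

    def test_endpoints_preserved(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=60))
        shuf = dinucleotide_shuffle(seq, rng)
        assert (shuf[0], shuf[-1]) == (seq[0], seq[-1])

    def test_shuffle_control_deterministic(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(5)]
        assert shuffle_control(seqs, seed=11) == shuffle_control(seqs, seed=11)

    def test_shuffle_control_empty_rejected(self):
        with pytest.raises(ValueError):
            shuffle_control([], seed=1)


class TestFisherMotifTest:
    def test_worked_table(self):
        # C(3,3) C(17,7) / C(20,10) = 19448 / 184756
        assert fisher_motif_test(3, 10, 0, 10) == pytest.approx(
            19448 / 184756, abs=1e-12
        )

    def test_zero_foreground_hits(self):
        assert fisher_motif_test(0, 10, 5, 10) == 1.0

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            fisher_motif_test(11, 10, 0, 10)


class TestBhAdjust:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-15
        )

    def test_single_value(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=40)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=25))
    @settings(max_examples=100)
    def test_matches_naive_formula(self, pvalues):
        # naive oracle: q_(i) = min_{j >= i} p_(j) * m / j on the sorted scale
        p = np.asarray(pvalues)
        m = p.size
        order = np.argsort(p, kind="stable")
        expected = np.empty(m)
        for rank_pos, idx in enumerate(order):
            candidates = [
                p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
            ]
            expected[idx] = min(1.0, min(candidates))
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


def _result(motif_id, q):
    return MotifEnrichmentResult(motif_id, "TF", 0, 10, 0, 10, min(q, 1.0), q)


def _families(motif_id, qE, qF, qDE, qDF):
    return (
        {motif_id: _result(motif_id, qE)},
        {motif_id: _result(motif_id, qF)},
        {motif_id: _result(motif_id, qDE)},
        {motif_id: _result(motif_id, qDF)},
    )


class TestPartitionMotifs:
    def test_epi_only(self):
        labels = partition_motifs(*_families("m", 0.001, 0.8, 0.9, 0.9))
        assert labels["m"] is MotifPartition.EPI_ONLY

    def test_epi_preferred(self):
        labels = partition_motifs(*_families("m", 0.001, 0.001, 0.01, 0.9))
        assert labels["m"] is MotifPartition.EPI_PREFERRED

    def test_fiber_only(self):
        labels = partition_motifs(*_families("m", 0.8, 0.001, 0.9, 0.9))
        assert labels["m"] is MotifPartition.FIBER_ONLY

    def test_fiber_preferred(self):
        labels = partition_motifs(*_families("m", 0.01, 0.001, 0.9, 0.01))
        assert labels["m"] is MotifPartition.FIBER_PREFERRED

    def test_shared(self):
        labels = partition_motifs(*_families("m", 0.01, 0.01, 0.9, 0.9))
        assert labels["m"] is MotifPartition.SHARED

    def test_none(self):
        labels = partition_motifs(*_families("m", 0.9, 0.9, 0.9, 0.9))
        assert labels["m"] is MotifPartition.NONE

    def test_epi_preferred_precedence(self, caplog):
        with caplog.at_level("INFO"):
            labels = partition_motifs(*_families("m", 0.01, 0.01, 0.01, 0.01))
        assert labels["m"] is MotifPartition.EPI_PREFERRED

    def test_missing_motif_named(self):
        epi, fib, de, df = _families("m", 0.5, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError, match="fiber"):
            partition_motifs(epi, {}, de, df)

    @pytest.mark.parametrize("bits", range(16))
    def test_exhaustive_single_label(self, bits):
        qs = [0.01 if bits & (1 << i) else 0.9 for i in range(4)]
        labels = partition_motifs(*_families("m", *qs))
        assert isinstance(labels["m"], MotifPartition)
        assert len(labels) == 1


class TestCombineSpeciesLabels:
    @pytest.mark.parametrize(
        "la,lb,expected",
        [
            ("FIBER_ONLY", "FIBER_ONLY", "FIBER_ONLY"),
            ("FIBER_ONLY", "FIBER_PREFERRED", "FIBER_PREFERRED"),
            ("EPI_ONLY", "EPI_PREFERRED", "EPI_PREFERRED"),
            ("SHARED", "SHARED", "SHARED"),
            ("FIBER_ONLY", "EPI_ONLY", "NONE"),
            ("FIBER_ONLY", "NONE", "NONE"),
        ],
    )
    def test_rules(self, la, lb, expected):
        out = combine_species_labels(
            {"m": MotifPartition(la)}, {"m": MotifPartition(lb)}
        )
        assert out["m"] is MotifPartition(expected)

    def test_mismatched_libraries(self):
        with pytest.raises(ValueError):
            combine_species_labels({"m": MotifPartition.NONE}, {})


class TestExpressionFilter:
    def _de(self, *genes):
        return [DeRecord(g, 0.0, 0.5) for g in genes]

    def test_present_in_both_kept(self):
        out = expression_filter(
            {"m": MotifPartition.FIBER_ONLY},
            {"m": "Pax6"},
            self._de("PAX6", "GJA1"),
            self._de("pax6"),
        )
        assert out == {"m": MotifPartition.FIBER_ONLY}

    def test_present_in_one_dropped(self):
        out = expression_filter(
            {"m": MotifPartition.FIBER_ONLY},
            {"m": "PAX6"},
            self._de("PAX6"),
            self._de("GJA1"),
        )
        assert out == {}

    def test_unmapped_dropped_with_log(self, caplog):
        with caplog.at_level("WARNING"):
            out = expression_filter(
                {"m": MotifPartition.FIBER_ONLY}, {}, self._de("X"), self._de("X")
            )
        assert out == {}
        assert any("no TF mapping" in r.message for r in caplog.records)
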