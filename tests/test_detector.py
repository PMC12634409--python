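"""Maximal-run scanning: oracle equivalence and scan invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import MIXED_EXAMPLE, random_sequence
from naive_oracle import oracle_scan
from zdnascan.detector import RunScanner, ScanParams, ZfsHit, scan_sequence
from zdnascan.scoring import MODEL_1, MODEL_2
from zdnascan.sequence_io import reverse_complement

DEFAULTS = ScanParams()

dna = st.text(alphabet="ACGTNacgt", min_size=0, max_size=300)


def as_dicts(hits):
    return [dict(sequence_id=h.sequence_id, start=h.start, end=h.end,
                 sequence=h.sequence.upper(), raw_score=h.raw_score,
                 score_percent=pytest.approx(h.score_percent),
                 gc_richness=pytest.approx(h.gc_richness),
                 gt_richness=pytest.approx(h.gt_richness)) for h in hits]


def oracle_dicts(seq, model, params):
    out = []
    for h in oracle_scan(seq, model, params):
        h = dict(h)
        h["sequence"] = h["sequence"].upper()
        out.append(h)
    return out


class TestScanParams:
    def test_min_length_floor(self):
        with pytest.raises(ValueError):
            ScanParams(min_length=1)

    def test_percent_range(self):
        with pytest.raises(ValueError):
            ScanParams(min_score_percent=101)


class TestWorkedExamples:
    def test_planted_gc_repeat(self):
        rec = "AAAA" + "GC" * 8 + "TTTT"
        hits = scan_sequence(rec, MODEL_1, DEFAULTS)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.length) == (4, 20, 16)
        assert h.score_percent == pytest.approx(100.0)

    def test_mixed_example_rejected_by_strict_model(self):
        assert scan_sequence(MIXED_EXAMPLE, MODEL_1, DEFAULTS) == []

    def test_mixed_example_rescued_by_permissive_model(self):
        (h,) = scan_sequence(MIXED_EXAMPLE, MODEL_2, DEFAULTS)
        assert (h.start, h.end) == (0, 14)
        assert h.raw_score == pytest.approx(16.5)
        assert h.score_percent == pytest.approx(63.46, abs=0.01)

    def test_ca_repeat_scores_half_under_permissive_model(self):
        (h,) = scan_sequence("CA" * 20, MODEL_2, DEFAULTS)
        assert (h.start, h.end) == (0, 40)
        assert h.score_percent == pytest.approx(50.0)

    def test_all_n_and_empty_yield_nothing(self):
        assert scan_sequence("N" * 50, MODEL_1, DEFAULTS) == []
        assert scan_sequence("", MODEL_1, DEFAULTS) == []


@pytest.mark.parametrize("model", [MODEL_1, MODEL_2], ids=lambda m: m.name)
class TestOracleEquivalence:
    def test_random_sequences_match_oracle(self, rng, model):
        params = ScanParams(min_length=4, min_score_percent=30)
        for _ in range(150):
            seq = random_sequence(rng, int(rng.integers(2, 400)), "ACGTN")
            assert as_dicts(scan_sequence(seq, model, params)) == \
                oracle_dicts(seq, model, params)

    def test_repeat_rich_sequences_match_oracle(self, rng, model):
        units = ["GC", "CA", "AT", "GCGT", "A", "N"]
        for _ in range(100):
            seq = "".join(units[int(rng.integers(0, len(units)))]
                          * int(rng.integers(1, 12))
                          for _ in range(int(rng.integers(1, 30))))
            assert as_dicts(scan_sequence(seq, model, DEFAULTS)) == \
                oracle_dicts(seq, model, DEFAULTS)


class TestInvariants:
    @given(dna)
    def test_hypothesis_oracle_equivalence(self, seq):
        params = ScanParams(min_length=3, min_score_percent=20)
        assert as_dicts(scan_sequence(seq, MODEL_2, params)) == \
            oracle_dicts(seq, MODEL_2, params)

    @given(dna)
    def test_strand_symmetry(self, seq):
        fwd = scan_sequence(seq, MODEL_2, DEFAULTS)
        rev = scan_sequence(reverse_complement(seq), MODEL_2, DEFAULTS)
        L = len(seq)
        mirrored = sorted((L - h.end, L - h.start, round(h.raw_score, 9),
                           round(h.score_percent, 6), round(h.gc_richness, 6),
                           round(h.gt_richness, 6)) for h in fwd)
        actual = sorted((h.start, h.end, round(h.raw_score, 9),
                         round(h.score_percent, 6), round(h.gc_richness, 6),
                         round(h.gt_richness, 6)) for h in rev)
        assert actual == mirrored

    @given(dna, dna)
    def test_concatenation_locality(self, left, right):
        # when the junction carries an AA break step, no run can span
        # it, so each flank's hits are exactly preserved
        params = ScanParams(min_length=4, min_score_percent=25)
        left, right = left + "A", "A" + right
        combined = scan_sequence(left + right, MODEL_2, params)
        expected = [(h.start, h.end) for h in scan_sequence(left, MODEL_2,
                                                            params)]
        off = len(left)
        expected += [(h.start + off, h.end + off)
                     for h in scan_sequence(right, MODEL_2, params)]
        assert [(h.start, h.end) for h in combined] == expected

    @given(dna)
    def test_threshold_monotonicity(self, seq):
        base = {(h.start, h.end)
                for h in scan_sequence(seq, MODEL_2,
                                       ScanParams(4, 25.0))}
        for params in (ScanParams(6, 25.0), ScanParams(4, 60.0)):
            assert {(h.start, h.end)
                    for h in scan_sequence(seq, MODEL_2, params)} <= base

    def test_hits_sorted_and_disjoint(self, rng):
        seq = random_sequence(rng, 5000)
        hits = scan_sequence(seq, MODEL_2, ScanParams(4, 10.0))
        for a, b in zip(hits, hits[1:]):
            assert a.end <= b.start

    def test_determinism(self, rng):
        seq = random_sequence(rng, 2000)
        assert scan_sequence(seq, MODEL_2, DEFAULTS) == \
            scan_sequence(seq, MODEL_2, DEFAULTS)


class TestStreaming:
    """Chunked feeding must be equivalent to one-shot scanning."""

    @pytest.mark.parametrize("chunk", [1, 2, 3, 7, 64])
    def test_chunked_equals_whole(self, rng, chunk):
        seq = ("AA" + "GC" * 10 + random_sequence(rng, 500, "ACGTN")
               + "CA" * 30 + "TT")
        whole = scan_sequence(seq, MODEL_2, DEFAULTS)
        scanner = RunScanner("seq1", MODEL_2, DEFAULTS)
        for i in range(0, len(seq), chunk):
            scanner.feed(seq[i:i + chunk])
        assert scanner.finish() == whole

    def test_run_spanning_many_chunks(self):
        # GG and CC guard steps break on both sides of the repeat
        seq = "GG" + "GC" * 500 + "CC"
        scanner = RunScanner("s", MODEL_1, DEFAULTS)
        for i in range(0, len(seq), 16):
            scanner.feed(seq[i:i + 16])
        (h,) = scanner.finish()
        assert (h.start, h.end) == (2, 1002)
        assert h.score_percent == pytest.approx(100.0)
        assert h.sequence == "GC" * 500


class TestHitValidation:
    def test_inconsistent_hit_rejected(self):
        with pytest.raises(ValueError):
            ZfsHit("s", 0, 5, "GCGC", 1, 1, 1, 1)
        with pytest.raises(ValueError):
            ZfsHit("s", 5, 5, "", 1, 1, 1, 1)
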