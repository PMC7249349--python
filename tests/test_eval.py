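import math

import numpy as np
import pytest

from scsim import (CallRecord, FilterThresholds, apply_post_filters,
                   score_calls, titv_ratio)
from scsim.errors import RangeError


def _calls_with_tp(n_called, tp, truth):
    """Build a call set hitting exactly ``tp`` of the truth sites."""
    truth = sorted(truth)
    calls = [(pos, alt) for pos, alt in truth[:tp]]
    pos = max(p for p, _ in truth) + 1
    while len(calls) < n_called:
        calls.append((pos, "A"))
        pos += 1
    return calls


class TestScoreCalls:
    def test_monovar_like_benchmark_counts(self):
        """90 truth sites, 156 calls, 88 hits -> recall 97.77%, precision
        56.4%, F1 0.715."""
        truth = [(i * 10 + 1, "G") for i in range(90)]
        report = score_calls(_calls_with_tp(156, 88, truth), truth)
        assert report.recall * 100 == pytest.approx(97.77, abs=0.01)
        assert report.precision * 100 == pytest.approx(56.4, abs=0.05)
        assert report.f1 == pytest.approx(0.715, abs=0.001)

    def test_bcftools_like_benchmark_counts(self):
        truth = [(i * 10 + 1, "G") for i in range(90)]
        report = score_calls(_calls_with_tp(154, 88, truth), truth)
        assert report.precision * 100 == pytest.approx(57.1, abs=0.05)
        assert report.f1 == pytest.approx(0.721, abs=0.001)

    def test_perfect_caller(self):
        truth = [(5, "T"), (11, "C")]
        r = score_calls(truth, truth)
        assert r.recall == r.precision == r.f1 == 1.0

    def test_empty_call_set_warns_zero_precision(self, caplog):
        with caplog.at_level("WARNING"):
            r = score_calls([], [(1, "A")])
        assert r.precision == 0.0 and r.f1 == 0.0
        assert any("empty call set" in m.message for m in caplog.records)

    def test_alt_allele_must_match(self):
        r = score_calls([(10, "C")], [(10, "T")])
        assert r.tp == 0 and r.fp == 1 and r.fn == 1

    def test_off_by_one_heuristic_warns(self, caplog):
        with caplog.at_level("WARNING"):
            score_calls([(11, "A"), (21, "A")], [(10, "A"), (20, "A")])
        assert any("coordinate" in m.message for m in caplog.records)

    def test_brute_force_oracle(self, rng):
        """On small random sets, score_calls must equal naive pairwise
        matching."""
        for _ in range(50):
            truth = {(int(p), "ACGT"[int(b)]) for p, b in
                     zip(rng.integers(1, 30, 12), rng.integers(0, 4, 12))}
            calls = {(int(p), "ACGT"[int(b)]) for p, b in
                     zip(rng.integers(1, 30, 12), rng.integers(0, 4, 12))}
            tp = sum(1 for c in calls for t in truth if c == t)
            r = score_calls(calls, truth)
            assert r.tp == tp
            assert r.fp == len(calls) - tp and r.fn == len(truth) - tp
            assert r.tp + r.fn == r.n_truth and r.tp + r.fp == r.n_called
            # F1 consistency from stored precision/recall
            if r.precision + r.recall > 0:
                expect = 2 * r.precision * r.recall / (r.precision + r.recall)
                assert abs(r.f1 - expect) < 1e-9


GOOD = dict(mq=60.0, bq=35.0, alt_reads=6, alt_fwd=3, alt_rev=3)


class TestPostFilters:
    def test_mapping_quality_strictly_greater(self):
        calls = [CallRecord(1, "A", "G", **{**GOOD, "mq": 1.0}),
                 CallRecord(2, "A", "G", **{**GOOD, "mq": 1.01})]
        kept, _ = apply_post_filters(calls)
        assert [c.position for c in kept] == [2]

    def test_all_filters_pass(self):
        kept, n_skip = apply_post_filters([CallRecord(1, "A", "G", **GOOD)])
        assert len(kept) == 1 and n_skip == 0

    @pytest.mark.parametrize("field, value", [
        ("bq", 30.0), ("alt_reads", 5),
    ])
    def test_threshold_boundaries_removed(self, field, value):
        kept, _ = apply_post_filters([CallRecord(1, "A", "G",
                                                 **{**GOOD, field: value})])
        assert kept == []

    def test_one_sided_strand_bias_removed(self):
        c = CallRecord(1, "A", "G", mq=60, bq=35, alt_reads=10,
                       alt_fwd=10, alt_rev=0)
        kept, _ = apply_post_filters([c])
        assert kept == []

    def test_few_one_sided_reads_tolerated(self):
        # below the strand_min arming threshold the one-sided rule is off
        c = CallRecord(1, "A", "G", mq=60, bq=35, alt_reads=6,
                       alt_fwd=3, alt_rev=0)
        kept, _ = apply_post_filters([c])
        assert len(kept) == 1

    def test_fisher_mode_removes_extreme_imbalance(self):
        biased = CallRecord(1, "A", "G", mq=60, bq=35, alt_reads=30,
                            alt_fwd=30, alt_rev=0, ref_fwd=3, ref_rev=40)
        balanced = CallRecord(2, "A", "G", mq=60, bq=35, alt_reads=30,
                              alt_fwd=15, alt_rev=15, ref_fwd=20, ref_rev=20)
        kept, _ = apply_post_filters(
            [biased, balanced], FilterThresholds(strand_mode="fisher"))
        assert [c.position for c in kept] == [2]

    def test_missing_annotation_skips_filter_with_count(self):
        c = CallRecord(1, "A", "G", mq=None, bq=35, alt_reads=6,
                       alt_fwd=3, alt_rev=3)
        kept, n_skip = apply_post_filters([c])
        assert len(kept) == 1 and n_skip == 1

    def test_filtering_direction(self, rng):
        """Filters only remove calls: recall never rises, and precision
        rises whenever any false positive is removed."""
        truth = [(i, "G") for i in range(1, 40)]
        calls = []
        for i in range(1, 80):
            calls.append(CallRecord(
                i, "A", "G", mq=float(rng.integers(0, 60)),
                bq=float(rng.integers(20, 40)),
                alt_reads=int(rng.integers(0, 12)),
                alt_fwd=int(rng.integers(0, 6)), alt_rev=int(rng.integers(0, 6))))
        before = score_calls(calls, truth)
        kept, _ = apply_post_filters(calls)
        after = score_calls(kept, truth)
        assert after.recall <= before.recall
        assert after.precision >= before.precision or after.fp < before.fp


class TestTiTv:
    def test_small_example(self):
        assert titv_ratio([("A", "G"), ("C", "T"), ("A", "C")]) == 2.0

    def test_all_transitions_infinite(self):
        assert math.isinf(titv_ratio([("A", "G"), ("T", "C")]))

    def test_empty_undefined(self):
        with pytest.raises(RangeError):
            titv_ratio([])

    def test_default_matrix_band(self, assigned_sites):
        ratio = titv_ratio([(s.ref_base, s.alt_base) for s in assigned_sites])
        assert 0.8 < ratio < 2.4   # loose at n=60; the 3000-site band is elsewhere
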