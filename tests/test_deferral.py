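"""Deferral segmentation, confidence aggregation, selection and evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import seizedefer as sd
from seizedefer.deferral import DeferralSegment, score_segments
from seizedefer.detection import SeizureFlag
from seizedefer.labeling import SeizureEvent


def assert_exact_tiling(segments, duration):
    segs = sorted(segments, key=lambda s: s.start_s)
    assert segs[0].start_s == 0.0
    assert segs[-1].end_s == pytest.approx(duration)
    for a, b in zip(segs, segs[1:]):
        assert a.end_s == pytest.approx(b.start_s)


class TestBuildSegments:
    def test_flag_centred_in_300s_segment(self):
        flags = [SeizureFlag(600.0, 611.0)]
        segs = sd.build_deferral_segments(3600, flags)
        flag_segs = [s for s in segs if s.contains_flag]
        assert len(flag_segs) == 1
        assert flag_segs[0].start_s == pytest.approx(455.5)  # centre 605.5 +- 150
        assert flag_segs[0].end_s == pytest.approx(755.5)
        assert_exact_tiling(segs, 3600)

    def test_close_flag_segments_merged(self):
        # two flags 200 s apart -> their 5-min segments are < 5 min apart
        flags = [SeizureFlag.at(1000.0), SeizureFlag.at(1200.0)]
        segs = sd.build_deferral_segments(3600, flags)
        assert sum(s.contains_flag for s in segs) == 1
        assert_exact_tiling(segs, 3600)

    def test_no_flags_exact_tiles(self):
        segs = sd.build_deferral_segments(1500, [])
        assert len(segs) == 5
        assert all(s.length_s == 300.0 for s in segs)

    def test_boundary_flag_shifted_inward(self):
        segs = sd.build_deferral_segments(3600, [SeizureFlag.at(5.0)])
        fseg = next(s for s in segs if s.contains_flag)
        assert fseg.start_s == 0.0 and fseg.length_s == 300.0
        assert_exact_tiling(segs, 3600)

    def test_interior_segments_at_least_300s(self):
        flags = [SeizureFlag.at(700.0), SeizureFlag.at(2000.0)]
        segs = sd.build_deferral_segments(4000, flags)
        for s in sorted(segs, key=lambda x: x.start_s)[:-1]:
            if s.start_s > 0:
                assert s.length_s >= 300.0 - 1e-9
        assert_exact_tiling(segs, 4000)

    @given(
        st.integers(900, 7200),
        st.lists(st.integers(0, 7000), max_size=5),
    )
    def test_tiling_property(self, duration, starts):
        flags = [SeizureFlag.at(s) for s in sorted(starts) if s + 11 <= duration]
        segs = sd.build_deferral_segments(duration, flags)
        assert_exact_tiling(segs, duration)
        # every flag is covered by a flag segment
        for f in flags:
            assert any(
                s.contains_flag and s.start_s <= f.start_s and f.end_s <= s.end_s + 1e-9
                for s in segs
            )


class TestAggregateConfidence:
    def test_full_percentage_is_plain_mean(self):
        seg = DeferralSegment(0.0, 300.0)
        scores = np.arange(400.0)
        n = 299  # segments fully inside [0, 300]
        assert sd.aggregate_confidence(seg, scores, 100.0) == pytest.approx(
            scores[:n].mean()
        )

    def test_plow5_averages_15_lowest_of_299(self):
        seg = DeferralSegment(0.0, 300.0)
        rng = np.random.default_rng(0)
        scores = rng.random(400)
        k = math.ceil(0.05 * 299)  # = 15
        assert k == 15
        expected = np.sort(scores[:299])[:15].mean()
        assert sd.aggregate_confidence(seg, scores, 5.0) == pytest.approx(expected)

    def test_single_segment_ignores_plow(self):
        seg = DeferralSegment(100.0, 103.0)
        scores = np.zeros(200)
        scores[100] = 7.0
        scores[101] = 9.0
        # contained starts: 100, 101 -> k = max(1, ceil(0.01*2)) = 1
        assert sd.aggregate_confidence(seg, scores, 1.0) == 7.0

    def test_invalid_plow(self):
        seg = DeferralSegment(0.0, 300.0)
        for p in (0.0, 101.0):
            with pytest.raises(ValueError):
                sd.aggregate_confidence(seg, np.ones(400), p)


def _scored_segments(scores_by_segment):
    segs = []
    t = 0.0
    for sc in scores_by_segment:
        segs.append(DeferralSegment(t, t + 300.0, score=sc))
        t += 300.0
    return segs


class TestSelectDeferrals:
    def test_fraction_one_defers_everything(self):
        segs = _scored_segments(range(10))
        assert len(sd.select_deferrals(segs, 1.0)) == 10

    def test_fraction_zero_flags_first_defers_exactly_flag_segments(self):
        segs = _scored_segments(range(10))
        segs[3].contains_flag = True
        segs[3].score = None
        deferred = sd.select_deferrals(segs, 0.0)
        assert [s.start_s for s in deferred] == [segs[3].start_s]

    def test_lowest_scored_deferred_first(self):
        scores = [5, 2, 9, 1, 7, 3, 8, 0, 6, 4]
        segs = _scored_segments(scores)
        deferred = sd.select_deferrals(segs, 0.3)
        got = sorted(s.score for s in deferred)
        assert got == [0, 1, 2]

    def test_random_mode_needs_rng(self):
        with pytest.raises(ValueError):
            sd.select_deferrals(_scored_segments(range(4)), 0.5, mode="random")


class TestEvaluateWithDeferral:
    def test_everything_deferred_is_perfect(self):
        events = [SeizureEvent(100, 140, None)]
        flags = [SeizureFlag.at(500.0)]  # a false positive
        m = sd.evaluate_with_deferral(events, flags, [(0.0, 3600.0)], 3600)
        assert (m.ds, m.fdr_per_24h, m.ppv, m.f1) == (100.0, 0.0, 100.0, 100.0)

    def test_flags_first_zero_fraction_zeroes_fdr(self):
        """Deferring exactly the flag-containing segments removes every FP."""
        events = [SeizureEvent(1000, 1040, None)]
        flags = [SeizureFlag.at(1005.0), SeizureFlag.at(2000.0)]
        segs = sd.build_deferral_segments(3600, flags)
        deferred = sd.select_deferrals(
            score_segments(segs, np.ones(3599), 5.0), 0.0
        )
        m = sd.evaluate_with_deferral(events, flags, deferred, 3600)
        assert m.fp == 0 and m.fdr_per_24h == 0.0
        assert m.tp == 1  # the genuine event lies inside a deferred flag segment

    def test_split_seizure_under_10s_each_side_is_undetected(self):
        # 18-s seizure: 9 s deferred, 9 s not, no surviving flag on it
        events = [SeizureEvent(100, 118, None)]
        m = sd.evaluate_with_deferral(events, [], [(0.0, 109.0)], 3600)
        assert m.tp == 0 and m.fn == 1

    def test_ten_deferred_seconds_count_as_detected(self):
        events = [SeizureEvent(100, 118, None)]
        m = sd.evaluate_with_deferral(events, [], [(0.0, 110.0)], 3600)
        assert m.tp == 1

    def test_any_overlap_mode_one_second_overlap_checks_flag(self):
        # FP flag overlapping a deferred region by 1 s disappears in any-overlap mode
        flags = [SeizureFlag.at(299.0)]  # interval [299, 310], overlap [299,300]
        m10 = sd.evaluate_with_deferral([], flags, [(0.0, 300.0)], 3600, mode="any_overlap")
        assert m10.fp == 0
        m = sd.evaluate_with_deferral([], flags, [(0.0, 300.0)], 3600)
        assert m.fp == 1  # standard mode requires full containment

    def test_any_overlap_checked_flag_on_genuine_seizure_is_tp(self):
        events = [SeizureEvent(295, 320, None)]  # only 5 s deferred
        flags = [SeizureFlag.at(299.0)]
        m = sd.evaluate_with_deferral(events, flags, [(0.0, 300.0)], 3600, mode="any_overlap")
        assert m.tp == 1 and m.fp == 0


class TestDeferralCurve:
    def _patients(self, seed=0, n=4):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            duration = 3600
            n_seg = duration - 1
            events = [SeizureEvent(500 + 700 * i % 1800, 540 + 700 * i % 1800, None)]
            preds = np.zeros(n_seg, dtype=int)
            on = int(events[0].onset_s)
            preds[on : on + 30] = 1  # detected seizure
            fp_at = 2800
            preds[fp_at : fp_at + 12] = 1  # a false run
            scores = rng.random(n_seg) + 1.0
            scores[fp_at : fp_at + 12] = 0.1  # low confidence at the FP
            out.append(
                {
                    "duration_s": duration,
                    "events": events,
                    "flags": sd.seizure_flags(preds),
                    "scores": scores,
                }
            )
        return out

    def test_flags_first_fdr_identically_zero_along_sweep(self):
        curves = sd.deferral_curve(self._patients(), [0.0, 0.2, 0.5, 1.0])
        for c in curves:
            assert c["metrics"]["fdr_per_24h"]["mean"] == 0.0

    def test_ds_monotone_and_perfect_at_one(self):
        curves = sd.deferral_curve(self._patients(), [0.0, 0.3, 0.6, 1.0])
        ds = [c["metrics"]["ds"]["mean"] for c in curves]
        assert all(b >= a - 1e-9 for a, b in zip(ds, ds[1:]))
        last = curves[-1]["metrics"]
        assert last["ds"]["mean"] == 100.0
        assert last["fdr_per_24h"]["mean"] == 0.0
        assert last["ppv"]["mean"] == 100.0

    def test_segment_statistics_reported(self):
        curves = sd.deferral_curve(self._patients(), [0.5])
        c = curves[0]
        assert c["deferred_segments_per_24h"] > 0
        assert c["mean_deferred_length_min"] >= 5.0 - 1e-9
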