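import numpy as np
import pandas as pd
import pytest

from nirsbreath import (ConditionSegment, PeakSet, compute_breath_features,
                        compute_o2hb_amplitude, detect_breaths,
                        filter_outliers_ci, window_aggregate)
from tests.conftest import sinusoid


def make_breath_table(intervals, depths=None, fs=10.0):
    intervals = np.asarray(intervals, float)
    depths = np.ones_like(intervals) if depths is None else np.asarray(depths)
    starts = np.concatenate([[0], np.cumsum(intervals[:-1])]) * fs
    return pd.DataFrame({
        "min_index_start": starts.astype(int),
        "max_index": (starts + intervals * fs / 3).astype(int),
        "min_index_end": (starts + intervals * fs).astype(int),
        "interval_s": intervals,
        "depth": depths,
        "excluded": False,
    })


def make_segment(raw, name="baseline", fs=10.0):
    return ConditionSegment(condition_name=name, start_index=0,
                            end_index=len(raw), channels={"O2Hb": raw}, fs=fs)


class TestBreathFeatures:
    def test_arithmetic_from_definitions(self):
        # minima at samples 0 and 40 (values -1), maximum at 20 (value +1)
        sig = np.zeros(41)
        sig[0] = sig[40] = -1.0
        sig[20] = 1.0
        pk = PeakSet(maxima=[20], minima=[0, 40], min_separation_s=2.0,
                     alternating=True)
        bt = compute_breath_features(pk, sig, fs=10.0)
        assert len(bt) == 1
        assert bt.loc[0, "interval_s"] == pytest.approx(4.0)
        assert bt.loc[0, "depth"] == pytest.approx(2.0)

    def test_rapid_sinusoid_interval_and_depth(self):
        # 25 breaths/min sinusoid of amplitude A: intervals 2.4 s, depths 2A
        A = 0.7
        sig = sinusoid(2.4, 120.0, amplitude=A)
        bt = compute_breath_features(detect_breaths(sig, 10.0), sig, 10.0)
        assert bt["interval_s"].mean() == pytest.approx(2.4, rel=0.02)
        assert bt["depth"].mean() == pytest.approx(2 * A, rel=0.05)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(5)
        sig = np.convolve(rng.normal(size=1200), np.ones(15) / 15, "same")
        pk = detect_breaths(sig, 10.0)
        bt = compute_breath_features(pk, sig, 10.0)
        # independent oracle: walk the merged extremum sequence directly
        idx, kind = pk.merged()
        expected = []
        mins = idx[kind < 0]
        for lo, hi in zip(mins[:-1], mins[1:]):
            mids = idx[(idx > lo) & (idx < hi) & (kind == 1)]
            expected.append(((hi - lo) / 10.0, sig[mids[0]] - sig[lo]))
        assert len(bt) == len(expected)
        np.testing.assert_allclose(bt["interval_s"], [e[0] for e in expected])
        np.testing.assert_allclose(bt["depth"], [e[1] for e in expected])

    def test_fewer_than_two_minima_gives_empty_table(self, caplog):
        pk = PeakSet(maxima=[10], minima=[5], min_separation_s=1.0,
                     alternating=True)
        with caplog.at_level("WARNING", logger="nirsbreath"):
            bt = compute_breath_features(pk, np.zeros(20), 10.0)
        assert len(bt) == 0

    def test_requires_alternating_peakset(self):
        pk = PeakSet(maxima=[10, 20], minima=[30], min_separation_s=1.0)
        with pytest.raises(ValueError, match="alternating"):
            compute_breath_features(pk, np.zeros(40), 10.0)


class TestCIFilter:
    def test_single_long_breath_excluded(self):
        bt = make_breath_table([2.4] * 19 + [10.0])
        iv = bt["interval_s"].to_numpy()
        z = (10.0 - iv.mean()) / iv.std(ddof=1)
        assert z > 1.96  # numeric oracle: the outlier is beyond the band
        out = filter_outliers_ci(bt)
        assert out["excluded"].sum() == 1
        assert bool(out.loc[19, "excluded"])

    def test_zero_sd_excludes_nothing(self):
        out = filter_outliers_ci(make_breath_table([2.4] * 20))
        assert out["excluded"].sum() == 0

    def test_short_table_unchanged_with_warning(self, caplog):
        bt = make_breath_table([2.4, 9.0])
        with caplog.at_level("WARNING", logger="nirsbreath"):
            out = filter_outliers_ci(bt)
        assert out["excluded"].sum() == 0
        assert any("skipped" in m for m in caplog.messages)

    def test_raising_level_never_excludes_more(self):
        rng = np.random.default_rng(11)
        bt = make_breath_table(rng.lognormal(1.2, 0.4, size=60))
        counts = [filter_outliers_ci(bt, level=lv)["excluded"].sum()
                  for lv in (0.80, 0.90, 0.95, 0.99)]
        assert counts == sorted(counts, reverse=True)


class TestAmplitude:
    def test_constant_signal(self):
        assert compute_o2hb_amplitude(np.full(600, 3.2), 10.0, (0, 600)) \
            == pytest.approx(3.2)

    def test_linear_ramp_mean(self):
        # 0.01·t μM over a 60-s window starting at t=0 averages 0.3 μM
        t = np.arange(600) / 10.0
        assert compute_o2hb_amplitude(0.01 * t, 10.0, (0, 600)) \
            == pytest.approx(0.3, abs=0.001)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty window"):
            compute_o2hb_amplitude(np.ones(100), 10.0, (50, 50))


class TestWindowAggregate:
    @pytest.mark.parametrize("minutes,expected", [(3, 3), (5, 5), (1.5, 1)])
    def test_window_count_is_floor_of_duration(self, minutes, expected):
        fs, dur = 10.0, minutes * 60.0
        sig = sinusoid(4.0, dur)
        bt = compute_breath_features(detect_breaths(sig, fs), sig, fs)
        rows = window_aggregate(filter_outliers_ci(bt), make_segment(sig),
                                sig, fs, participant_id="P00")
        assert len(rows) == expected
        assert list(rows["window_index"]) == list(range(expected))

    def test_window_mean_bounded_by_member_intervals(self):
        fs = 10.0
        sig = sinusoid(3.0, 300.0) + 0.1 * sinusoid(50.0, 300.0)
        bt = filter_outliers_ci(
            compute_breath_features(detect_breaths(sig, fs), sig, fs))
        rows = window_aggregate(bt, make_segment(sig), sig, fs)
        kept = bt.loc[~bt["excluded"]]
        for _, r in rows.iterrows():
            lo, hi = r["window_index"] * 600, (r["window_index"] + 1) * 600
            member = kept.loc[(kept["min_index_start"] >= lo)
                              & (kept["min_index_start"] < hi), "interval_s"]
            assert member.min() <= r["interval_mean_s"] <= member.max()

    def test_segment_shorter_than_window_rejected(self):
        sig = sinusoid(4.0, 30.0)
        bt = make_breath_table([4.0] * 5)
        with pytest.raises(ValueError, match="shorter"):
            window_aggregate(bt, make_segment(sig), sig, 10.0)

    def test_excluded_breaths_dropped_from_window_means(self):
        bt = make_breath_table([2.4] * 19 + [10.0])
        bt = filter_outliers_ci(bt)
        raw = np.zeros(int(bt["min_index_end"].max()) + 600)
        rows = window_aggregate(bt, make_segment(raw), raw, 10.0)
        assert rows["interval_mean_s"].max() == pytest.approx(2.4)
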