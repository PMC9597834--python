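"""AV schedule, call bookkeeping, detection-range model, visual-acoustic join."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from gwforage.acoustics import (
    CallRecord,
    DetectionModel,
    av_schedule,
    call_rate,
    class_distribution,
    compare_years,
    detection_probability,
    detection_radius,
    detection_radius_series,
    join_visual_acoustic,
)
from gwforage.spatial import social_context
from gwforage.transects import WhaleObservation


def _call(hour_offset, cls, base=dt.datetime(2015, 7, 1, 0)):
    return CallRecord(timestamp=base + dt.timedelta(hours=hour_offset), call_class=cls)


class TestAVSchedule:
    def test_every_fifth_full_day(self):
        sched = av_schedule(
            dt.datetime(2015, 5, 6, 14), dt.datetime(2015, 5, 21, 9)
        )
        assert sched.full_days == [dt.date(2015, 5, 7), dt.date(2015, 5, 12),
                                   dt.date(2015, 5, 17)]

    def test_short_deployment_empty(self):
        sched = av_schedule(dt.datetime(2015, 5, 6, 14), dt.datetime(2015, 5, 7, 2))
        assert sched.full_days == []
        assert sched.day_coverage_fraction == 0.0

    def test_long_deployment_one_fifth_coverage(self):
        sched = av_schedule(dt.datetime(2015, 5, 6), dt.datetime(2015, 9, 14))
        assert sched.day_coverage_fraction == pytest.approx(0.2, abs=0.01)

    def test_transect_windows_added(self):
        t = dt.datetime(2015, 6, 10, 11)
        sched = av_schedule(
            dt.datetime(2015, 5, 6), dt.datetime(2015, 9, 14), transect_times=[t]
        )
        assert sched.transect_windows == [(t, t + dt.timedelta(hours=1))]
        assert sched.contains(t + dt.timedelta(minutes=30))

    def test_empty_deployment_errors(self):
        with pytest.raises(ValueError):
            av_schedule(dt.datetime(2015, 5, 6), dt.datetime(2015, 5, 6))


class TestClassDistribution:
    def test_both_denominators(self):
        calls = (
            [_call(0, "class2_sweep")] * 1130
            + [_call(0, "class3_moan")] * 1622
            + [_call(0, "class1_knock")] * 1809
            + [_call(0, "class4_rumble")] * 13
            + [_call(0, "motherese")] * 1177
        )
        dist = class_distribution(calls).set_index("call_class")
        assert dist.loc["class2_sweep", "pct_core"] == pytest.approx(
            100 * 1130 / 4574, abs=0.05
        )
        assert dist.loc["class3_moan", "pct_all"] == pytest.approx(
            100 * 1622 / 5751, abs=0.05
        )
        assert math.isnan(dist.loc["motherese", "pct_core"])
        assert dist["count"].sum() == 5751

    def test_single_call(self):
        dist = class_distribution([_call(0, "class1_knock")]).set_index("call_class")
        assert dist.loc["class1_knock", "pct_all"] == 100.0
        assert dist.loc["class3_moan", "pct_all"] == 0.0

    def test_unknown_class_rejected_at_construction(self):
        with pytest.raises(ValueError):
            CallRecord(timestamp=dt.datetime(2015, 7, 1), call_class="class5_click")


class TestCallRate:
    def test_direct_arithmetic(self):
        calls = [_call(0.1 * i, "class1_knock") for i in range(6)]
        rates = call_rate(calls, whales_present=3, window_hours=2.0).set_index("call_class")
        assert rates.loc["class1_knock", "rate"] == pytest.approx(1.0)

    def test_zero_calls(self):
        rates = call_rate([], whales_present=2, window_hours=1.0).set_index("call_class")
        assert rates.loc["class1_knock", "rate"] == 0.0

    def test_zero_whales_keeps_counts_drops_rates(self):
        calls = [_call(0, "class3_moan")]
        rates = call_rate(calls, whales_present=0, window_hours=1.0).set_index("call_class")
        assert rates.loc["class3_moan", "count"] == 1
        assert math.isnan(rates.loc["class3_moan", "rate"])

    def test_motherese_rate_never_reported(self):
        calls = [_call(0, "motherese")] * 4
        rates = call_rate(calls, whales_present=2, window_hours=1.0).set_index("call_class")
        assert rates.loc["motherese", "count"] == 4
        assert math.isnan(rates.loc["motherese", "rate"])

    def test_negative_window_errors(self):
        with pytest.raises(ValueError):
            call_rate([], whales_present=1, window_hours=-1.0)


class TestDetectionModel:
    def test_extreme_noise_probability_zero(self):
        m = DetectionModel(n_draws=20_000, seed=1)
        p = detection_probability(10.0, m.sl_mean + 50.0, m)
        assert p == pytest.approx(0.0, abs=1e-3)

    def test_median_case_half(self):
        m = DetectionModel(n_draws=200_000, seed=2)
        r = 500.0
        nl = m.sl_mean - 20 * math.log10(r)
        assert detection_probability(r, nl, m) == pytest.approx(0.5, abs=0.01)

    def test_monte_carlo_matches_closed_form(self):
        m = DetectionModel(n_draws=100_000, seed=3)
        r, nl = 500.0, 100.0
        p_mc = detection_probability(r, nl, m)
        p_cf = norm.cdf((m.sl_mean - 20 * math.log10(r) - nl) / m.sl_sd)
        se = math.sqrt(p_cf * (1 - p_cf) / m.n_draws)
        assert abs(p_mc - p_cf) <= 3 * se

    def test_monotone_in_range_and_noise(self):
        m = DetectionModel(n_draws=50_000, seed=4)
        probs_r = [detection_probability(r, 100.0, m) for r in (10, 100, 1000, 5000)]
        assert all(a >= b for a, b in zip(probs_r, probs_r[1:]))
        probs_nl = [detection_probability(500.0, nl, m) for nl in (80, 100, 120)]
        assert all(a >= b for a, b in zip(probs_nl, probs_nl[1:]))

    def test_below_reference_distance_errors(self):
        m = DetectionModel()
        with pytest.raises(ValueError):
            detection_probability(0.5, 100.0, m)


class TestDetectionRadius:
    def test_closed_form_at_half(self):
        m = DetectionModel()
        r = detection_radius(np.array([96.9]), m, p_threshold=0.5)
        assert r[0] == pytest.approx(1000.0, rel=1e-9)

    def test_constant_noise_equal_quantiles(self):
        m = DetectionModel()
        noise = pd.Series(np.full(120, 100.0))
        _, summary = detection_radius_series(noise, m)
        assert summary["exceeded_10pct_m"] == pytest.approx(summary["exceeded_90pct_m"])

    def test_quantile_transform_of_normal_noise(self):
        m = DetectionModel()
        rng = np.random.default_rng(5)
        mu, sd = 100.0, 8.0
        noise = pd.Series(rng.normal(mu, sd, size=50_000))
        _, summary = detection_radius_series(noise, m)
        # radius is monotone decreasing in NL, so the 90th radius quantile
        # maps to the 10th noise quantile
        nl_q10 = mu + sd * norm.ppf(0.10)
        want = 10 ** ((m.sl_mean - nl_q10) / 20)
        assert summary["exceeded_10pct_m"] == pytest.approx(want, rel=0.02)

    def test_extreme_noise_floored_and_flagged(self):
        m = DetectionModel()
        noise = pd.Series([m.sl_mean + 5 * m.sl_sd] * 10)
        series, summary = detection_radius_series(noise, m)
        assert (series == 1.0).all()
        assert summary["n_floored"] == 10

    def test_empty_noise_errors(self):
        with pytest.raises(ValueError):
            detection_radius_series(pd.Series(dtype=float), DetectionModel())


class TestVisualAcousticJoin:
    @staticmethod
    def _snapshot(tid, ts, n_whales):
        m = 1.0 / 111_320.0
        units = [
            WhaleObservation(timestamp=ts, lat=49.25 + i * 200 * m, lon=-126.15)
            for i in range(n_whales)
        ]
        return social_context(units, transect_id=tid, timestamp=ts)

    def test_calls_outside_windows_empty_join(self):
        ts = dt.datetime(2015, 7, 1, 10)
        snap = self._snapshot("t1", ts, 2)
        calls = [_call(0, "class1_knock", base=dt.datetime(2015, 8, 1))]
        joined = join_visual_acoustic([snap], calls)
        assert joined["count_class1_knock"].sum() == 0

    def test_three_snapshot_hand_enumeration(self):
        base = dt.datetime(2015, 7, 1, 10)
        snaps = [
            self._snapshot("t1", base, 2),
            self._snapshot("t2", base + dt.timedelta(hours=2), 3),
            self._snapshot("t3", base + dt.timedelta(hours=4), 1),
        ]
        calls = (
            [_call(0.2, "class1_knock", base), _call(0.5, "class3_moan", base)]
            + [_call(2.1, "class1_knock", base)] * 3
            + [_call(4.9, "class2_sweep", base)]
            + [_call(6.0, "class1_knock", base)]  # outside every window
        )
        joined = join_visual_acoustic(snaps, calls).set_index("transect_id")
        assert joined.loc["t1", "count_class1_knock"] == 1
        assert joined.loc["t1", "count_class3_moan"] == 1
        assert joined.loc["t2", "count_class1_knock"] == 3
        assert joined.loc["t3", "count_class2_sweep"] == 1
        # conservation through the join: all in-window calls attributed once
        count_cols = [c for c in joined.columns if c.startswith("count_")]
        assert joined[count_cols].to_numpy().sum() == 6

    def test_rates_follow_whale_number(self):
        base = dt.datetime(2015, 7, 1, 10)
        snap = self._snapshot("t1", base, 4)
        calls = [_call(0.1 * i, "class1_knock", base) for i in range(8)]
        joined = join_visual_acoustic([snap], calls)
        assert joined.loc[0, "rate_class1_knock"] == pytest.approx(8 / 4)

    def test_snapshot_without_timestamp_errors(self):
        snap = self._snapshot("t1", dt.datetime(2015, 7, 1, 10), 2)
        snap.timestamp = None
        with pytest.raises(ValueError):
            join_visual_acoustic([snap], [])


class TestYearComparison:
    def test_identical_samples_not_significant(self):
        rng = np.random.default_rng(6)
        a = rng.poisson(3, size=40)
        _, p = compare_years(a, a)
        assert p > 0.9
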