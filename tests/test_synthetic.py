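"""Generator contracts: determinism, conservation, limits, structural recovery."""

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest

import gwforage as g
from gwforage.synthetic import (
    SimulationConfig,
    generate_dataset,
    simulate_call_log,
    simulate_prey_whale_dynamics,
    simulate_sighting_histories,
)
from gwforage.spatial import social_context
from gwforage.transects import WhaleObservation, transects_to_frame


def brute_lag1_acf(values):
    x = np.asarray(values, dtype=float)
    d = x - x.mean()
    return float(np.sum(d[1:] * d[:-1]) / np.sum(d * d))


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(loyal_return_prob=1.5)

    def test_nonnegative_rates(self):
        with pytest.raises(ValueError):
            SimulationConfig(removal_per_whale_day=-0.1)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(prey_capacity=float("nan"))

    def test_season_ordering(self):
        with pytest.raises(ValueError):
            SimulationConfig(season_start=(9, 6), season_end=(5, 24))


class TestDeterminism:
    def test_identical_seed_identical_dataset(self):
        a = generate_dataset(SimulationConfig(seed=9))
        b = generate_dataset(SimulationConfig(seed=9))
        pd.testing.assert_frame_equal(
            transects_to_frame(a.transects), transects_to_frame(b.transects)
        )
        assert [h.whale_id for h in a.catalogue] == [h.whale_id for h in b.catalogue]
        assert [
            (c.timestamp, c.call_class) for c in a.calls
        ] == [(c.timestamp, c.call_class) for c in b.calls]
        pd.testing.assert_series_equal(a.noise, b.noise)

    def test_different_seed_differs(self):
        a = generate_dataset(SimulationConfig(seed=1))
        b = generate_dataset(SimulationConfig(seed=2))
        assert transects_to_frame(a.transects).to_csv() != transects_to_frame(
            b.transects
        ).to_csv()


class TestPreyWhaleDynamics:
    def test_zero_intensity_all_counts_zero(self):
        cfg = SimulationConfig(seed=3, attraction_intensity=0.0)
        _, transects = simulate_prey_whale_dynamics(cfg)
        assert all(t.whale_count == 0 for t in transects)

    def test_prey_nonnegative_and_capacity_fixed_point(self):
        truth, _ = simulate_prey_whale_dynamics(SimulationConfig(seed=4))
        assert all(p >= 0 for p in truth["prey_start_of_year"])
        cfg = SimulationConfig(seed=4, removal_per_whale_day=0.0)
        truth0, _ = simulate_prey_whale_dynamics(cfg)
        assert all(
            p == pytest.approx(cfg.prey_capacity)
            for p in truth0["prey_start_of_year"]
        )

    def test_dates_inside_season_window(self):
        cfg = SimulationConfig(seed=5)
        _, transects = simulate_prey_whale_dynamics(cfg)
        for t in transects:
            assert dt.date(t.year, *cfg.season_start) <= t.date
            assert t.date <= dt.date(t.year, *cfg.season_end)

    def test_high_removal_gives_negative_lag1_autocorrelation(self):
        """Strong annual prey removal alternates high and low whale years."""
        negatives = 0
        n_rep = 200
        for seed in range(n_rep):
            cfg = SimulationConfig(seed=seed, n_years=20)
            _, transects = simulate_prey_whale_dynamics(cfg)
            means = (
                pd.Series({t.transect_id: t.whale_count for t in transects})
                .groupby(lambda tid: tid.split("-")[0])
                .mean()
            )
            if means.std() > 0:
                negatives += brute_lag1_acf(means.to_numpy()) < 0
        assert negatives > n_rep / 2


class TestSightingHistories:
    def test_deterministic_pool_all_return(self):
        cfg = SimulationConfig(
            seed=6, loyal_return_prob=1.0, single_visit_rate=0.0, calf_fraction=0.0
        )
        ds = generate_dataset(cfg)
        returners = [h for h in ds.catalogue if h.category == "return"]
        assert len(returners) == len(ds.catalogue)

    def test_no_loyal_pool_all_single_visit(self):
        cfg = SimulationConfig(seed=7, loyal_pool_size=0, calf_fraction=0.0)
        ds = generate_dataset(cfg)
        assert all(h.category == "single_visit" for h in ds.catalogue)

    def test_every_whale_has_a_sighting(self):
        ds = generate_dataset(SimulationConfig(seed=8))
        assert all(len(h.sightings) >= 1 for h in ds.catalogue)

    def test_conservation_of_individuals(self):
        ds = generate_dataset(SimulationConfig(seed=9))
        t = ds.truth
        assert (
            t["n_loyal_catalogued"] + t["n_single_catalogued"] + t["n_calves_catalogued"]
            == len(ds.catalogue)
        )

    def test_sightings_inside_season_windows(self):
        cfg = SimulationConfig(seed=10)
        ds = generate_dataset(cfg)
        for h in ds.catalogue:
            for d in h.sightings:
                assert dt.date(d.year, *cfg.season_start) <= d <= dt.date(
                    d.year, *cfg.season_end
                )

    def test_empty_transects_error(self):
        cfg = SimulationConfig(seed=11)
        with pytest.raises(ValueError):
            simulate_sighting_histories(cfg, [], {})

    def test_residency_gap_recovery(self):
        """A 10-day injected loyal-vs-single residency gap is recovered."""
        gaps = []
        for seed in range(30):
            ds = generate_dataset(SimulationConfig(seed=seed))
            fid = g.classify_catalogue(ds.catalogue)
            pools = ds.truth["pools"]
            pw = fid.per_whale
            loyal = pw[pw["whale_id"].map(pools) == "loyal"]["residency_days"]
            single = pw[pw["whale_id"].map(pools) == "single"]["residency_days"]
            gaps.append(loyal.mean() - single.mean())
        assert np.mean(gaps) == pytest.approx(10.0, abs=2.0)


class TestLocations:
    def test_zero_drift_centers_on_base(self):
        cfg = SimulationConfig(seed=12, lat_drift_per_month=0.0)
        ds = generate_dataset(cfg)
        from gwforage.spatial import monthly_weighted_means

        means = monthly_weighted_means(ds.transects)
        # every monthly mean near the base center (scatter ~700 m ~ 0.006 deg)
        assert np.allclose(means["lat"], cfg.base_lat, atol=0.02)

    def test_positive_drift_slope_recovered(self):
        slopes = []
        for seed in range(60):
            cfg = SimulationConfig(seed=seed, n_years=4)
            ds = generate_dataset(cfg)
            from gwforage.spatial import monthly_weighted_means

            means = monthly_weighted_means(ds.transects)
            pooled = means.groupby("month").apply(
                lambda grp: np.average(grp["lat"], weights=grp["n_whales"]),
                include_groups=False,
            )
            if len(pooled) >= 3:
                slopes.append(np.polyfit(pooled.index, pooled.to_numpy(), 1)[0])
        assert np.mean(np.array(slopes) > 0) >= 0.95

    def test_counts_preserved_by_location_stage(self):
        ds = generate_dataset(SimulationConfig(seed=13))
        # partitioning into individuals/groups/pairs conserves whale counts
        for t in ds.transects:
            assert t.whale_count == sum(u.count_contribution for u in t.units)


class TestCallLog:
    @staticmethod
    def _snapshot(ts, spacing_m, n=4):
        m = 1.0 / 111_320.0
        units = [
            WhaleObservation(timestamp=ts, lat=49.25 + i * spacing_m * m, lon=-126.15)
            for i in range(n)
        ]
        return social_context(units, transect_id="t", timestamp=ts)

    def test_zero_whales_empty_log(self):
        cfg = SimulationConfig(seed=14)
        snap = social_context([], transect_id="t", timestamp=dt.datetime(2016, 7, 1, 10))
        calls, _ = simulate_call_log(cfg, [snap])
        assert calls == []

    def test_every_call_within_snapshot_window(self):
        ds = generate_dataset(SimulationConfig(seed=15))
        windows = [
            (s.timestamp, s.timestamp + dt.timedelta(hours=1)) for s in ds.snapshots
        ]
        for c in ds.calls:
            assert any(a <= c.timestamp < b for a, b in windows)

    def test_motherese_only_with_pairs(self):
        ds = generate_dataset(SimulationConfig(seed=16))
        pair_windows = [
            (s.timestamp, s.timestamp + dt.timedelta(hours=1))
            for s in ds.snapshots
            if s.n_pairs > 0
        ]
        for c in ds.calls:
            if c.call_class == "motherese":
                assert any(a <= c.timestamp < b for a, b in pair_windows)

    def test_distance_sweep_knock_down_moan_up(self):
        cfg = SimulationConfig(seed=17, call_rate_base=5.0)
        ts = dt.datetime(2016, 7, 1, 10)
        distances = np.linspace(50, 1500, 12)
        knock_frac, moan_frac = [], []
        rng = np.random.default_rng(99)
        for d in distances:
            snaps = [
                self._snapshot(ts + dt.timedelta(days=i), d) for i in range(10)
            ]
            calls, _ = simulate_call_log(cfg, snaps, rng=rng)
            dist = g.class_distribution(calls).set_index("call_class")
            core = dist.loc[list(g.acoustics.CORE_CLASSES), "count"].sum()
            knock_frac.append(dist.loc["class1_knock", "count"] / core)
            moan_frac.append(dist.loc["class3_moan", "count"] / core)
        # monotone trend on binned output: rank correlation with distance
        from scipy.stats import spearmanr

        assert spearmanr(distances, knock_frac)[0] < -0.8
        assert spearmanr(distances, moan_frac)[0] > 0.8
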