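import dataclasses
from datetime import date

import numpy as np
import pandas as pd
import pytest

from aodpm25.grid import GridSpec, season_of
from aodpm25.synthetic import (MetConfig, MetVarConfig, TruthConfig, default_dates,
                               read_fixture, sample_monitors, simulate_aod_pair,
                               simulate_fixture, simulate_meteorology,
                               simulate_static_layers, simulate_truth_pm25,
                               write_fixture)
from conftest import noiseless_truth


class TestMeteorology:
    def test_seeded_reproducibility(self, small_grid):
        dates = default_dates(2018, 30)
        a = simulate_meteorology(small_grid, dates, seed=5)
        b = simulate_meteorology(small_grid, dates, seed=5)
        for name in a:
            np.testing.assert_array_equal(a[name].values, b[name].values)

    def test_rh_is_a_fraction(self, small_grid):
        met = simulate_meteorology(small_grid, default_dates(2018, 365), seed=1)
        rh = met["rh"].values
        assert rh.min() >= 0.0 and rh.max() <= 1.0

    def test_zero_amplitude_gives_constant_mean(self, small_grid):
        cfg = MetConfig(temp=MetVarConfig(mean=21.5, seasonal_amplitude=0.0, spatial_amplitude=0.0))
        met = simulate_meteorology(small_grid, default_dates(2018, 10), seed=2, config=cfg)
        np.testing.assert_allclose(met["temp"].values, 21.5)

    def test_empty_dates_rejected(self, small_grid):
        with pytest.raises(ValueError):
            simulate_meteorology(small_grid, [], seed=0)

    def test_fields_complete_and_seasonal(self, small_grid):
        met = simulate_meteorology(small_grid, default_dates(2018, 365), seed=3)
        for name, st in met.items():
            assert not st.mask.any(), name
        temp = met["temp"].values.mean(axis=(1, 2))
        assert temp.max() - temp.min() > 5.0  # seasonal cycle present


class TestAODPair:
    def test_noiseless_identity(self, small_grid):
        truth = noiseless_truth(gap_fraction={s: 0.0 for s in ("winter", "pre-monsoon", "monsoon", "post-monsoon")},
                                water_fraction=0.0)
        pair = simulate_aod_pair(small_grid, default_dates(2018, 20), truth)
        sat, rean = pair
        assert not sat.mask.any()
        expected = pair.alpha[None] + pair.beta[None] * rean.values
        np.testing.assert_allclose(sat.values, expected, rtol=0, atol=1e-12)

    def test_full_masking(self, small_grid):
        truth = noiseless_truth(gap_fraction={s: 1.0 for s in ("winter", "pre-monsoon", "monsoon", "post-monsoon")})
        pair = simulate_aod_pair(small_grid, default_dates(2018, 10), truth)
        assert pair.satellite.mask.all()
        assert not pair.reanalysis.mask.any()

    def test_bad_gap_fraction_rejected(self):
        with pytest.raises(ValueError):
            TruthConfig(gap_fraction={"winter": 1.2, "pre-monsoon": 0.3,
                                      "monsoon": 0.3, "post-monsoon": 0.3})

    def test_seasonal_gap_fractions_realized(self):
        # >= 1e4 cell-days per season: 40x50 cells x 365 days
        grid = GridSpec(21.3, 74.4, 40, 50, 0.03)
        gaps = {"winter": 0.3, "pre-monsoon": 0.3, "monsoon": 0.8, "post-monsoon": 0.3}
        truth = TruthConfig(seed=11, gap_fraction=gaps, water_fraction=0.0)
        pair = simulate_aod_pair(grid, default_dates(2018, 365), truth)
        labels = np.array([season_of(d) for d in pair.satellite.dates])
        for season, frac in gaps.items():
            realized = pair.satellite.mask[labels == season].mean()
            assert abs(realized - frac) < 0.02, season

    def test_water_cells_always_missing(self, small_grid):
        truth = TruthConfig(seed=4, water_fraction=0.05)
        pair = simulate_aod_pair(small_grid, default_dates(2018, 30), truth)
        assert pair.water_mask.sum() == round(0.05 * small_grid.n_lat * small_grid.n_lon)
        assert pair.satellite.mask[:, pair.water_mask].all()

    def test_aod_non_negative(self, small_grid):
        truth = TruthConfig(seed=4, link_noise_sd=0.5)
        pair = simulate_aod_pair(small_grid, default_dates(2018, 30), truth)
        assert pair.satellite.values.min() >= 0.0
        assert pair.n_clipped > 0  # large noise must have clipped something


class TestTruthPM25:
    def test_deterministic_limit_is_exact_linear_model(self, noiseless_bundle):
        b = noiseless_bundle
        t = b.truth
        a = t.fixed_effects
        aod = b.aod.satellite_full.values
        expect = (a[0] + a[1] * aod + a[2] * b.met["temp"].values + a[3] * b.met["rh"].values
                  + a[4] * b.met["v10"].values + a[5] * b.met["pres"].values
                  + a[6] * b.static.urban[None] + a[7] * b.static.grass[None])
        expect = np.maximum(expect, t.pm25_floor)
        np.testing.assert_allclose(b.pm25_truth.values, expect, rtol=1e-12)

    def test_plausible_concentrations_at_reported_covariates(self):
        # fixed effects at the reported mean AOD and typical meteorology
        a = TruthConfig().fixed_effects
        pm = (a[0] + a[1] * 0.4034 + a[2] * 25.0 + a[3] * 0.55 + a[4] * 1.0
              + a[5] * 100000.0 + a[6] * 5.0 + a[7] * 5.0)
        assert 0.0 < pm < 300.0

    def test_day_random_effects_have_zero_mean(self, small_grid):
        truth = TruthConfig(seed=9)
        dates = default_dates(2018, 365) + default_dates(2019, 365)[:135]  # 500 days
        met = simulate_meteorology(small_grid, dates, truth.seed)
        pair = simulate_aod_pair(small_grid, dates, truth)
        static = simulate_static_layers(small_grid, truth.seed)
        _, report = simulate_truth_pm25(met, pair.satellite_full, truth,
                                        static.urban.astype(float), static.grass.astype(float))
        re = report["random_effects"]
        sds = np.asarray(truth.re_sd)
        for k, term in enumerate(re.columns):
            bound = 3.0 * sds[k] / np.sqrt(len(re))
            assert abs(re[term].mean()) < bound, term

    def test_missing_covariate_rejected(self, small_grid):
        truth = TruthConfig(seed=1)
        dates = default_dates(2018, 5)
        met = simulate_meteorology(small_grid, dates, truth.seed)
        del met["rh"]
        pair = simulate_aod_pair(small_grid, dates, truth)
        with pytest.raises(ValueError, match="rh"):
            simulate_truth_pm25(met, pair.satellite_full, truth,
                                np.zeros(small_grid.shape), np.zeros(small_grid.shape))


class TestMonitors:
    def test_exact_sampling_without_noise(self, noiseless_bundle):
        b = noiseless_bundle
        for sid, g in b.monitors.groupby("station_id"):
            i, j = int(g["cell_i"].iloc[0]), int(g["cell_j"].iloc[0])
            np.testing.assert_array_equal(g["pm25"].to_numpy(), b.pm25_truth.values[:, i, j])

    def test_stations_never_share_a_cell(self, fixture_bundle):
        cells = fixture_bundle.monitors[["cell_i", "cell_j"]].drop_duplicates()
        assert len(cells) == fixture_bundle.truth.n_stations

    def test_outlier_injection_rate(self, small_grid):
        truth = noiseless_truth(seed=21)
        dates = default_dates(2018, 300)
        met = simulate_meteorology(small_grid, dates, truth.seed)
        pair = simulate_aod_pair(small_grid, dates, truth)
        static = simulate_static_layers(small_grid, truth.seed)
        pm, _ = simulate_truth_pm25(met, pair.satellite_full, truth,
                                    static.urban.astype(float), static.grass.astype(float))
        # ~1e4 records at rate 1e-3: Binomial(10200, 0.001), mean ~10
        mon = sample_monitors(pm, 34, noise_sd=0.0, outlier_rate=0.001, seed=13)
        n_out = int((mon["pm25"] >= 500.0).sum())
        assert 3 <= n_out <= 20
        assert mon.loc[mon["pm25"] >= 500.0, "pm25"].max() <= 1000.0

    def test_too_many_stations_rejected(self, noiseless_bundle):
        with pytest.raises(ValueError):
            sample_monitors(noiseless_bundle.pm25_truth, 10**6, 0.0, 0.0, 1)


class TestStaticLayers:
    def test_district_partition(self, small_grid):
        st = simulate_static_layers(small_grid, seed=2)
        assert st.districts.shape == small_grid.shape
        assert st.districts.min() == 0 and st.districts.max() == 19
        # partition: every cell labeled exactly once is inherent to a label array;
        # check all 20 districts are non-empty
        assert len(np.unique(st.districts)) == 20

    def test_counts_are_non_negative_integers(self, small_grid):
        st = simulate_static_layers(small_grid, seed=2)
        for arr in (st.urban, st.grass, st.crop):
            assert np.issubdtype(arr.dtype, np.integer)
            assert arr.min() >= 0
            assert arr.max() <= 25  # fine_factor^2

    def test_baseline_mortality_ci_ordered(self, small_grid):
        st = simulate_static_layers(small_grid, seed=2)
        h = st.health
        assert (h["bm_lo"] <= h["bm_mid"]).all() and (h["bm_mid"] <= h["bm_hi"]).all()
        assert (h["pop"] >= 0).all()

    def test_age_groups_partition_population(self, small_grid):
        st = simulate_static_layers(small_grid, seed=2)
        per_district = st.health[st.health["disease"] == "IHD"].groupby("district")["pop"].sum()
        for d, total in per_district.items():
            assert total == pytest.approx(st.population[st.districts == d].sum(), rel=1e-9)


class TestFixtureIO:
    def test_round_trip(self, tmp_path, noiseless_bundle):
        paths = write_fixture(noiseless_bundle, tmp_path / "fx")
        back = read_fixture(tmp_path / "fx")
        np.testing.assert_allclose(back["pm25_truth"].values, noiseless_bundle.pm25_truth.values, rtol=1e-12)
        np.testing.assert_array_equal(back["aod_sat"].mask, noiseless_bundle.aod.satellite.mask)
        got = back["aod_sat"].values[~back["aod_sat"].mask]
        want = noiseless_bundle.aod.satellite.values[~noiseless_bundle.aod.satellite.mask]
        np.testing.assert_allclose(got, want, rtol=1e-12)
        assert back["manifest"]["seed"] == noiseless_bundle.truth.seed
        assert back["dates"] == noiseless_bundle.dates

    def test_fixed_seed_bit_identical_bundle(self, small_grid, tmp_path):
        dates = default_dates(2018, 15)
        for d in ("a", "b"):
            write_fixture(simulate_fixture(small_grid, dates, TruthConfig(seed=17)), tmp_path / d)
        for name in ("dynamic.nc", "static.nc", "monitors.csv", "health.csv", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes(), name
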