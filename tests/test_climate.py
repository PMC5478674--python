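"""Synthetic precipitation trajectories and wind-event sampling."""

import statistics

import numpy as np
import pandas as pd
import pytest
from scipy.special import gamma

from vista import (ClimateSeries, ScenarioSpec, WindClimatology,
                   equilibrium_year_forcing, generate_precip_trajectory,
                   load_climate_table, moving_sigma,
                   perturb_around_trajectory, sample_wind_event)
from vista.config import SEASONS


def make_series(values_by_year, site="t"):
    rows = [(y, s, v) for y, sv in values_by_year.items()
            for s, v in zip(SEASONS, sv)]
    return ClimateSeries(pd.DataFrame(rows,
                                      columns=["year", "season", "precip_mm"]),
                         site)


class TestTrajectoryGeneration:
    def test_deterministic_linear_trend(self):
        spec = ScenarioSpec(year_start=2017, year_end=2100,
                            season_means={"DJF": 200.0, "MAM": 50.0,
                                          "JJA": 10.0, "SON": 60.0},
                            season_trends={"DJF": -0.5, "MAM": 0.0,
                                           "JJA": 0.0, "SON": 0.0},
                            sigma_annual_mm=0.0)
        series = generate_precip_trajectory(spec)
        assert series.value(2100, "DJF") == pytest.approx(158.5)
        assert series.value(2017, "DJF") == pytest.approx(200.0)
        assert series.value(2050, "MAM") == pytest.approx(50.0)

    def test_sigma_zero_exactly_deterministic(self):
        spec = ScenarioSpec(year_start=2000, year_end=2010)
        a = generate_precip_trajectory(spec, np.random.default_rng(1))
        b = generate_precip_trajectory(spec, np.random.default_rng(2))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_seasonal_sigma_partition(self):
        # annual-equivalent 30 mm splits as 30/2 per season
        assert ScenarioSpec(sigma_annual_mm=30.0).sigma_season_mm == 15.0

    def test_stationary_mean_within_three_se(self):
        n_years = 10_000
        spec = ScenarioSpec(year_start=0, year_end=n_years - 1,
                            season_means={"DJF": 200.0, "MAM": 80.0,
                                          "JJA": 30.0, "SON": 90.0},
                            season_trends={s: 0.0 for s in SEASONS},
                            sigma_annual_mm=30.0)
        series = generate_precip_trajectory(spec, np.random.default_rng(3))
        djf = series.season_series("DJF")
        se = 15.0 / np.sqrt(n_years)
        assert abs(djf.mean() - 200.0) < 3 * se

    def test_precipitation_never_negative(self):
        spec = ScenarioSpec(year_start=0, year_end=300,
                            season_means={s: 5.0 for s in SEASONS},
                            season_trends={s: 0.0 for s in SEASONS},
                            sigma_annual_mm=160.0)
        series = generate_precip_trajectory(spec, np.random.default_rng(4))
        assert (series.data["precip_mm"] >= 0).all()

    def test_annual_total_is_sum_of_seasons(self):
        spec = ScenarioSpec(year_start=2000, year_end=2020,
                            sigma_annual_mm=30.0)
        series = generate_precip_trajectory(spec, np.random.default_rng(5))
        annual = series.annual_totals()
        for year in (2000, 2010, 2020):
            manual = sum(series.value(year, s) for s in SEASONS)
            assert annual[year] == pytest.approx(manual)

    def test_low_variability_has_smaller_cv_than_high(self):
        means = {"DJF": 200.0, "MAM": 80.0, "JJA": 30.0, "SON": 90.0}
        cvs = {}
        for sigma in (30.0, 160.0):
            spec = ScenarioSpec(year_start=0, year_end=499,
                                season_means=means,
                                season_trends={s: 0.0 for s in SEASONS},
                                sigma_annual_mm=sigma)
            s = generate_precip_trajectory(spec, np.random.default_rng(6))
            a = s.annual_totals()
            cvs[sigma] = a.std() / a.mean()
        assert cvs[30.0] < cvs[160.0]

    def test_empty_year_range_rejected(self):
        with pytest.raises(ValueError, match="year range"):
            ScenarioSpec(year_start=2100, year_end=2000)


class TestEquilibriumForcing:
    def test_window_is_21_years_centred(self):
        series = make_series({y: (float(y), 1.0, 1.0, 1.0)
                              for y in range(2015, 2046)})
        forcing = equilibrium_year_forcing(series, 2030)
        assert forcing["DJF"] == pytest.approx(np.mean(range(2020, 2041)))

    def test_constant_series_gives_constant(self):
        series = make_series({y: (7.0, 7.0, 7.0, 7.0)
                              for y in range(2000, 2061)})
        forcing = equilibrium_year_forcing(series, 2030)
        assert all(v == pytest.approx(7.0) for v in forcing.values())

    def test_ramp_window_mean_is_midpoint(self):
        series = make_series({y: (2.0 * y, 0.0, 0.0, 0.0)
                              for y in range(2000, 2061)})
        forcing = equilibrium_year_forcing(series, 2030)
        assert forcing["DJF"] == pytest.approx(2.0 * 2030)

    def test_incomplete_window_names_missing_years(self):
        series = make_series({y: (1.0,) * 4 for y in range(2025, 2036)})
        with pytest.raises(ValueError, match="2020"):
            equilibrium_year_forcing(series, 2030)


class TestMovingSigma:
    def test_constant_series_sigma_zero(self):
        series = make_series({y: (5.0,) * 4 for y in range(2000, 2010)})
        sig = moving_sigma(series)
        assert np.allclose(sig.to_numpy(), 0.0)

    def test_alternating_matches_brute_force(self):
        vals = {y: (100.0 if y % 2 == 0 else 200.0,) * 4
                for y in range(2000, 2011)}
        series = make_series(vals)
        sig = moving_sigma(series, window=5)
        # interior year: centred window over 5 alternating values
        window_vals = [vals[y][0] for y in range(2003, 2008)]
        assert sig.loc[2005, "DJF"] == pytest.approx(
            statistics.stdev(window_vals))

    def test_too_short_series_rejected(self):
        series = make_series({y: (1.0,) * 4 for y in range(2000, 2003)})
        with pytest.raises(ValueError, match="at least"):
            moving_sigma(series)

    def test_perturbation_stays_nonnegative_and_differs(self):
        series = make_series({y: (50.0 + (y % 7) * 30.0,) * 4
                              for y in range(2000, 2040)})
        noisy = perturb_around_trajectory(series, np.random.default_rng(8))
        assert (noisy.data["precip_mm"] >= 0).all()
        assert not np.allclose(noisy.data["precip_mm"],
                               series.data["precip_mm"])


class TestWindSampling:
    def test_degenerate_climatology(self):
        probs = np.zeros(16)
        probs[4] = 1.0     # due-east bin, 90 deg
        clim = WindClimatology(weibull={s: (2.0, 1e-9) for s in SEASONS},
                               direction_probs=probs)
        ev = sample_wind_event(clim, "DJF", np.random.default_rng(0))
        assert ev.direction == pytest.approx(90.0)
        assert ev.speed < 1e-6

    def test_weibull_mean_closed_form(self, climatology):
        rng = np.random.default_rng(9)
        speeds = [sample_wind_event(climatology, "SON", rng).speed
                  for _ in range(100_000)]
        k, lam = climatology.weibull["SON"]
        expected = lam * gamma(1.0 + 1.0 / k)
        assert np.mean(speeds) == pytest.approx(expected, rel=0.01)

    def test_same_seed_identical_event(self, climatology):
        a = sample_wind_event(climatology, "JJA", np.random.default_rng(5))
        b = sample_wind_event(climatology, "JJA", np.random.default_rng(5))
        assert a == b

    def test_unnormalised_direction_table_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            WindClimatology(direction_probs=np.full(16, 0.1))

    def test_climatology_file_roundtrip(self, climatology, tmp_path):
        for name in ("clim.yaml", "clim.json"):
            path = tmp_path / name
            climatology.to_file(path)
            back = WindClimatology.from_file(path)
            assert back.weibull == climatology.weibull
            np.testing.assert_allclose(back.direction_probs,
                                       climatology.direction_probs)


class TestClimateTables:
    def test_single_year_roundtrip(self, tmp_path):
        series = make_series({2030: (120.0, 40.0, 5.0, 60.0)})
        path = tmp_path / "clim.csv"
        series.to_csv(path)
        back = load_climate_table(path)
        assert len(back) == 4
        pd.testing.assert_frame_equal(back.data, series.data)

    def test_missing_season_rejected(self, tmp_path):
        df = pd.DataFrame({"year": [2030] * 3,
                           "season": ["DJF", "MAM", "SON"],
                           "precip_mm": [1.0, 2.0, 3.0]})
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="JJA"):
            load_climate_table(path)

    def test_negative_precip_rejected(self, tmp_path):
        df = pd.DataFrame({"year": [2030] * 4, "season": list(SEASONS),
                           "precip_mm": [1.0, -2.0, 3.0, 4.0]})
        path = tmp_path / "neg.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="negative"):
            load_climate_table(path)

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "mal.csv"
        path.write_text("year,season,precip_mm\n2030,DJF,1.0\n2030,MAM,oops\n")
        with pytest.raises(ValueError, match="line 3"):
            load_climate_table(path)
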