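"""Climate/SST feature catalogue: elementary counts, phase assembly,
standardization, and lead-time selection."""

import numpy as np
import pandas as pd
import pytest
from oracles import (
    count_above_oracle,
    count_below_oracle,
    dry_spell_oracle,
    median_oracle,
    percentile_oracle,
)

from maizecast.features import (
    FeatureTable,
    count_dry_spells,
    count_percentile_events,
    count_threshold_days,
    long_term_percentile,
    phase_weather_features,
    select_lead_time,
    sst_features,
)
from maizecast.growing_season import SeasonCalendar
from maizecast.weather import SSTSeries


class TestElementaryOps:
    def test_percentile_linear_interpolation_midpoint(self):
        assert long_term_percentile(np.arange(1, 101), 50) == 50.5

    def test_percentile_of_constant_series(self):
        assert long_term_percentile(np.full(150, 7.0), 99) == 7.0

    def test_percentile_matches_sort_interpolate_oracle(self, rng):
        vals = rng.gamma(1.0, 8.0, 500)
        for q in (1, 50, 99):
            assert long_term_percentile(vals, q) == pytest.approx(percentile_oracle(vals, q))

    def test_percentile_requires_reference_sample(self):
        with pytest.raises(ValueError):
            long_term_percentile(np.arange(10), 99)

    def test_exceedance_counts_are_strict(self):
        assert count_percentile_events([1, 2, 3], 2, "above") == 1
        assert count_percentile_events([1, 2, 3], 2, "below") == 1
        assert count_percentile_events([1, 2, 3], 5, "above") == 0

    def test_threshold_day_counts(self):
        precip = [0.0, 4.0, 6.0, 20.0]
        assert count_threshold_days(precip, 5.0, "above") == 2
        assert count_threshold_days(precip, 5.0, "below") == 2  # zero-rain days count

    def test_counts_match_loop_oracle(self, rng):
        vals = rng.gamma(0.9, 8.0, 200)
        thr = float(np.median(vals))
        assert count_percentile_events(vals, thr, "above") == count_above_oracle(vals, thr)
        assert count_percentile_events(vals, thr, "below") == count_below_oracle(vals, thr)

    def test_dry_spells_fully_dry_phase_is_one_run(self):
        assert count_dry_spells(np.zeros(55), 5) == 1

    def test_dry_spells_alternating_days_never_qualify(self):
        precip = np.tile([0.0, 5.0], 30)
        for n in (5, 10, 15, 20):
            assert count_dry_spells(precip, n) == 0

    def test_dry_spells_match_run_length_oracle(self, rng):
        for _ in range(50):
            p = np.where(rng.random(60) < 0.5, rng.gamma(1, 5, 60), 0.0)
            for n in (5, 10, 15, 20):
                assert count_dry_spells(p, n) == dry_spell_oracle(p, n)


def _flat_weather(precip, tas, region="X", base_year=2009, years=(2010,)):
    from maizecast.weather import RegionDailyWeather

    df = pd.DataFrame(
        {"precip": precip, "tas": tas, "tasmax": tas + 5.0, "tasmin": tas - 5.0}
    )
    return RegionDailyWeather(region, base_year, tuple(years), {"c0": df}, {"c0": 1.0})


class TestPhaseFeatures:
    def test_constant_season_values(self):
        n = 2 * 365
        precip = np.full(n, 2.0)
        tas = np.full(n, 25.0)
        w = _flat_weather(precip, tas)
        cal = SeasonCalendar("X", "unimodal", onset_offset=0, split_day=55)
        thr = {"tasmax_p99": 31.0, "tasmin_p01": 19.0, "precip_p99": 3.0}
        out = phase_weather_features(w, cal, 2010, "v", thr)
        assert out["tas.median_v"] == 25.0
        assert out["tas.max_v"] == 30.0
        assert out["tas.min_v"] == 20.0
        assert out["Psum_v"] == pytest.approx(110.0)  # 2 mm/day over 55 days
        assert out["cdd5_v"] == 0
        assert out["pB5_v"] == 55 and out["pA5_v"] == 0
        assert out["precip.p99_v"] == 0

    def test_every_feature_matches_its_standalone_oracle(self, small_dataset):
        region = small_dataset.regions[0]
        w = small_dataset.weather[region]
        cal = small_dataset.calendars[region]
        from maizecast.features import longterm_thresholds

        thr = longterm_thresholds(w, cal, small_dataset.years)
        for year in small_dataset.years[:3]:
            for phase in ("v", "r"):
                start, n_days = cal.phase_offsets(phase)
                sub = w.season_slice(w.mean, year, start, n_days)
                p = sub["precip"].to_numpy()
                got = phase_weather_features(w, cal, year, phase, thr)
                assert got[f"tas.median_{phase}"] == pytest.approx(median_oracle(sub["tas"]))
                assert got[f"tas.max_{phase}"] == pytest.approx(median_oracle(sub["tasmax"]))
                assert got[f"tas.min_{phase}"] == pytest.approx(median_oracle(sub["tasmin"]))
                assert got[f"Psum_{phase}"] == pytest.approx(float(p.sum()))
                for t in (5, 10, 15):
                    assert got[f"pA{t}_{phase}"] == count_above_oracle(p, t)
                    assert got[f"pB{t}_{phase}"] == count_below_oracle(p, t)
                for n in (5, 10, 15, 20):
                    assert got[f"cdd{n}_{phase}"] == dry_spell_oracle(p, n)
                assert got[f"tas.max99_{phase}"] == count_above_oracle(
                    sub["tasmax"], thr["tasmax_p99"]
                )
                assert got[f"tas.min01_{phase}"] == count_below_oracle(
                    sub["tasmin"], thr["tasmin_p01"]
                )
                assert got[f"precip.p99_{phase}"] == count_above_oracle(p, thr["precip_p99"])

    def test_features_ignore_weather_outside_season_and_lead_window(self, small_dataset):
        import copy

        from maizecast.features import build_feature_table

        region = small_dataset.regions[0]
        w = copy.deepcopy(small_dataset.weather[region])
        cal = small_dataset.calendars[region]
        year = small_dataset.years[4]
        base = (year - w.base_year) * 365
        # corrupt the 30 days after the season end of one mid-series year
        for df in w.cells.values():
            i0 = base + cal.end_offset + 5
            df.loc[i0 : i0 + 30, "precip"] = 99.0
        del w.__dict__["mean"]  # invalidate cache after mutation
        before = small_dataset.features[region].df
        after = build_feature_table(
            w, cal, small_dataset.sst, small_dataset.years
        ).df
        # only the percentile-threshold features may move (reference pool is
        # in-season days only, which were untouched) — nothing should change
        pd.testing.assert_frame_equal(before, after)


class TestSstFeatures:
    def _series(self, values, base_year=2009):
        return SSTSeries("nino34", base_year, np.asarray(values, dtype=float))

    def test_constant_anomaly_series(self):
        sst = self._series(np.full(36, 0.4))
        cal = SeasonCalendar("X", "unimodal", onset_offset=20, split_day=55)
        out = sst_features(sst, cal, 2010, 120)
        assert out["nino34_120.median"] == pytest.approx(0.4)
        assert out["nino34_120.p99"] == 0
        assert out["nino34_120.p01"] == 0

    def test_window_counts_match_loop_oracle(self, small_dataset):
        cal = small_dataset.calendars[small_dataset.regions[0]]
        sst = small_dataset.sst["wp"]
        hi = percentile_oracle(sst.anomaly, 99)
        lo = percentile_oracle(sst.anomaly, 1)
        for year in small_dataset.years[:4]:
            out = sst_features(sst, cal, year, 120)
            yb = (year - sst.base_year) * 365
            mids = sst.month_mid_offsets()
            w0, w1 = yb + cal.onset_offset - 120, yb + cal.split_offset - 120
            vals = [a for a, m in zip(sst.anomaly, mids) if w0 <= m <= w1]
            assert out["wp_120.median"] == pytest.approx(median_oracle(vals))
            assert out["wp_120.p99"] == count_above_oracle(vals, hi)
            assert out["wp_120.p01"] == count_below_oracle(vals, lo)

    def test_window_outside_series_raises(self):
        sst = self._series(np.zeros(12), base_year=2010)
        cal = SeasonCalendar("X", "unimodal", onset_offset=10, split_day=55)
        with pytest.raises(ValueError, match="window outside series"):
            sst_features(sst, cal, 2030, 120)

    def test_lead_time_chosen_by_yield_correlation(self, rng):
        sst = self._series(rng.normal(0, 0.5, 48), base_year=2009)
        cal = SeasonCalendar("X", "unimodal", onset_offset=30, split_day=55)
        years = [2010, 2011, 2012]
        feats = [
            sst_features(sst, cal, y, 120)["nino34_120.median"] for y in years
        ]
        anomalies = pd.Series(2.0 * np.asarray(feats), index=years)
        assert select_lead_time(sst, cal, years, anomalies, [30, 120]) == 120

    def test_single_candidate_returned_unchanged(self, rng):
        sst = self._series(rng.normal(0, 0.5, 48))
        cal = SeasonCalendar("X", "unimodal", onset_offset=30, split_day=55)
        anomalies = pd.Series([0.1, -0.2, 0.3], index=[2010, 2011, 2012])
        assert select_lead_time(sst, cal, [2010, 2011, 2012], anomalies, [90]) == 90

    def test_tied_candidates_prefer_shorter_lead(self, rng):
        sst = self._series(rng.normal(0, 0.5, 48))
        cal = SeasonCalendar("X", "unimodal", onset_offset=30, split_day=55)
        years = [2010, 2011, 2012]
        # leads 3 and 8 shift the window by 5 days without changing which
        # month midpoints fall inside it -> identical features, a pure tie
        f3 = [sst_features(sst, cal, y, 3)["nino34_3.median"] for y in years]
        f8 = [sst_features(sst, cal, y, 8)["nino34_8.median"] for y in years]
        assert f3 == f8
        anomalies = pd.Series(np.asarray(f3) + [0.01, -0.02, 0.01], index=years)
        assert select_lead_time(sst, cal, years, anomalies, [8, 3]) == 3


class TestStandardize:
    def _table(self, cols, years=(2010, 2011, 2012)):
        df = pd.DataFrame(cols, index=pd.Index(years, name="year")).astype(float)
        return FeatureTable("X", df, {c: "v" for c in df.columns})

    def test_sample_sd_scaling(self):
        ft = self._table({"a": [1, 2, 3]}).standardize([2010, 2011, 2012])
        assert np.allclose(ft.df["a"], [-1, 0, 1])  # sample sd of {1,2,3} is 1

    def test_constant_column_flagged_not_scaled(self):
        ft = self._table({"a": [2, 2, 2], "b": [1, 2, 3]}).standardize([2010, 2011, 2012])
        assert ft.zero_variance == ("a",)
        assert "a" not in ft.std_params
        assert np.allclose(ft.df["a"], 2.0)

    def test_fit_year_statistics_applied_to_held_out_year(self):
        ft = self._table({"a": [1.0, 3.0, 10.0]})
        out = ft.standardize([2010, 2011])
        mu, sd = out.std_params["a"]
        assert (mu, sd) == (2.0, pytest.approx(np.sqrt(2)))
        assert out.df.loc[2012, "a"] == pytest.approx((10.0 - 2.0) / np.sqrt(2))

    def test_standardized_columns_have_zero_mean_unit_sd_over_fit_years(self, small_dataset):
        ft = small_dataset.features_std[small_dataset.regions[0]]
        fit = ft.df.loc[list(small_dataset.years)]
        for col in ft.std_params:
            assert abs(fit[col].mean()) < 1e-8
            assert abs(fit[col].std(ddof=1) - 1.0) < 1e-8

    def test_scope_subsetting(self, small_dataset):
        ft = small_dataset.features[small_dataset.regions[0]]
        fc = ft.subset_scope("forecast")
        assert all(not c.endswith("_r") for c in fc.columns)
        assert any(c.endswith("_v") for c in fc.columns)
        assert any(ft.phase[c] == "sst" for c in fc.columns)
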