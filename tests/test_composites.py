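"""Tercile-composite machinery: detrending oracles, tercile bookkeeping,
envelope calibration under the null, and power under an injected coupling."""

import numpy as np
import pandas as pd
import pytest

from vinoclim import composites as cmp

from conftest import make_monthly_series


YEARS = list(range(1993, 2018))  # 25 years


class TestDetrendMonthly:
    def test_exact_linear_series_gives_zero_residuals(self):
        years = np.arange(2000, 2015)
        vals = np.array([[0.5 * y + m for m in range(12)] for y in years])
        resid = cmp.detrend_monthly(make_monthly_series(vals, years))
        assert np.allclose(resid.to_numpy(), 0.0, atol=1e-9)

    def test_month_independence(self, rng):
        years = np.arange(2000, 2015)
        vals = rng.normal(size=(len(years), 12))
        base = cmp.detrend_monthly(make_monthly_series(vals, years))
        shifted = vals.copy()
        shifted[:, 4] += 7.5  # constant added to every May
        after = cmp.detrend_monthly(make_monthly_series(shifted, years))
        for m in range(1, 13):
            if m == 5:
                continue
            assert np.allclose(base.xs(m, level="month"),
                               after.xs(m, level="month"), atol=1e-10)

    def test_matches_per_month_least_squares_oracle(self, rng):
        years = np.arange(2000, 2020)
        vals = rng.normal(size=(len(years), 12)) + 0.1 * years[:, None]
        resid = cmp.detrend_monthly(make_monthly_series(vals, years))
        for m in range(1, 13):
            y = vals[:, m - 1]
            t = years.astype(float)
            design = np.column_stack([np.ones_like(t), t])
            beta = np.linalg.lstsq(design, y, rcond=None)[0]
            oracle = y - design @ beta
            assert np.allclose(resid.xs(m, level="month").to_numpy(), oracle,
                               atol=1e-10)

    def test_residual_means_vanish(self, rng):
        years = np.arange(2000, 2012)
        vals = rng.normal(size=(len(years), 12))
        resid = cmp.detrend_monthly(make_monthly_series(vals, years))
        for m in range(1, 13):
            assert abs(resid.xs(m, level="month").mean()) < 1e-9

    def test_short_months_excluded(self):
        idx = pd.MultiIndex.from_tuples(
            [(y, 1) for y in range(2000, 2010)] + [(2000, 2), (2001, 2)],
            names=["year", "month"])
        s = pd.Series(np.arange(12.0), index=idx)
        resid = cmp.detrend_monthly(s)
        assert 2 not in resid.index.get_level_values("month")


class TestClassifyTerciles:
    def test_25_years_gives_8_per_extreme_set(self, rng):
        s = pd.Series(rng.normal(size=25), index=YEARS)
        terc = cmp.classify_terciles(s)
        assert terc.m == 8
        assert len(terc.low_years) == 8 and len(terc.high_years) == 8
        assert not set(terc.low_years) & set(terc.high_years)
        assert set(terc.labels.index) == set(YEARS)

    def test_minimal_case(self):
        s = pd.Series([1.0, 2.0, 3.0, 1.5, 2.5, 0.5], index=range(2000, 2006))
        terc = cmp.classify_terciles(s, detrend=False)
        assert terc.m == 2
        assert 2005 in terc.low_years and 2002 in terc.high_years

    def test_matches_sort_based_oracle(self, rng):
        years = list(range(1995, 2018))  # n = 23
        vals = rng.normal(size=len(years))
        s = pd.Series(vals, index=years)
        terc = cmp.classify_terciles(s, detrend=False)
        order = np.argsort(vals, kind="stable")
        m = len(years) // 3
        assert set(terc.low_years) == {years[i] for i in order[:m]}
        assert set(terc.high_years) == {years[i] for i in order[-m:]}

    def test_boundary_ties_broken_by_year_order(self):
        s = pd.Series([5.0, 1.0, 3.0, 3.0, 3.0, 9.0], index=range(2000, 2006))
        terc = cmp.classify_terciles(s, detrend=False)
        # low set: 1.0 (2001) then the earliest of the tied 3.0s (2002)
        assert set(terc.low_years) == {2001, 2002}
        # high set: 9.0 (2005) then 5.0 (2000)
        assert set(terc.high_years) == {2005, 2000}


class TestCompositeAnomalies:
    def test_zero_residuals_zero_composites(self):
        resid = make_monthly_series(np.zeros((10, 12)), range(2000, 2010))
        comp = cmp.composite_anomalies(resid, range(2000, 2005))
        assert np.allclose(comp.to_numpy(), 0.0)

    def test_all_years_composite_vanishes_after_detrend(self, rng):
        years = np.arange(2000, 2015)
        vals = rng.normal(size=(len(years), 12))
        resid = cmp.detrend_monthly(make_monthly_series(vals, years))
        comp = cmp.composite_anomalies(resid, years)
        assert np.allclose(comp.to_numpy(), 0.0, atol=1e-9)

    def test_matches_mean_oracle(self, rng):
        years = np.arange(2000, 2012)
        vals = rng.normal(size=(len(years), 12))
        resid = make_monthly_series(vals, years)
        subset = [2001, 2005, 2010]
        comp = cmp.composite_anomalies(resid, subset)
        rows = [i for i, y in enumerate(years) if y in subset]
        assert np.allclose(comp.to_numpy(), vals[rows].mean(axis=0), atol=1e-12)


class TestBootstrapEnvelope:
    def test_zero_residuals_degenerate_envelope(self):
        resid = make_monthly_series(np.zeros((25, 12)), YEARS)
        env = cmp.bootstrap_envelope(resid, m=8, n_boot=500, seed=0)
        assert np.allclose(env["lo"], 0.0) and np.allclose(env["hi"], 0.0)

    def test_reproducible_under_seed(self, rng):
        resid = make_monthly_series(rng.normal(size=(25, 12)), YEARS)
        a = cmp.bootstrap_envelope(resid, m=8, n_boot=500, seed=3)
        b = cmp.bootstrap_envelope(resid, m=8, n_boot=500, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_half_width_matches_clt(self):
        """i.i.d. N(0,1), m=8: 95th percentile of the mean ~ 1.645/sqrt(8)."""
        rng = np.random.default_rng(11)
        resid = make_monthly_series(rng.normal(size=(25, 12)), YEARS)
        env = cmp.bootstrap_envelope(resid, m=8, n_boot=20_000, seed=1)
        expected = 1.645 / np.sqrt(8)
        assert env["hi"].mean() == pytest.approx(expected, abs=0.12)
        assert env["lo"].mean() == pytest.approx(-expected, abs=0.12)

    def test_envelope_widens_as_m_decreases(self, rng):
        resid = make_monthly_series(rng.normal(size=(25, 12)), YEARS)
        widths = []
        for m in (16, 8, 4):
            env = cmp.bootstrap_envelope(resid, m=m, n_boot=4000, seed=9)
            widths.append((env["hi"] - env["lo"]).mean())
        assert widths[0] < widths[1] < widths[2]

    def test_subsample_mode_rejects_oversized_m(self, rng):
        resid = make_monthly_series(rng.normal(size=(10, 12)), range(2000, 2010))
        with pytest.raises(ValueError, match="without replacement"):
            cmp.bootstrap_envelope(resid, m=11, n_boot=500, replace=False)

    def test_null_draw_outside_envelope_about_10_percent(self):
        """A random same-size composite escapes the 5-95 envelope ~10% of the time."""
        rng = np.random.default_rng(21)
        flags = trials = 0
        for _ in range(1000):
            mat = rng.normal(size=(25, 3))  # 3 months is enough per draw
            resid = pd.Series(
                mat.ravel(),
                index=pd.MultiIndex.from_product([YEARS, [1, 2, 3]],
                                                 names=["year", "month"]))
            env = cmp.bootstrap_envelope(resid, m=8, n_boot=400, seed=int(rng.integers(2**31)))
            draw = rng.integers(0, 25, size=8)
            means = mat[draw].mean(axis=0)
            flags += int(((means < env["lo"].to_numpy())
                          | (means > env["hi"].to_numpy())).sum())
            trials += 3
        assert 0.07 <= flags / trials <= 0.13


class TestCompositeReport:
    @staticmethod
    def coupled_data(coupling, seed, n_years=25):
        """Monthly variable with a May anomaly tied to high-index years."""
        rng = np.random.default_rng(seed)
        years = np.array(YEARS[:n_years])
        index = pd.Series(rng.normal(size=n_years), index=years)
        vals = rng.normal(size=(n_years, 12))
        terc = cmp.classify_terciles(index)
        high = np.isin(years, terc.high_years)
        vals[high, 4] += coupling  # May
        return make_monthly_series(vals, years), index

    def test_injected_may_anomaly_detected(self):
        """+1.5 sd May anomaly in high-index years flags May >= 90% of runs."""
        hits = 0
        reps = 100
        for rep in range(reps):
            monthly, index = self.coupled_data(1.5, seed=rep)
            res = cmp.composite_report(monthly, index, n_boot=1000, seed=rep)
            if res.flags.loc[5, "high"]:
                hits += 1
        assert hits / reps >= 0.90

    def test_null_flag_rate_calibrated(self):
        """Without coupling, subsample envelopes flag ~10% of cells (both tails)."""
        flags = cells = 0
        reps = 150
        for rep in range(reps):
            monthly, index = self.coupled_data(0.0, seed=10_000 + rep)
            res = cmp.composite_report(monthly, index, n_boot=600,
                                       seed=rep, replace=False)
            flags += int(res.flags.to_numpy().sum())
            cells += res.flags.size
        assert 0.07 <= flags / cells <= 0.13

    def test_default_envelope_conservative_under_null(self):
        """With-replacement envelopes flag at most the nominal 10% rate."""
        flags = cells = 0
        reps = 100
        for rep in range(reps):
            monthly, index = self.coupled_data(0.0, seed=50_000 + rep)
            res = cmp.composite_report(monthly, index, n_boot=600, seed=rep)
            flags += int(res.flags.to_numpy().sum())
            cells += res.flags.size
        assert flags / cells <= 0.13

    def test_index_sign_flip_swaps_categories(self, rng):
        monthly, index = self.coupled_data(1.0, seed=5)
        a = cmp.composite_report(monthly, index, n_boot=500, seed=1)
        b = cmp.composite_report(monthly, -index, n_boot=500, seed=1)
        pd.testing.assert_series_equal(a.composites["high"], b.composites["low"],
                                       check_names=False)
        pd.testing.assert_series_equal(a.composites["low"], b.composites["high"],
                                       check_names=False)

    def test_invariant_to_added_linear_trend(self):
        monthly, index = self.coupled_data(1.0, seed=6)
        years = monthly.index.get_level_values("year").to_numpy(dtype=float)
        trended = monthly + 0.3 * (years - years.mean())
        a = cmp.composite_report(monthly, index, n_boot=500, seed=2)
        b = cmp.composite_report(trended, index, n_boot=500, seed=2)
        pd.testing.assert_frame_equal(a.composites, b.composites, atol=1e-9)

    def test_weighted_category_composites_sum_to_zero(self, rng):
        monthly, index = self.coupled_data(0.0, seed=7)
        res = cmp.composite_report(monthly, index, n_boot=500, seed=3)
        resid = cmp.detrend_monthly(monthly)
        terc = res.terciles
        mid_years = terc.labels.index[terc.labels == "mid"]
        mid = cmp.composite_anomalies(resid, mid_years)
        n = len(terc.labels)
        total = (res.composites["high"] * terc.m + res.composites["low"] * terc.m
                 + mid * len(mid_years)) / n
        assert np.allclose(total.to_numpy(), 0.0, atol=1e-9)

    def test_tidy_frame_shape(self):
        monthly, index = self.coupled_data(1.0, seed=8)
        res = cmp.composite_report(monthly, index, n_boot=500, seed=4)
        tidy = res.to_frame()
        assert len(tidy) == 24  # 12 months x 2 categories
        assert set(tidy.columns) == {"month", "category", "composite",
                                     "lo", "hi", "significant"}
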