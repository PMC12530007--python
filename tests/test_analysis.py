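"""Daily regression filters, Spearman analysis, and sweep plumbing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import thialloc as th
from thialloc.analysis import classify_slope_signal, daily_regression


def two_pass_ols(x, y):
    """Closed-form OLS oracle (independent of scipy.linregress)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    syy = np.sum((y - ym) ** 2)
    slope = sxy / sxx
    return slope, ym - slope * xm, sxy**2 / (sxx * syy)


class TestDailyRegression:
    def test_perfect_line_recovered(self):
        g = np.arange(1.0, 11.0)
        m = 2.0 * g + 1.0
        res = daily_regression(g, m)
        assert res.passed_filters and res.reported
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.intercept == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.n_included == 10

    def test_ols_matches_closed_form(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(1, 10, 50)
        m = 0.7 * g + rng.normal(0, 1, 50) + 5
        res = daily_regression(g, m)
        slope, intercept, r2 = two_pass_ols(g, m)
        assert res.slope == pytest.approx(slope, abs=1e-12)
        assert res.intercept == pytest.approx(intercept, abs=1e-12)
        assert res.r_squared == pytest.approx(r2, abs=1e-12)

    def test_zero_gonad_females_excluded_and_fraction_rule(self):
        # 40% of the population at c_g = 0 fails the 2/3 inclusion rule
        g = np.r_[np.zeros(4), np.linspace(1, 5, 6)]
        m = np.linspace(5, 10, 10)
        res = daily_regression(g, m)
        assert res.n_included == 6
        assert not res.passed_filters and not res.reported

    def test_all_zero_gonads_fail(self):
        res = daily_regression(np.zeros(10), np.ones(10))
        assert not res.passed_filters

    @pytest.mark.parametrize("axis", ["gonad", "muscle"])
    def test_variation_threshold_both_tissues(self, axis):
        # spread of 0.4 nmol/g (below the 0.5 threshold) blocks the fit
        n = 12
        narrow = np.linspace(1.0, 1.4, n)
        wide = np.linspace(1.0, 6.0, n)
        g, m = (narrow, wide) if axis == "gonad" else (wide, narrow)
        res = daily_regression(g, m)
        assert not res.passed_filters

    def test_fewer_than_three_included_fail(self):
        res = daily_regression(np.array([1.0, 5.0]), np.array([2.0, 3.0]))
        assert not res.passed_filters

    def test_filters_idempotent_and_order_independent(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(0, 8, 30)
        g[rng.random(30) < 0.1] = 0.0
        m = rng.uniform(5, 12, 30)
        a = daily_regression(g, m)
        perm = rng.permutation(30)
        b = daily_regression(g[perm], m[perm])
        assert a.passed_filters == b.passed_filters
        if a.passed_filters:
            assert a.slope == pytest.approx(b.slope, abs=1e-12)

    def test_std_variation_measure_switch(self):
        g = np.linspace(1.0, 1.6, 20)  # range 0.6 passes, std ~0.18 fails
        m = np.linspace(1.0, 9.0, 20)
        assert daily_regression(g, m, variation_measure="range").passed_filters
        assert not daily_regression(g, m, variation_measure="std").passed_filters

    def test_empty_snapshot_rejected(self):
        with pytest.raises(ValueError):
            daily_regression(np.array([]), np.array([]))


class TestSlopeTrajectory:
    def test_identical_females_never_pass(self):
        class FakeSim:
            n_years = 1
            c_g = np.full((1, 5, 20), 3.0, dtype=np.float32)
            c_m = np.full((1, 5, 20), 7.0, dtype=np.float32)
            params = th.ModelParameters()

            def snapshot(self, year, day):
                return (
                    np.asarray(self.c_g[year - 1, day - 1], float),
                    np.asarray(self.c_m[year - 1, day - 1], float),
                )

        traj = th.slope_trajectory(FakeSim())
        assert not traj.results["passed_filters"].any()
        assert classify_slope_signal(traj)["label"] == "none"

    def test_classification_requires_sustained_signal(self):
        days = np.arange(1, 41)
        df = pd.DataFrame(
            {
                "year": 1,
                "day": days,
                "slope": 0.5,
                "reported": days <= 5,  # five transient days only
            }
        )
        traj = th.SlopeTrajectory("x", df)
        assert classify_slope_signal(traj)["label"] == "none"
        df2 = df.assign(reported=days <= 15)
        assert classify_slope_signal(th.SlopeTrajectory("x", df2))["label"] == "positive"


class TestSpearman:
    @staticmethod
    def table(g, m, **cols):
        base = {"system": "limited", "gonad_total_thiamine": g, "muscle_total_thiamine": m}
        base.update(cols)
        return pd.DataFrame(base)

    def test_monotone_pairs(self):
        g = np.arange(10.0)
        assert th.spearman_correlation(self.table(g, g**2)).loc[0, "rho"] == pytest.approx(1.0)
        assert th.spearman_correlation(self.table(g, -g))["rho"].iloc[0] == pytest.approx(-1.0)

    def test_tied_table_matches_midrank_oracle(self):
        # one tie in the muscle column; frozen midrank Pearson value
        g = [1, 2, 3, 4, 5, 6]
        m = [2, 1, 4, 4, 5, 7]
        res = th.spearman_correlation(self.table(g, m))
        assert res.loc[0, "rho"] == pytest.approx(0.9276336570439175, abs=1e-12)
        rg, rm = stats.rankdata(g), stats.rankdata(m)
        manual = stats.pearsonr(rg, rm).statistic
        assert res.loc[0, "rho"] == pytest.approx(manual, abs=1e-12)

    def test_small_groups_flagged_without_p_value(self):
        tab = self.table(
            [1, 2, 3, 4, 5], [1, 2, 3, 4, 5],
            system=["a", "a", "b", "b", "b"],
        )
        res = th.spearman_correlation(tab).set_index("system")
        assert res.loc["a", "flagged"] and np.isnan(res.loc["a", "p_value"])
        assert not res.loc["b", "flagged"]

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="muscle"):
            th.spearman_correlation(pd.DataFrame({"system": [], "gonad_total_thiamine": []}))


class TestScenarioSweep:
    def test_sweep_runs_grid_and_records_failures(self):
        rng_params = th.ModelParameters(
            days_per_year=60, d_s=60, i_max=1, N=50,
            reproductive_mode="semelparous",
            growth={"gonad_buildup_days": 30},
            grid={"c_step": 3.0, "alpha_step": 0.5, "n_input_nodes": 1},
        )
        out = th.scenario_sweep(
            rng_params, {"c_b_mean": [2.0, -1.0]}, seeds=(0, 1), window=30
        )
        ok = out[out["error"] == ""]
        bad = out[out["error"] != ""]
        assert len(ok) == 2  # two seeds for the valid cell
        assert len(bad) == 1 and "c_b_mean" in bad["error"].iloc[0]
        assert {"n_reported", "sign"} <= set(out.columns)
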