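"""Tissue-correlation statistics: the model's early-warning indicator.

For each simulated day a cross-sectional ordinary least-squares regression
of muscle TDP concentration (response) on gonadal free-thiamine
concentration (predictor) is fitted across the population.  To keep
round-off-dominated snapshots out of the record, a day is only fitted when

* females with c_g > 0 are included, and more than 2/3 of the population
  qualifies,
* the variation of the included concentrations exceeds 0.5 nmol/g in both
  tissues (range by default; a standard-deviation reading is available via
  ``variation_measure='std'``) — a regression against a variable whose
  spread has collapsed to numerical noise is meaningless in either
  direction,
* at least three females remain.

A fitted day is *reported* when its R^2 exceeds 0.2.  The sign and trend
of the reported slopes over the final pre-spawning window are the model's
diagnostic of thiamine limitation: positive and rising slopes indicate a
constrained input, negative slopes a replete one, and no reported days an
abrupt allocation switch.

Empirical-style tissue tables (system x river x life stage) are analyzed
with Spearman rank correlations per group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import ModelParameters

__all__ = [
    "DailyRegressionResult",
    "SlopeTrajectory",
    "daily_regression",
    "slope_trajectory",
    "spearman_correlation",
    "scenario_sweep",
    "terminal_window_summary",
]

R2_REPORTING_THRESHOLD = 0.2
MIN_VARIATION = 0.5  # nmol/g
MIN_INCLUDED_FRACTION = 2.0 / 3.0


@dataclass
class DailyRegressionResult:
    """One day's cross-sectional gonad-to-muscle regression."""

    year: int
    day: int
    n_included: int
    frac_included: float
    variation_g: float
    variation_m: float
    slope: float
    intercept: float
    r_squared: float
    passed_filters: bool
    reported: bool


@dataclass
class SlopeTrajectory:
    """Ordered daily regression results for one scenario."""

    scenario: str
    results: pd.DataFrame = field(repr=False)

    def reported(self) -> pd.DataFrame:
        return self.results[self.results["reported"]]


def daily_regression(
    c_g: np.ndarray,
    c_m: np.ndarray,
    year: int = 1,
    day: int = 1,
    variation_measure: str = "range",
) -> DailyRegressionResult:
    """Fit one day's snapshot, applying the inclusion filters.

    ``c_g``/``c_m`` are the per-female concentrations; the denominator of
    the inclusion fraction is the full snapshot size.
    """
    c_g = np.asarray(c_g, dtype=float)
    c_m = np.asarray(c_m, dtype=float)
    if c_g.size == 0:
        raise ValueError("empty snapshot")
    include = c_g > 0
    n_inc = int(include.sum())
    frac = n_inc / c_g.size
    g, m = c_g[include], c_m[include]
    spread = (lambda x: float(np.ptp(x))) if variation_measure == "range" else (
        lambda x: float(np.std(x))
    )
    var_g = spread(g) if n_inc > 0 else 0.0
    var_m = spread(m) if n_inc > 0 else 0.0
    passed = (
        n_inc >= 3
        and frac > MIN_INCLUDED_FRACTION
        and var_g > MIN_VARIATION
        and var_m > MIN_VARIATION
    )
    if not passed:
        return DailyRegressionResult(
            year, day, n_inc, frac, var_g, var_m,
            np.nan, np.nan, np.nan, False, False,
        )
    fit = stats.linregress(g, m)
    r2 = float(fit.rvalue**2)
    return DailyRegressionResult(
        year, day, n_inc, frac, var_g, var_m,
        float(fit.slope), float(fit.intercept), r2, True,
        r2 > R2_REPORTING_THRESHOLD,
    )


def slope_trajectory(
    sim, params: ModelParameters | None = None, scenario: str = ""
) -> SlopeTrajectory:
    """Daily regressions over every (year, day) of a simulated population."""
    if params is None:
        params = sim.params
    rows = []
    for year in range(1, sim.n_years + 1):
        for day in range(1, sim.c_g.shape[1] + 1):
            g, m = sim.snapshot(year, day)
            rows.append(
                daily_regression(g, m, year, day, params.variation_measure).__dict__
            )
    df = pd.DataFrame(rows)
    return SlopeTrajectory(scenario=scenario, results=df)


def spearman_correlation(
    table: pd.DataFrame,
    group_by: Sequence[str] = ("system",),
    muscle_col: str = "muscle_total_thiamine",
    gonad_col: str = "gonad_total_thiamine",
) -> pd.DataFrame:
    """Spearman rank correlation of muscle vs gonad thiamine per group.

    Ties are handled by midranks (scipy's convention); groups with fewer
    than three rows are flagged and get no p-value.
    """
    for col in (muscle_col, gonad_col, *group_by):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    rows = []
    for keys, grp in table.groupby(list(group_by), observed=True, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        n = len(grp)
        g_vals, m_vals = grp[gonad_col].to_numpy(), grp[muscle_col].to_numpy()
        if n < 3 or np.ptp(g_vals) == 0 or np.ptp(m_vals) == 0:
            rho, p, flagged = np.nan, np.nan, True
        else:
            rho, p = stats.spearmanr(g_vals, m_vals)
            flagged = False
        rows.append(dict(zip(group_by, keys)) | {"rho": rho, "p_value": p, "n": n, "flagged": flagged})
    return pd.DataFrame(rows)


def terminal_window_summary(
    traj: SlopeTrajectory, params: ModelParameters, window: int = 60, year: int = 1
) -> dict:
    """Aggregate the reported slopes over the last ``window`` pre-spawn days.

    Returns the number of reported days, the majority slope sign (+1, -1,
    or 0 when nothing is reported), and the mean reported slope.
    """
    df = traj.results
    sel = df[(df["year"] == year) & (df["day"] > params.d_s - window) & df["reported"]]
    slopes = sel["slope"].to_numpy()
    if slopes.size == 0:
        sign = 0
    else:
        sign = int(np.sign(np.median(np.sign(slopes))))
    return {
        "n_reported": int(slopes.size),
        "sign": sign,
        "mean_slope": float(np.mean(slopes)) if slopes.size else np.nan,
        "n_positive": int(np.sum(slopes > 0)),
        "n_negative": int(np.sum(slopes < 0)),
    }


def classify_slope_signal(
    traj: SlopeTrajectory, min_days: int = 10, year: int = 1
) -> dict:
    """Classify a season's slope trajectory as a correlation signal.

    A usable early-warning signal must be *sustained*: single days passing
    the R^2 rule during an abrupt allocation switch wash out within days
    and would never be sampled reliably in the field.  A sign is detected
    when at least ``min_days`` reported days carry it over the season.
    ``label`` is one of ``none``, ``positive``, ``negative``, ``mixed``.
    """
    df = traj.results
    rep = df[(df["year"] == year) & df["reported"]]
    n_pos = int((rep["slope"] > 0).sum())
    n_neg = int((rep["slope"] < 0).sum())
    pos, neg = n_pos >= min_days, n_neg >= min_days
    label = {(False, False): "none", (True, False): "positive",
             (False, True): "negative", (True, True): "mixed"}[(pos, neg)]
    return {
        "n_reported": int(len(rep)),
        "positive_days": n_pos,
        "negative_days": n_neg,
        "label": label,
    }


def scenario_sweep(
    base_params: ModelParameters,
    grid: Mapping[str, Sequence],
    seeds: Sequence[int] = (0,),
    n_years: int = 1,
    window: int = 60,
) -> pd.DataFrame:
    """Optimize, simulate, and summarize every parameter combination.

    ``grid`` maps parameter names to value lists; the Cartesian product is
    swept.  The policy is computed once per combination and reused across
    seeds.  Individual scenario failures are recorded (``error`` column)
    and the sweep continues.
    """
    from .optimizer import optimize_policy
    from .simulate import simulate_population

    names = list(grid)
    rows = []
    for combo in itertools.product(*(grid[n] for n in names)):
        overrides = dict(zip(names, combo))
        label = ",".join(f"{k}={v}" for k, v in overrides.items())
        try:
            params = base_params.replace(**overrides)
            policy = optimize_policy(params)
            for seed in seeds:
                sim = simulate_population(policy, params, seed=seed, n_years=n_years)
                traj = slope_trajectory(sim, params, scenario=label)
                summary = terminal_window_summary(traj, params, window=window)
                rows.append({**overrides, "seed": seed, "error": "", **summary})
        except Exception as exc:  # noqa: BLE001 - sweep must survive bad cells
            rows.append({**overrides, "seed": np.nan, "error": str(exc)})
    return pd.DataFrame(rows)
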