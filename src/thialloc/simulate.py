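"""Forward Monte-Carlo simulation of a population following the policy.

N females all start at (c_g_init, c_m_init) and each day draw an
independent blood thiamine level from the beta input distribution, look up
their allocation fraction by bilinear interpolation of the optimal policy
at their current state, and apply the daily tissue update.  On the
spawning day the pre-reset state is recorded, the gonadal thiamine leaves
with the eggs (c_g resets to 0), and iteroparous females continue into the
next year.

Mortality is not applied as removal: survival shapes the policy through
the optimizer, but the correlation analysis needs the full panel of
trajectories.  An optional flag draws the daily survival lottery and
records each female's death day for demographic output; her state tracking
still continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import physiology as phys
from .life_history import build_trajectory
from .optimizer import AllocationPolicy, expected_recruits
from .params import ModelParameters

__all__ = ["PopulationTimeSeries", "draw_daily_input", "simulate_population"]


def draw_daily_input(
    rng: np.random.Generator, params: ModelParameters, size: int = 1, day: int | None = None
) -> np.ndarray:
    """Sample the daily blood thiamine level for ``size`` females.

    Beta(beta_shape) mapped affinely onto
    [c_b_mean - c_b_halfwidth, c_b_mean + c_b_halfwidth]; identically zero
    on days inside the pre-spawning starvation window.
    """
    if day is not None and params.starvation_days > 0 and day > params.d_s - params.starvation_days:
        return np.zeros(size)
    if params.c_b_halfwidth == 0:
        return np.full(size, params.c_b_mean)
    a, b = params.beta_shape
    x = rng.beta(a, b, size=size)
    return params.c_b_mean - params.c_b_halfwidth + 2 * params.c_b_halfwidth * x


@dataclass
class PopulationTimeSeries:
    """Per-day state panel of the simulated population.

    Daily arrays are indexed ``[year-1, day-1, female]``; spawn arrays
    ``[year-1, female]``.  ``spawn_recruits`` is r(c_g) * w_g at spawning
    (the recruit output conditional on survival to that day).
    """

    c_g: np.ndarray
    c_m: np.ndarray
    alpha: np.ndarray
    c_b: np.ndarray
    spawn_c_g: np.ndarray
    spawn_c_m: np.ndarray
    spawn_w_g: np.ndarray
    spawn_recruits: np.ndarray
    params: ModelParameters
    seed: int
    counters: dict = field(default_factory=dict)
    death_year: np.ndarray | None = None

    @property
    def n_years(self) -> int:
        return self.c_g.shape[0]

    @property
    def n_females(self) -> int:
        return self.c_g.shape[2]

    def snapshot(self, year: int, day: int) -> tuple[np.ndarray, np.ndarray]:
        """(c_g, c_m) pairs across the population on one calendar day."""
        return (
            np.asarray(self.c_g[year - 1, day - 1], dtype=float),
            np.asarray(self.c_m[year - 1, day - 1], dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        ny, nd, nf = self.c_g.shape
        years, days, females = np.indices((ny, nd, nf))
        return pd.DataFrame(
            {
                "female_id": females.ravel(),
                "year": years.ravel() + 1,
                "day": days.ravel() + 1,
                "c_g": self.c_g.ravel(),
                "c_m": self.c_m.ravel(),
                "alpha": self.alpha.ravel(),
                "c_b": self.c_b.ravel(),
            }
        )

    def spawn_table(self) -> pd.DataFrame:
        ny, nf = self.spawn_c_g.shape
        years, females = np.indices((ny, nf))
        return pd.DataFrame(
            {
                "female_id": females.ravel(),
                "year": years.ravel() + 1,
                "spawn_c_g": self.spawn_c_g.ravel(),
                "spawn_c_m": self.spawn_c_m.ravel(),
                "spawn_w_g": self.spawn_w_g.ravel(),
                "spawn_recruits": self.spawn_recruits.ravel(),
            }
        )


def _interp_policy(alpha_day: np.ndarray, c_grid: np.ndarray, c_g: np.ndarray, c_m: np.ndarray):
    """Bilinear interpolation of one day's alpha surface at female states."""
    step = c_grid[1] - c_grid[0] if len(c_grid) > 1 else 1.0
    xg = np.clip(c_g, c_grid[0], c_grid[-1]) / step
    xm = np.clip(c_m, c_grid[0], c_grid[-1]) / step
    ig = np.minimum(xg.astype(np.int64), len(c_grid) - 2)
    im = np.minimum(xm.astype(np.int64), len(c_grid) - 2)
    fg, fm = xg - ig, xm - im
    a = (
        alpha_day[ig, im] * (1 - fg) * (1 - fm)
        + alpha_day[ig + 1, im] * fg * (1 - fm)
        + alpha_day[ig, im + 1] * (1 - fg) * fm
        + alpha_day[ig + 1, im + 1] * fg * fm
    )
    return np.clip(a, 0.0, 1.0)


def simulate_population(
    policy: AllocationPolicy,
    params: ModelParameters | None = None,
    seed: int | None = None,
    n_years: int | None = None,
    track_mortality: bool = False,
) -> PopulationTimeSeries:
    """Simulate N females following the optimal policy under stochastic input.

    Runs are reproducible bit-for-bit given (seed, params, policy).  For
    iteroparous females ``n_years`` defaults to the policy horizon;
    semelparous runs stop after the first spawning.
    """
    if params is None:
        params = policy.params
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    trajectory = build_trajectory(params)

    n_days = params.d_s
    if params.reproductive_mode == "semelparous":
        n_years = 1
    elif n_years is None:
        n_years = policy.n_years
    n = params.N

    shape = (n_years, n_days, n)
    out = {k: np.zeros(shape, dtype=np.float32) for k in ("c_g", "c_m", "alpha", "c_b")}
    spawn = {k: np.zeros((n_years, n), dtype=np.float32) for k in
             ("spawn_c_g", "spawn_c_m", "spawn_w_g", "spawn_recruits")}
    counters: dict = {}
    alive = np.ones(n, dtype=bool)
    death_year = np.zeros(n, dtype=np.int32) if track_mortality else None

    c_g = np.full(n, float(params.c_g_init))
    c_m = np.full(n, float(params.c_m_init))
    for yi in range(n_years):
        pol_year = min(yi, policy.n_years - 1)
        for d in range(n_days):
            out["c_g"][yi, d] = c_g
            out["c_m"][yi, d] = c_m
            day = d + 1
            if day == n_days:  # spawning day: record output, eggs leave, no update
                w_g_spawn = trajectory.w_g[yi, d]
                spawn["spawn_c_g"][yi] = c_g
                spawn["spawn_c_m"][yi] = c_m
                spawn["spawn_w_g"][yi] = w_g_spawn
                spawn["spawn_recruits"][yi] = expected_recruits(c_g, w_g_spawn, 1.0, params)
                c_g = np.zeros(n)
                continue
            c_b = draw_daily_input(rng, params, size=n, day=day)
            alpha = _interp_policy(
                np.asarray(policy.alpha[pol_year, d], dtype=float), policy.c_grid, c_g, c_m
            )
            out["alpha"][yi, d] = alpha
            out["c_b"][yi, d] = c_b
            if track_mortality:
                p = phys.daily_survival(c_m, params)
                died = alive & (rng.random(n) >= p)
                if death_year is not None:
                    death_year[died] = yi + 1
                alive &= ~died
            state = phys.daily_update(
                phys.TissueState(c_g, c_m), alpha, c_b,
                trajectory.w_g[yi, d], trajectory.w_m[yi, d], trajectory.w_b[yi, d],
                trajectory.w_g[yi, d + 1], trajectory.w_m[yi, d + 1],
                params, counters,
            )
            c_g, c_m = np.asarray(state.c_g), np.asarray(state.c_m)

    return PopulationTimeSeries(
        c_g=out["c_g"], c_m=out["c_m"], alpha=out["alpha"], c_b=out["c_b"],
        spawn_c_g=spawn["spawn_c_g"], spawn_c_m=spawn["spawn_c_m"],
        spawn_w_g=spawn["spawn_w_g"], spawn_recruits=spawn["spawn_recruits"],
        params=params, seed=seed, counters=counters, death_year=death_year,
    )
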