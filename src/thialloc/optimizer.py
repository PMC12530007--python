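"""Backward optimization of the state-dependent allocation strategy.

The decision variable is the daily fraction alpha(d, i, c_g, c_m) of the
blood free-thiamine pool allocated to muscles (1 - alpha goes to gonads).
Fitness is the expected lifetime production of recruits

    V = R_1 + sum_{i>=2} (chained p_f) * R_i,

where the recruit output of year i is R_i = r(c_g at spawning) * w_g(d_s, i)
times the within-year product of daily survivals, and p_f is the
post-spawning migration survival.  The policy is found by dynamic
programming on a regular (c_g, c_m) grid:

* within a year, for d < d_s:
      V(d, s) = p(c_m) * max_alpha E_{c_b}[ V(d+1, step(s, alpha, c_b)) ]
  with the expectation over the stochastic blood level taken on
  equal-weight quantile nodes of the beta input distribution, and off-grid
  next states evaluated by bilinear interpolation of the value surface;
* on the spawning day,
      V(d_s, s) = r(c_g) * w_g(d_s, i) + p_f(c_m) * V(1, i+1, (0, c_m))
  for iteroparous females before year i_max (gonads reset when the eggs
  leave), and V(d_s, s) = r(c_g) * w_g(d_s, i) at the horizon or for
  semelparous females.

Because the daily survival p multiplies the recursion each day, the
within-year survival product of the recruit formula emerges over days
1..d_s-1; the spawning-day value is the terminal reward itself.

Ties between allocation levels are broken toward the smaller alpha.  The
gonad and muscle transitions each depend on only their own concentration,
so a day's expected value on the full grid reduces to two 1-D interpolation
stencils applied to the rows and columns of the next day's value surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from . import physiology as phys
from .life_history import TissueTrajectory, build_trajectory
from .params import ModelParameters

__all__ = ["AllocationPolicy", "expected_recruits", "input_nodes", "optimize_policy"]


@dataclass
class AllocationPolicy:
    """Optimal allocation fraction and fitness-to-go on the state grid.

    Arrays are indexed ``[year-1, day-1, i_cg, i_cm]`` with day in 1..d_s.
    ``value`` is the expected future recruit production at the start of the
    day, before that day's survival lottery has resolved for d < d_s and
    equal to the spawning reward (plus discounted continuation) at d_s.
    """

    alpha: np.ndarray
    value: np.ndarray
    c_grid: np.ndarray
    alpha_grid: np.ndarray
    params: ModelParameters

    @property
    def n_years(self) -> int:
        return self.alpha.shape[0]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path,
            alpha=self.alpha,
            value=self.value,
            c_grid=self.c_grid,
            alpha_grid=self.alpha_grid,
            params=json.dumps(self.params.to_dict()),
        )

    @classmethod
    def load(cls, path: str | Path) -> "AllocationPolicy":
        with np.load(path, allow_pickle=False) as z:
            params = ModelParameters.from_dict(json.loads(str(z["params"])))
            return cls(
                alpha=z["alpha"], value=z["value"],
                c_grid=z["c_grid"], alpha_grid=z["alpha_grid"], params=params,
            )


def expected_recruits(c_g_at_spawn, w_g_at_spawn, survival_product, params: ModelParameters):
    """Recruit output of one spawning: r(c_g) * gonad mass * survival to spawn."""
    if params.recruits_use_raw_concentration:
        weight = np.asarray(c_g_at_spawn, dtype=float)
    else:
        weight = phys.recruitment_probability(c_g_at_spawn, params)
    return weight * w_g_at_spawn * survival_product


def input_nodes(params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """Equal-weight quantile nodes of the daily blood-level distribution.

    The beta-distributed input on [c_b_mean - hw, c_b_mean + hw] is
    discretized at the quantile midpoints (2j+1)/(2Q); with one node or a
    degenerate distribution the mean is used.
    """
    q = params.grid.n_input_nodes
    if params.c_b_halfwidth == 0 or q == 1:
        return np.array([params.c_b_mean]), np.array([1.0])
    a, b = params.beta_shape
    probs = (np.arange(q) + 0.5) / q
    x = stats.beta.ppf(probs, a, b)
    vals = params.c_b_mean - params.c_b_halfwidth + 2 * params.c_b_halfwidth * x
    return vals, np.full(q, 1.0 / q)


def _interp_stencil(c_next: np.ndarray, c_grid: np.ndarray):
    step = c_grid[1] - c_grid[0] if len(c_grid) > 1 else 1.0
    x = np.clip(c_next, c_grid[0], c_grid[-1]) / step
    idx = np.minimum(x.astype(np.int64), len(c_grid) - 2)
    idx = np.maximum(idx, 0)
    return idx, x - idx


def optimize_policy(
    params: ModelParameters, trajectory: TissueTrajectory | None = None
) -> AllocationPolicy:
    """Compute the optimal allocation policy by backward induction.

    For semelparous females only the first year matters (the line ends at
    the first spawning), so a single year is computed.
    """
    if trajectory is None:
        trajectory = build_trajectory(params)

    n_days = params.d_s
    n_years = 1 if params.reproductive_mode == "semelparous" else params.i_max
    c_grid = np.arange(0.0, params.c_x + params.grid.c_step / 2, params.grid.c_step)
    n_c = len(c_grid)
    alpha_grid = np.arange(0.0, 1.0 + params.grid.alpha_step / 2, params.grid.alpha_step)
    alpha_grid = np.minimum(alpha_grid, 1.0)
    n_a = len(alpha_grid)

    cb_nodes, cb_weights = input_nodes(params)
    starv_start = n_days - params.starvation_days  # input is zero for day > starv_start

    p_vec = phys.daily_survival(c_grid, params)  # day-independent, over c_m
    pf_vec = phys.migration_survival(c_grid, params)
    reward_weight = (
        c_grid.copy()
        if params.recruits_use_raw_concentration
        else phys.recruitment_probability(c_grid, params)
    )
    iteroparous = params.reproductive_mode == "iteroparous"

    alpha_out = np.zeros((n_years, n_days, n_c, n_c), dtype=np.float32)
    value_out = np.zeros((n_years, n_days, n_c, n_c), dtype=np.float32)

    v_next_year_day1: np.ndarray | None = None  # V(1, i+1, ., .)
    for yi in range(n_years - 1, -1, -1):
        # spawning day: terminal reward plus migration-discounted continuation
        v_day = reward_weight[:, None] * trajectory.w_g[yi, n_days - 1]
        v_day = np.broadcast_to(v_day, (n_c, n_c)).copy()
        if iteroparous and v_next_year_day1 is not None:
            # post-spawn state is (c_g = 0, c_m unchanged)
            v_day = v_day + pf_vec[None, :] * v_next_year_day1[0, :][None, :]
        value_out[yi, n_days - 1] = v_day
        alpha_out[yi, n_days - 1] = 0.0

        for d in range(n_days - 2, -1, -1):  # day index d -> day number d+1
            w_g_t, w_m_t, w_b_t = (
                trajectory.w_g[yi, d], trajectory.w_m[yi, d], trajectory.w_b[yi, d],
            )
            w_g_n, w_m_n = trajectory.w_g[yi, d + 1], trajectory.w_m[yi, d + 1]
            if d + 1 > starv_start:
                nodes, weights = np.array([0.0]), np.array([1.0])
            else:
                nodes, weights = cb_nodes, cb_weights

            # batch every (alpha, input-node) pair; both transitions are
            # separable in their own concentration, so one day's expected
            # value is two 1-D interpolation stencils on the value surface
            n_q = len(nodes)
            a_b = np.repeat(alpha_grid, n_q)[:, None]
            cb_b = np.tile(nodes, n_a)[:, None]
            cg_next = phys.gonad_step(c_grid[None, :], a_b, cb_b, w_g_t, w_b_t, w_g_n, params)
            cm_next = phys.muscle_step(c_grid[None, :], a_b, cb_b, w_m_t, w_b_t, w_m_n, params)
            ig, fg = _interp_stencil(cg_next, c_grid)
            im, fm = _interp_stencil(cm_next, c_grid)
            vg = v_day[ig, :] * (1.0 - fg)[..., None] + v_day[ig + 1, :] * fg[..., None]
            v = (
                np.take_along_axis(vg, im[:, None, :], axis=2) * (1.0 - fm)[:, None, :]
                + np.take_along_axis(vg, im[:, None, :] + 1, axis=2) * fm[:, None, :]
            )
            cand = np.einsum(
                "q,aqgm->agm", weights, v.reshape(n_a, n_q, n_c, n_c)
            )
            best = np.argmax(cand, axis=0)  # first max -> smallest alpha on ties
            v_day = p_vec[None, :] * np.take_along_axis(cand, best[None], axis=0)[0]
            if not np.all(np.isfinite(v_day)):
                bad = np.argwhere(~np.isfinite(v_day))[0]
                raise FloatingPointError(
                    f"non-finite value at year {yi + 1}, day {d + 1}, state index {tuple(bad)}"
                )
            alpha_out[yi, d] = alpha_grid[best]
            value_out[yi, d] = v_day

        v_next_year_day1 = v_day

    return AllocationPolicy(
        alpha=alpha_out, value=value_out, c_grid=c_grid, alpha_grid=alpha_grid, params=params
    )
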