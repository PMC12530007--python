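"""Brute-force enumeration oracle for tiny allocation problems.

Instances are constructed so every daily update lands exactly on state-grid
nodes (unit masses, zero loss, inputs and allocation levels in half-unit
steps), which makes backward induction interpolation-free and therefore
exactly comparable to exhaustive enumeration of all allocation sequences.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from thialloc import ModelParameters
from thialloc import physiology as phys
from thialloc.life_history import TissueTrajectory

ALPHA_LEVELS = (0.0, 0.5, 1.0)


def tiny_params(rng: np.random.Generator, n_days: int | None = None,
                n_years: int = 1) -> ModelParameters:
    """Random tiny problem: <= 4 days, 6x6 state grid, deterministic input."""
    T = int(rng.integers(2, 5)) if n_days is None else n_days
    amin = float(rng.uniform(0.01, 0.2))
    amax = float(rng.uniform(amin, 0.9))
    return ModelParameters(
        c_x=2.5,
        k_x_g=0.0,
        k_x_m=0.0,
        q_m=1.0,
        annual_survival_min=amin,
        annual_survival_max=amax,
        u=float(rng.uniform(0.05, 2.0)),
        v=float(rng.uniform(0.05, 2.0)),
        l=float(rng.uniform(0.05, 1.0)),
        excretion_model="linear",
        c_b_mean=float(rng.choice([1.0, 2.0])),
        c_b_halfwidth=0.0,
        days_per_year=T,
        d_s=T,
        i_max=n_years,
        reproductive_mode="semelparous" if n_years == 1 else "iteroparous",
        growth=dict(gonad_buildup_days=1),
        grid=dict(c_step=0.5, alpha_step=0.5, n_input_nodes=1),
        N=1,
        c_g_init=0.0,
        c_m_init=0.0,
    )


def unit_trajectory(params: ModelParameters) -> TissueTrajectory:
    """All tissue masses pinned to 1 g (grid-aligned dynamics)."""
    shape = (params.i_max, params.d_s)
    ones = np.ones(shape)
    return TissueTrajectory(
        w_m=ones.copy(), w_g=ones.copy(), w_b=ones.copy(),
        days_per_year=params.days_per_year, spawn_day=params.d_s,
    )


def _step(g: float, m: float, alpha: float, params: ModelParameters):
    g2 = float(phys.gonad_step(g, alpha, params.c_b_mean, 1.0, 1.0, 1.0, params))
    m2 = float(phys.muscle_step(m, alpha, params.c_b_mean, 1.0, 1.0, 1.0, params))
    return g2, m2


def _year_outcomes(params: ModelParameters, g0: float, m0: float):
    """Enumerate one year's alpha sequences.

    Yields (survival product over days 1..d_s-1, c_g at d_s, c_m at d_s).
    """
    T = params.d_s
    for seq in product(ALPHA_LEVELS, repeat=T - 1):
        g, m = g0, m0
        surv = 1.0
        for alpha in seq:
            surv *= float(phys.daily_survival(m, params))
            g, m = _step(g, m, alpha, params)
        yield surv, g, m


def enumerate_semelparous(params: ModelParameters, g0: float, m0: float) -> float:
    """Best fitness over all single-year allocation sequences."""
    best = -np.inf
    for surv, g, m in _year_outcomes(params, g0, m0):
        reward = float(phys.recruitment_probability(g, params))  # w_g = 1
        best = max(best, surv * reward)
    return best


def enumerate_two_year(params: ModelParameters, g0: float, m0: float) -> float:
    """Best fitness for a 2-year iteroparous female (migration-survival chain)."""
    assert params.i_max == 2
    best = -np.inf
    second_year_best: dict[float, float] = {}
    for surv1, g1, m1 in _year_outcomes(params, g0, m0):
        if m1 not in second_year_best:
            second_year_best[m1] = enumerate_semelparous(params, 0.0, m1)
        pf = float(phys.migration_survival(m1, params))
        r1 = float(phys.recruitment_probability(g1, params))
        best = max(best, surv1 * (r1 + pf * second_year_best[m1]))
    return best
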