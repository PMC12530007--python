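"""Concentration-dependent rates, probabilities, and the daily tissue update.

The state of a female is the pair (c_g, c_m): free thiamine concentration
in the gonads and TDP concentration in the muscles, both in nmol/g and
clamped to the tissue ceiling c_x.

Response functions
------------------
* recruitment probability  r(c_g) = (c_g / c_x) ** v
* daily adult survival     p(c_m) = p0 + (px - p0) * (c_m / c_x) ** u
* post-spawning migration  p_f(c_m) = (c_m / c_x) ** l
* loss rate k(c): either a sigmoid in concentration (renal reabsorption
  switching to active secretion), a reabsorption power law joined
  continuously to linear passive transport at a threshold c_t, or a plain
  linear law.

Daily update
------------
Each day the whole free-thiamine pool of the blood, c_b * w_b nmol, is
split by the allocation fraction alpha: a share alpha goes to the muscles
(converted to TDP with efficiency q_m) and 1 - alpha to the gonads.  Losses
are k(c) * w per tissue.  The balance is kept in amounts (nmol), floored at
zero (loss cannot exceed content), and converted back to concentration with
the next day's tissue mass, so growth dilutes; concentrations clamp at c_x
and the surplus is discarded.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .params import ModelParameters

__all__ = [
    "TissueState",
    "recruitment_probability",
    "daily_survival",
    "migration_survival",
    "loss_rate_sigmoid",
    "loss_rate_reabsorption",
    "loss_rate_linear",
    "loss_rate",
    "gonad_step",
    "muscle_step",
    "daily_update",
]


class TissueState(NamedTuple):
    c_g: np.ndarray | float
    c_m: np.ndarray | float


def _check_conc(c, c_x: float, name: str):
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError(f"{name} must be non-negative")
    if np.any(c > c_x + 1e-9):
        raise ValueError(f"{name} exceeds the ceiling c_x={c_x}")
    return c


def recruitment_probability(c_g, params: ModelParameters):
    """Probability that spawned offspring recruit, r = (c_g/c_x)**v."""
    c_g = _check_conc(c_g, params.c_x, "c_g")
    return (c_g / params.c_x) ** params.v


def daily_survival(c_m, params: ModelParameters):
    """Daily adult survival, p = p0 + (px - p0)*(c_m/c_x)**u."""
    c_m = _check_conc(c_m, params.c_x, "c_m")
    return params.p0 + (params.px - params.p0) * (c_m / params.c_x) ** params.u


def migration_survival(c_m, params: ModelParameters):
    """Probability of surviving the post-spawning migration, (c_m/c_x)**l."""
    c_m = _check_conc(c_m, params.c_x, "c_m")
    return (c_m / params.c_x) ** params.l


def loss_rate_sigmoid(c, k_x: float, c_x: float, b: float):
    """Sigmoidal loss rate: reabsorption at low c, active secretion at high c.

    k = k_x * [ ((b-1)/(b+1)) * b**((0.5*c_x - c)/(0.5*c_x)) + 1 ]**-1,
    which rises from ~0 at c = 0 through k_x*(b+1)/(2b) at the half-ceiling
    to ~k_x at the ceiling, approaching a step function as b grows.
    """
    if b <= 1:
        raise ValueError(f"sigmoid shape b must be > 1, got {b}")
    c = np.asarray(c, dtype=float)
    half = 0.5 * c_x
    return k_x / ((b - 1.0) / (b + 1.0) * b ** ((half - c) / half) + 1.0)


def loss_rate_reabsorption(c, k_x: float, c_x: float, b_c: float, c_t: float, a: float):
    """Reabsorption power law below c_t, linear passive transport above.

    k = a * c**b_c for c < c_t and k = k_x * c / c_x above, with ``a``
    derived so the branches meet continuously at the threshold.
    """
    expected_a = k_x * c_t / (c_x * c_t**b_c)
    if not np.isclose(a, expected_a, rtol=1e-9, atol=0.0):
        raise ValueError(
            f"reabsorption coefficient a={a} does not make the loss curve "
            f"continuous at c_t={c_t} (expected {expected_a})"
        )
    c = np.asarray(c, dtype=float)
    return np.where(c < c_t, a * c**b_c, k_x * c / c_x)


def loss_rate_linear(c, k_x: float, c_x: float):
    """Loss rate strictly proportional to concentration, k = k_x*c/c_x."""
    return k_x * np.asarray(c, dtype=float) / c_x


def loss_rate(c, k_x: float, a: float, params: ModelParameters):
    """Dispatch on the configured excretion model."""
    if params.excretion_model == "sigmoid":
        return loss_rate_sigmoid(c, k_x, params.c_x, params.b)
    if params.excretion_model == "reabsorption_passive":
        return loss_rate_reabsorption(c, k_x, params.c_x, params.b_c, params.c_t, a)
    return loss_rate_linear(c, k_x, params.c_x)


def _amount_to_conc(amount, w_next, c_x: float, counters: dict | None, key: str):
    amount = np.asarray(amount, dtype=float)
    floored = amount < 0
    amount = np.where(floored, 0.0, amount)
    c = amount / w_next
    clamped = c > c_x
    c = np.where(clamped, c_x, c)
    if counters is not None:
        counters[f"{key}_floored"] = counters.get(f"{key}_floored", 0) + int(np.sum(floored))
        counters[f"{key}_clamped"] = counters.get(f"{key}_clamped", 0) + int(np.sum(clamped))
    return c


def gonad_step(
    c_g, alpha, c_b, w_g_today, w_b_today, w_g_next,
    params: ModelParameters, counters: dict | None = None,
):
    """One-day gonad concentration update (amount balance, then dilution)."""
    k_g = loss_rate(c_g, params.k_x_g, params.a_g, params)
    amount = (
        np.asarray(c_g, dtype=float) * w_g_today
        + (1.0 - np.asarray(alpha, dtype=float)) * np.asarray(c_b) * w_b_today
        - k_g * w_g_today
    )
    return _amount_to_conc(amount, w_g_next, params.c_x, counters, "gonad")


def muscle_step(
    c_m, alpha, c_b, w_m_today, w_b_today, w_m_next,
    params: ModelParameters, counters: dict | None = None,
):
    """One-day muscle TDP update; inflow is converted with efficiency q_m."""
    k_m = loss_rate(c_m, params.k_x_m, params.a_m, params)
    amount = (
        np.asarray(c_m, dtype=float) * w_m_today
        + params.q_m * np.asarray(alpha, dtype=float) * np.asarray(c_b) * w_b_today
        - k_m * w_m_today
    )
    return _amount_to_conc(amount, w_m_next, params.c_x, counters, "muscle")


def daily_update(
    state: TissueState,
    alpha,
    c_b,
    w_g_today, w_m_today, w_b_today,
    w_g_next, w_m_next,
    params: ModelParameters,
    counters: dict | None = None,
) -> TissueState:
    """Explicit one-day Euler step of both tissue concentrations.

    Inflow and losses are evaluated at the start-of-day state; the updated
    amounts are divided by the next day's tissue masses.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha must lie in [0, 1]")
    if np.any(np.asarray(c_b, dtype=float) < 0):
        raise ValueError("c_b must be non-negative")
    c_g = gonad_step(state.c_g, alpha, c_b, w_g_today, w_b_today, w_g_next, params, counters)
    c_m = muscle_step(state.c_m, alpha, c_b, w_m_today, w_b_today, w_m_next, params, counters)
    return TissueState(c_g=c_g, c_m=c_m)
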