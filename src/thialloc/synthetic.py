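"""Synthetic tissue-measurement tables (stand-in for field data).

Generates per-female total-thiamine concentrations in muscle and gonad for
two contrasting systems — a thiamine-limited one (low input) and a replete
one (high input) — sampled at four migration stages (feeding area, river
mouth, upstream, spawning grounds), with rivers assigned round-robin and
multiplicative lognormal measurement noise.  The values come from running
the full optimize + simulate pipeline under each system's parameters, so
the tables are synthetic but mechanistically generated; they emulate the
*structure* of empirical salmon tissue datasets, not any published values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .optimizer import optimize_policy
from .params import ModelParameters
from .simulate import simulate_population

__all__ = ["STAGES", "default_stage_days", "generate_tissue_dataset"]

STAGES = ("feeding", "river_mouth", "upstream", "spawning")

LIMITED_RIVERS = ("Torne", "Lulea", "Umea")
REPLETE_RIVERS = ("Drammen", "Driva", "Atran", "Enningdal")


def default_stage_days(params: ModelParameters) -> dict[str, int]:
    """Sampling day per stage: ~6, 3, 1 months before spawning, and d_s."""
    d_s = params.d_s
    return {
        "feeding": max(1, d_s - 180),
        "river_mouth": max(1, d_s - 90),
        "upstream": max(1, d_s - 30),
        "spawning": d_s,
    }


def generate_tissue_dataset(
    params_limited: ModelParameters,
    params_replete: ModelParameters,
    n_per_stage: int = 25,
    stage_days: dict[str, int] | None = None,
    noise_cv: float = 0.10,
    seed: int = 0,
    policies: tuple | None = None,
) -> pd.DataFrame:
    """Build a two-system tissue table by running the model end to end.

    Each system's policy is optimized under its own parameters and a
    population simulated for the pre-spawning year; ``n_per_stage``
    distinct females are sampled at each stage's calendar day.  Muscle and
    gonad concentrations get independent multiplicative lognormal noise of
    coefficient of variation ``noise_cv`` (0 disables noise).  The output
    schema matches the analysis module's empirical-table contract:
    system, river, stage, female_id, muscle_total_thiamine,
    gonad_total_thiamine.

    ``policies`` optionally supplies precomputed (limited, replete)
    allocation policies so repeated draws skip the optimization step.
    """
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv**2))) if noise_cv > 0 else 0.0
    frames = []
    for sys_idx, (system, params, rivers) in enumerate(
        (
            ("limited", params_limited, LIMITED_RIVERS),
            ("replete", params_replete, REPLETE_RIVERS),
        )
    ):
        days = stage_days or default_stage_days(params)
        missing = set(STAGES) - set(days)
        if missing:
            raise ValueError(f"stage_days missing stages: {sorted(missing)}")
        bad = {s: d for s, d in days.items() if not (1 <= d <= params.d_s)}
        if bad:
            raise ValueError(f"stage days outside the simulated calendar: {bad}")
        policy = policies[sys_idx] if policies is not None else optimize_policy(params)
        sim = simulate_population(
            policy, params, seed=int(rng.integers(2**31)), n_years=1
        )
        if n_per_stage > sim.n_females:
            raise ValueError("n_per_stage exceeds the simulated population size")
        for stage in STAGES:
            g, m = sim.snapshot(1, days[stage])
            chosen = rng.choice(sim.n_females, size=n_per_stage, replace=False)
            g, m = g[chosen], m[chosen]
            if sigma > 0:
                g = g * rng.lognormal(-0.5 * sigma**2, sigma, n_per_stage)
                m = m * rng.lognormal(-0.5 * sigma**2, sigma, n_per_stage)
            frames.append(
                pd.DataFrame(
                    {
                        "system": system,
                        "river": [rivers[i % len(rivers)] for i in range(n_per_stage)],
                        "stage": stage,
                        "female_id": chosen,
                        "muscle_total_thiamine": m,
                        "gonad_total_thiamine": g,
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    df["stage"] = pd.Categorical(df["stage"], categories=list(STAGES), ordered=True)
    return df
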