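"""Deterministic tissue-mass trajectories over the female's life.

The female is followed from one year before her first spawning.  Within
each year, days run 1..d_s (spawning day); the year transition happens at
spawning, so the trajectory arrays cover exactly those days.  Somatic
(muscle) mass follows a saturating growth curve in cumulative time, blood
mass is a fixed fraction of somatic mass, and gonads ramp linearly over the
final ``gonad_buildup_days`` of each year to the gonadosomatic-index peak
at spawning, after which eggs are released over one day and gonad mass
resets to a small epsilon mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParameters

__all__ = ["TissueTrajectory", "build_trajectory"]


@dataclass
class TissueTrajectory:
    """Tissue masses (g) indexed ``[year-1, day-1]`` with day in 1..d_s."""

    w_m: np.ndarray
    w_g: np.ndarray
    w_b: np.ndarray
    days_per_year: int
    spawn_day: int

    @property
    def n_years(self) -> int:
        return self.w_m.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        years, days = np.indices(self.w_m.shape)
        return pd.DataFrame(
            {
                "year": years.ravel() + 1,
                "day": days.ravel() + 1,
                "w_m": self.w_m.ravel(),
                "w_g": self.w_g.ravel(),
                "w_b": self.w_b.ravel(),
            }
        )


def build_trajectory(params: ModelParameters) -> TissueTrajectory:
    """Deterministic masses for every (year, day) up to ``i_max`` years."""
    g = params.growth
    n_years, n_days = params.i_max, params.d_s

    # cumulative age in days at each (year, day); growth runs on the full
    # calendar even when d_s < days_per_year
    t = (
        np.arange(n_years)[:, None] * params.days_per_year
        + np.arange(1, n_days + 1)[None, :]
    ).astype(float)

    if g.growth_mode == "fixed":
        w_m = np.full((n_years, n_days), g.soma_initial_mass)
    else:
        w_m = g.soma_asymptotic_mass - (
            g.soma_asymptotic_mass - g.soma_initial_mass
        ) * np.exp(-g.soma_growth_rate * t)
    w_b = g.blood_fraction * w_m

    w_g = np.full((n_years, n_days), g.gonad_reset_mass)
    ramp_start = n_days - g.gonad_buildup_days  # day index of last pre-ramp day
    days = np.arange(1, n_days + 1)
    in_ramp = days > ramp_start
    frac = np.where(in_ramp, (days - ramp_start) / g.gonad_buildup_days, 0.0)
    peak = g.gonad_peak_fraction * w_m[:, -1]  # gonad mass at spawning, per year
    w_g = np.where(
        in_ramp[None, :],
        g.gonad_reset_mass + (peak[:, None] - g.gonad_reset_mass) * frac[None, :],
        w_g,
    )

    return TissueTrajectory(
        w_m=w_m, w_g=w_g, w_b=w_b, days_per_year=params.days_per_year, spawn_day=n_days
    )
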