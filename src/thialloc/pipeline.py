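"""One-call optimize -> simulate -> analyze convenience wrapper."""

from __future__ import annotations

from dataclasses import dataclass

from .analysis import SlopeTrajectory, slope_trajectory
from .optimizer import AllocationPolicy, optimize_policy
from .params import ModelParameters
from .simulate import PopulationTimeSeries, simulate_population

__all__ = ["ScenarioResult", "run_scenario"]


@dataclass
class ScenarioResult:
    params: ModelParameters
    policy: AllocationPolicy
    sim: PopulationTimeSeries
    slopes: SlopeTrajectory


def run_scenario(
    params: ModelParameters,
    seed: int | None = None,
    n_years: int = 1,
    policy: AllocationPolicy | None = None,
    scenario: str = "",
) -> ScenarioResult:
    """Optimize the policy (unless given), simulate, and fit daily slopes."""
    if policy is None:
        policy = optimize_policy(params)
    sim = simulate_population(policy, params, seed=seed, n_years=n_years)
    slopes = slope_trajectory(sim, params, scenario=scenario)
    return ScenarioResult(params=params, policy=policy, sim=sim, slopes=slopes)
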