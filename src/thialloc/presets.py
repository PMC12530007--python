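"""Named scenario presets.

The model's headline contrast is between a thiamine-limited system (mean
blood level c_b = 2 nmol/g, the "low input" scenario) and a replete system
(c_b = 6 nmol/g, "high input").  The baseline physiology uses the sigmoidal
excretion law (renal reabsorption at low concentration switching to active
secretion at high concentration, shape b = 200) with shallow survival and
recruitment exponents u = v = 0.025 (survival and recruitment saturate
quickly with concentration, as expected for an enzymatic cofactor).

``reabsorption_scenario`` configures the alternative loss law without
active secretion — a reabsorption power function below the threshold c_t
and passive linear transport above it — with the shallow fitness scalings
(u = v = 0.025) used when comparing against field data.

``desk_scale`` coarsens the numerical grids and shrinks the population so a
full optimize + simulate + analyze pass runs in seconds; the science
parameters are untouched.
"""

from __future__ import annotations

from .params import ModelParameters

__all__ = [
    "low_input_baseline",
    "high_input_baseline",
    "linear_excretion_scenario",
    "survival_recruitment_scenario",
    "reabsorption_scenario",
    "semelparous_scenario",
    "desk_scale",
]


def low_input_baseline(**overrides) -> ModelParameters:
    """Thiamine-limited system: sigmoid excretion, c_b_mean = 2 nmol/g."""
    base = dict(c_b_mean=2.0, excretion_model="sigmoid", b=200.0, u=0.025, v=0.025)
    base.update(overrides)
    return ModelParameters(**base)


def high_input_baseline(**overrides) -> ModelParameters:
    """Replete system: sigmoid excretion, c_b_mean = 6 nmol/g."""
    return low_input_baseline(c_b_mean=6.0, **overrides)


def linear_excretion_scenario(c_b_mean: float = 2.0, **overrides) -> ModelParameters:
    """Loss rate strictly proportional to concentration (passive only)."""
    return low_input_baseline(excretion_model="linear", c_b_mean=c_b_mean, **overrides)


def survival_recruitment_scenario(
    u: float, v: float, c_b_mean: float = 2.0, **overrides
) -> ModelParameters:
    """Sweep point over the survival (u) and recruitment (v) exponents, b = 200."""
    return low_input_baseline(u=u, v=v, b=200.0, c_b_mean=c_b_mean, **overrides)


def reabsorption_scenario(
    b_c: float = 3.0, c_t: float = 6.0, c_b_mean: float = 2.0, **overrides
) -> ModelParameters:
    """Reabsorption-only loss law (no active secretion), u = v = 0.025.

    The preset grid spans b_c in {3, 6} and c_t in {6, 10} nmol/g.
    """
    base = dict(
        excretion_model="reabsorption_passive",
        b_c=b_c,
        c_t=c_t,
        u=0.025,
        v=0.025,
        c_b_mean=c_b_mean,
    )
    base.update(overrides)
    return ModelParameters(**base)


def semelparous_scenario(c_b_mean: float = 2.0, **overrides) -> ModelParameters:
    """Single-spawning life history (dies after first reproduction)."""
    return low_input_baseline(
        reproductive_mode="semelparous", c_b_mean=c_b_mean, **overrides
    )


def desk_scale(params: ModelParameters, n: int = 500) -> ModelParameters:
    """Coarsen numerics for a fast end-to-end run (N females, coarse grids)."""
    return params.replace(
        N=n,
        grid=dict(c_step=0.5, alpha_step=0.1, n_input_nodes=3),
    )
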