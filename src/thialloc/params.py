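"""Model parameters, validation, and derived constants.

All concentrations are in nmol/g wet weight, masses in g, rates in
nmol/g/day, and time in days.  A model year has ``days_per_year`` days and
spawning happens on day ``d_s`` (by default the last day of the year); the
female is followed for up to ``i_max`` years, starting one year before her
first spawning.

Two constants are derived rather than set directly:

* ``p0`` and ``px`` — the daily survival probabilities at zero and at
  ceiling muscle thiamine — are obtained from the annual survival anchors
  (0.001 and 0.25 by default) via ``p^days_per_year = annual``.
* ``a_g``/``a_m`` — the reabsorption power-law coefficients — are fixed by
  requiring the power branch and the linear passive-transport branch of the
  loss curve to meet continuously at the threshold concentration ``c_t``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "GridParameters",
    "GrowthParameters",
    "ModelParameters",
    "ValidationError",
    "derive_daily_survival_bounds",
    "derive_reabsorption_coefficient",
    "load_config",
    "save_config",
]

EXCRETION_MODELS = ("sigmoid", "reabsorption_passive", "linear")
REPRODUCTIVE_MODES = ("iteroparous", "semelparous")
GROWTH_MODES = ("growing", "fixed")
VARIATION_MEASURES = ("range", "std")


class ValidationError(ValueError):
    """A parameter failed validation; the message names the field."""


def derive_daily_survival_bounds(
    annual_min: float, annual_max: float, days_per_year: int
) -> tuple[float, float]:
    """Convert annual survival anchors to daily probabilities.

    Solves ``p0**days_per_year == annual_min`` and
    ``px**days_per_year == annual_max`` exactly (via the exp/log closed
    form), so that a female held at the minimum muscle level survives a
    whole year with probability ``annual_min`` and one at the ceiling with
    probability ``annual_max``.
    """
    if not (0.0 < annual_min <= annual_max < 1.0):
        raise ValidationError(
            "annual survival anchors must satisfy 0 < annual_min <= annual_max < 1, "
            f"got ({annual_min}, {annual_max})"
        )
    if days_per_year < 1:
        raise ValidationError(f"days_per_year must be >= 1, got {days_per_year}")
    p0 = annual_min ** (1.0 / days_per_year)
    px = annual_max ** (1.0 / days_per_year)
    return p0, px


def derive_reabsorption_coefficient(
    c_t: float, k_x: float, c_x: float, b_c: float
) -> float:
    """Coefficient of the reabsorption power law, ``k = a * c**b_c``.

    Chosen so the power branch meets the linear passive-transport branch
    ``k = k_x * c / c_x`` continuously at the threshold ``c_t``:
    ``a * c_t**b_c = k_x * c_t / c_x``.
    """
    for name, val in (("c_t", c_t), ("k_x", k_x), ("c_x", c_x), ("b_c", b_c)):
        if val <= 0:
            raise ValidationError(f"{name} must be positive, got {val}")
    if c_t >= c_x:
        raise ValidationError(f"c_t must be below the ceiling c_x, got c_t={c_t}, c_x={c_x}")
    return k_x * c_t / (c_x * c_t**b_c)


@dataclass
class GridParameters:
    """Numerical discretization of the optimizer's state and action space.

    ``c_step`` is the resolution of the (c_g, c_m) state grid, ``alpha_step``
    the resolution of the allocation-fraction grid, and ``n_input_nodes``
    the number of equal-weight quantile nodes used to take the expectation
    over the stochastic daily blood level during backward induction.
    """

    c_step: float = 0.5
    alpha_step: float = 0.05
    n_input_nodes: int = 5

    def validate(self, c_x: float) -> None:
        if self.c_step <= 0:
            raise ValidationError(f"c_step must be positive, got {self.c_step}")
        n = c_x / self.c_step
        if abs(n - round(n)) > 1e-9:
            raise ValidationError(
                f"c_step={self.c_step} must divide the ceiling c_x={c_x} evenly"
            )
        if not (0 < self.alpha_step <= 1):
            raise ValidationError(f"alpha_step must be in (0, 1], got {self.alpha_step}")
        if self.n_input_nodes < 1:
            raise ValidationError(f"n_input_nodes must be >= 1, got {self.n_input_nodes}")


@dataclass
class GrowthParameters:
    """Tissue-mass trajectory parameters.

    Somatic (muscle) mass follows a saturating curve from
    ``soma_initial_mass`` toward ``soma_asymptotic_mass`` at rate
    ``soma_growth_rate`` (per day).  Gonads ramp linearly over the final
    ``gonad_buildup_days`` of each year to ``gonad_peak_fraction`` of the
    somatic mass at spawning (the gonadosomatic index), then reset to
    ``gonad_reset_mass`` when the eggs are released.  Blood mass is a fixed
    fraction of somatic mass.  ``growth_mode='fixed'`` freezes somatic and
    blood mass at their initial values (capital breeders that do not grow
    after maturation).
    """

    soma_initial_mass: float = 2000.0
    soma_asymptotic_mass: float = 9000.0
    soma_growth_rate: float = 8e-4
    gonad_peak_fraction: float = 0.20
    gonad_buildup_days: int = 120
    blood_fraction: float = 0.06
    gonad_reset_mass: float = 1.0
    growth_mode: str = "growing"

    def validate(self, days_per_year: int) -> None:
        for name in (
            "soma_initial_mass",
            "soma_asymptotic_mass",
            "soma_growth_rate",
            "gonad_peak_fraction",
            "blood_fraction",
            "gonad_reset_mass",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.gonad_peak_fraction >= 1:
            raise ValidationError(
                f"gonad_peak_fraction must be < 1, got {self.gonad_peak_fraction}"
            )
        if not (0 < self.gonad_buildup_days <= days_per_year):
            raise ValidationError(
                f"gonad_buildup_days must be in (0, days_per_year], got {self.gonad_buildup_days}"
            )
        if self.soma_asymptotic_mass < self.soma_initial_mass:
            raise ValidationError("soma_asymptotic_mass must be >= soma_initial_mass")
        if self.growth_mode not in GROWTH_MODES:
            raise ValidationError(f"growth_mode must be one of {GROWTH_MODES}")


@dataclass
class ModelParameters:
    """Every model parameter and scenario switch, plus derived constants.

    Derived fields (``p0``, ``px``, ``a_g``, ``a_m``) are computed by
    :meth:`__post_init__`; after mutating fields call :meth:`replace` or
    :meth:`validate` to re-derive.
    """

    # physiology
    c_x: float = 30.0
    k_x_g: float = 0.5
    k_x_m: float = 0.35
    q_m: float = 0.9
    # survival / recruitment shape
    annual_survival_min: float = 0.001
    annual_survival_max: float = 0.25
    u: float = 0.025
    v: float = 0.025
    l: float = 0.2
    # excretion
    excretion_model: str = "sigmoid"
    b: float = 200.0
    b_c: float = 3.0
    c_t: float = 6.0
    # thiamine input
    c_b_mean: float = 2.0
    c_b_halfwidth: float = 2.0
    beta_shape: tuple[float, float] = (4.0, 4.0)
    starvation_days: int = 0
    # calendar / life history
    days_per_year: int = 365
    d_s: int = 365
    i_max: int = 15
    reproductive_mode: str = "iteroparous"
    growth: GrowthParameters = field(default_factory=GrowthParameters)
    grid: GridParameters = field(default_factory=GridParameters)
    # population
    N: int = 1000
    seed: int = 0
    c_g_init: float = 0.0
    c_m_init: float = 15.0
    # analysis switches
    recruits_use_raw_concentration: bool = False
    variation_measure: str = "range"
    # derived (do not set directly)
    p0: float = field(default=0.0, compare=False)
    px: float = field(default=0.0, compare=False)
    a_g: float = field(default=0.0, compare=False)
    a_m: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if isinstance(self.growth, dict):
            self.growth = GrowthParameters(**self.growth)
        if isinstance(self.grid, dict):
            self.grid = GridParameters(**self.grid)
        self.beta_shape = tuple(float(x) for x in self.beta_shape)  # type: ignore[assignment]
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.c_x <= 0:
            raise ValidationError(f"c_x must be positive, got {self.c_x}")
        for name in ("k_x_g", "k_x_m"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not (0 < self.q_m <= 1):
            raise ValidationError(f"q_m must be in (0, 1], got {self.q_m}")
        for name in ("u", "v", "l"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"exponent {name} must be positive, got {getattr(self, name)}")
        if self.excretion_model not in EXCRETION_MODELS:
            raise ValidationError(
                f"excretion_model must be one of {EXCRETION_MODELS}, got {self.excretion_model!r}"
            )
        if self.excretion_model == "sigmoid" and self.b <= 1:
            raise ValidationError(f"sigmoid shape b must be > 1, got {self.b}")
        if self.excretion_model == "reabsorption_passive" and not (0 < self.c_t < self.c_x):
            raise ValidationError(
                f"c_t must satisfy 0 < c_t < c_x under the reabsorption model, got {self.c_t}"
            )
        if self.c_b_halfwidth < 0:
            raise ValidationError(f"c_b_halfwidth must be >= 0, got {self.c_b_halfwidth}")
        if self.c_b_mean - self.c_b_halfwidth < 0:
            raise ValidationError(
                "blood input range must be non-negative: "
                f"c_b_mean={self.c_b_mean} - c_b_halfwidth={self.c_b_halfwidth} < 0"
            )
        if any(s <= 0 for s in self.beta_shape) or len(self.beta_shape) != 2:
            raise ValidationError(f"beta_shape must be two positive numbers, got {self.beta_shape}")
        if self.days_per_year < 1:
            raise ValidationError(f"days_per_year must be >= 1, got {self.days_per_year}")
        if not (1 <= self.d_s <= self.days_per_year):
            raise ValidationError(f"d_s must be in [1, days_per_year], got {self.d_s}")
        if self.i_max < 1:
            raise ValidationError(f"i_max must be >= 1, got {self.i_max}")
        if self.reproductive_mode not in REPRODUCTIVE_MODES:
            raise ValidationError(f"reproductive_mode must be one of {REPRODUCTIVE_MODES}")
        if self.starvation_days < 0 or self.starvation_days > self.d_s:
            raise ValidationError(f"starvation_days must be in [0, d_s], got {self.starvation_days}")
        if self.N < 1:
            raise ValidationError(f"N must be >= 1, got {self.N}")
        for name in ("c_g_init", "c_m_init"):
            val = getattr(self, name)
            if not (0 <= val <= self.c_x):
                raise ValidationError(f"{name} must be in [0, c_x], got {val}")
        if self.variation_measure not in VARIATION_MEASURES:
            raise ValidationError(f"variation_measure must be one of {VARIATION_MEASURES}")
        self.growth.validate(self.days_per_year)
        self.grid.validate(self.c_x)
        self._derive()

    def _derive(self) -> None:
        self.p0, self.px = derive_daily_survival_bounds(
            self.annual_survival_min, self.annual_survival_max, self.days_per_year
        )
        if self.excretion_model == "reabsorption_passive":
            self.a_g = derive_reabsorption_coefficient(self.c_t, self.k_x_g, self.c_x, self.b_c)
            self.a_m = derive_reabsorption_coefficient(self.c_t, self.k_x_m, self.c_x, self.b_c)
        else:
            self.a_g = self.a_m = 0.0

    # -- convenience -----------------------------------------------------
    def replace(self, **overrides: Any) -> "ModelParameters":
        """Return a new validated parameter set with the given overrides."""
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["beta_shape"] = list(self.beta_shape)
        # derived values are recomputed on load; keep them for metadata only
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParameters":
        d = dict(d)
        for derived in ("p0", "px", "a_g", "a_m"):
            d.pop(derived, None)
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValidationError(f"unknown configuration keys: {sorted(extra)}")
        return cls(**d)


def load_config(path: str | Path) -> ModelParameters:
    """Load and validate a scenario configuration (YAML or JSON)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"configuration in {path} must be a mapping")
    return ModelParameters.from_dict(data)


def save_config(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set to YAML or JSON (round-trips with load_config)."""
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
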