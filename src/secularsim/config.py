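"""Configuration schema for the society simulator.

All tunable quantities live here, grouped by process: prosocial behaviour,
demography (wellbeing, mortality, marriage, reproduction), central
institutions, and the yearly schedule.  Configurations serialise to YAML or
JSON; unknown keys are rejected so a typo never silently falls back to a
default.
"""

from __future__ import annotations

import importlib.resources
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class ConfigurationError(ValueError):
    """Raised when a run configuration fails validation."""


class ReproductionTiming(str, Enum):
    BEFORE_PB = "before_pb"
    AFTER_PB = "after_pb"
    RANDOM = "random"


class CITiming(str, Enum):
    BEFORE_PB = "before_pb"
    AFTER_PB = "after_pb"


class ThreatMode(str, Enum):
    #: the same threat value is applied every year
    CONSTANT = "constant"
    #: yearly threat ~ Uniform(0, 2 * threat_value) — same mean as constant
    STOCHASTIC_UNIFORM = "stochastic_uniform"


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class BehaviourParams(_StrictModel):
    """Prosocial behaviour (PB) triggering, effects and religiosity decay.

    A prosocial act fires when anxiety x religiosity strictly exceeds
    ``pb_threshold``.  It lowers the insecurity of the performer and up to
    ``num_neigh_benefited`` neighbours within ``radius_local_area``, raises
    the religiosity of performer/beneficiaries still in the socialisation
    window (age <= 25), and costs the performer wellbeing.
    """

    pb_threshold: float = Field(0.05, gt=0.0, le=1.0)
    pb_inc_rel_self: float = Field(0.3, ge=0.0, le=1.0)
    pb_inc_rel_neigh: float = Field(0.3, ge=0.0, le=1.0)
    pb_dec_insec_self: float = Field(0.3, ge=0.0, le=1.0)
    pb_dec_insec_neigh: float = Field(0.3, ge=0.0, le=1.0)
    pb_wellbeing_cost: float = Field(0.01, ge=0.0, le=1.0)
    num_neigh_benefited: int = Field(5, ge=0)
    threat_value: float = Field(0.1, ge=0.0)
    threat_mode: ThreatMode = ThreatMode.CONSTANT
    rel_dec_perc: float = Field(0.01, ge=0.0, le=1.0)
    #: if True religiosity decays by subtraction instead of multiplication
    rel_dec_additive: bool = False
    #: benefit only neighbours with religiosity > performer's - this tolerance;
    #: 1.0 disables parochialism entirely
    parochial_prosociality: float = Field(1.0, ge=0.0, le=1.0)
    radius_local_area: float = Field(50.0, gt=0.0)
    pb_min_age: int = Field(12, ge=0)
    socialisation_max_age: int = Field(25, ge=0)
    #: religiosity decays for ages in [rel_decay_min_age, socialisation_max_age]
    rel_decay_min_age: int = Field(0, ge=0)


class DemographyParams(_StrictModel):
    """Wellbeing dynamics, mortality, marriage and reproduction.

    The age-related wellbeing delta follows C - 4C * u**Exp with
    u = (age - wb_age_threshold) / (100 - wb_age_threshold); the insecurity
    delta is piecewise linear through (0, +wb_max_inc), (wb_insec_threshold, 0)
    and (1, -wb_max_dec).  Reproduction probability is a logistic curve on the
    weighted mean of the couple's wellbeing and insecurity.
    """

    rep_cost: float = Field(0.1, ge=0.0, lt=1.0)
    rep_mid_threshold: float = Field(0.7, gt=0.0, lt=1.0)
    rep_curve_shape: float = Field(10.0, gt=0.0)
    importance_insec: float = Field(0.5, ge=0.0)
    importance_wb: float = Field(1.0, gt=0.0)
    wb_age_threshold: float = Field(50.0, gt=0.0, lt=100.0)
    wb_intercept_C: float = Field(0.02, gt=0.0)
    wb_exp_gain: float = Field(2.0, gt=0.0)
    wb_exp_loss: float = Field(2.0, gt=0.0)
    wb_insec_threshold: float = Field(0.1, gt=0.0, lt=1.0)
    wb_max_inc: float = Field(0.05, ge=0.0)
    wb_max_dec: float = Field(0.25, ge=0.0)
    marriage_age_diff: float = Field(8.0, ge=0.0)
    marriage_min_age: int = Field(15, ge=0)
    reproductive_age_min: int = Field(15, ge=0)
    reproductive_age_max: int = Field(49, ge=0)
    #: polynomial coefficients (highest power first) in wellbeing -> yearly
    #: death probability; None selects the shipped default curve
    mortality_curve: Optional[list[float]] = None
    #: polynomial coefficients (highest power first) in age/100 -> initial
    #: wellbeing; None selects the shipped default curve
    init_wb_curve: Optional[list[float]] = None
    #: use the literally printed (increasing) form of the insecurity gain
    eq3_as_printed: bool = False
    #: signed-power extension of the age delta below the threshold
    wb_age_signed_extension: bool = True

    @model_validator(mode="after")
    def _check_ages(self) -> "DemographyParams":
        if self.reproductive_age_min > self.reproductive_age_max:
            raise ValueError("reproductive_age_min exceeds reproductive_age_max")
        return self


class InstitutionParams(_StrictModel):
    """Central institution: universal insecurity relief taxed from adults."""

    ci_enabled: bool = False
    ci_benefit: float = Field(0.3, ge=0.0)
    ci_wb_cost: float = Field(0.02, ge=0.0)
    #: agents strictly older than this pay the wellbeing cost
    ci_min_tax_age: int = Field(18, ge=0)


class ScheduleConfig(_StrictModel):
    """Event ordering and the simulation horizon."""

    reproduction_timing: ReproductionTiming = ReproductionTiming.BEFORE_PB
    ci_timing: CITiming = CITiming.AFTER_PB
    threat_start_year: int = Field(100, ge=0)
    ci_start_year: int = Field(200, ge=0)
    horizon: int = Field(600, ge=1)
    record_interval: int = Field(25, ge=1)

    @model_validator(mode="after")
    def _check_order(self) -> "ScheduleConfig":
        if not (self.threat_start_year <= self.ci_start_year <= self.horizon):
            raise ValueError(
                "require threat_start_year <= ci_start_year <= horizon"
            )
        if self.horizon % self.record_interval != 0:
            raise ValueError("record_interval must divide horizon")
        return self


class SimulationConfig(_StrictModel):
    """Full parameter bundle for one simulation run."""

    n_agents: int = Field(1000, ge=1)
    space_size: float = Field(500.0, gt=0.0)
    #: super-individual guard: above this many simulated agents a random half
    #: of the population units is culled and the reported population scale
    #: doubles, keeping per-capita dynamics while bounding runtime and memory
    #: (the model has no density dependence, so thriving societies otherwise
    #: grow without limit).  None disables rescaling.
    max_population: Optional[int] = Field(20_000, ge=10)
    threats_enabled: bool = True
    pb_enabled: bool = True
    seed: int = Field(0, ge=0)
    behaviour: BehaviourParams = Field(default_factory=BehaviourParams)
    demography: DemographyParams = Field(default_factory=DemographyParams)
    institutions: InstitutionParams = Field(default_factory=InstitutionParams)
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)

    def reference_model_variant(self) -> "SimulationConfig":
        """Copy of this config with threats and prosocial behaviour off."""
        cfg = self.model_copy(deep=True)
        cfg.threats_enabled = False
        cfg.pb_enabled = False
        cfg.institutions.ci_enabled = False
        return cfg


# ---------------------------------------------------------------------------
# default curves (mortality and initial wellbeing)
# ---------------------------------------------------------------------------

def _default_mortality_curve() -> np.ndarray:
    """Yearly death probability as a polynomial in wellbeing.

    Shaped after a 1950s-style life table re-parameterised on wellbeing: near
    certain death at wellbeing 0, a very low plateau above ~0.5.  Expressed as
    0.005 + 0.945 * (1 - wb)**8 expanded into monomial coefficients.
    """
    base = np.polynomial.polynomial.polypow([1.0, -1.0], 8) * 0.945
    base[0] += 0.005
    return base[::-1].copy()  # highest power first, np.polyval convention


def _default_init_wb_curve() -> np.ndarray:
    """Initial wellbeing as a polynomial in age/100.

    High and slowly rising through childhood and adulthood, declining steeply
    at old ages — the silhouette of a mid-century survival-probability curve.
    """
    return np.array([-0.90, 0.0, 0.0, 0.10, 0.92])


DEFAULT_MORTALITY_CURVE: np.ndarray = _default_mortality_curve()
DEFAULT_INIT_WB_CURVE: np.ndarray = _default_init_wb_curve()


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def config_to_dict(config: SimulationConfig) -> dict:
    return config.model_dump(mode="json")


def config_from_dict(data: dict) -> SimulationConfig:
    try:
        return SimulationConfig.model_validate(data)
    except Exception as exc:  # pydantic.ValidationError
        raise ConfigurationError(str(exc)) from exc


def save_run_config(config: SimulationConfig, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_run_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML (or JSON — a YAML subset) run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return config_from_dict(data)


def load_calibrated_profile() -> dict:
    """The repository's calibrated reference-model demography fragment."""
    res = importlib.resources.files("secularsim") / "profiles" / "reference_model.yaml"
    with res.open() as fh:
        return yaml.safe_load(fh)


def calibrated_config(**overrides) -> SimulationConfig:
    """A SimulationConfig whose demography uses the calibrated profile."""
    profile = load_calibrated_profile()
    data = {"demography": profile["demography"]}
    cfg = SimulationConfig.model_validate(data)
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg
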