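"""Reference-model calibration.

The reference model (RM) is the baseline against which every experiment is
read: threats and prosocial behaviour switched off, and the demographic
parameters (reproduction cost and curve, wellbeing-age curve, security gain,
marriage age window) tuned so the population neither explodes nor collapses
over centuries.  The objective is the residual sum of squares between the
observed yearly growth ratio pop_{t+1}/pop_t and 1, averaged over seeded
replicates; a bounded derivative-free search (differential evolution with
restarts and common random numbers) minimises it.  The winning parameter set
is persisted as the repository's default calibrated profile.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import differential_evolution

from .config import SimulationConfig, ScheduleConfig
from . import engine

__all__ = [
    "CalibrationSpec",
    "growth_rate_rss",
    "growth_rate_objective",
    "calibrate_reference_model",
    "save_profile",
]


def growth_rate_rss(populations) -> float:
    """Residual sum of squares of yearly growth ratios against 1.

    The series is truncated at the first zero population (the ratio is
    undefined there); the engine-coupled objective adds the extinction
    penalty on top.
    """
    pops = np.asarray(populations, dtype=float)
    if np.any(pops == 0):
        pops = pops[: int(np.argmax(pops == 0))]
    if len(pops) < 2:
        return 0.0
    ratios = pops[1:] / pops[:-1]
    return float(np.sum((ratios - 1.0) ** 2))

#: score assigned to a replicate that goes extinct — dominates any finite
#: residual a surviving run can accumulate
EXTINCTION_PENALTY_PER_YEAR = 1.0

#: population at which a replicate is declared runaway and truncated
RUNAWAY_POPULATION_FACTOR = 20

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "rep_cost": (0.02, 0.30),
    "rep_mid_threshold": (0.40, 0.95),
    "rep_curve_shape": (2.0, 30.0),
    "wb_age_threshold": (30.0, 70.0),
    "wb_intercept_C": (0.002, 0.05),
    "wb_exp_gain": (0.5, 5.0),
    "wb_exp_loss": (0.5, 5.0),
    "wb_max_inc": (0.01, 0.15),
    "marriage_age_diff": (1.0, 20.0),
}


@dataclass
class CalibrationSpec:
    """Search space and budget for the reference-model calibration."""

    free_parameters: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    horizon: int = 500
    replicates_per_candidate: int = 2
    #: differential-evolution generations per restart
    budget: int = 30
    restarts: int = 4
    n_agents: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.free_parameters.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
        if self.replicates_per_candidate < 1:
            raise ValueError("replicates_per_candidate must be >= 1")


def _rm_config(spec: CalibrationSpec, values: dict[str, float], seed: int) -> SimulationConfig:
    cfg = SimulationConfig(
        n_agents=spec.n_agents,
        seed=seed,
        threats_enabled=False,
        pb_enabled=False,
        schedule=ScheduleConfig(
            horizon=spec.horizon,
            record_interval=spec.horizon,  # per-year records are enough here
            threat_start_year=0,
            ci_start_year=0,
        ),
    )
    for name, value in values.items():
        setattr(cfg.demography, name, float(value))
    return cfg


def _growth_score_one(config: SimulationConfig) -> float:
    """Growth-rate RSS of a single run, with extinction/runaway handling."""
    horizon = config.schedule.horizon
    cap = RUNAWAY_POPULATION_FACTOR * config.n_agents
    society = engine.initialize_society(config)
    prev = society.size
    score = 0.0
    for t in range(1, horizon + 1):
        engine.step_year(society, config)
        pop = society.size
        if pop == 0:
            # truncated: remaining years carry the extinction penalty
            score += (horizon - t + 1) * EXTINCTION_PENALTY_PER_YEAR
            return score
        ratio = pop / prev
        score += (ratio - 1.0) ** 2
        if pop > cap:
            # runaway: extrapolate the last growth ratio over remaining years
            score += (horizon - t) * (ratio - 1.0) ** 2
            return score
        prev = pop
    return score


def growth_rate_objective(
    values: dict[str, float],
    spec: CalibrationSpec,
) -> float:
    """Mean growth-rate RSS over the spec's replicates (common random numbers)."""
    scores = [
        _growth_score_one(_rm_config(spec, values, seed=spec.seed * 1000 + r))
        for r in range(spec.replicates_per_candidate)
    ]
    return float(np.mean(scores))


def calibrate_reference_model(spec: CalibrationSpec):
    """Bounded derivative-free search for a stable reference model.

    Runs ``spec.restarts`` differential-evolution searches with distinct
    seeds and returns (best parameter dict, best score).  Raises RuntimeError
    if every evaluated candidate went extinct.
    """
    names = list(spec.free_parameters)
    bounds = [spec.free_parameters[n] for n in names]

    def objective(x: np.ndarray) -> float:
        return growth_rate_objective(dict(zip(names, x)), spec)

    best_x, best_f = None, np.inf
    for r in range(spec.restarts):
        result = differential_evolution(
            objective,
            bounds,
            seed=spec.seed + 17 * r,
            maxiter=spec.budget,
            popsize=6,
            tol=1e-6,
            polish=False,
            updating="immediate",
        )
        if result.fun < best_f:
            best_x, best_f = result.x, float(result.fun)
    if best_x is None or best_f >= spec.horizon * EXTINCTION_PENALTY_PER_YEAR:
        raise RuntimeError(
            "calibration failed: every candidate went extinct "
            f"(best score {best_f:.1f})"
        )
    return dict(zip(names, (float(v) for v in best_x))), best_f


def save_profile(
    values: dict[str, float],
    score: float,
    spec: CalibrationSpec,
    path: str | Path,
) -> None:
    """Write a calibrated demography fragment with provenance metadata."""
    payload = {
        "provenance": {
            "tool": "secularsim.calibration",
            "seed": spec.seed,
            "horizon": spec.horizon,
            "replicates_per_candidate": spec.replicates_per_candidate,
            "restarts": spec.restarts,
            "budget": spec.budget,
            "score": float(score),
            "date": datetime.date.today().isoformat(),
        },
        "demography": {k: round(float(v), 6) for k, v in values.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
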