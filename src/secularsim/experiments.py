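"""Latin-hypercube experiment driver and trajectory classification.

Builds stratified designs over the behavioural parameter ranges, runs one
simulation per (sample x reproduction/CI schedule) with reproducibly derived
seeds, and classifies every trajectory: success (population > 2500 at year
600), population trend and religiosity trend (Pearson correlation against
year over the 25-year samples from year 200, significant at p < 0.1), and
the pace of religiosity decline among thriving-but-secularising societies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats
from scipy.stats import qmc

from .config import (
    CITiming,
    ReproductionTiming,
    SimulationConfig,
)
from .engine import Trajectory, run_simulation

__all__ = [
    "PARAM_RANGES_FIRST",
    "PARAM_RANGES_SECOND",
    "PARAM_RANGES_THIRD",
    "PARAM_RANGES_CI",
    "ExperimentDesign",
    "latin_hypercube_design",
    "grid_design",
    "run_experiment_batch",
    "pearson_trend_test",
    "classify_population_trajectory",
    "classify_religiosity_trajectory",
    "is_successful",
    "pace_category",
    "classify_results",
]

SUCCESS_POPULATION = 2500
TREND_START_YEAR = 200
TREND_P_THRESHOLD = 0.1

#: behaviour parameters that are sampled (name -> config attribute on
#: BehaviourParams; institution parameters live on InstitutionParams)
_BEHAVIOUR_PARAMS = {
    "pb_threshold", "pb_inc_rel_self", "pb_inc_rel_neigh",
    "pb_dec_insec_self", "pb_dec_insec_neigh", "pb_wellbeing_cost",
    "num_neigh_benefited", "threat_value", "rel_dec_perc",
    "parochial_prosociality",
}
_INSTITUTION_PARAMS = {"ci_benefit", "ci_wb_cost"}
_INTEGER_PARAMS = {"num_neigh_benefited"}

PARAM_RANGES_FIRST: dict[str, tuple[float, float]] = {
    "pb_threshold": (0.001, 0.500),
    "pb_inc_rel_self": (0.100, 0.500),
    "pb_inc_rel_neigh": (0.100, 0.500),
    "pb_dec_insec_self": (0.100, 0.500),
    "pb_dec_insec_neigh": (0.100, 0.500),
    "pb_wellbeing_cost": (0.001, 0.500),
    "num_neigh_benefited": (0.0, 10.0),
    "threat_value": (0.001, 0.500),
    "rel_dec_perc": (0.001, 0.500),
}

PARAM_RANGES_SECOND = dict(
    PARAM_RANGES_FIRST,
    pb_threshold=(0.001, 0.100),
    pb_wellbeing_cost=(0.001, 0.100),
    num_neigh_benefited=(5.0, 10.0),
)

PARAM_RANGES_THIRD = dict(
    PARAM_RANGES_SECOND,
    pb_threshold=(0.001, 0.050),
    pb_dec_insec_self=(0.250, 0.500),
    pb_dec_insec_neigh=(0.250, 0.500),
    pb_wellbeing_cost=(0.001, 0.025),
)

PARAM_RANGES_CI = dict(
    PARAM_RANGES_THIRD,
    threat_value=(0.001, 0.300),
    rel_dec_perc=(0.001, 0.250),
    parochial_prosociality=(0.200, 1.000),
    ci_wb_cost=(0.001, 0.050),
    ci_benefit=(0.100, 0.500),
)


@dataclass
class ExperimentDesign:
    """A sampled parameter design plus the schedules to run it under."""

    parameter_ranges: dict[str, tuple[float, float]]
    n_samples: int
    seed: int
    schedules: list[tuple[ReproductionTiming, CITiming]] = field(
        default_factory=lambda: [
            (ReproductionTiming.BEFORE_PB, CITiming.AFTER_PB),
            (ReproductionTiming.RANDOM, CITiming.AFTER_PB),
            (ReproductionTiming.AFTER_PB, CITiming.AFTER_PB),
        ]
    )

    def samples(self) -> pd.DataFrame:
        return latin_hypercube_design(self.parameter_ranges, self.n_samples, self.seed)


def latin_hypercube_design(
    ranges: dict[str, tuple[float, float]], n_samples: int, seed: int
) -> pd.DataFrame:
    """Latin-hypercube sample: one point per equal-width stratum per parameter.

    Integer-valued parameters (the beneficiary count) are rounded to the
    nearest integer after sampling.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    names = list(ranges)
    for name in names:
        lo, hi = ranges[name]
        if lo >= hi:
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n_samples)
    lows = np.array([ranges[n][0] for n in names])
    highs = np.array([ranges[n][1] for n in names])
    scaled = qmc.scale(unit, lows, highs)
    frame = pd.DataFrame(scaled, columns=names)
    for name in names:
        if name in _INTEGER_PARAMS:
            frame[name] = np.rint(frame[name]).astype(int)
    frame.insert(0, "sample_id", np.arange(n_samples))
    return frame


def grid_design(levels: dict[str, Iterable[float]]) -> pd.DataFrame:
    """Full-factorial design from user-supplied level values per parameter."""
    names = list(levels)
    grids = np.meshgrid(*[np.asarray(list(levels[n])) for n in names], indexing="ij")
    frame = pd.DataFrame({n: g.ravel() for n, g in zip(names, grids)})
    frame.insert(0, "sample_id", np.arange(len(frame)))
    return frame


# ---------------------------------------------------------------------------
# batch execution
# ---------------------------------------------------------------------------

def _config_for_row(
    row: dict, base: SimulationConfig, timing: ReproductionTiming,
    ci_timing: CITiming, seed: int,
) -> SimulationConfig:
    cfg = base.model_copy(deep=True)
    cfg.seed = int(seed)
    cfg.schedule.reproduction_timing = timing
    cfg.schedule.ci_timing = ci_timing
    ci_sampled = False
    for name, value in row.items():
        if name in _BEHAVIOUR_PARAMS:
            setattr(
                cfg.behaviour, name,
                int(value) if name in _INTEGER_PARAMS else float(value),
            )
        elif name in _INSTITUTION_PARAMS:
            setattr(cfg.institutions, name, float(value))
            ci_sampled = True
    if ci_sampled:
        cfg.institutions.ci_enabled = True
    return cfg


def _run_one(row: dict, base: SimulationConfig, timing, ci_timing, seed: int) -> dict:
    cfg = _config_for_row(row, base, timing, ci_timing, seed)
    out = dict(row)
    out["reproduction_timing"] = timing.value
    out["ci_timing"] = ci_timing.value
    out["run_seed"] = int(seed)
    try:
        traj = run_simulation(cfg)
        out.update(_classify_trajectory(traj))
    except Exception as exc:  # never abort the batch for one bad run
        out["error"] = f"{type(exc).__name__}: {exc}"
        return out
    out["error"] = ""
    return out


def run_experiment_batch(
    design: ExperimentDesign,
    base_config: SimulationConfig,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """One classified run per (sample x schedule).

    Per-run seeds are derived from the design seed and the sample index, so
    the same sample keeps the same seed across schedules (matched
    comparisons) and serial/parallel execution give identical tables.
    """
    samples = design.samples()
    run_seeds = np.random.SeedSequence(design.seed).generate_state(design.n_samples)
    run_seeds = (run_seeds % (2**31)).astype(np.int64)
    tasks = []
    for _, row in samples.iterrows():
        row = row.to_dict()
        seed = run_seeds[int(row["sample_id"])]
        for timing, ci_timing in design.schedules:
            tasks.append((row, timing, ci_timing, seed))
    if n_jobs == 1:
        rows = [_run_one(r, base_config, t, c, s) for (r, t, c, s) in tasks]
    else:
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_run_one)(r, base_config, t, c, s) for (r, t, c, s) in tasks
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["sample_id", "reproduction_timing", "ci_timing"], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# trend tests and classification
# ---------------------------------------------------------------------------

def pearson_trend_test(series_x, series_y) -> tuple[float, float, int]:
    """Pearson r, two-sided p, and the trend sign (-1, 0, +1).

    A constant series has no defined correlation and is reported as
    non-significant (r = 0, p = 1, sign 0).
    """
    x = np.asarray(series_x, dtype=float)
    y = np.asarray(series_y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a trend test")
    if np.ptp(y) == 0.0 or np.ptp(x) == 0.0:
        return 0.0, 1.0, 0
    r, p = stats.pearsonr(x, y)
    sign = 0 if p >= TREND_P_THRESHOLD else (1 if r > 0 else -1)
    return float(r), float(p), sign


def _trend_series(traj: Trajectory, values: np.ndarray):
    years = traj.sampled_years
    mask = years >= TREND_START_YEAR
    return years[mask], values[mask]


def classify_population_trajectory(traj: Trajectory) -> str:
    """dying / surviving / thriving from the year-200+ population samples."""
    if traj.final_population == 0:
        return "dying"
    x, y = _trend_series(traj, traj.sampled_population)
    _, _, sign = pearson_trend_test(x, y)
    return {-1: "dying", 0: "surviving", 1: "thriving"}[sign]


def classify_religiosity_trajectory(traj: Trajectory) -> str:
    """declining / increasing / stable from year-200+ mean religiosity."""
    x, y = _trend_series(traj, traj.sampled_religiosity)
    _, _, sign = pearson_trend_test(x, y)
    return {-1: "declining", 0: "stable", 1: "increasing"}[sign]


def is_successful(traj: Trajectory) -> bool:
    """Population strictly above 2500 at the end of the run."""
    return traj.final_population > SUCCESS_POPULATION


def pace_category(
    population_trend: str, religiosity_trend: str, final_mean_religiosity: float
) -> dict[str, bool]:
    """Pace-of-secularisation flags for a thriving, religiosity-declining run.

    The slow/medium/fast flag covers every such run; medium/fast additionally
    requires year-600 mean religiosity below 0.5, fast below 0.125.
    """
    if population_trend != "thriving" or religiosity_trend != "declining":
        raise ValueError("pace categories apply only to thriving societies "
                         "with declining religiosity")
    return {
        "pace_smf": True,
        "pace_mf": final_mean_religiosity < 0.5,
        "pace_f": final_mean_religiosity < 0.125,
    }


def _classify_trajectory(traj: Trajectory) -> dict:
    pop_trend = classify_population_trajectory(traj)
    rel_trend = classify_religiosity_trajectory(traj)
    out = {
        "final_population": traj.final_population,
        "final_mean_religiosity": traj.final_mean_religiosity,
        "success": is_successful(traj),
        "population_trend": pop_trend,
        "religiosity_trend": rel_trend,
        "pace_smf": False,
        "pace_mf": False,
        "pace_f": False,
    }
    if pop_trend == "thriving" and rel_trend == "declining":
        out.update(pace_category(pop_trend, rel_trend, traj.final_mean_religiosity))
    return out


def classify_results(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    """Classify an iterable of trajectories into a results table."""
    return pd.DataFrame([_classify_trajectory(t) for t in trajectories])
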