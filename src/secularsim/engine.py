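"""Core engine: agent/society state, initialisation, threats, the yearly cycle.

The society is a struct-of-arrays: one numpy array per agent variable, always
compacted to the living population.  A year runs as

  1. marriage formation
  2. threat exposure (from ``threat_start_year``)
  3. central institution, when scheduled before prosocial behaviour
  4. reproduction, when scheduled before prosocial behaviour
  5. prosocial behaviour over agents in shuffled order
  6. central institution, when scheduled after prosocial behaviour
  7. reproduction, when scheduled after prosocial behaviour
  8. wellbeing drift with age
  9. wellbeing drift with insecurity
 10. religiosity decay of the young
 11. mortality
 12. ageing, offspring join, recording

Under the random reproduction schedule a single seeded coin per year places
reproduction before or after the prosocial stage.  Every source of
randomness is derived from (config.seed, year, stage), so trajectories are
bit-identical across repeated runs and independent of execution order in a
batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from . import behaviour, demography, institutions
from .config import (
    CITiming,
    ReproductionTiming,
    SimulationConfig,
    ThreatMode,
)

log = logging.getLogger(__name__)

__all__ = [
    "SocietyState",
    "Trajectory",
    "compute_anxiety",
    "initialize_society",
    "apply_threats",
    "step_year",
    "run_simulation",
]

# stage indices for per-year seed derivation
_STAGE_MARRIAGE = 0
_STAGE_REPRO = 1
_STAGE_PB = 2
_STAGE_MORTALITY = 3
_STAGE_COIN = 4
_STAGE_THREAT = 5


@dataclass
class SocietyState:
    """Struct-of-arrays state of all living agents."""

    year: int
    space_size: float
    age: np.ndarray
    gender: np.ndarray  # 0 = female, 1 = male
    partner: np.ndarray  # index of partner, -1 = single
    religiosity: np.ndarray
    wellbeing: np.ndarray
    insecurity: np.ndarray
    sensitivity: np.ndarray
    anxiety: np.ndarray
    x: np.ndarray
    y: np.ndarray

    @property
    def size(self) -> int:
        return int(self.age.shape[0])

    @staticmethod
    def array_fields() -> tuple[str, ...]:
        return (
            "age", "gender", "partner", "religiosity", "wellbeing",
            "insecurity", "sensitivity", "anxiety", "x", "y",
        )

    def married(self) -> np.ndarray:
        return self.partner >= 0


@dataclass
class Trajectory:
    """Per-year society summaries plus the coarse sampled series."""

    record_interval: int
    year: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    population_size: np.ndarray = None
    mean_religiosity: np.ndarray = None
    mean_insecurity: np.ndarray = None
    mean_wellbeing: np.ndarray = None
    births: np.ndarray = None
    deaths: np.ndarray = None
    pb_count: np.ndarray = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.year,
                "pop": self.population_size,
                "mean_rel": self.mean_religiosity,
                "mean_ins": self.mean_insecurity,
                "mean_wb": self.mean_wellbeing,
                "births": self.births,
                "deaths": self.deaths,
                "pb_count": self.pb_count,
            }
        )

    @property
    def sampled_years(self) -> np.ndarray:
        return self.year[:: self.record_interval]

    @property
    def sampled_population(self) -> np.ndarray:
        return self.population_size[:: self.record_interval]

    @property
    def sampled_religiosity(self) -> np.ndarray:
        return self.mean_religiosity[:: self.record_interval]

    def sampled_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.sampled_years,
                "pop": self.sampled_population,
                "mean_rel": self.sampled_religiosity,
            }
        )

    @property
    def final_population(self) -> int:
        return int(self.population_size[-1])

    @property
    def final_mean_religiosity(self) -> float:
        return float(self.mean_religiosity[-1])


def compute_anxiety(insecurity, sensitivity):
    """Anxiety is the product of insecurity and sensitivity."""
    ins = np.asarray(insecurity, dtype=np.float64)
    sens = np.asarray(sensitivity, dtype=np.float64)
    if np.any((ins < 0) | (ins > 1)) or np.any((sens < 0) | (sens > 1)):
        raise ValueError("insecurity and sensitivity must lie in [0, 1]")
    return ins * sens


_M64 = (1 << 64) - 1


def _stage_seed(seed: int, year: int, stage: int) -> int:
    """Deterministic 32-bit stream seed for (run seed, year, stage).

    splitmix64 finaliser over a linear mix — cheap enough to call for every
    stage of every simulated year.
    """
    z = (
        seed * 0x9E3779B97F4A7C15
        + year * 0xBF58476D1CE4E5B9
        + stage * 0x94D049BB133111EB
        + 0x2545F4914F6CDD1D
    ) & _M64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _M64
    return (z ^ (z >> 31)) & 0xFFFFFFFF


def initialize_society(config: SimulationConfig) -> SocietyState:
    """Create the initial society.

    Ages follow a decreasing "pyramid" mass (P(age = a) proportional to
    100 - a over 0..100); religiosity and sensitivity are Normal(0.5, 0.1)
    clamped into [0, 1]; insecurity and hence anxiety start at 0; wellbeing
    comes from the initial-wellbeing age curve; positions are uniform over
    the square; everybody starts single.
    """
    n = config.n_agents
    rng = np.random.default_rng(_stage_seed(config.seed, 0, 7))
    ages_support = np.arange(0, 101)
    weights = (100.0 - ages_support)
    weights[weights < 0] = 0.0
    weights /= weights.sum()
    age = rng.choice(ages_support, size=n, p=weights).astype(np.int64)
    gender = (rng.random(n) < 0.5).astype(np.int8)
    religiosity = np.clip(rng.normal(0.5, 0.1, size=n), 0.0, 1.0)
    sensitivity = np.clip(rng.normal(0.5, 0.1, size=n), 0.0, 1.0)
    insecurity = np.zeros(n)
    wellbeing = demography.initial_wellbeing(
        age, demography._init_wb_coeffs(config.demography)
    )
    return SocietyState(
        year=0,
        space_size=config.space_size,
        age=age,
        gender=gender,
        partner=np.full(n, -1, dtype=np.int64),
        religiosity=religiosity,
        wellbeing=wellbeing,
        insecurity=insecurity,
        sensitivity=sensitivity,
        anxiety=np.zeros(n),
        x=rng.random(n) * config.space_size,
        y=rng.random(n) * config.space_size,
    )


def apply_threats(society: SocietyState, threat_value: float) -> SocietyState:
    """Raise every agent's insecurity by the year's threat, capped at 1."""
    if threat_value < 0:
        raise ValueError("threat value must be non-negative")
    ins = society.insecurity
    np.minimum(ins + threat_value, 1.0, out=ins)
    society.anxiety[:] = ins * society.sensitivity
    return society


def _append_offspring(society: SocietyState, off: dict) -> None:
    if off["n"] == 0:
        return
    n = off["n"]
    society.age = np.concatenate([society.age, np.zeros(n, dtype=society.age.dtype)])
    society.gender = np.concatenate([society.gender, off["gender"]])
    society.partner = np.concatenate(
        [society.partner, np.full(n, -1, dtype=society.partner.dtype)]
    )
    society.religiosity = np.concatenate([society.religiosity, off["religiosity"]])
    society.wellbeing = np.concatenate([society.wellbeing, off["wellbeing"]])
    society.insecurity = np.concatenate([society.insecurity, off["insecurity"]])
    society.sensitivity = np.concatenate([society.sensitivity, off["sensitivity"]])
    society.anxiety = np.concatenate(
        [society.anxiety, off["insecurity"] * off["sensitivity"]]
    )
    society.x = np.concatenate([society.x, off["x"]])
    society.y = np.concatenate([society.y, off["y"]])


@njit(cache=True)
def _post_stage_kernel(
    age, rel, wb, ins, sens, anx,
    c, age_thr, exp_gain, exp_loss, signed_ext,
    max_inc, ins_thr, max_dec, eq3_printed,
    dec_min_age, dec_max_age, dec_perc, dec_additive,
    mort_coeffs,
):
    """Fused end-of-year update: wellbeing drift with age and insecurity,
    religiosity decay, anxiety refresh, and the death-probability vector.

    Element-for-element identical to composing wb_age_delta,
    wb_insecurity_delta, decay_religiosity and death_probability (a property
    the test suite asserts); fused purely to keep per-year overhead low.
    """
    n = age.shape[0]
    p_death = np.empty(n)
    nc = mort_coeffs.shape[0]
    for i in range(n):
        u = (age[i] - age_thr) / (100.0 - age_thr)
        if u >= 0.0:
            delta = c - 4.0 * c * np.abs(u) ** exp_loss
        elif signed_ext:
            delta = c + 4.0 * c * np.abs(u) ** exp_gain
        else:
            delta = c - 4.0 * c * np.sign(u) * np.abs(u) ** exp_gain
        w = wb[i] + delta
        if w < 0.0:
            w = 0.0
        elif w > 1.0:
            w = 1.0
        if ins[i] <= ins_thr:
            if eq3_printed:
                d2 = max_inc + ins[i] * max_inc / ins_thr
            else:
                d2 = max_inc * (1.0 - ins[i] / ins_thr)
        else:
            d2 = -max_dec * (ins[i] - ins_thr) / (1.0 - ins_thr)
        w = w + d2
        if w < 0.0:
            w = 0.0
        elif w > 1.0:
            w = 1.0
        wb[i] = w
        if dec_min_age <= age[i] <= dec_max_age:
            if dec_additive:
                r = rel[i] - dec_perc
                rel[i] = r if r > 0.0 else 0.0
            else:
                rel[i] = rel[i] * (1.0 - dec_perc)
        anx[i] = ins[i] * sens[i]
        # horner evaluation of the mortality polynomial, clamped like the
        # public death_probability
        p = 0.0
        for k in range(nc):
            p = p * w + mort_coeffs[k]
        if p < 0.0:
            p = 0.0
        elif p > 1.0:
            p = 1.0
        p_death[i] = p
    return p_death


def _run_post_stage(society: SocietyState, config: SimulationConfig, seed: int) -> int:
    """Wellbeing drift, decay, mortality; returns the number of deaths."""
    dem = config.demography
    beh = config.behaviour
    p_death = _post_stage_kernel(
        society.age, society.religiosity, society.wellbeing,
        society.insecurity, society.sensitivity, society.anxiety,
        dem.wb_intercept_C, dem.wb_age_threshold,
        dem.wb_exp_gain, dem.wb_exp_loss, dem.wb_age_signed_extension,
        dem.wb_max_inc, dem.wb_insec_threshold, dem.wb_max_dec,
        dem.eq3_as_printed,
        beh.rel_decay_min_age, beh.socialisation_max_age,
        beh.rel_dec_perc, beh.rel_dec_additive,
        demography._mortality_coeffs(dem),
    )
    rng = np.random.default_rng(seed)
    dead = rng.random(society.size) < p_death
    demography.remove_agents(society, dead)
    return int(dead.sum())


def step_year(society: SocietyState, config: SimulationConfig) -> dict:
    """Advance the society by one year in place.

    Returns the year's tallies: births, deaths, pb_count.  An empty society
    is a valid no-op that simply advances the clock.
    """
    year = society.year + 1
    sched = config.schedule
    stats = {"births": 0, "deaths": 0, "pb_count": 0}
    if society.size == 0:
        society.year = year
        return stats

    # reproduction placement for this year
    timing = sched.reproduction_timing
    if timing is ReproductionTiming.RANDOM:
        coin = np.random.default_rng(
            _stage_seed(config.seed, year, _STAGE_COIN)
        ).random()
        repro_before = coin < 0.5
    else:
        repro_before = timing is ReproductionTiming.BEFORE_PB

    demography.form_marriages(
        society, config.demography, _stage_seed(config.seed, year, _STAGE_MARRIAGE)
    )

    if config.threats_enabled and year >= sched.threat_start_year:
        tv = config.behaviour.threat_value
        if config.behaviour.threat_mode is ThreatMode.STOCHASTIC_UNIFORM:
            tv = np.random.default_rng(
                _stage_seed(config.seed, year, _STAGE_THREAT)
            ).uniform(0.0, 2.0 * tv)
        apply_threats(society, tv)

    def _run_ci() -> None:
        institutions.apply_central_institution(
            society, config.institutions, year, sched.ci_start_year
        )

    def _run_repro() -> dict:
        off = demography.attempt_reproduction_all(
            society, config.demography, _stage_seed(config.seed, year, _STAGE_REPRO)
        )
        stats["births"] += off["n"]
        return off

    offspring = {"n": 0}
    if sched.ci_timing is CITiming.BEFORE_PB:
        _run_ci()
    if repro_before:
        offspring = _run_repro()

    if config.pb_enabled:
        stats["pb_count"] = behaviour.run_pb_stage(
            society, config.behaviour, _stage_seed(config.seed, year, _STAGE_PB)
        )

    if sched.ci_timing is CITiming.AFTER_PB:
        _run_ci()
    if not repro_before:
        offspring = _run_repro()

    # wellbeing drift (age first, then insecurity, clamped into [0, 1]),
    # religiosity decay and mortality, fused into one pass
    stats["deaths"] = _run_post_stage(
        society, config, _stage_seed(config.seed, year, _STAGE_MORTALITY)
    )

    society.age += 1
    _append_offspring(society, offspring)
    society.anxiety = society.insecurity * society.sensitivity
    society.year = year
    return stats


_STAGE_RESCALE = 6


def _rescale_population(society: SocietyState, seed: int) -> float:
    """Cull a random half of the population units, couples staying together.

    Returns the factor by which the reported population scale must grow
    (simulated / kept).  Used as a super-individual guard when a society
    outgrows the configured ceiling: each remaining agent thereafter stands
    for more than one person, which preserves per-capita demographic and
    behavioural rates while bounding runtime.
    """
    n = society.size
    idx = np.arange(n)
    heads = idx[(society.partner < 0) | (society.partner > idx)]
    rng = np.random.default_rng(seed)
    drop_heads = rng.permutation(heads)[: len(heads) // 2]
    drop = np.zeros(n, dtype=bool)
    drop[drop_heads] = True
    partners = society.partner[drop_heads]
    drop[partners[partners >= 0]] = True
    demography.remove_agents(society, drop)
    return n / society.size


def _society_means(society: SocietyState) -> tuple[float, float, float]:
    if society.size == 0:
        return 0.0, 0.0, 0.0
    return (
        float(society.religiosity.mean()),
        float(society.insecurity.mean()),
        float(society.wellbeing.mean()),
    )


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Run a full simulation from a fresh society; returns the trajectory.

    The record at year 0 describes the initial society; on extinction the
    remaining years are recorded as population 0.
    """
    horizon = config.schedule.horizon
    society = initialize_society(config)
    nrec = horizon + 1
    pop = np.zeros(nrec, dtype=np.int64)
    mrel = np.zeros(nrec)
    mins = np.zeros(nrec)
    mwb = np.zeros(nrec)
    births = np.zeros(nrec, dtype=np.int64)
    deaths = np.zeros(nrec, dtype=np.int64)
    pbs = np.zeros(nrec, dtype=np.int64)
    pop[0] = society.size
    mrel[0], mins[0], mwb[0] = _society_means(society)
    scale = 1.0  # persons represented per simulated agent
    for t in range(1, nrec):
        if society.size == 0:
            break  # remaining records stay zero
        stats = step_year(society, config)
        if (
            config.max_population is not None
            and society.size > config.max_population
        ):
            scale *= _rescale_population(
                society, _stage_seed(config.seed, t, _STAGE_RESCALE)
            )
        pop[t] = int(round(society.size * scale))
        mrel[t], mins[t], mwb[t] = _society_means(society)
        births[t] = int(round(stats["births"] * scale))
        deaths[t] = int(round(stats["deaths"] * scale))
        pbs[t] = int(round(stats["pb_count"] * scale))
        if log.isEnabledFor(logging.DEBUG):
            log.debug(
                "year %d pop %d births %d deaths %d pb %d",
                t, pop[t], births[t], deaths[t], pbs[t],
            )
    return Trajectory(
        record_interval=config.schedule.record_interval,
        year=np.arange(nrec),
        population_size=pop,
        mean_religiosity=mrel,
        mean_insecurity=mins,
        mean_wellbeing=mwb,
        births=births,
        deaths=deaths,
        pb_count=pbs,
    )
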