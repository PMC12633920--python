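import numpy as np
import pytest

from secularsim import (
    BehaviourParams,
    DemographyParams,
    ScheduleConfig,
    SimulationConfig,
    SocietyState,
)


@pytest.fixture(scope="session")
def rm_config():
    """Calibrated reference-model configuration (threats and PB off)."""
    from secularsim import calibrated_config

    cfg = calibrated_config()
    return cfg.reference_model_variant()


def make_society(
    n=50,
    space=500.0,
    seed=0,
    ages=None,
    religiosity=None,
    insecurity=None,
    sensitivity=None,
    positions=None,
) -> SocietyState:
    """Hand-built small society for unit tests."""
    rng = np.random.default_rng(seed)
    age = np.asarray(ages if ages is not None else rng.integers(0, 80, n))
    n = len(age)
    rel = np.asarray(
        religiosity if religiosity is not None else rng.random(n), dtype=float
    )
    ins = np.asarray(
        insecurity if insecurity is not None else rng.random(n), dtype=float
    )
    sens = np.asarray(
        sensitivity if sensitivity is not None else rng.random(n), dtype=float
    )
    if positions is not None:
        x, y = (np.asarray(p, dtype=float) for p in positions)
    else:
        x, y = rng.random(n) * space, rng.random(n) * space
    return SocietyState(
        year=0,
        space_size=space,
        age=age.astype(np.int64),
        gender=rng.integers(0, 2, n).astype(np.int8),
        partner=np.full(n, -1, dtype=np.int64),
        religiosity=rel,
        wellbeing=np.full(n, 0.8),
        insecurity=ins,
        sensitivity=sens,
        anxiety=ins * sens,
        x=x,
        y=y,
    )


def quick_config(horizon=100, n_agents=300, seed=0, **kwargs) -> SimulationConfig:
    """Small, fast configuration for behavioural tests."""
    sched = kwargs.pop("schedule", None) or ScheduleConfig(
        horizon=horizon,
        record_interval=25 if horizon % 25 == 0 else horizon,
        threat_start_year=kwargs.pop("threat_start_year", 0),
        ci_start_year=kwargs.pop("ci_start_year", 0),
    )
    return SimulationConfig(
        n_agents=n_agents,
        seed=seed,
        schedule=sched,
        behaviour=kwargs.pop("behaviour", BehaviourParams()),
        demography=kwargs.pop("demography", DemographyParams()),
        **kwargs,
    )
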