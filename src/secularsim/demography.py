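"""Demographic processes: wellbeing dynamics, mortality, marriage, reproduction.

Wellbeing drifts every year with age and with insecurity; it maps to a yearly
death probability through a shipped (or user-supplied) polynomial curve.
Marriage pairs eligible singles of opposite gender; married females of
reproductive age may bear one child per year with a probability given by a
logistic curve on the couple's pooled wellbeing and insecurity.  The
per-agent loops (matching, births) are numba kernels; everything else is
plain vector arithmetic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .config import (
    DEFAULT_INIT_WB_CURVE,
    DEFAULT_MORTALITY_CURVE,
    DemographyParams,
)

__all__ = [
    "initial_wellbeing",
    "wb_age_delta",
    "wb_insecurity_delta",
    "death_probability",
    "reproduction_probability",
    "apply_mortality",
    "form_marriages",
    "attempt_reproduction_all",
]


def _mortality_coeffs(params: DemographyParams) -> np.ndarray:
    if params.mortality_curve is None:
        return DEFAULT_MORTALITY_CURVE
    return np.asarray(params.mortality_curve, dtype=np.float64)


def _init_wb_coeffs(params: DemographyParams) -> np.ndarray:
    if params.init_wb_curve is None:
        return DEFAULT_INIT_WB_CURVE
    return np.asarray(params.init_wb_curve, dtype=np.float64)


# ---------------------------------------------------------------------------
# wellbeing curves and deltas
# ---------------------------------------------------------------------------

def initial_wellbeing(age, curve=None):
    """Initial wellbeing for an agent of the given age (polynomial in age/100).

    Output is clamped to [0, 1].  Ages must lie in [0, 100].
    """
    age = np.asarray(age, dtype=np.float64)
    if np.any((age < 0) | (age > 100)):
        raise ValueError("age out of [0, 100]")
    coeffs = DEFAULT_INIT_WB_CURVE if curve is None else np.asarray(curve, float)
    val = np.polyval(coeffs, age / 100.0)
    return np.clip(val, 0.0, 1.0)


def wb_age_delta(age, params: DemographyParams):
    """Signed yearly wellbeing change from ageing.

    For age >= wb_age_threshold: C - 4C * u**Exp2 with
    u = (age - threshold)/(100 - threshold) — equal to C at the threshold and
    -3C at age 100.  Below the threshold the same expression continues with a
    signed power of |u| and the gain exponent, so the delta is largest at age
    0 and meets C at the threshold.
    """
    age = np.asarray(age, dtype=np.float64)
    c = params.wb_intercept_C
    thr = params.wb_age_threshold
    u = (age - thr) / (100.0 - thr)
    above = c - 4.0 * c * np.abs(u) ** params.wb_exp_loss
    if params.wb_age_signed_extension:
        below = c + 4.0 * c * np.abs(u) ** params.wb_exp_gain
    else:  # raw formula, defined only for integer exponents in general
        below = c - 4.0 * c * np.sign(u) * np.abs(u) ** params.wb_exp_gain
    return np.where(u >= 0.0, above, below)


def wb_insecurity_delta(insecurity, params: DemographyParams):
    """Signed yearly wellbeing change from insecurity.

    Piecewise linear and continuous: +wb_max_inc at insecurity 0, zero at
    wb_insec_threshold, -wb_max_dec at insecurity 1.
    """
    ins = np.asarray(insecurity, dtype=np.float64)
    if np.any((ins < 0) | (ins > 1)):
        raise ValueError("insecurity out of [0, 1]")
    thr = params.wb_insec_threshold
    if params.eq3_as_printed:
        gain = params.wb_max_inc + ins * params.wb_max_inc / thr
    else:
        gain = params.wb_max_inc * (1.0 - ins / thr)
    loss = -params.wb_max_dec * (ins - thr) / (1.0 - thr)
    return np.where(ins <= thr, gain, loss)


def death_probability(wellbeing, curve=None):
    """Yearly probability of dying at the given wellbeing, clamped to [0, 1]."""
    wb = np.clip(np.asarray(wellbeing, dtype=np.float64), 0.0, 1.0)
    coeffs = DEFAULT_MORTALITY_CURVE if curve is None else np.asarray(curve, float)
    return np.clip(np.polyval(coeffs, wb), 0.0, 1.0)


def reproduction_probability(avg_wellbeing, avg_insecurity, params: DemographyParams):
    """Logistic reproduction probability on the pooled couple state.

    x = (WB * w_wb + Ins * w_ins) / (w_wb + w_ins);  p = 1/(1 + exp(-b(x-a))).
    Higher insecurity raises the probability — reproduction is prioritised in
    insecure environments.
    """
    wb = np.asarray(avg_wellbeing, dtype=np.float64)
    ins = np.asarray(avg_insecurity, dtype=np.float64)
    x = (wb * params.importance_wb + ins * params.importance_insec) / (
        params.importance_wb + params.importance_insec
    )
    return 1.0 / (1.0 + np.exp(-params.rep_curve_shape * (x - params.rep_mid_threshold)))


# ---------------------------------------------------------------------------
# mortality
# ---------------------------------------------------------------------------

def apply_mortality(society, params: DemographyParams, seed: int):
    """Kill each agent independently with death_probability(wellbeing).

    Removes the dead, widows their partners and remaps partner indices.
    Returns the number of deaths.
    """
    p = death_probability(society.wellbeing, _mortality_coeffs(params))
    rng = np.random.default_rng(seed)
    dead = rng.random(society.size) < p
    remove_agents(society, dead)
    return int(dead.sum())


def remove_agents(society, dead: np.ndarray) -> None:
    """Drop agents flagged in the boolean mask, keeping partner links valid."""
    if not dead.any():
        return
    partner = society.partner
    # widow survivors whose partner died
    widowed = (partner >= 0) & dead[np.maximum(partner, 0)]
    partner[widowed] = -1
    keep = ~dead
    new_index = np.cumsum(keep) - 1
    for name in society.array_fields():
        setattr(society, name, getattr(society, name)[keep])
    partner = society.partner
    has = partner >= 0
    partner[has] = new_index[partner[has]]


# ---------------------------------------------------------------------------
# marriage
# ---------------------------------------------------------------------------

@njit(cache=True)
def _marriage_kernel(age, gender, partner, min_age, max_diff, seed):
    np.random.seed(seed)
    n = age.shape[0]
    # eligible singles, iterated in random order
    singles = np.empty(n, dtype=np.int64)
    m = 0
    for i in range(n):
        if partner[i] < 0 and age[i] > min_age:
            singles[m] = i
            m += 1
    for i in range(m - 1, 0, -1):  # Fisher-Yates shuffle
        j = np.random.randint(0, i + 1)
        tmp = singles[i]
        singles[i] = singles[j]
        singles[j] = tmp
    formed = 0
    cand = np.empty(m, dtype=np.int64)
    for s in range(m):
        i = singles[s]
        if partner[i] >= 0:
            continue
        k = 0
        for t in range(m):
            j = singles[t]
            if j == i or partner[j] >= 0 or gender[j] == gender[i]:
                continue
            if abs(age[i] - age[j]) <= max_diff:
                cand[k] = j
                k += 1
        if k > 0:
            j = cand[np.random.randint(0, k)]
            partner[i] = j
            partner[j] = i
            formed += 1
    return formed


def form_marriages(society, params: DemographyParams, seed: int) -> int:
    """Pair eligible singles (opposite gender, age > marriage_min_age,
    age difference <= marriage_age_diff); returns marriages formed."""
    return int(
        _marriage_kernel(
            society.age,
            society.gender,
            society.partner,
            params.marriage_min_age,
            params.marriage_age_diff,
            np.uint32(seed),
        )
    )


# ---------------------------------------------------------------------------
# reproduction
# ---------------------------------------------------------------------------

@njit(cache=True)
def _reproduction_kernel(
    age, gender, partner, rel, wb, ins, sens,
    a, b, imp_wb, imp_ins, rep_cost, age_min, age_max, space, seed,
):
    np.random.seed(seed)
    n = age.shape[0]
    max_births = n
    off_rel = np.empty(max_births)
    off_ins = np.empty(max_births)
    off_sens = np.empty(max_births)
    off_wb = np.empty(max_births)
    off_gender = np.empty(max_births, dtype=np.int8)
    off_x = np.empty(max_births)
    off_y = np.empty(max_births)
    births = 0
    for i in range(n):
        # at most one birth per married female of reproductive age per year
        if gender[i] != 0 or partner[i] < 0:
            continue
        if age[i] < age_min or age[i] > age_max:
            continue
        j = partner[i]
        avg_wb = 0.5 * (wb[i] + wb[j])
        avg_ins = 0.5 * (ins[i] + ins[j])
        x = (avg_wb * imp_wb + avg_ins * imp_ins) / (imp_wb + imp_ins)
        p = 1.0 / (1.0 + np.exp(-b * (x - a)))
        if np.random.random() >= p:
            continue
        loss_i = rep_cost * wb[i]
        loss_j = rep_cost * wb[j]
        wb[i] -= loss_i
        wb[j] -= loss_j
        child_wb = loss_i + loss_j
        if child_wb > 1.0:
            child_wb = 1.0
        src = i if np.random.random() < 0.5 else j
        off_rel[births] = rel[src]
        off_ins[births] = ins[src]
        off_sens[births] = sens[src]
        off_wb[births] = child_wb
        off_gender[births] = 1 if np.random.random() < 0.5 else 0
        off_x[births] = np.random.random() * space
        off_y[births] = np.random.random() * space
        births += 1
    return (
        births,
        off_rel[:births], off_ins[:births], off_sens[:births],
        off_wb[:births], off_gender[:births], off_x[:births], off_y[:births],
    )


def attempt_reproduction_all(society, params: DemographyParams, seed: int):
    """Run the yearly reproduction opportunity for every married female aged
    within the reproductive range.

    Parents each lose rep_cost x their own wellbeing; the child's initial
    wellbeing is the sum of the two losses.  The child copies religiosity,
    insecurity and sensitivity from one uniformly chosen parent.  Returns the
    offspring as a dict of arrays (possibly empty).
    """
    (births, rel, ins, sens, wb, gender, x, y) = _reproduction_kernel(
        society.age, society.gender, society.partner,
        society.religiosity, society.wellbeing, society.insecurity,
        society.sensitivity,
        params.rep_mid_threshold, params.rep_curve_shape,
        params.importance_wb, params.importance_insec,
        params.rep_cost,
        params.reproductive_age_min, params.reproductive_age_max,
        society.space_size, np.uint32(seed),
    )
    return {
        "n": births,
        "religiosity": rel,
        "insecurity": ins,
        "sensitivity": sens,
        "wellbeing": wb,
        "gender": gender,
        "x": x,
        "y": y,
    }
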