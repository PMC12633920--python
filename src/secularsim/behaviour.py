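"""Prosocial behaviour: triggering, parochial beneficiary choice, effects, decay.

A prosocial act is an emergent event, not an agent attribute: any agent of at
least ``pb_min_age`` performs one in a year when its anxiety x religiosity
strictly exceeds the threshold.  The act lowers the insecurity of the
performer and of up to ``num_neigh_benefited`` randomly chosen eligible
neighbours, raises religiosity for those still in the socialisation window,
and costs the performer wellbeing.  Religiosity otherwise decays every year
while young — the forgetting side of the secularisation balance.

The yearly stage iterates agents in a shuffled order over a uniform spatial
grid (cell size = neighbourhood radius), so each neighbourhood query touches
only 9 cells.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .config import BehaviourParams

__all__ = [
    "pb_trigger",
    "eligible_beneficiaries",
    "perform_prosocial_act",
    "decay_religiosity",
    "run_pb_stage",
]


def pb_trigger(anxiety, religiosity, pb_threshold: float):
    """True when anxiety x religiosity strictly exceeds the threshold."""
    anx = np.asarray(anxiety, dtype=np.float64)
    rel = np.asarray(religiosity, dtype=np.float64)
    return anx * rel > pb_threshold


def eligible_beneficiaries(performer: int, society, params: BehaviourParams):
    """Indices of agents a performer may benefit.

    All living agents other than the performer within the neighbourhood
    radius whose religiosity exceeds the performer's minus the parochial
    tolerance.  With parochial_prosociality = 1 the religiosity condition is
    satisfied by every agent.
    """
    dx = society.x - society.x[performer]
    dy = society.y - society.y[performer]
    near = dx * dx + dy * dy <= params.radius_local_area**2
    open_enough = society.religiosity > (
        society.religiosity[performer] - params.parochial_prosociality
    )
    mask = near & open_enough
    mask[performer] = False
    return np.nonzero(mask)[0]


def perform_prosocial_act(performer: int, society, params: BehaviourParams, seed: int):
    """Execute one prosocial act in place; returns the beneficiary indices.

    The performer pays the wellbeing cost, loses insecurity, and (while in
    the socialisation window) gains religiosity; up to num_neigh_benefited
    beneficiaries are drawn uniformly without replacement from the eligible
    set and receive the neighbour effects.  Anxiety is refreshed for every
    touched agent.  Caller is responsible for the trigger/age preconditions.
    """
    if society.age[performer] < params.pb_min_age:
        raise ValueError("performer below pb_min_age")
    cands = eligible_beneficiaries(performer, society, params)
    ins = society.insecurity
    wb = society.wellbeing
    rel = society.religiosity
    ins[performer] = max(ins[performer] - params.pb_dec_insec_self, 0.0)
    wb[performer] = max(wb[performer] - params.pb_wellbeing_cost, 0.0)
    if society.age[performer] <= params.socialisation_max_age:
        rel[performer] = min(rel[performer] + params.pb_inc_rel_self, 1.0)
    rng = np.random.default_rng(seed)
    take = min(params.num_neigh_benefited, len(cands))
    chosen = rng.choice(cands, size=take, replace=False) if take else cands[:0]
    for j in chosen:
        ins[j] = max(ins[j] - params.pb_dec_insec_neigh, 0.0)
        if society.age[j] <= params.socialisation_max_age:
            rel[j] = min(rel[j] + params.pb_inc_rel_neigh, 1.0)
    touched = np.append(chosen, performer)
    society.anxiety[touched] = ins[touched] * society.sensitivity[touched]
    return chosen


def decay_religiosity(age, religiosity, params: BehaviourParams):
    """Yearly religiosity decay for agents in the socialisation window.

    Multiplicative by default (religiosity * (1 - rel_dec_perc)); an additive
    variant is available for robustness checks.  Agents past the window keep
    their religiosity for life.
    """
    age = np.asarray(age)
    rel = np.asarray(religiosity, dtype=np.float64).copy()
    young = (age >= params.rel_decay_min_age) & (age <= params.socialisation_max_age)
    if params.rel_dec_additive:
        rel[young] = np.maximum(rel[young] - params.rel_dec_perc, 0.0)
    else:
        rel[young] *= 1.0 - params.rel_dec_perc
    return rel


@njit(cache=True)
def _pb_stage_kernel(
    age, rel, wb, ins, sens, x, y,
    threshold, inc_self, inc_neigh, dec_self, dec_neigh, cost,
    k_max, pp, radius, min_age, soc_max_age, space, seed,
):
    np.random.seed(seed)
    n = age.shape[0]
    if n == 0:
        return 0
    # uniform grid with cell size = radius/2; a 5x5 cell block covers the
    # neighbourhood disc with ~30% less slack than radius-sized cells
    cs = radius * 0.5
    ncell = int(np.ceil(space / cs))
    if ncell < 1:
        ncell = 1
    cell = np.empty(n, dtype=np.int64)
    counts = np.zeros(ncell * ncell + 1, dtype=np.int64)
    for i in range(n):
        cx = int(x[i] / cs)
        cy = int(y[i] / cs)
        if cx >= ncell:
            cx = ncell - 1
        if cy >= ncell:
            cy = ncell - 1
        cell[i] = cx * ncell + cy
        counts[cell[i] + 1] += 1
    for c in range(1, ncell * ncell + 1):
        counts[c] += counts[c - 1]
    order_in_cell = np.empty(n, dtype=np.int64)
    fill = counts[:-1].copy()
    for i in range(n):
        order_in_cell[fill[cell[i]]] = i
        fill[cell[i]] += 1

    # shuffled iteration order over all agents
    order = np.arange(n)
    for i in range(n - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = order[i]
        order[i] = order[j]
        order[j] = tmp

    r2 = radius * radius
    cand = np.empty(n, dtype=np.int64)
    pb_count = 0
    for s in range(n):
        i = order[s]
        if age[i] < min_age:
            continue
        if ins[i] * sens[i] * rel[i] <= threshold:
            continue
        # perform: self effects first
        pb_count += 1
        ins_i = ins[i] - dec_self
        ins[i] = ins_i if ins_i > 0.0 else 0.0
        wb_i = wb[i] - cost
        wb[i] = wb_i if wb_i > 0.0 else 0.0
        if age[i] <= soc_max_age:
            rel_i = rel[i] + inc_self
            rel[i] = rel_i if rel_i < 1.0 else 1.0
        if k_max <= 0:
            continue
        # gather eligible neighbours from the 3x3 cell block
        rel_floor = rel[i] - pp
        cx = cell[i] // ncell
        cy = cell[i] % ncell
        m = 0
        for gx in range(cx - 2, cx + 3):
            if gx < 0 or gx >= ncell:
                continue
            for gy in range(cy - 2, cy + 3):
                if gy < 0 or gy >= ncell:
                    continue
                c = gx * ncell + gy
                for t in range(counts[c], counts[c + 1]):
                    j = order_in_cell[t]
                    if j == i:
                        continue
                    dx = x[j] - x[i]
                    dy = y[j] - y[i]
                    if dx * dx + dy * dy > r2:
                        continue
                    if rel[j] > rel_floor:
                        cand[m] = j
                        m += 1
        # uniform sample without replacement (partial Fisher-Yates)
        take = k_max if k_max < m else m
        for t in range(take):
            u = t + np.random.randint(0, m - t)
            j = cand[u]
            cand[u] = cand[t]
            cand[t] = j
            ins_j = ins[j] - dec_neigh
            ins[j] = ins_j if ins_j > 0.0 else 0.0
            if age[j] <= soc_max_age:
                rel_j = rel[j] + inc_neigh
                rel[j] = rel_j if rel_j < 1.0 else 1.0
    return pb_count


def run_pb_stage(society, params: BehaviourParams, seed: int) -> int:
    """Run one year's prosocial-behaviour stage in place.

    Agents act at most once, in a freshly shuffled order; triggering uses the
    current insecurity x sensitivity, so earlier acts in the same year can
    calm later would-be performers.  Returns the number of acts performed.
    """
    return int(
        _pb_stage_kernel(
            society.age, society.religiosity, society.wellbeing,
            society.insecurity, society.sensitivity, society.x, society.y,
            params.pb_threshold,
            params.pb_inc_rel_self, params.pb_inc_rel_neigh,
            params.pb_dec_insec_self, params.pb_dec_insec_neigh,
            params.pb_wellbeing_cost,
            params.num_neigh_benefited, params.parochial_prosociality,
            params.radius_local_area, params.pb_min_age,
            params.socialisation_max_age, society.space_size,
            np.uint32(seed),
        )
    )
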