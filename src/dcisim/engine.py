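"""Simulation orchestration: initialization, the per-step schedule, runs.

One step executes, in fixed order:

1. deposit agent rates and solve the four molecular fields;
2. per-agent environmental updates (hypoxia/necrosis/calcification, then
   density-triggered quiescence) from the freshly sampled local conditions;
3. apoptosis draws (dead cells are removed immediately);
4. cycle-clock advance, growth, terminal differentiation at the division
   cap, and mitosis for mature, signalling-gated cells (daughter phenotype
   draw and adjacent placement);
5. dedifferentiation draws for active progenitors that did not divide;
6. mechanical relaxation of all bodies;
7. counters, transition log, and the per-step metrics record.

Agents are processed in stable id order (array order); daughters join the
schedule on the next step.  All randomness flows through named child streams
of a single root seed, so trajectories are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from . import cells, fields, mechanics, metrics
from .cells import (ACTIVE, CALCIFIED, DIFFERENTIATED, ER_NA, ER_NEG, ER_POS,
                    HYPOXIC, NECROTIC, PROGENITOR, QUIESCENT, STEM,
                    Population)
from .params import ParameterSet, RngStreams, per_step_probability

__all__ = ["SimulationState", "RunResult", "initialize", "step", "run"]

_NEWBORN_VOL_FRAC = 0.5  # daughters start at half the mature volume

# composite phenotype code: lineage when active, else status
_COMP_NAMES = np.array(["stem", "progenitor", "differentiated",
                        "quiescent", "hypoxic", "necrotic", "calcified"])


def _composite(lineage: np.ndarray, status: np.ndarray) -> np.ndarray:
    return np.where(status == ACTIVE, lineage, status + 2).astype(np.int16)


@dataclass
class SimulationState:
    params: ParameterSet
    duct: mechanics.Duct
    geometry: fields.GridGeometry
    grids: dict
    pop: Population
    rng: RngStreams
    clock_h: float = 0.0
    initiation_x: float = 0.0
    counters: dict = dfield(default_factory=lambda: {
        "proliferation": 0, "dedifferentiation": 0, "apoptosis": 0})
    transitions: list = dfield(default_factory=list)
    records: list = dfield(default_factory=list)

    def transition_log(self) -> pd.DataFrame:
        return pd.DataFrame(self.transitions,
                            columns=["t_h", "cell_id", "from", "to", "cause"])

    def record_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


class RunResult:
    """Outcome of :func:`run`: metrics time series plus the final state."""

    def __init__(self, state: SimulationState, record: pd.DataFrame,
                 arrest_time_d, arrest_criterion):
        self.state = state
        self.record = record
        self.arrest_time_d = arrest_time_d
        self.arrest_criterion = arrest_criterion


# --------------------------------------------------------------------------- #

def _log(state, ids, frm_names, to_names, cause):
    t = state.clock_h
    state.transitions.extend(
        (t, int(i), f, s, cause)
        for i, f, s in zip(np.atleast_1d(ids),
                           np.broadcast_to(frm_names, np.atleast_1d(ids).shape),
                           np.broadcast_to(to_names, np.atleast_1d(ids).shape)))


def _radius_for(clock, cycle_time, mature_radius):
    """Linear volume growth from half to full size over the cycle."""
    frac = np.clip(np.divide(clock, cycle_time,
                             out=np.ones_like(clock), where=cycle_time > 0),
                   0.0, 1.0)
    vol_frac = _NEWBORN_VOL_FRAC + (1.0 - _NEWBORN_VOL_FRAC) * frac
    return mature_radius * np.cbrt(vol_frac)


def initialize(params: ParameterSet, seed: int) -> SimulationState:
    """Fresh simulation: ``n_tic`` stem TICs adjacent on the +y interior wall."""
    params = params.validate()
    duct = mechanics.Duct(params.duct_length, params.duct_radius)
    geometry, grids = fields.make_duct_grids(duct, params)
    rng = RngStreams(seed)
    pop = Population()

    n = params.n_tic
    r0 = params.cell_radius * np.cbrt(_NEWBORN_VOL_FRAC)
    # a row of adjacent cells along the axis, centered on the initiation site
    offsets = (np.arange(n) - (n - 1) / 2.0) * (2.0 * r0)
    pos = np.column_stack([offsets,
                           np.full(n, duct.radius - r0),
                           np.zeros(n)])
    tau = np.atleast_1d(cells.assign_cycle_time(params, rng.cycle, size=n))
    ids = pop.add(pos, r0, STEM, ER_NA, tau, is_tic=True)

    state = SimulationState(params=params, duct=duct, geometry=geometry,
                            grids=grids, pop=pop, rng=rng)
    _log(state, ids, "birth", "stem", "initialization")
    fields.update_all_fields(pop, grids, params)
    _record(state)
    return state


# --------------------------------------------------------------------------- #

def step(state: SimulationState) -> SimulationState:
    p = state.params
    pop = state.pop
    dt = p.dt

    # (1) molecular fields and local density
    samples = fields.update_all_fields(pop, state.grids, p)
    if pop.n:
        occ3d = fields.occupancy_grid(
            pop.col("pos"), 4.0 / 3.0 * np.pi * pop.col("radius") ** 3,
            state.geometry, p.occupancy_window, p.occupancy_ref_packing)
        occ = occ3d.ravel()[state.geometry.flat_voxel_of(pop.col("pos"))]
    else:
        occ = np.zeros(0)

    lineage = pop.col("lineage")
    status = pop.col("status")
    comp_before = _composite(lineage, status)

    # (2a) hypoxia / necrosis / calcification
    o2 = samples["O2"]
    live = (status != NECROTIC) & (status != CALCIFIED)
    low = np.zeros(pop.n, dtype=bool)
    low[live] = o2[live] < p.hypoxia_threshold
    hyp = pop.col("hypoxia_h")
    nec = pop.col("necrosis_h")
    status[live & low] = HYPOXIC
    hyp[live & low] += dt
    recovered = live & ~low & (status == HYPOXIC)
    status[recovered] = ACTIVE
    hyp[recovered] = 0.0
    to_nec = (status == HYPOXIC) & (hyp > p.t_necrosis)
    status[to_nec] = NECROTIC
    nec[to_nec] = 0.0
    nec[status == NECROTIC] += dt
    status[(status == NECROTIC) & (nec > p.t_calcify)] = CALCIFIED

    # (2b) density-triggered quiescence for cycling stem/progenitor cells
    cyc = ((status == ACTIVE) | (status == QUIESCENT)) & (
        (lineage == STEM) | (lineage == PROGENITOR))
    if pop.n:
        dense = occ >= p.theta_q
        status[cyc & dense] = QUIESCENT
        status[cyc & ~dense] = ACTIVE

    comp_now = _composite(lineage, status)
    changed = np.nonzero(comp_now != comp_before)[0]
    if changed.size:
        ids = pop.col("ids")
        state.transitions.extend(zip(
            [state.clock_h] * changed.size, ids[changed].tolist(),
            _COMP_NAMES[comp_before[changed]].tolist(),
            _COMP_NAMES[comp_now[changed]].tolist(),
            ["environment"] * changed.size))

    # (3) apoptosis (phenotype-dependent eligibility)
    eligible = cells.apoptosis_eligible_mask(lineage, status,
                                             p.apoptosis_scope)
    die = eligible & (state.rng.apoptosis.random(pop.n) < p.omega_apop)
    if np.any(die):
        idx = np.nonzero(die)[0]
        state.transitions.extend(zip(
            [state.clock_h] * idx.size, pop.col("ids")[idx].tolist(),
            _COMP_NAMES[comp_now[idx]].tolist(),
            ["apoptotic"] * idx.size, ["apoptosis"] * idx.size))
        state.counters["apoptosis"] += int(idx.size)
        keep = pop.remove(die)
        samples = {k: v[keep] for k, v in samples.items()}
        lineage = pop.col("lineage")
        status = pop.col("status")

    # (4) cycle advance, growth, terminal differentiation, mitosis
    cycling = (status == ACTIVE) & ((lineage == STEM) | (lineage == PROGENITOR))
    clock = pop.col("cycle_clock")
    ctime = pop.col("cycle_time")
    clock[cycling] += dt
    rad = pop.col("radius")
    rad[cycling] = _radius_for(clock[cycling], ctime[cycling], p.cell_radius)

    mature = cycling & (clock >= ctime)
    exhaust = mature & (lineage == PROGENITOR) & (
        pop.col("divisions") >= p.p_max)
    if np.any(exhaust):
        lineage[exhaust] = DIFFERENTIATED
        _log(state, pop.col("ids")[exhaust], "progenitor", "differentiated",
             "division-cap")

    gate = cells.er_gate_mask(lineage, pop.col("er"), samples["E2"],
                              samples["FGF"], p)
    divide = mature & ~exhaust & gate
    div_idx = np.nonzero(divide)[0]
    dd_candidates = cells.dediff_eligible_mask(lineage, status, divide)

    n_div = len(div_idx)
    if n_div:
        d_lin, d_er = cells.choose_daughter_phenotypes(
            lineage[div_idx], pop.col("er")[div_idx], p, state.rng.phenotype)
        prog_mother = lineage[div_idx] == PROGENITOR
        pop.col("divisions")[div_idx[prog_mother]] += 1
        # progenitor daughters of progenitor mothers inherit the incremented
        # generation count; daughters of stem mothers start fresh
        d_div = np.where(prog_mother & (d_lin == PROGENITOR),
                         pop.col("divisions")[div_idx], 0)
        r_new = p.cell_radius * np.cbrt(_NEWBORN_VOL_FRAC)
        d_pos = mechanics.place_daughters(
            pop.col("pos")[div_idx], pop.col("radius")[div_idx],
            np.full(n_div, r_new), state.duct, state.rng.placement)
        # the mother also restarts as a newborn body with a fresh cycle time
        clock[div_idx] = 0.0
        ctime[div_idx] = cells.assign_cycle_time(p, state.rng.cycle,
                                                 size=n_div)
        rad[div_idx] = r_new
        d_tau = np.atleast_1d(cells.assign_cycle_time(p, state.rng.cycle,
                                                      size=n_div))
        new_ids = pop.add(d_pos, r_new, d_lin, d_er, d_tau, divisions=d_div)
        state.counters["proliferation"] += n_div
        state.transitions.extend(zip(
            [state.clock_h] * n_div, new_ids.tolist(),
            ["birth"] * n_div, _COMP_NAMES[d_lin].tolist(),
            ["mitosis"] * n_div))

    # (5) dedifferentiation (pre-division index space; daughters excluded)
    if p.omega_dd > 0.0 and np.any(dd_candidates):
        n_pre = len(dd_candidates)
        p_step = per_step_probability(p.omega_dd, dt,
                                      pop.col("cycle_time")[:n_pre])
        dd = dd_candidates & (state.rng.dediff.random(n_pre) < p_step)
        if np.any(dd):
            pop.col("lineage")[:n_pre][dd] = STEM
            pop.col("er")[:n_pre][dd] = ER_NA
            pop.col("divisions")[:n_pre][dd] = 0
            state.counters["dedifferentiation"] += int(dd.sum())
            _log(state, pop.col("ids")[:n_pre][dd], "progenitor", "stem",
                 "dedifferentiation")

    # (6) mechanics
    mechanics.relax_positions(pop.col("pos"), pop.col("radius"), state.duct,
                              overlap_tol=p.overlap_tol,
                              max_iter=p.relax_max_iter,
                              relax_factor=p.relax_factor)

    # (7) bookkeeping
    state.clock_h += dt
    _record(state)
    return state


def _record(state: SimulationState):
    p = state.params
    pop = state.pop
    lineage = pop.col("lineage")
    status = pop.col("status")
    er = pop.col("er")
    x = pop.col("pos")[:, 0]
    live = pop.is_live()
    n_live = int(live.sum())
    calcified = status == CALCIFIED
    row = {
        "t_h": state.clock_h,
        "t_d": state.clock_h / 24.0,
        "n_total": pop.n,
        "n_live": n_live,
        "n_stem": int((live & (lineage == STEM)).sum()),
        "n_progenitor": int((live & (lineage == PROGENITOR)).sum()),
        "n_differentiated": int((live & (lineage == DIFFERENTIATED)).sum()),
        "n_quiescent": int((status == QUIESCENT).sum()),
        "n_hypoxic": int((status == HYPOXIC).sum()),
        "n_necrotic": int((status == NECROTIC).sum()),
        "n_calcified": int(calcified.sum()),
        "n_er_pos": int((live & (er == ER_POS)).sum()),
        "n_er_neg": int((live & (er == ER_NEG)).sum()),
        "stem_pct": (100.0 * (live & (lineage == STEM)).sum() / n_live
                     if n_live else np.nan),
        "extent_um": (metrics.axial_extent(x, state.initiation_x)
                      if pop.n else np.nan),
        "calc_extent_um": metrics.calcification_extent(x[calcified]),
        "prolif_cum": state.counters["proliferation"],
        "dediff_cum": state.counters["dedifferentiation"],
        "apop_cum": state.counters["apoptosis"],
        "edge_competent": (metrics.edges_competent(
            x, lineage, status, pop.col("divisions"), p.p_max, p.edge_band)
            if pop.n else False),
        "edge_quiescent": (metrics.edges_all_quiescent(
            x, lineage, status, p.edge_band) if pop.n else False),
    }
    state.records.append(row)


def run(params: ParameterSet, seed: int, t_end_days: float,
        stop_on_arrest: bool = False) -> RunResult:
    """Run a full simulation; metrics are recorded every step (30 min).

    With ``stop_on_arrest``, the run ends early once both leading edges have
    stayed free of proliferation-competent cells for
    ``params.arrest_persistence`` days (the arrest diagnostic).
    """
    state = initialize(params, seed)
    n_steps = int(round(t_end_days * 24.0 / params.dt))
    steps_per_day = max(int(round(24.0 / params.dt)), 1)
    # early-stop scan window: long enough to hold the persistence interval
    scan = int((params.arrest_persistence + 2.0) * steps_per_day) + 1
    for k in range(1, n_steps + 1):
        step(state)
        if state.pop.n == 0:
            break
        if stop_on_arrest and k % steps_per_day == 0:
            recent = pd.DataFrame(state.records[-scan:])
            at, _ = metrics.detect_arrest(
                recent, persistence_days=params.arrest_persistence)
            if at is not None:
                break
    record = state.record_frame()
    arrest_time, criterion = metrics.detect_arrest(
        record, persistence_days=params.arrest_persistence)
    return RunResult(state, record, arrest_time, criterion)
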