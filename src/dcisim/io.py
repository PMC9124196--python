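"""Snapshot persistence, run manifests, and scripted test fixtures.

Agent snapshots are CSV (columns documented in :meth:`Population.to_dataframe`
order, positions at full float precision); field snapshots are HDF5 (one
dataset per species); the run manifest is JSON and carries everything needed
to reproduce the run bit-identically: the config hash, the root seed, the
simulated clock, counters, and the exact RNG stream states.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .cells import Population
from .engine import SimulationState
from .params import ParameterSet, RngStreams

__all__ = ["write_snapshot", "read_snapshot", "make_fixture", "FIXTURES"]

_AGENT_COLUMNS = ["id", "x", "y", "z", "radius", "lineage", "status", "er",
                  "cycle_clock", "cycle_time", "divisions", "hypoxia_h",
                  "necrosis_h", "is_tic"]


def write_snapshot(state: SimulationState, path) -> Path:
    """Persist a full simulation state under directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    df = state.pop.to_dataframe()[_AGENT_COLUMNS]
    df.to_csv(path / "agents.csv", index=False, float_format="%.17g")
    with h5py.File(path / "fields.h5", "w") as fh:
        for sp, grid in state.grids.items():
            fh.create_dataset(sp, data=grid.values)
    state.params.to_yaml(path / "config.yaml")
    manifest = {
        "version": __version__,
        "config_hash": state.params.config_hash(),
        "clock_h": state.clock_h,
        "initiation_x": state.initiation_x,
        "counters": state.counters,
        "rng": state.rng.state(),
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=int)
    return path


def read_snapshot(path) -> SimulationState:
    """Rebuild a :class:`SimulationState` written by :func:`write_snapshot`."""
    from . import fields as fields_mod
    from . import mechanics

    path = Path(path)
    for required in ("agents.csv", "manifest.json", "config.yaml"):
        if not (path / required).exists():
            raise FileNotFoundError(f"snapshot incomplete: missing {required}")
    try:
        with open(path / "manifest.json") as fh:
            manifest = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt manifest.json: {exc}") from exc
    params = ParameterSet.from_yaml(path / "config.yaml")
    try:
        df = pd.read_csv(path / "agents.csv", float_precision="round_trip")
        missing = set(_AGENT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
        pop = Population.from_dataframe(df) if len(df) else Population()
    except (ValueError, KeyError) as exc:
        raise ValueError(f"corrupt agents.csv at {path}: {exc}") from exc

    duct = mechanics.Duct(params.duct_length, params.duct_radius)
    geometry, grids = fields_mod.make_duct_grids(duct, params)
    with h5py.File(path / "fields.h5", "r") as fh:
        for sp, grid in grids.items():
            data = fh[sp][...]
            if data.shape != grid.values.shape:
                raise ValueError(f"field {sp} shape mismatch in snapshot")
            grid.values = data
    state = SimulationState(
        params=params, duct=duct, geometry=geometry, grids=grids, pop=pop,
        rng=RngStreams.from_state(manifest["rng"]),
        clock_h=float(manifest["clock_h"]),
        initiation_x=float(manifest["initiation_x"]),
        counters={k: int(v) for k, v in manifest["counters"].items()})
    return state


# --------------------------------------------------------------------------- #
# Fixtures: deterministic miniature states used across the test suite
# --------------------------------------------------------------------------- #

def _fixture_five_tic_init():
    from . import engine
    return engine.initialize(ParameterSet(duct_length=200.0,
                                          duct_inner_diameter=100.0), seed=0)

def _fixture_two_overlapping_cells():
    from .cells import ER_POS, PROGENITOR
    pop = Population()
    pop.add(np.array([[0.0, 0.0, 0.0], [8.0, 0.0, 0.0]]), 5.0, PROGENITOR,
            ER_POS, 20.0)
    return pop

def _fixture_edge_all_differentiated():
    """A lesion whose edge bands hold only terminally differentiated cells."""
    from .cells import DIFFERENTIATED, ER_POS, PROGENITOR
    pop = Population()
    xs = np.linspace(-100.0, 100.0, 21)
    pos = np.column_stack([xs, np.zeros_like(xs), np.zeros_like(xs)])
    lineage = np.where(np.abs(xs) > 60.0, DIFFERENTIATED, PROGENITOR)
    pop.add(pos, 5.0, lineage, ER_POS, 20.0)
    return pop

def _fixture_arrested_duct():
    """Per-step record for which arrest fires immediately."""
    t = np.arange(0, 6 * 24, 12) / 24.0
    return pd.DataFrame({"t_d": t, "extent_um": np.full_like(t, 80.0),
                         "edge_competent": np.zeros_like(t, dtype=bool),
                         "stem_pct": np.zeros_like(t)})

def _fixture_hypoxic_core():
    """Dense axial plug of cells; its core O2 falls below the wall value."""
    from .cells import ER_POS, PROGENITOR
    pop = Population()
    rng = np.random.default_rng(7)
    n = 400
    pos = np.column_stack([rng.uniform(-40, 40, n),
                           rng.uniform(-30, 30, n),
                           rng.uniform(-30, 30, n)])
    pop.add(pos, 5.0, PROGENITOR, ER_POS, 20.0)
    return pop

def _fixture_mm_curve():
    """Noiseless dose–response pairs from the reference saturation curve."""
    x = np.array([0.0001, 0.00025, 0.0005, 0.001, 0.0025, 0.005, 0.0075, 0.01])
    return x, 13.74 * x / (0.0262 + x)


FIXTURES = {
    "five-tic-init": _fixture_five_tic_init,
    "two-overlapping-cells": _fixture_two_overlapping_cells,
    "edge-all-differentiated": _fixture_edge_all_differentiated,
    "arrested-duct": _fixture_arrested_duct,
    "hypoxic-core": _fixture_hypoxic_core,
    "mm-curve": _fixture_mm_curve,
}


def make_fixture(name: str):
    """Deterministic miniature states for tests; see :data:`FIXTURES`."""
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"known: {sorted(FIXTURES)}") from None
    return factory()
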