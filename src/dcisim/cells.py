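"""Cell agents: the phenotype state machine and its vectorized population.

The hierarchy has three lineage compartments — stem (including the founding
TICs), progenitor, terminally differentiated — crossed with a status overlay
(active, quiescent, hypoxic, necrotic, calcified).  A cell's reported
phenotype is its status when the status is not "active", otherwise its
lineage; this matches the one-axis phenotype vocabulary used throughout the
metrics.

Allowed transitions are the differentiation hierarchy (stem -> progenitor
daughters -> differentiated), the reverse dedifferentiation edge
(progenitor -> stem), reversible quiescence and hypoxia, the irreversible
hypoxia -> necrosis -> calcification track, and removal by apoptosis.
Terminally differentiated cells never proliferate and never dedifferentiate;
stem cells never dedifferentiate (there is a single stem phenotype); cells
may not dedifferentiate on a step in which they divide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet, per_step_probability, sample_lognormal_bounded

__all__ = [
    "STEM", "PROGENITOR", "DIFFERENTIATED",
    "ACTIVE", "QUIESCENT", "HYPOXIC", "NECROTIC", "CALCIFIED",
    "ER_NA", "ER_POS", "ER_NEG",
    "CellAgent", "Population", "ALLOWED_TRANSITIONS",
    "assign_cycle_time", "proliferation_gate", "choose_daughter_phenotype",
    "attempt_dedifferentiation", "apoptosis_check", "quiescence_update",
    "hypoxia_update", "phenotype_name",
]

# lineage codes
STEM, PROGENITOR, DIFFERENTIATED = 0, 1, 2
# status codes
ACTIVE, QUIESCENT, HYPOXIC, NECROTIC, CALCIFIED = 0, 1, 2, 3, 4
# estrogen receptor status
ER_NA, ER_POS, ER_NEG = 0, 1, 2

_LINEAGE_NAMES = {STEM: "stem", PROGENITOR: "progenitor",
                  DIFFERENTIATED: "differentiated"}
_STATUS_NAMES = {QUIESCENT: "quiescent", HYPOXIC: "hypoxic",
                 NECROTIC: "necrotic", CALCIFIED: "calcified"}
_ER_NAMES = {ER_NA: "na", ER_POS: "er+", ER_NEG: "er-"}
_ER_CODES = {v: k for k, v in _ER_NAMES.items()}


def phenotype_name(lineage: int, status: int) -> str:
    """Composite phenotype label of one cell."""
    if status != ACTIVE:
        return _STATUS_NAMES[status]
    return _LINEAGE_NAMES[lineage]


#: every phenotype edge the engine may ever log (plus birth and apoptosis
#: pseudo-states); the transition log is asserted against this set.
ALLOWED_TRANSITIONS = frozenset({
    ("birth", "stem"), ("birth", "progenitor"), ("birth", "differentiated"),
    ("stem", "quiescent"), ("stem", "hypoxic"), ("stem", "apoptotic"),
    ("progenitor", "stem"),            # dedifferentiation
    ("progenitor", "differentiated"),  # terminal differentiation at the cap
    ("progenitor", "quiescent"), ("progenitor", "hypoxic"),
    ("progenitor", "apoptotic"),
    ("quiescent", "stem"), ("quiescent", "progenitor"),
    ("quiescent", "hypoxic"), ("quiescent", "apoptotic"),
    ("differentiated", "hypoxic"), ("differentiated", "apoptotic"),
    ("hypoxic", "stem"), ("hypoxic", "progenitor"),
    ("hypoxic", "differentiated"), ("hypoxic", "necrotic"),
    ("hypoxic", "apoptotic"),
    ("necrotic", "calcified"),
})


# --------------------------------------------------------------------------- #
# Per-cell view
# --------------------------------------------------------------------------- #

@dataclass
class CellAgent:
    """One discrete cell (scalar view; the engine stores populations)."""

    id: int
    pos: np.ndarray
    radius: float
    lineage: int
    status: int
    er: int
    cycle_clock: float
    cycle_time: float
    divisions: int = 0
    hypoxia_h: float = 0.0
    necrosis_h: float = 0.0
    is_tic: bool = False

    @property
    def phenotype(self) -> str:
        return phenotype_name(self.lineage, self.status)


class Population:
    """Structure-of-arrays store of all agents in one simulation.

    Rows are stable during a step; removals compact the arrays and return the
    keep-mask so per-agent scratch arrays can be compacted alongside.
    """

    _F8 = ("radius", "cycle_clock", "cycle_time", "hypoxia_h", "necrosis_h")
    _I = ("lineage", "status", "er", "divisions")

    def __init__(self, capacity: int = 256):
        cap = max(int(capacity), 1)
        self.n = 0
        self._next_id = 0
        self.ids = np.zeros(cap, dtype=np.int64)
        self.pos = np.zeros((cap, 3))
        for name in self._F8:
            setattr(self, name, np.zeros(cap))
        for name in self._I:
            setattr(self, name, np.zeros(cap, dtype=np.int16))
        self.is_tic = np.zeros(cap, dtype=bool)

    # -- storage --------------------------------------------------------- #

    def _grow(self, need: int):
        cap = len(self.ids)
        if need <= cap:
            return
        new = max(2 * cap, need)
        self.ids = np.resize(self.ids, new)
        self.pos = np.vstack([self.pos, np.zeros((new - cap, 3))])
        for name in self._F8:
            setattr(self, name, np.resize(getattr(self, name), new))
        for name in self._I:
            setattr(self, name, np.resize(getattr(self, name), new))
        self.is_tic = np.resize(self.is_tic, new)

    def add(self, pos, radius, lineage, er, cycle_time, cycle_clock=0.0,
            divisions=0, status=ACTIVE, is_tic=False) -> np.ndarray:
        pos = np.atleast_2d(pos)
        k = len(pos)
        self._grow(self.n + k)
        sl = slice(self.n, self.n + k)
        new_ids = np.arange(self._next_id, self._next_id + k, dtype=np.int64)
        self.ids[sl] = new_ids
        self.pos[sl] = pos
        self.radius[sl] = radius
        self.lineage[sl] = lineage
        self.status[sl] = status
        self.er[sl] = er
        self.cycle_clock[sl] = cycle_clock
        self.cycle_time[sl] = cycle_time
        self.divisions[sl] = divisions
        self.hypoxia_h[sl] = 0.0
        self.necrosis_h[sl] = 0.0
        self.is_tic[sl] = is_tic
        self._next_id += k
        self.n += k
        return new_ids

    def remove(self, mask: np.ndarray) -> np.ndarray:
        """Drop rows where ``mask`` is True; returns the keep-mask."""
        keep = ~np.asarray(mask, dtype=bool)
        k = int(keep.sum())
        idx = np.nonzero(keep)[0]
        self.ids[:k] = self.ids[:self.n][idx]
        self.pos[:k] = self.pos[:self.n][idx]
        for name in self._F8 + self._I + ("is_tic",):
            arr = getattr(self, name)
            arr[:k] = arr[:self.n][idx]
        self.n = k
        return keep

    # -- views ----------------------------------------------------------- #

    def col(self, name: str) -> np.ndarray:
        return getattr(self, name)[:self.n]

    def view(self):
        """Dict of active-row views (shared memory)."""
        return {name: self.col(name) for name in
                ("ids", "pos") + self._F8 + self._I + ("is_tic",)}

    def is_live(self) -> np.ndarray:
        """Live cells: everything except necrotic and calcified bodies."""
        s = self.col("status")
        return (s != NECROTIC) & (s != CALCIFIED)

    def agent(self, i: int) -> CellAgent:
        return CellAgent(
            id=int(self.col("ids")[i]), pos=self.col("pos")[i].copy(),
            radius=float(self.col("radius")[i]),
            lineage=int(self.col("lineage")[i]),
            status=int(self.col("status")[i]), er=int(self.col("er")[i]),
            cycle_clock=float(self.col("cycle_clock")[i]),
            cycle_time=float(self.col("cycle_time")[i]),
            divisions=int(self.col("divisions")[i]),
            hypoxia_h=float(self.col("hypoxia_h")[i]),
            necrosis_h=float(self.col("necrosis_h")[i]),
            is_tic=bool(self.col("is_tic")[i]))

    def to_dataframe(self):
        import pandas as pd
        v = self.view()
        return pd.DataFrame({
            "id": v["ids"], "x": v["pos"][:, 0], "y": v["pos"][:, 1],
            "z": v["pos"][:, 2], "radius": v["radius"],
            "lineage": [_LINEAGE_NAMES[c] for c in v["lineage"]],
            "status": ["active" if c == ACTIVE else _STATUS_NAMES[c]
                       for c in v["status"]],
            "er": [_ER_NAMES[c] for c in v["er"]],
            "cycle_clock": v["cycle_clock"], "cycle_time": v["cycle_time"],
            "divisions": v["divisions"], "hypoxia_h": v["hypoxia_h"],
            "necrosis_h": v["necrosis_h"], "is_tic": v["is_tic"],
        })

    @classmethod
    def from_dataframe(cls, df) -> "Population":
        lin_codes = {v: k for k, v in _LINEAGE_NAMES.items()}
        st_codes = {v: k for k, v in _STATUS_NAMES.items()}
        st_codes["active"] = ACTIVE
        pop = cls(capacity=max(len(df), 1))
        n = len(df)
        pop.n = n
        pop.ids[:n] = df["id"].to_numpy(dtype=np.int64)
        pop.pos[:n] = df[["x", "y", "z"]].to_numpy(dtype=float)
        pop.radius[:n] = df["radius"].to_numpy(dtype=float)
        pop.lineage[:n] = [lin_codes[s] for s in df["lineage"]]
        pop.status[:n] = [st_codes[s] for s in df["status"]]
        pop.er[:n] = [_ER_CODES[s] for s in df["er"]]
        pop.cycle_clock[:n] = df["cycle_clock"].to_numpy(dtype=float)
        pop.cycle_time[:n] = df["cycle_time"].to_numpy(dtype=float)
        pop.divisions[:n] = df["divisions"].to_numpy(dtype=int)
        pop.hypoxia_h[:n] = df["hypoxia_h"].to_numpy(dtype=float)
        pop.necrosis_h[:n] = df["necrosis_h"].to_numpy(dtype=float)
        pop.is_tic[:n] = df["is_tic"].to_numpy(dtype=bool)
        pop._next_id = int(pop.ids[:n].max()) + 1 if n else 0
        return pop


# --------------------------------------------------------------------------- #
# Vectorized state-machine operations (scalar wrappers follow each)
# --------------------------------------------------------------------------- #

def assign_cycle_time(params: ParameterSet, rng: np.random.Generator,
                      size=None):
    """Bounded-lognormal cycle time(s): mean tau_p, floored at tau_min."""
    return sample_lognormal_bounded(params.tau_p, params.tau_sigma,
                                    params.tau_min, rng, size=size,
                                    convention=params.lognormal_convention)


def er_gate_mask(lineage, er, e2, fgf, params: ParameterSet):
    """Signalling gate: ER+ need estrogen, ER- need FGF, stems per config."""
    lineage = np.asarray(lineage)
    er = np.asarray(er)
    e2 = np.asarray(e2, dtype=float)
    fgf = np.asarray(fgf, dtype=float)
    gate = np.ones(lineage.shape, dtype=bool)
    if params.stem_er_gated:
        gate &= np.where(lineage == STEM, e2 >= params.theta_e, True)
    gate &= np.where((lineage != STEM) & (er == ER_POS),
                     e2 >= params.theta_e, True)
    gate &= np.where((lineage != STEM) & (er == ER_NEG),
                     fgf >= params.theta_fgf, True)
    return gate


def proliferation_gate(cell: CellAgent, local_e2: float, local_fgf: float,
                       local_density: float, params: ParameterSet) -> bool:
    """May this mature stem/progenitor divide now?

    Requires: not density-quiesced, the ER-appropriate signalling threshold
    met, and (progenitors) the division cap not yet reached.
    """
    if cell.status not in (ACTIVE, QUIESCENT) or cell.lineage not in (
            STEM, PROGENITOR):
        raise ValueError("proliferation gate applies to stem/progenitor cells")
    if local_density >= params.theta_q:
        return False
    gate = bool(er_gate_mask(np.array([cell.lineage]), np.array([cell.er]),
                             np.array([local_e2]), np.array([local_fgf]),
                             params)[0])
    if cell.lineage == PROGENITOR and cell.divisions >= params.p_max:
        return False
    return gate


def choose_daughter_phenotypes(mother_lineage, mother_er,
                               params: ParameterSet,
                               rng: np.random.Generator):
    """Vectorized mitosis phenotype draw.

    Stem mothers: daughter is stem with probability ``omega_sc``, otherwise a
    progenitor assigned ER+ with probability ``omega_sc_pm`` (else ER-).
    Progenitor mothers: daughter is a progenitor with probability ``omega_p``
    (else terminally differentiated), inheriting the mother's ER status.
    """
    mother_lineage = np.asarray(mother_lineage)
    mother_er = np.asarray(mother_er)
    k = len(mother_lineage)
    d_lin = np.empty(k, dtype=np.int16)
    d_er = np.empty(k, dtype=np.int16)
    u_branch = rng.random(k)
    u_er = rng.random(k)
    stem_m = mother_lineage == STEM
    # stem mothers
    is_stem_d = stem_m & (u_branch < params.omega_sc)
    d_lin[is_stem_d] = STEM
    d_er[is_stem_d] = ER_NA
    prog_d = stem_m & ~is_stem_d
    d_lin[prog_d] = PROGENITOR
    d_er[prog_d] = np.where(u_er[prog_d] < params.omega_sc_pm, ER_POS, ER_NEG)
    # progenitor mothers
    pm = ~stem_m
    sym = pm & (u_branch < params.omega_p)
    d_lin[sym] = PROGENITOR
    d_lin[pm & ~sym] = DIFFERENTIATED
    d_er[pm] = mother_er[pm]
    return d_lin, d_er


def choose_daughter_phenotype(mother: CellAgent, params: ParameterSet,
                              rng: np.random.Generator) -> tuple[str, str]:
    """Scalar wrapper; returns (lineage name, er name) for the daughter."""
    lin, er = choose_daughter_phenotypes(np.array([mother.lineage]),
                                         np.array([mother.er]), params, rng)
    return _LINEAGE_NAMES[int(lin[0])], _ER_NAMES[int(er[0])]


def dediff_eligible_mask(lineage, status, dividing):
    """Progenitors, currently active, not dividing this step."""
    return ((np.asarray(lineage) == PROGENITOR)
            & (np.asarray(status) == ACTIVE)
            & ~np.asarray(dividing, dtype=bool))


def attempt_dedifferentiation(cell: CellAgent, params: ParameterSet,
                              rng: np.random.Generator,
                              dividing_this_step: bool) -> bool:
    """Stochastic progenitor -> stem reversion for one cell (scalar path).

    Quiescent, hypoxic, differentiated and stem cells are ineligible, as are
    cells dividing on this step.  The per-step Bernoulli probability is
    derived from the per-cell-cycle probability ``omega_dd`` and the cell's
    own cycle time, so the per-cycle rate matches the configured value.
    """
    if not dediff_eligible_mask([cell.lineage], [cell.status],
                                [dividing_this_step])[0]:
        return False
    if params.omega_dd == 0.0:
        return False
    p = per_step_probability(params.omega_dd, params.dt, cell.cycle_time)
    if rng.random() < p:
        cell.lineage = STEM
        cell.er = ER_NA
        cell.divisions = 0
        return True
    return False


def apoptosis_eligible_mask(lineage, status, scope: str = "non_cycling"):
    """Which live cells face the per-step apoptosis draw.

    Death probabilities are phenotype dependent: under the default
    ``non_cycling`` scope, apoptosis acts on the quiescent, hypoxic and
    terminally differentiated compartments, while actively cycling
    stem/progenitor cells evade it (apoptosis evasion by proliferating
    cancer cells).  ``scope="all"`` exposes every live cell.
    """
    lineage = np.asarray(lineage)
    status = np.asarray(status)
    live = (status != NECROTIC) & (status != CALCIFIED)
    if scope == "all":
        return live
    return live & ((status == QUIESCENT) | (status == HYPOXIC)
                   | (lineage == DIFFERENTIATED))


def apoptosis_check(cell: CellAgent, params: ParameterSet,
                    rng: np.random.Generator) -> bool:
    """Per-step apoptosis Bernoulli for one live cell."""
    if cell.status in (NECROTIC, CALCIFIED):
        raise ValueError("apoptosis applies to live cells only")
    if not apoptosis_eligible_mask([cell.lineage], [cell.status],
                                   params.apoptosis_scope)[0]:
        return False
    return bool(rng.random() < params.omega_apop)


def quiescence_update(cell: CellAgent, local_occupancy: float,
                      params: ParameterSet) -> str:
    """Density-triggered reversible quiescence for one stem/progenitor."""
    if cell.lineage not in (STEM, PROGENITOR) or cell.status not in (
            ACTIVE, QUIESCENT):
        raise ValueError("quiescence applies to cycling stem/progenitor cells")
    cell.status = QUIESCENT if local_occupancy >= params.theta_q else ACTIVE
    return cell.phenotype


def hypoxia_update(cell: CellAgent, local_o2: float,
                   params: ParameterSet) -> str:
    """Hypoxia clock for one cell; necrosis and calcification are permanent."""
    dt = params.dt
    if cell.status == CALCIFIED:
        return cell.phenotype
    if cell.status == NECROTIC:
        cell.necrosis_h += dt
        if cell.necrosis_h > params.t_calcify:
            cell.status = CALCIFIED
        return cell.phenotype
    if local_o2 < params.hypoxia_threshold:
        cell.status = HYPOXIC
        cell.hypoxia_h += dt
        if cell.hypoxia_h > params.t_necrosis:
            cell.status = NECROTIC
            cell.necrosis_h = 0.0
    elif cell.status == HYPOXIC:
        cell.status = ACTIVE
        cell.hypoxia_h = 0.0
    return cell.phenotype
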