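"""Run outputs: axial extents, advance rates, arrest and edge diagnostics.

All metrics are recomputable from snapshots (agent tables and per-step
records) alone; nothing depends on hidden engine state.  The lesion advances
away from the initiation site in both axial directions, so extent-type
metrics are the *summed* axial span on both sides of the initiation site.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cells import CALCIFIED, NECROTIC, PROGENITOR, QUIESCENT, STEM

__all__ = ["axial_extent", "advance_rate", "detect_arrest", "stem_fraction",
           "calcification_metrics", "calcification_extent",
           "leading_edge_quiescence_time", "edges_competent",
           "edges_all_quiescent", "run_outputs"]


def axial_extent(x: np.ndarray, initiation_x: float = 0.0) -> float:
    """Summed axial advance in both directions from the initiation site [µm]."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("axial extent of an empty population is undefined")
    return float((x.max() - initiation_x) + (initiation_x - x.min()))


def advance_rate(t_days: np.ndarray, extent_um: np.ndarray,
                 t_min: float = 0.0, t_max: float = np.inf) -> float:
    """Least-squares slope of extent vs time [µm/day] over a window."""
    t = np.asarray(t_days, dtype=float)
    e = np.asarray(extent_um, dtype=float)
    sel = (t >= t_min) & (t <= t_max) & np.isfinite(e)
    if sel.sum() < 2 or np.ptp(t[sel]) == 0:
        raise ValueError("advance rate needs >= 2 snapshots spanning time")
    return float(np.polyfit(t[sel], e[sel], 1)[0])


def stem_fraction(lineage: np.ndarray, status: np.ndarray) -> float:
    """Stem cells as a percentage of the live population.

    Necrotic and calcified bodies are excluded from the denominator.
    """
    lineage = np.asarray(lineage)
    status = np.asarray(status)
    live = (status != NECROTIC) & (status != CALCIFIED)
    n_live = int(live.sum())
    if n_live == 0:
        raise ValueError("stem fraction of an empty live population")
    return 100.0 * float((live & (lineage == STEM)).sum()) / n_live


def calcification_extent(x_calcified: np.ndarray) -> float:
    x = np.asarray(x_calcified, dtype=float)
    return float(x.max() - x.min()) if x.size else 0.0


def calcification_metrics(x: np.ndarray, status: np.ndarray) -> tuple[float, int]:
    """(axial span of calcified agents [µm], calcified count)."""
    cal = np.asarray(status) == CALCIFIED
    return calcification_extent(np.asarray(x, dtype=float)[cal]), int(cal.sum())


def _edge_bands(x: np.ndarray, band: float) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = x.min(), x.max()
    return x <= lo + band, x >= hi - band


def edges_competent(x, lineage, status, divisions, p_max: int,
                    band: float) -> bool:
    """Do *both* leading edges still hold proliferation-competent cells?

    Competent: a live stem cell, or a live progenitor below the division cap
    (quiescent cells count — they may re-enter the cycle).  Returns False
    when either edge band has none, i.e. the arrest condition of that state.
    """
    x = np.asarray(x, dtype=float)
    lineage = np.asarray(lineage)
    status = np.asarray(status)
    divisions = np.asarray(divisions)
    live = (status != NECROTIC) & (status != CALCIFIED)
    competent = live & ((lineage == STEM)
                        | ((lineage == PROGENITOR) & (divisions < p_max)))
    low, high = _edge_bands(x, band)
    return bool(np.any(competent & low) and np.any(competent & high))


def edges_all_quiescent(x, lineage, status, band: float) -> bool:
    """Are all proliferative-phenotype cells in both edge bands quiescent?"""
    x = np.asarray(x, dtype=float)
    lineage = np.asarray(lineage)
    status = np.asarray(status)
    live = (status != NECROTIC) & (status != CALCIFIED)
    prolif = live & ((lineage == STEM) | (lineage == PROGENITOR))
    quiet = prolif & (status == QUIESCENT)
    low, high = _edge_bands(x, band)
    for b in (low, high):
        if not np.any(prolif & b):       # no proliferative cells at this edge
            continue
        if np.any(prolif & b & ~(status == QUIESCENT)):
            return False
    return bool(np.any(prolif & (low | high)))


def detect_arrest(record: pd.DataFrame, persistence_days: float = 2.0,
                  flat_eps_um: float = 10.0,
                  growth_eps_um_per_day: float = 1.0,
                  incompetent_fraction: float = 0.9) -> tuple:
    """Arrest time [days] from a per-step record, or (None, None).

    Arrest is *terminal* cessation of progression; a transient stall that
    later recovers is not arrest.  Three criteria, in priority order:

    * ``extinction`` — the live population reaches zero; the onset is the
      start of the final unbroken incompetent stretch.
    * ``edge-incompetent`` — an incompetence onset from which the remainder
      of the record stays at least ``incompetent_fraction`` free of
      proliferation-competent cells in both leading-edge bands (tolerating
      brief flickers as a melting shell exposes interior cells), spanning
      at least ``persistence_days``, with extent growth below
      ``growth_eps_um_per_day`` afterwards.
    * ``flat-extent`` — the furthest-reach extent never again grows by
      ``flat_eps_um`` (about one cell diameter) after the onset, which
      precedes the record end by at least ``persistence_days``.

    Returns ``(time, criterion)`` with the name of the test that fired.
    """
    if len(record) == 0:
        return None, None
    t = record["t_d"].to_numpy()
    ext_all = record["extent_um"].to_numpy(dtype=float)
    if "edge_competent" in record:
        inc = ~record["edge_competent"].to_numpy(dtype=bool)
        if "n_live" in record:
            dead = record["n_live"].to_numpy() == 0
            if dead.any():
                # earliest incompetence holding continuously to extinction
                k = int(np.argmax(dead))
                gaps = np.nonzero(~inc[:k + 1])[0]
                start = int(gaps[-1]) + 1 if len(gaps) else 0
                return float(t[min(start, k)]), "extinction"
        n = len(t)
        tail_inc = np.cumsum(inc[::-1])[::-1]  # incompetent counts from i on
        onsets = np.nonzero(inc & ~np.roll(inc, 1))[0]
        if inc[0]:
            onsets = np.unique(np.concatenate([[0], onsets]))
        for i in onsets:
            span = t[-1] - t[i]
            if span < persistence_days:
                break
            if tail_inc[i] / (n - i) < incompetent_fraction:
                continue
            growth = ext_all[-1] - ext_all[i]
            if not np.isfinite(growth) or growth < growth_eps_um_per_day * span:
                return float(t[i]), "edge-incompetent"
    # terminal flat-reach: the furthest-reach curve never grows again
    reach = np.fmax.accumulate(np.where(np.isfinite(ext_all), ext_all,
                                        -np.inf))
    if np.isfinite(reach[-1]):
        flat = ((reach[-1] - reach) < flat_eps_um) & \
            (t <= t[-1] - persistence_days)
        idx = np.nonzero(flat)[0]
        if idx.size:
            return float(t[idx[0]]), "flat-extent"
    return None, None


def leading_edge_quiescence_time(record: pd.DataFrame):
    """First time [days] both edge bands' proliferative cells are all quiescent."""
    if "edge_quiescent" not in record or len(record) == 0:
        return None
    flags = record["edge_quiescent"].to_numpy(dtype=bool)
    idx = np.nonzero(flags)[0]
    return float(record["t_d"].iloc[idx[0]]) if idx.size else None


def run_outputs(record: pd.DataFrame, arrest_time_d=None,
                window_t_min: float = 0.0) -> dict:
    """Scalar outputs of one run, truncated at arrest when given.

    The outputs mirror the quantities examined in the perturbation studies:
    advance rate, proliferation events per day, calcification extent and
    count, time to leading-edge quiescence, and final (or at-arrest) cell
    counts by class.
    """
    rec = record
    if arrest_time_d is not None:
        rec = record[record["t_d"] <= arrest_time_d]
        if len(rec) == 0:
            rec = record.iloc[:1]
    last = rec.iloc[-1]
    t = rec["t_d"].to_numpy()
    out = {"t_end_d": float(last["t_d"]), "arrest_time_d": arrest_time_d}
    # invasion is irreversible: advance is measured on the furthest reach to
    # date, so the series is monotone even when the cell mass later regresses
    reach = np.fmax.accumulate(rec["extent_um"].to_numpy(dtype=float))
    try:
        out["advance_rate_um_d"] = advance_rate(t, reach, t_min=window_t_min)
    except ValueError:
        out["advance_rate_um_d"] = np.nan
    span = max(float(last["t_d"]), 1e-9)
    out["prolif_per_day"] = float(last["prolif_cum"]) / span
    out["calc_extent_um"] = float(last["calc_extent_um"])
    out["n_calcified"] = int(last["n_calcified"])
    out["quiescence_time_d"] = leading_edge_quiescence_time(rec)
    out["n_total"] = int(last["n_live"])
    out["n_er_pos"] = int(last["n_er_pos"])
    out["n_er_neg"] = int(last["n_er_neg"])
    out["stem_pct"] = float(last["stem_pct"])
    return out
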