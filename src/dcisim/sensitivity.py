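"""Perturbation studies: LHS designs, multivariate regression, response fits.

Three study designs are supported, mirroring the staged analysis of the
model:

* ``no_dediff_global`` — Latin hypercube perturbation of the 13 globally
  varied parameters with the dedifferentiation pathway off; outputs are
  truncated at the time of growth arrest.
* ``dediff_global`` — the reduced, most-influential parameter set (plus the
  dedifferentiation probability over its biological range) with the pathway
  on; no arrest truncation.
* ``dediff_local`` — only the dedifferentiation probability is swept
  (triplicate per value, finer increments at the low end, everything else at
  baseline); advance-rate and stem-density analyses use the steady-state
  window t >= 15 days of a 35-day horizon.

The regression layer is ordinary least squares with two-sided t tests
(p < 0.05 significant, deliberately uncorrected) and standardized effect
magnitudes |beta_j * SD(x_j) / SD(y)| for Pareto ranking.  The local sweep
is summarized by a Michaelis–Menten fit of advance rate vs per-cycle
dedifferentiation probability and a through-origin linear fit of the daily
change in stem percent density vs the probability in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from scipy.stats import qmc

from . import engine, metrics
from .params import (DEDIFF_STUDY_PARAMS, GLOBAL_STUDY_PARAMS, ParameterSet,
                     ParameterSpec, spec_ppf, table1_specs)

__all__ = ["ScaleProfile", "DESK_PROFILE", "FULL_PROFILE", "RegressionResult",
           "ResponseFit", "lhs_design", "multivariate_ols",
           "fit_michaelis_menten", "fit_linear_origin", "run_study",
           "sweep_omega_dd", "analyze_local_sweep",
           "DEFAULT_OMEGA_DD_SWEEP_PCT"]

#: local-sweep grid in percent per cell cycle, finer at the low end
DEFAULT_OMEGA_DD_SWEEP_PCT = (0.01, 0.025, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0)


# --------------------------------------------------------------------------- #
# Profiles
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ScaleProfile:
    """Geometry/horizon bundle applied on top of a base parameter set.

    ``overrides`` carries scale-dependent structural constants; the desk
    profile raises the per-cell oxygen uptake by the squared radius ratio so
    the dimensionless uptake/diffusion balance (and hence the radial O2
    profile and the hypoxic core) of the published geometry is preserved in
    the narrower lumen.
    """

    name: str
    duct_length: float
    duct_inner_diameter: float
    grid_h: float
    t_end_days: float
    analysis_t_min: float = 15.0  #: steady-state window start [days]
    overrides: tuple = ()         #: ((param, value), ...) applied on top

    def apply(self, params: ParameterSet) -> ParameterSet:
        return params.replace(duct_length=self.duct_length,
                              duct_inner_diameter=self.duct_inner_diameter,
                              grid_h=self.grid_h, **dict(self.overrides))


#: desk-scale profile used by the bundled studies and their tests
DESK_PROFILE = ScaleProfile("desk", duct_length=400.0,
                            duct_inner_diameter=80.0, grid_h=10.0,
                            t_end_days=35.0,
                            overrides=(("kappa_o2", 1875.0),))

#: the published geometry (1 mm duct, 200 µm lumen)
FULL_PROFILE = ScaleProfile("full", duct_length=1000.0,
                            duct_inner_diameter=200.0, grid_h=10.0,
                            t_end_days=35.0)

PROFILES = {"desk": DESK_PROFILE, "full": FULL_PROFILE}


# --------------------------------------------------------------------------- #
# LHS
# --------------------------------------------------------------------------- #

def lhs_design(specs: dict[str, ParameterSpec] | list[ParameterSpec],
               n: int, seed: int) -> pd.DataFrame:
    """Latin hypercube design: one draw per equal-probability stratum.

    Every column is stratified on the quantile scale of its declared
    distribution (so lognormal columns are stratified in probability, not in
    value) and independently permuted across rows.
    """
    if n < 2:
        raise ValueError("an LHS design needs n >= 2")
    if isinstance(specs, dict):
        items = list(specs.items())
    else:
        items = [(s.name, s) for s in specs]
    sampler = qmc.LatinHypercube(d=len(items), seed=seed)
    u = sampler.random(n)
    cols = {name: spec_ppf(spec, u[:, j])
            for j, (name, spec) in enumerate(items)}
    return pd.DataFrame(cols)


# --------------------------------------------------------------------------- #
# Regression
# --------------------------------------------------------------------------- #

@dataclass
class RegressionResult:
    """One multivariate OLS fit: R², per-parameter effects and p values."""

    output: str
    r_squared: float
    table: pd.DataFrame  #: index = parameter; columns coef, p_value, std_effect
    alpha: float = 0.05

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["p_value"] < self.alpha])


def multivariate_ols(design: pd.DataFrame, y: np.ndarray,
                     output_name: str = "output") -> RegressionResult:
    """OLS of one output on all perturbed parameters simultaneously."""
    y = np.asarray(y, dtype=float)
    X = design.to_numpy(dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need more runs than parameters (+ intercept)")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < k + 1:
        raise ValueError("rank-deficient design matrix")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    sd_y = y.std(ddof=1)
    coefs = model.params[1:]
    std_eff = (np.abs(coefs * X.std(axis=0, ddof=1) / sd_y)
               if sd_y > 0 else np.zeros(k))
    table = pd.DataFrame({"coef": coefs, "p_value": model.pvalues[1:],
                          "std_effect": std_eff}, index=list(design.columns))
    return RegressionResult(output=output_name,
                            r_squared=float(model.rsquared), table=table)


# --------------------------------------------------------------------------- #
# Response-surface fits for the local sweep
# --------------------------------------------------------------------------- #

@dataclass
class ResponseFit:
    """Michaelis–Menten or through-origin linear summary of a dose response."""

    kind: str                 # "michaelis-menten" | "linear-origin"
    params: dict
    r_squared: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "michaelis-menten":
            return (self.params["v_max"] * x
                    / (self.params["k_m"] + x))
        return self.params["slope"] * x


def _r2(y, yhat, about_zero=False):
    y = np.asarray(y, dtype=float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum(y ** 2) if about_zero
                   else np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def fit_michaelis_menten(x, y) -> ResponseFit:
    """Nonlinear least squares of ``y = v_max * x / (k_m + x)``.

    Multi-start over a grid of K_M initializations; raises on
    non-convergence with diagnostics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("Michaelis-Menten fit needs >= 3 distinct x values")

    def mm(x_, vmax, km):
        return vmax * x_ / (km + x_)

    v0 = max(float(np.max(y)), 1e-12)
    x_scale = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0
    best = None
    errors = []
    for km0 in (0.1 * x_scale, x_scale, 10.0 * x_scale, 100.0 * x_scale):
        try:
            popt, _ = curve_fit(mm, x, y, p0=[v0, km0],
                                bounds=([0.0, 1e-12], [np.inf, np.inf]),
                                maxfev=20000)
        except RuntimeError as exc:  # pragma: no cover - depends on data
            errors.append(str(exc))
            continue
        sse = float(np.sum((y - mm(x, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:  # pragma: no cover
        raise RuntimeError("Michaelis-Menten fit did not converge: "
                           + "; ".join(errors))
    vmax, km = best[1]
    return ResponseFit("michaelis-menten",
                       {"v_max": float(vmax), "k_m": float(km)},
                       _r2(y, mm(x, vmax, km)))


def fit_linear_origin(x, y) -> ResponseFit:
    """Zero-intercept least squares: slope = sum(xy)/sum(x²); R² about zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("through-origin fit needs >= 2 points")
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("through-origin fit undefined for all-zero x")
    slope = float(np.sum(x * y) / sxx)
    return ResponseFit("linear-origin", {"slope": slope},
                       _r2(y, slope * x, about_zero=True))


# --------------------------------------------------------------------------- #
# Studies
# --------------------------------------------------------------------------- #

@dataclass
class StudyResult:
    study: str
    design: pd.DataFrame        #: one row per run (parameter draws + seed)
    runs: pd.DataFrame          #: per-run scalar outputs
    regressions: dict = dfield(default_factory=dict)
    fits: dict = dfield(default_factory=dict)
    records: list = dfield(default_factory=list)  #: per-run metric frames


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def _params_from_row(base: ParameterSet, row: pd.Series) -> ParameterSet:
    kwargs = {}
    for name, val in row.items():
        if name in ("seed", "run", "replicate"):
            continue
        kwargs[name] = int(val) if name == "p_max" else float(val)
    return base.replace(**kwargs)


def _study_outputs(result: engine.RunResult, truncate_at_arrest: bool,
                   t_min: float = 0.0) -> dict:
    arrest = result.arrest_time_d if truncate_at_arrest else None
    out = metrics.run_outputs(result.record, arrest_time_d=arrest,
                              window_t_min=t_min)
    out["arrest_time_d"] = result.arrest_time_d
    out["arrested"] = result.arrest_time_d is not None
    return out


def run_study(study_id: str, n_runs: int, seed: int,
              profile: ScaleProfile = DESK_PROFILE,
              base_params: ParameterSet | None = None,
              keep_records: bool = False,
              sweep_pct=DEFAULT_OMEGA_DD_SWEEP_PCT,
              n_replicates: int = 3) -> StudyResult:
    """Execute one of the three perturbation studies.

    ``n_runs`` is the LHS size for the global studies and is ignored by the
    local sweep (which runs ``len(sweep_pct) * n_replicates`` simulations).
    """
    base = (base_params or ParameterSet()).validate()
    base = profile.apply(base)
    specs = table1_specs()

    if study_id == "no_dediff_global":
        design = lhs_design({k: specs[k] for k in GLOBAL_STUDY_PARAMS},
                            n_runs, seed)
        base_run = base.replace(omega_dd=0.0)
        truncate, stop_on_arrest = True, True
    elif study_id == "dediff_global":
        design = lhs_design({k: specs[k] for k in DEDIFF_STUDY_PARAMS},
                            n_runs, seed)
        base_run = base
        truncate, stop_on_arrest = False, False
    elif study_id == "dediff_local":
        return _run_local_sweep(base, seed, profile, sweep_pct, n_replicates,
                                keep_records)
    else:
        raise ValueError(f"unknown study {study_id!r}")

    seeds = _child_seeds(seed, len(design))
    rows, records = [], []
    for i, run_seed in enumerate(seeds):
        params = _params_from_row(base_run, design.iloc[i])
        if study_id == "no_dediff_global":
            params = params.replace(omega_dd=0.0)
        res = engine.run(params, run_seed, profile.t_end_days,
                         stop_on_arrest=stop_on_arrest)
        rows.append(_study_outputs(res, truncate))
        if keep_records:
            records.append(res.record)
    design = design.assign(seed=seeds)
    runs = pd.DataFrame(rows)

    result = StudyResult(study=study_id, design=design, runs=runs,
                         records=records)
    X = design[[c for c in design.columns if c != "seed"]]
    for output in ("advance_rate_um_d", "prolif_per_day", "calc_extent_um",
                   "n_calcified", "n_total", "n_er_pos", "n_er_neg"):
        y = runs[output].to_numpy(dtype=float)
        if np.all(np.isfinite(y)) and len(runs) > X.shape[1] + 1:
            result.regressions[output] = multivariate_ols(X, y, output)
    return result


def sweep_omega_dd(base: ParameterSet, seed: int,
                   profile: ScaleProfile = DESK_PROFILE,
                   sweep_pct=DEFAULT_OMEGA_DD_SWEEP_PCT,
                   n_replicates: int = 3,
                   keep_records: bool = False) -> StudyResult:
    """Local sweep of the dedifferentiation probability at baseline."""
    return _run_local_sweep(profile.apply(base.validate()), seed, profile,
                            sweep_pct, n_replicates, keep_records)


def _run_local_sweep(base, seed, profile, sweep_pct, n_replicates,
                     keep_records) -> StudyResult:
    sweep_pct = tuple(sweep_pct)
    n_total = len(sweep_pct) * n_replicates
    seeds = _child_seeds(seed, n_total)
    rows, records = [], []
    t_min = profile.analysis_t_min
    k = 0
    for pct in sweep_pct:
        for rep in range(n_replicates):
            params = base.replace(omega_dd=pct / 100.0)
            res = engine.run(params, seeds[k], profile.t_end_days,
                             stop_on_arrest=False)
            out = _study_outputs(res, truncate_at_arrest=False, t_min=t_min)
            out.update(omega_dd_pct=pct, replicate=rep, seed=seeds[k])
            out["stem_pct_slope_per_day"] = _stem_slope(res.record, t_min)
            rows.append(out)
            if keep_records:
                records.append(res.record)
            k += 1
    runs = pd.DataFrame(rows)
    design = runs[["omega_dd_pct", "replicate", "seed"]].copy()
    result = StudyResult(study="dediff_local", design=design, runs=runs,
                         records=records)
    result.fits = analyze_local_sweep(runs)
    return result


def _stem_slope(record: pd.DataFrame, t_min: float) -> float:
    """Average daily change of stem percent density over the analysis window."""
    sel = record[(record["t_d"] >= t_min)
                 & np.isfinite(record["stem_pct"])]
    if len(sel) < 2 or np.ptp(sel["t_d"].to_numpy()) == 0:
        return np.nan
    return float(np.polyfit(sel["t_d"], sel["stem_pct"], 1)[0])


def analyze_local_sweep(runs: pd.DataFrame) -> dict:
    """Triplicate means plus the two published response fits.

    The Michaelis–Menten fit relates mean advance rate [µm/day] to the
    per-cycle dedifferentiation probability on the *fraction* scale (so K_M
    is a per-cycle probability); the through-origin fit relates the mean
    daily change in stem percent density to the probability in *percent*.
    """
    grp = runs.groupby("omega_dd_pct", sort=True)
    summary = grp.agg(advance_rate_mean=("advance_rate_um_d", "mean"),
                      advance_rate_sd=("advance_rate_um_d", "std"),
                      stem_slope_mean=("stem_pct_slope_per_day", "mean"),
                      stem_slope_sd=("stem_pct_slope_per_day", "std"),
                      stem_pct_final=("stem_pct", "mean")).reset_index()
    x_frac = summary["omega_dd_pct"].to_numpy() / 100.0
    mm = fit_michaelis_menten(x_frac, summary["advance_rate_mean"].to_numpy())
    lin = fit_linear_origin(summary["omega_dd_pct"].to_numpy(),
                            summary["stem_slope_mean"].to_numpy())
    return {"summary": summary, "michaelis_menten": mm, "linear_origin": lin}
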