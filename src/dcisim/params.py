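"""Model parameters, sampling distributions, and the seeded RNG contract.

The parameter space has two layers:

* the biological parameters perturbed in the sensitivity studies (cell cycle
  time, phenotype branching probabilities, signalling thresholds, metabolic
  multipliers, the dedifferentiation probability), each with a baseline and a
  published perturbation range/distribution, and
* structural constants of the simulator (geometry, time step, field-solver
  constants, mechanics tolerances) that are fixed per run but configurable.

All stochastic draws in the package come from named child streams of a single
root seed, so that toggling one stochastic pathway (e.g. dedifferentiation)
does not perturb the draws of another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass
import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "ParameterSpec",
    "RngStreams",
    "lognormal_underlying",
    "per_step_probability",
    "sample_uniform",
    "sample_lognormal_bounded",
    "sample_spec",
    "table1_specs",
]


# --------------------------------------------------------------------------- #
# Parameter set
# --------------------------------------------------------------------------- #

@dataclass
class ParameterSet:
    """Every tunable of one simulation run.

    Units: lengths in µm, times in hours unless noted, concentrations
    normalized so the duct-wall boundary value of oxygen and estrogen is 1.
    Probabilities are fractions in [0, 1].
    """

    # --- cell hierarchy / behaviour -------------------------------------- #
    tau_p: float = 20.0        #: mean cell cycle time [h]
    tau_sigma: float = 2.0     #: arithmetic SD of the cycle-time lognormal [h]
    tau_min: float = 16.0      #: hard floor on sampled cycle times [h]
    omega_p: float = 0.75      #: progenitor daughter is progenitor (vs differentiated)
    omega_sc: float = 0.12     #: stem daughter is stem
    omega_sc_pm: float = 0.50  #: non-stem daughter of a stem cell is ER+ (vs ER-)
    omega_apop: float = 0.00705  #: apoptosis probability per time step
    p_max: int = 18            #: progenitor proliferation cycles before terminal differentiation
    theta_q: float = 0.70      #: local volume-occupancy threshold for quiescence
    omega_dd: float = 0.004    #: dedifferentiation probability per cell per cycle (0 = off)

    # --- hybrid (agent <-> continuum) coupling --------------------------- #
    lambda_c: float = 4.5      #: cancer-cell oxygen metabolism vs healthy baseline
    lambda_e: float = 1.0      #: estrogen metabolism multiplier (ER+ cells)
    lambda_fgf: float = 0.72   #: FGF uptake multiplier (ER- cells)
    lambda_areg: float = 0.086  #: AREG production multiplier (stimulated ER+ cells)
    theta_e: float = 0.85      #: estrogen proliferation threshold (normalized)
    theta_fgf: float = 0.70    #: FGF proliferation threshold (normalized)

    # --- geometry and schedule ------------------------------------------- #
    duct_length: float = 1000.0         #: axial duct length [µm]
    duct_inner_diameter: float = 200.0  #: inner luminal diameter [µm]
    dt: float = 0.5                     #: discrete time step [h] (30 simulated minutes)
    n_tic: int = 5                      #: tumor-initiating cells at t = 0

    # --- mechanics (structural) ------------------------------------------ #
    cell_radius: float = 5.0   #: mature cell radius [µm]; newborns start at half volume
    overlap_tol: float = 0.25  #: admissible residual pair overlap after relaxation [µm]
    relax_max_iter: int = 40
    relax_factor: float = 0.7  #: fraction of the pairwise overlap corrected per sweep

    # --- continuum fields (structural) ----------------------------------- #
    grid_h: float = 10.0       #: voxel edge [µm]
    d_o2: float = 2000.0       #: diffusivities [µm^2/s]
    d_e2: float = 1000.0
    d_areg: float = 100.0
    d_fgf: float = 100.0
    kappa_o2: float = 300.0    #: healthy per-cell O2 uptake coefficient [µm^3/s]
    kappa_e2: float = 30.0     #: baseline per-cell E2 uptake coefficient [µm^3/s]
    q_areg: float = 800.0      #: per-cell AREG production scale [conc µm^3/s]
    k_relay: float = 0.2       #: stromal AREG->FGF relay rate at wall voxels [1/s]
    kappa_fgf: float = 30.0    #: baseline per-cell FGF uptake coefficient [µm^3/s]
    k_decay: float = 0.0025    #: first-order clearance of AREG/FGF [1/s]
    field_rtol: float = 1e-5   #: relative residual tolerance of the field solver

    # --- hypoxia / necrosis / calcification (structural) ------------------ #
    hypoxia_threshold: float = 0.30  #: normalized O2 below which cells are hypoxic
    t_necrosis: float = 12.0   #: continuous hypoxia before necrosis [h]
    t_calcify: float = 24.0    #: time after necrosis before calcification [h]

    # --- local density estimate ------------------------------------------ #
    occupancy_window: float = 50.0  #: edge of the cubic sampling neighbourhood [µm]
    occupancy_ref_packing: float = 0.64  #: volume fraction of a confluent packing

    # --- switches and diagnostics ----------------------------------------- #
    stem_er_gated: bool = True      #: stem cells obey the estrogen gate
    apoptosis_scope: str = "all"  #: "all" live cells, or "non_cycling" (quiescent/hypoxic/differentiated)
    lognormal_convention: str = "arithmetic"  #: or "geometric"; see lognormal_underlying
    edge_band: float = 25.0         #: leading-edge band width for arrest metrics [µm]
    arrest_persistence: float = 5.0  #: days both edges must stay incompetent

    # ------------------------------------------------------------------ #

    @property
    def duct_radius(self) -> float:
        return 0.5 * self.duct_inner_diameter

    def validate(self) -> "ParameterSet":
        probs = {
            "omega_p": self.omega_p, "omega_sc": self.omega_sc,
            "omega_sc_pm": self.omega_sc_pm, "omega_apop": self.omega_apop,
            "omega_dd": self.omega_dd,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in ("tau_p", "tau_min", "duct_length", "duct_inner_diameter",
                     "dt", "cell_radius", "grid_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.p_max < 1:
            raise ValueError("p_max must be >= 1")
        if self.n_tic < 1:
            raise ValueError("n_tic must be >= 1")
        if not 0.0 <= self.theta_q <= 1.0:
            raise ValueError("theta_q must lie in [0, 1]")
        if self.lognormal_convention not in ("arithmetic", "geometric"):
            raise ValueError("lognormal_convention must be 'arithmetic' or 'geometric'")
        if self.apoptosis_scope not in ("non_cycling", "all"):
            raise ValueError("apoptosis_scope must be 'non_cycling' or 'all'")
        return self

    # -- config round trip ---------------------------------------------- #

    def to_config(self) -> dict:
        """Flat-key mapping of every field (YAML/JSON friendly)."""
        return dataclasses.asdict(self)

    @classmethod
    def from_config(cls, cfg: dict) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise KeyError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in cfg:
                v = cfg[f.name]
                if f.type in ("int",):
                    v = int(v)
                elif f.type in ("float",):
                    v = float(v)
                kwargs[f.name] = v
        return cls(**kwargs).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls.from_config(cfg)

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs).validate()

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_config(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------- #
# Perturbation specs
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ParameterSpec:
    """Declared sampling distribution of one perturbed parameter.

    ``uniform`` specs carry ``(low, high)``; ``lognormal`` specs carry an
    arithmetic ``(mean, spread)`` pair plus an optional lower clip and upper
    clip (used for probabilities, which must stay within [0, 1]).
    """

    name: str
    distribution: str            # "uniform" | "lognormal"
    baseline: float
    low: float = math.nan
    high: float = math.nan
    mean: float = math.nan
    spread: float = math.nan
    lower_clip: float = 0.0
    upper_clip: float = math.inf
    integer: bool = False

    def __post_init__(self):
        if self.distribution == "uniform":
            if not self.low < self.high and self.low != self.high:
                raise ValueError(f"{self.name}: uniform spec needs low <= high")
            if not (self.low <= self.baseline <= self.high):
                raise ValueError(f"{self.name}: baseline outside [low, high]")
        elif self.distribution == "lognormal":
            if not self.mean > 0:
                raise ValueError(f"{self.name}: lognormal mean must be > 0")
            if self.spread < 0:
                raise ValueError(f"{self.name}: lognormal spread must be >= 0")
        else:
            raise ValueError(f"{self.name}: unknown distribution {self.distribution!r}")


def table1_specs() -> dict[str, ParameterSpec]:
    """The published baseline/range table as :class:`ParameterSpec` objects.

    Keys are :class:`ParameterSet` field names.
    """
    return {
        "tau_p": ParameterSpec("tau_p", "uniform", 20.0, low=16.5, high=23.5),
        "omega_p": ParameterSpec("omega_p", "uniform", 0.75, low=0.50, high=1.00),
        "omega_sc": ParameterSpec("omega_sc", "lognormal", 0.12, mean=0.12,
                                  spread=0.06, upper_clip=1.0),
        "omega_sc_pm": ParameterSpec("omega_sc_pm", "uniform", 0.50, low=0.36, high=0.64),
        "omega_apop": ParameterSpec("omega_apop", "uniform", 0.00705,
                                    low=0.0010, high=0.0131),
        "p_max": ParameterSpec("p_max", "uniform", 18, low=11, high=25, integer=True),
        "theta_q": ParameterSpec("theta_q", "uniform", 0.70, low=0.50, high=0.90),
        "omega_dd": ParameterSpec("omega_dd", "uniform", 0.004, low=0.001, high=0.007),
        "lambda_c": ParameterSpec("lambda_c", "uniform", 4.5, low=3.0, high=6.0),
        "lambda_e": ParameterSpec("lambda_e", "uniform", 1.0, low=0.9, high=1.1),
        "lambda_fgf": ParameterSpec("lambda_fgf", "uniform", 0.72, low=0.648, high=0.792),
        "lambda_areg": ParameterSpec("lambda_areg", "uniform", 0.086, low=0.0774, high=0.096),
        "theta_e": ParameterSpec("theta_e", "lognormal", 0.85, mean=0.85, spread=0.2),
        "theta_fgf": ParameterSpec("theta_fgf", "lognormal", 0.70, mean=0.70, spread=0.15),
    }


#: parameters perturbed in the global study without dedifferentiation
GLOBAL_STUDY_PARAMS = (
    "tau_p", "omega_p", "omega_sc", "omega_sc_pm", "omega_apop", "p_max",
    "theta_q", "lambda_c", "lambda_e", "lambda_fgf", "lambda_areg",
    "theta_e", "theta_fgf",
)

#: reduced set perturbed in the study with the dedifferentiation pathway on
DEDIFF_STUDY_PARAMS = (
    "omega_p", "omega_sc", "p_max", "theta_q", "omega_dd", "lambda_c",
    "theta_e", "theta_fgf",
)


# --------------------------------------------------------------------------- #
# Stochastic primitives
# --------------------------------------------------------------------------- #

def lognormal_underlying(mean: float, spread: float,
                         convention: str = "arithmetic") -> tuple[float, float]:
    """(mu, sigma) of the underlying normal for a "mean ± spread" lognormal.

    ``arithmetic`` (default): the lognormal's arithmetic mean equals ``mean``
    and its arithmetic SD equals ``spread``.  ``geometric``: ``mean`` is the
    median (geometric mean) and ``spread/mean`` is the SD on the log scale.
    """
    if mean <= 0:
        raise ValueError("lognormal mean must be > 0")
    if spread < 0:
        raise ValueError("lognormal spread must be >= 0")
    if spread == 0:
        return math.log(mean), 0.0
    if convention == "arithmetic":
        sigma2 = math.log1p((spread / mean) ** 2)
        mu = math.log(mean) - 0.5 * sigma2
        return mu, math.sqrt(sigma2)
    if convention == "geometric":
        return math.log(mean), spread / mean
    raise ValueError(f"unknown lognormal convention {convention!r}")


def sample_uniform(spec: ParameterSpec, rng: np.random.Generator,
                   size=None):
    """Draw from a uniform :class:`ParameterSpec` (degenerate intervals allowed)."""
    if spec.distribution != "uniform":
        raise ValueError(f"{spec.name} is not a uniform spec")
    if spec.low == spec.high:
        return spec.low if size is None else np.full(size, spec.low)
    return rng.uniform(spec.low, spec.high, size=size)


def sample_lognormal_bounded(mean: float, spread: float, lower_clip: float,
                             rng: np.random.Generator, size=None,
                             upper_clip: float = math.inf,
                             convention: str = "arithmetic"):
    """Lognormal draw(s) clipped from below (and optionally above).

    The *unclipped* distribution has arithmetic mean ``mean`` (and SD
    ``spread``) under the default convention; clipping introduces the small,
    documented bias of the bounded distribution.
    """
    mu, sigma = lognormal_underlying(mean, spread, convention)
    if sigma == 0.0:
        draw = mean if size is None else np.full(size, float(mean))
    else:
        draw = rng.lognormal(mu, sigma, size=size)
    return np.clip(draw, lower_clip, upper_clip) if size is not None else float(
        min(max(draw, lower_clip), upper_clip))


def sample_spec(spec: ParameterSpec, rng: np.random.Generator, size=None,
                convention: str = "arithmetic"):
    """Draw from an arbitrary :class:`ParameterSpec`."""
    if spec.distribution == "uniform":
        v = sample_uniform(spec, rng, size=size)
    else:
        v = sample_lognormal_bounded(spec.mean, spec.spread, spec.lower_clip,
                                     rng, size=size, upper_clip=spec.upper_clip,
                                     convention=convention)
    if spec.integer:
        v = np.rint(v).astype(int) if size is not None else int(round(v))
    return v


def spec_ppf(spec: ParameterSpec, u, convention: str = "arithmetic"):
    """Quantile transform of uniform(0,1) variates to the spec's distribution.

    Used by Latin hypercube stratification; lognormal columns are stratified
    on the quantile scale.
    """
    u = np.asarray(u, dtype=float)
    if spec.distribution == "uniform":
        v = spec.low + u * (spec.high - spec.low)
    else:
        from scipy import stats
        mu, sigma = lognormal_underlying(spec.mean, spec.spread, convention)
        if sigma == 0.0:
            v = np.full_like(u, spec.mean)
        else:
            v = stats.lognorm.ppf(u, sigma, scale=math.exp(mu))
        v = np.clip(v, spec.lower_clip, spec.upper_clip)
    if spec.integer:
        v = np.rint(v).astype(int)
    return v


def per_step_probability(per_cycle_prob: float, dt: float, tau: float):
    """Per-step Bernoulli probability equivalent to a per-cell-cycle probability.

    Solves ``1 - (1 - p_step)**(tau/dt) = per_cycle_prob`` for ``p_step``, so
    that a Bernoulli trial applied at every step of a cycle of length ``tau``
    yields the stated per-cycle probability.
    Accepts scalars or arrays in any argument.
    """
    p = np.asarray(per_cycle_prob, dtype=float)
    dt_ = np.asarray(dt, dtype=float)
    tau_ = np.asarray(tau, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("per_cycle_prob must lie in [0, 1]")
    if np.any(dt_ <= 0) or np.any(tau_ <= 0):
        raise ValueError("dt and tau must be positive")
    with np.errstate(divide="ignore"):  # p = 1 -> log1p(-1) = -inf -> out = 1
        out = -np.expm1(np.log1p(-p) * (dt_ / tau_))
    if out.ndim == 0:
        return float(out)
    return out


# --------------------------------------------------------------------------- #
# RNG streams
# --------------------------------------------------------------------------- #

_STREAMS = ("cycle", "phenotype", "dediff", "apoptosis", "placement", "lhs")


class RngStreams:
    """Named, independent PCG64 child streams of a single root seed.

    Each stochastic subsystem draws from its own stream, so enabling or
    disabling one pathway leaves the draws of every other pathway unchanged.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(_STREAMS))
        self._gens = {name: np.random.Generator(np.random.PCG64(ss))
                      for name, ss in zip(_STREAMS, children)}

    def __getattr__(self, name):
        try:
            return self.__dict__["_gens"][name]
        except KeyError:
            raise AttributeError(name) from None

    def state(self) -> dict:
        """JSON-serializable snapshot of every stream."""
        return {"seed": self.seed,
                "streams": {k: g.bit_generator.state
                            for k, g in self._gens.items()}}

    @classmethod
    def from_state(cls, state: dict) -> "RngStreams":
        obj = cls(state["seed"])
        for k, s in state["streams"].items():
            obj._gens[k].bit_generator.state = s
        return obj
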