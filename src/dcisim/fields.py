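"""Reaction–diffusion fields (oxygen, estrogen, AREG, FGF) on the duct.

Each species obeys a quasi-steady Fick's-law balance on a regular voxel grid
masked to the luminal cylinder::

    D * lap(c) - k_lin * c + source = 0

with either a Dirichlet boundary on the duct wall (oxygen and estrogen enter
from the vasculature/stroma at the normalized value 1) or no-flux walls plus
first-order clearance (AREG, FGF).  Axial ends are always no-flux.  Per-cell
uptake is first order in the local concentration (which keeps solutions
non-negative and bounded — a discrete maximum principle), while production
terms are zeroth order.

The 7-point finite-difference operator is assembled once per geometry; the
per-step solve is a Jacobi-preconditioned conjugate-gradient iteration warm
started from the previous solution, so the cost tracks how much the agent
configuration actually changed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.ndimage import uniform_filter


def _pcg(L, D, k, b, x0, inv_diag, rtol, maxiter=2000, atol=1e-12):
    """Jacobi-preconditioned conjugate gradients for (D*L + diag(k)) x = b.

    Hand-rolled to avoid per-iteration wrapper overhead; the operator is SPD
    by construction (graph Laplacian plus non-negative diagonal).
    """
    x = x0.copy()
    r = b - (D * (L @ x) + k * x)
    b_norm = np.linalg.norm(b)
    tol = max(rtol * b_norm, atol)
    res = np.linalg.norm(r)
    if res <= tol:
        return x, res, 0
    z = inv_diag * r
    p = z.copy()
    rz = float(r @ z)
    for it in range(1, maxiter + 1):
        Ap = D * (L @ p) + k * p
        pAp = float(p @ Ap)
        if rz == 0.0 or pAp == 0.0:  # residual underflow: converged
            return x, res, it
        alpha = rz / pAp
        x += alpha * p
        r -= alpha * Ap
        res = np.linalg.norm(r)
        if res <= tol:
            return x, res, it
        z = inv_diag * r
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
    return x, res, maxiter

__all__ = ["GridGeometry", "FieldGrid", "update_all_fields",
           "occupancy_grid", "flux_balance"]

SPECIES = ("O2", "E2", "AREG", "FGF")


class GridGeometry:
    """Masked voxel grid plus the two FD operators used by the species.

    ``mask`` marks lumen voxels; ``dirichlet`` marks the wall-adjacent lumen
    shell used as the Dirichlet layer (and as the stromal FGF source shell).
    Two operator variants are prebuilt: one where the shell is held at a
    boundary value (O2/E2) and one where every lumen voxel is an unknown with
    no-flux walls (AREG/FGF).
    """

    def __init__(self, mask: np.ndarray, dirichlet: np.ndarray, h: float,
                 origin: np.ndarray):
        if mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.mask = mask.astype(bool)
        self.dirichlet = dirichlet.astype(bool) & self.mask
        self.h = float(h)
        self.origin = np.asarray(origin, dtype=float)
        self.shape = self.mask.shape
        self.voxel_volume = self.h ** 3
        self._ops: dict[bool, tuple] = {}
        for with_dirichlet in (True, False):
            self._ops[with_dirichlet] = self._build(with_dirichlet)

    # -- construction ---------------------------------------------------- #

    @classmethod
    def for_duct(cls, duct, h: float) -> "GridGeometry":
        """Bounding-box grid of a cylindrical duct, lumen-masked."""
        L, R = duct.length, duct.radius
        nx = max(int(np.ceil(L / h)), 1)
        nyz = max(int(np.ceil(2 * R / h)), 1)
        origin = np.array([-0.5 * nx * h, -0.5 * nyz * h, -0.5 * nyz * h])
        xs = origin[0] + (np.arange(nx) + 0.5) * h
        ys = origin[1] + (np.arange(nyz) + 0.5) * h
        zs = origin[2] + (np.arange(nyz) + 0.5) * h
        Y, Z = np.meshgrid(ys, zs, indexing="ij")
        disk = np.hypot(Y, Z) <= R
        mask = np.broadcast_to(disk[None, :, :], (nx, nyz, nyz)).copy()
        # wall shell: lumen voxels with a non-lumen radial neighbour
        interior = np.zeros_like(disk)
        interior[1:-1, 1:-1] = (disk[1:-1, 1:-1] & disk[:-2, 1:-1]
                                & disk[2:, 1:-1] & disk[1:-1, :-2]
                                & disk[1:-1, 2:])
        shell = disk & ~interior
        dirichlet = np.broadcast_to(shell[None, :, :], (nx, nyz, nyz)).copy()
        return cls(mask, dirichlet, h, origin)

    def _build(self, with_dirichlet: bool):
        """Assemble the unit graph Laplacian (h^-2 scaled) on active voxels."""
        active = self.mask & ~(self.dirichlet if with_dirichlet else
                               np.zeros_like(self.mask))
        idx = -np.ones(self.shape, dtype=np.int64)
        act_flat = np.nonzero(active.ravel())[0]
        idx.ravel()[act_flat] = np.arange(len(act_flat))
        n = len(act_flat)
        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        dir_count = np.zeros(n)
        inv_h2 = 1.0 / self.h ** 2
        for axis in range(3):
            for sgn in (-1, 1):
                shifted_idx = np.full(self.shape, -1, dtype=np.int64)
                shifted_dir = np.zeros(self.shape, dtype=bool)
                src = [slice(None)] * 3
                dst = [slice(None)] * 3
                if sgn == 1:
                    src[axis] = slice(1, None)
                    dst[axis] = slice(None, -1)
                else:
                    src[axis] = slice(None, -1)
                    dst[axis] = slice(1, None)
                shifted_idx[tuple(dst)] = idx[tuple(src)]
                if with_dirichlet:
                    shifted_dir[tuple(dst)] = self.dirichlet[tuple(src)]
                a = active & (shifted_idx >= 0)
                i = idx[a]
                j = shifted_idx[a]
                rows.append(i)
                cols.append(j)
                vals.append(np.full(len(i), -inv_h2))
                np.add.at(diag, i, inv_h2)
                if with_dirichlet:
                    b = active & shifted_dir
                    np.add.at(diag, idx[b], inv_h2)
                    np.add.at(dir_count, idx[b], inv_h2)
        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        L = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n))
        return act_flat, L, dir_count

    def active_index(self, with_dirichlet: bool) -> np.ndarray:
        return self._ops[with_dirichlet][0]

    def operator(self, with_dirichlet: bool):
        return self._ops[with_dirichlet][1]

    def dirichlet_weight(self) -> np.ndarray:
        return self._ops[True][2]

    # -- point <-> voxel ------------------------------------------------- #

    def voxel_of(self, points: np.ndarray) -> tuple[np.ndarray, ...]:
        pts = np.atleast_2d(points)
        ijk = np.floor((pts - self.origin) / self.h).astype(np.int64)
        for d, nd in enumerate(self.shape):
            if np.any((ijk[:, d] < 0) | (ijk[:, d] >= nd)):
                raise ValueError("position outside the field grid")
        return ijk[:, 0], ijk[:, 1], ijk[:, 2]

    def flat_voxel_of(self, points: np.ndarray) -> np.ndarray:
        i, j, k = self.voxel_of(points)
        return np.ravel_multi_index((i, j, k), self.shape)


@dataclass
class FieldGrid:
    """One continuum species on a :class:`GridGeometry`.

    ``boundary_value`` is the Dirichlet wall value (``None`` → no-flux walls).
    ``values`` holds the last solution on the full grid; it warm starts the
    next solve.
    """

    species: str
    geometry: GridGeometry
    diffusivity: float
    boundary_value: float | None = None
    values: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.values is None:
            init = self.boundary_value if self.boundary_value is not None else 0.0
            self.values = np.where(self.geometry.mask, float(init), 0.0)

    # ------------------------------------------------------------------ #

    def solve(self, k_lin: np.ndarray | float = 0.0,
              source: np.ndarray | float = 0.0, rtol: float = 1e-8) -> dict:
        """Solve the steady balance for given per-voxel rates (in place).

        ``k_lin`` [1/s] is the first-order consumption coefficient field and
        ``source`` [conc/s] the zeroth-order production (negative values are
        constant sinks).  Returns solver diagnostics.
        """
        geom = self.geometry
        dir_mode = self.boundary_value is not None
        act = geom.active_index(dir_mode)
        L = geom.operator(dir_mode)
        n = len(act)
        k = (np.broadcast_to(np.asarray(k_lin, dtype=float), geom.shape)
             .ravel()[act])
        s = (np.broadcast_to(np.asarray(source, dtype=float), geom.shape)
             .ravel()[act])
        if np.any(k < 0):
            raise ValueError("k_lin must be non-negative")
        D = self.diffusivity
        rhs = s.copy()
        if dir_mode:
            rhs = rhs + D * geom.dirichlet_weight() * self.boundary_value
        elif np.all(k == 0) and not np.any(s):
            # pure-Neumann Laplace: any constant solves it; keep current state
            return {"iterations": 0, "residual": 0.0}

        diag = D * L.diagonal() + k
        if np.any(diag <= 0):
            raise ValueError("singular operator: add decay or a boundary")
        x0 = self.values.ravel()[act]
        x, res, n_iter = _pcg(L, D, k, rhs, x0, 1.0 / diag, rtol)
        if res > max(rtol * np.linalg.norm(rhs), 1e-12) * 10:
            raise RuntimeError(
                f"{self.species} field solver did not converge "
                f"(iterations={n_iter}, residual={res:.3e})")
        out = self.values
        out.ravel()[act] = x
        if dir_mode:
            out[geom.dirichlet] = self.boundary_value
        out[~geom.mask] = 0.0
        # keep this solve's rates for flux diagnostics
        self._last = {"k": k, "s": s, "act": act, "dir_mode": dir_mode}
        return {"iterations": n_iter, "residual": res}

    def sample_at(self, points: np.ndarray) -> np.ndarray:
        """Concentration of the voxel containing each point (nearest-voxel)."""
        geom = self.geometry
        i, j, k = geom.voxel_of(points)
        if not np.all(geom.mask[i, j, k]):
            raise ValueError("position outside the lumen")
        out = self.values[i, j, k]
        return out if out.ndim else float(out)


def flux_balance(fieldgrid: FieldGrid) -> dict:
    """Steady-state conservation check of the last solve.

    Returns total boundary influx and net interior consumption (uptake minus
    production), both in conc·µm³/s; they agree to solver tolerance.
    """
    last = getattr(fieldgrid, "_last", None)
    if last is None:
        raise RuntimeError("no solve recorded on this field")
    geom = fieldgrid.geometry
    act = last["act"]
    vals = fieldgrid.values.ravel()[act]
    vox = geom.voxel_volume
    consumption = float(np.sum((last["k"] * vals - last["s"]) * vox))
    if last["dir_mode"]:
        D = fieldgrid.diffusivity
        w = geom.dirichlet_weight()  # (# dirichlet neighbours) / h^2
        influx = float(np.sum(D * w * (fieldgrid.boundary_value - vals) * vox))
    else:
        influx = 0.0
    return {"boundary_influx": influx, "net_consumption": consumption}


# --------------------------------------------------------------------------- #
# Agent coupling
# --------------------------------------------------------------------------- #

def _accumulate(flat_vox: np.ndarray, weights, shape) -> np.ndarray:
    size = int(np.prod(shape))
    w = np.broadcast_to(np.asarray(weights, dtype=float), flat_vox.shape)
    out = np.bincount(flat_vox, weights=w, minlength=size)
    return out.reshape(shape)


def update_all_fields(pop, grids: dict[str, FieldGrid], params) -> dict:
    """Deposit per-agent rates, solve all four species, sample at agents.

    Solve order matters: estrogen gates AREG production (only ER+ cells whose
    local E2 is at least ``theta_e`` secrete), and the stromal relay turns
    wall-local AREG into the FGF source, so O2 and E2 are solved first, then
    AREG, then FGF.  Returns per-agent samples for O2, E2 and FGF.

    ``pop`` must expose ``pos``, ``er``, and live-status masks (see
    :mod:`dcisim.cells`).
    """
    from . import cells  # cycle-free: cells does not import fields

    geom = grids["O2"].geometry
    n = pop.n
    vox_vol = geom.voxel_volume
    rtol = params.field_rtol
    if n == 0:
        for sp in SPECIES:
            grids[sp].solve(k_lin=(params.k_decay if grids[sp].boundary_value
                                   is None else 0.0), rtol=rtol)
        empty = np.zeros(0)
        return {"O2": empty, "E2": empty, "FGF": empty}

    flat = geom.flat_voxel_of(pop.col("pos"))
    live = pop.is_live()          # excludes necrotic/calcified
    er = pop.col("er")
    er_pos = live & (er == cells.ER_POS)
    er_neg = live & (er == cells.ER_NEG)

    # oxygen: every live tumor cell consumes at lambda_c x healthy baseline
    k_o2 = _accumulate(flat[live], params.lambda_c * params.kappa_o2 / vox_vol,
                       geom.shape)
    grids["O2"].solve(k_lin=k_o2, rtol=rtol)

    # estrogen: consumed by ER+ cells, scaled by lambda_e
    k_e2 = _accumulate(flat[er_pos], params.lambda_e * params.kappa_e2 / vox_vol,
                       geom.shape)
    grids["E2"].solve(k_lin=k_e2, rtol=rtol)
    e2_at = grids["E2"].values.ravel()[flat]

    # AREG: secreted by estrogen-stimulated ER+ cells, cleared first order
    stimulated = er_pos & (e2_at >= params.theta_e)
    s_areg = _accumulate(flat[stimulated],
                         params.lambda_areg * params.q_areg / vox_vol,
                         geom.shape)
    grids["AREG"].solve(k_lin=params.k_decay, source=s_areg, rtol=rtol)

    # FGF: stromal relay at the wall shell, linear in local AREG; consumed by
    # ER- cells; cleared first order
    s_fgf = np.where(geom.dirichlet,
                     params.k_relay * grids["AREG"].values, 0.0)
    k_fgf = _accumulate(flat[er_neg],
                        params.lambda_fgf * params.kappa_fgf / vox_vol,
                        geom.shape) + params.k_decay
    grids["FGF"].solve(k_lin=k_fgf, source=s_fgf, rtol=rtol)

    return {"O2": grids["O2"].values.ravel()[flat],
            "E2": e2_at,
            "FGF": grids["FGF"].values.ravel()[flat]}


def make_duct_grids(duct, params) -> tuple[GridGeometry, dict[str, FieldGrid]]:
    """The four species grids sharing one duct geometry."""
    geom = GridGeometry.for_duct(duct, params.grid_h)
    grids = {
        "O2": FieldGrid("O2", geom, params.d_o2, boundary_value=1.0),
        "E2": FieldGrid("E2", geom, params.d_e2, boundary_value=1.0),
        "AREG": FieldGrid("AREG", geom, params.d_areg, boundary_value=None),
        "FGF": FieldGrid("FGF", geom, params.d_fgf, boundary_value=None),
    }
    return geom, grids


# --------------------------------------------------------------------------- #
# Local volume occupancy
# --------------------------------------------------------------------------- #

def occupancy_grid(pos: np.ndarray, volumes: np.ndarray, geom: GridGeometry,
                   window: float, ref_packing: float = 0.64) -> np.ndarray:
    """Local cell density as a fraction of a confluent packing.

    Cell volumes are binned to voxels and averaged over a cubic window
    (edge ``window`` µm) with a matching average of the lumen indicator, so
    wall-adjacent neighbourhoods are normalized by the lumen volume they
    actually contain.  The raw volume fraction is then scaled by
    ``ref_packing`` (the volume fraction of a confluent random close packing
    of spheres), so a fully packed neighbourhood reads ~1.0 and the
    quiescence threshold's 0.5–0.9 range spans attainable densities.
    """
    size = max(int(round(window / geom.h)), 1)
    vol = _accumulate(geom.flat_voxel_of(pos), volumes, geom.shape)
    mean_vol = uniform_filter(vol, size=size, mode="constant")
    mean_lumen = uniform_filter(geom.mask.astype(float), size=size,
                                mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        occ = np.where(mean_lumen > 0,
                       mean_vol / (mean_lumen * geom.voxel_volume
                                   * ref_packing), 0.0)
    return occ
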