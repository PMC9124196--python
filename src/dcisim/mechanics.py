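"""Duct geometry and lattice-free cell mechanics.

Cells are soft spheres inside a rigid cylindrical duct segment.  Positions
are resolved by overdamped iterative relaxation: overlapping pairs repel
along their center line (a linear spring on the overlap), and any cell
pushed into the wall is projected back inside.  There is no long-range
adhesion; the law is deliberately the simplest one that produces confluent
packings, and is isolated here so a Hertz/JKR variant could substitute.

Coordinate convention: x is the duct axis with 0 at the midpoint; (y, z) are
the radial plane.  The lesion is initiated on the +y interior wall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["Duct", "CellBody", "neighbor_pairs", "relax_positions",
           "project_into_duct", "place_daughters", "place_daughter"]


@dataclass(frozen=True)
class Duct:
    """Rigid duct segment: axial extent [-length/2, +length/2], lumen radius."""

    length: float
    radius: float

    def __post_init__(self):
        if self.length <= 0 or self.radius <= 0:
            raise ValueError("duct length and radius must be positive")

    def contains(self, centers: np.ndarray, radii: np.ndarray,
                 tol: float = 1e-9) -> np.ndarray:
        """True where a sphere lies fully inside the duct (to tolerance)."""
        centers = np.atleast_2d(centers)
        radii = np.atleast_1d(radii)
        rho = np.hypot(centers[:, 1], centers[:, 2])
        ok_r = rho <= self.radius - radii + tol
        ok_x = np.abs(centers[:, 0]) <= 0.5 * self.length - radii + tol
        return ok_r & ok_x


@dataclass
class CellBody:
    """A single spherical cell body (convenience per-cell view)."""

    center: np.ndarray
    radius: float

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius ** 3


def _as_arrays(bodies):
    if isinstance(bodies, (list, tuple)):
        centers = np.array([np.asarray(b.center, dtype=float) for b in bodies])
        radii = np.array([b.radius for b in bodies], dtype=float)
        return centers, radii
    raise TypeError("expected a list of CellBody")


def neighbor_pairs(centers: np.ndarray, cutoff: float) -> np.ndarray:
    """Index pairs (i < j) with center distance < cutoff.

    ``centers`` may also be a list of :class:`CellBody`.
    """
    if not isinstance(centers, np.ndarray):
        centers, _ = _as_arrays(centers)
    n = len(centers)
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)
    tree = cKDTree(centers)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size:
        # strict inequality: drop pairs exactly at the cutoff
        d = np.linalg.norm(centers[pairs[:, 0]] - centers[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]
    return np.sort(pairs, axis=1)


def project_into_duct(centers: np.ndarray, radii: np.ndarray,
                      duct: Duct) -> np.ndarray:
    """Project sphere centers so every sphere lies inside the duct (in place)."""
    rho = np.hypot(centers[:, 1], centers[:, 2])
    rmax = duct.radius - radii
    bad = rho > rmax
    if np.any(bad):
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(rho[bad] > 0, rmax[bad] / rho[bad], 0.0)
        centers[bad, 1] *= scale
        centers[bad, 2] *= scale
    half = 0.5 * duct.length
    np.clip(centers[:, 0], -(half - radii), half - radii, out=centers[:, 0])
    return centers


def _pair_overlaps(centers, radii, pairs):
    d = centers[pairs[:, 0]] - centers[pairs[:, 1]]
    dist = np.linalg.norm(d, axis=1)
    return d, dist, (radii[pairs[:, 0]] + radii[pairs[:, 1]]) - dist


def relax_positions(centers: np.ndarray, radii: np.ndarray, duct: Duct,
                    overlap_tol: float = 0.25, max_iter: int = 40,
                    relax_factor: float = 0.7,
                    pairs: np.ndarray | None = None) -> dict:
    """Iteratively resolve pairwise overlaps and wall violations in place.

    Each sweep moves both members of an overlapping pair apart along their
    center line by ``relax_factor * overlap / 2`` each (equal and opposite for
    identical radii — the momentum-free contract), then projects everything
    back inside the duct.  Terminates when the worst overlap is within
    ``overlap_tol`` or after ``max_iter`` sweeps.

    Returns a diagnostics dict ``{converged, iterations, max_overlap}``.
    ``pairs`` may carry a precomputed candidate pair list (a superset of
    touching pairs remains valid across sweeps because displacements per
    sweep are bounded by the largest overlap).
    """
    n = len(centers)
    project_into_duct(centers, radii, duct)
    if n < 2:
        return {"converged": True, "iterations": 0, "max_overlap": 0.0}
    skin = 2.0
    cutoff = 2.0 * float(radii.max()) + skin
    if pairs is None:
        pairs = neighbor_pairs(centers, cutoff)

    i_all = j_all = rsum_all = None
    i = j = rsum = None
    drift = np.inf   # accumulated motion since the pair list was built
    refresh_every = 6
    max_overlap = 0.0
    for it in range(1, max_iter + 1):
        if drift > 0.5 * skin:
            # motion may have created pairs absent from the candidate list
            if i_all is not None:
                pairs = neighbor_pairs(centers, cutoff)
            i_all, j_all = pairs[:, 0], pairs[:, 1]
            rsum_all = radii[i_all] + radii[j_all]
            drift = 0.0
            refresh = True
        else:
            refresh = (it - 1) % refresh_every == 0
        if refresh:
            # working set: pairs that can reach >tol overlap within a few
            # sweeps (per-sweep motion is bounded by the skin check above)
            if len(i_all) == 0:
                return {"converged": True, "iterations": it - 1,
                        "max_overlap": 0.0}
            d_all = centers[i_all] - centers[j_all]
            dist_all = np.sqrt(np.einsum("ij,ij->i", d_all, d_all))
            near = (rsum_all - dist_all) > -0.5 * skin
            i, j, rsum = i_all[near], j_all[near], rsum_all[near]
            if len(i) == 0:
                ov = rsum_all - dist_all
                return {"converged": True, "iterations": it - 1,
                        "max_overlap": float(ov.max(initial=0.0))}
        d = centers[i] - centers[j]
        dist = np.sqrt(np.einsum("ij,ij->i", d, d))
        overlap = rsum - dist
        active = overlap > overlap_tol
        max_overlap = float(overlap.max(initial=0.0))
        if not np.any(active):
            return {"converged": True, "iterations": it - 1,
                    "max_overlap": max_overlap}
        ai, aj = i[active], j[active]
        dv = d[active]
        dn = dist[active]
        # coincident centers: separate along a fixed axis
        zero = dn < 1e-12
        if np.any(zero):
            dv[zero] = (1.0, 0.0, 0.0)
            dn[zero] = 1.0
        push = (0.5 * relax_factor) * (overlap[active] / dn)[:, None] * dv
        disp = np.zeros_like(centers)
        for k in range(3):
            disp[:, k] = (np.bincount(ai, weights=push[:, k], minlength=n)
                          - np.bincount(aj, weights=push[:, k], minlength=n))
        centers += disp
        project_into_duct(centers, radii, duct)
        drift += float(np.sqrt(np.einsum("ij,ij->i", disp, disp)).max())
    pairs = neighbor_pairs(centers, cutoff)
    if len(pairs):
        _, _, overlap = _pair_overlaps(centers, radii, pairs)
        max_overlap = float(overlap.max(initial=0.0))
    else:
        max_overlap = 0.0
    return {"converged": False, "iterations": max_iter,
            "max_overlap": max_overlap}


def place_daughters(mother_centers: np.ndarray, mother_radii: np.ndarray,
                    daughter_radii: np.ndarray, duct: Duct,
                    rng: np.random.Generator) -> np.ndarray:
    """Positions for newborn daughters adjacent to their mothers.

    Daughters are placed one mother-radius away in a random direction; any
    direction that would push the daughter through the duct wall is reflected
    about the local wall tangent plane (biasing placement into the luminal
    cavity), and a final projection guarantees containment.
    """
    m = np.atleast_2d(np.asarray(mother_centers, dtype=float))
    n = len(m)
    dirs = rng.normal(size=(n, 3))
    dirs /= np.maximum(np.linalg.norm(dirs, axis=1, keepdims=True), 1e-12)
    cand = m + dirs * np.asarray(mother_radii, dtype=float)[:, None]

    rho = np.hypot(cand[:, 1], cand[:, 2])
    lim = duct.radius - np.asarray(daughter_radii, dtype=float)
    bad = rho > lim
    if np.any(bad):
        # reflect the radial component of the step inward
        mr = np.hypot(m[bad, 1], m[bad, 2])
        ny = np.where(mr > 0, m[bad, 1] / np.maximum(mr, 1e-12), 0.0)
        nz = np.where(mr > 0, m[bad, 2] / np.maximum(mr, 1e-12), 1.0)
        radial = dirs[bad, 1] * ny + dirs[bad, 2] * nz
        out = radial > 0
        idx = np.nonzero(bad)[0][out]
        dirs[idx, 1] -= 2 * radial[out] * ny[out]
        dirs[idx, 2] -= 2 * radial[out] * nz[out]
        cand = m + dirs * np.asarray(mother_radii, dtype=float)[:, None]
    project_into_duct(cand, np.asarray(daughter_radii, dtype=float), duct)
    return cand


def place_daughter(mother: CellBody, duct: Duct,
                   rng: np.random.Generator,
                   daughter_radius: float | None = None) -> CellBody:
    """Single-cell convenience wrapper over :func:`place_daughters`."""
    r_d = mother.radius if daughter_radius is None else daughter_radius
    pos = place_daughters(np.asarray(mother.center, dtype=float)[None, :],
                          np.array([mother.radius]), np.array([r_d]),
                          duct, rng)[0]
    return CellBody(center=pos, radius=r_d)
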