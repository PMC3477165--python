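"""Implicit-membrane boundary walls built with a level-set approach.

Five scalar fields phi_1..phi_5 define the confining geometry around a
membrane protein:

* walls 1 and 2 are the planes at the lipid-head heights ``z_hi`` and
  ``z_lo`` (top and bottom of the implicit membrane slab);
* walls 3 and 4 are hemispheres capping the extracellular and cytoplasmic
  sides, sized so that every protein atom outside the slab keeps a chosen
  margin (default 2.0 nm) from the wall surface -- this carves out the
  water droplet;
* wall 5 ("membrane wall") hugs the initial transmembrane Calpha trace at
  an offset ``r_p`` (default 0.2 nm), using a log-sum-exp soft minimum over
  the Calpha source points so the field is smooth everywhere.

The allowed region is where the applicable level-set values are positive.
Each wall is only defined in its own z-zone (above the slab: walls 1 and 3;
below: 2 and 4; inside: 5); outside its zone a wall reports +inf so that
``d = min_i phi_i`` over the defined walls is the distance to the nearest
confining surface.

Boundary energetics: walls 1-2 carry a purely repulsive inverse-sixth
potential cut at ``d_rep`` (default 0.7 nm); walls 3-5 carry a softened
Lennard-Jones potential re-parameterized so its minimum sits exactly at
``d = r_p``, cut at ``1.5 r_p``.  Potentials are energy-shifted to zero at
their cutoffs and forces are force-shifted to vanish continuously there.
The force magnitude is clamped to ``f_max`` (default 1000 kJ mol^-1 nm^-1)
near the wall; the clamp acts on forces only, never on reported energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax

__all__ = [
    "WallSet",
    "WallConstructionError",
    "build_walls",
    "hemisphere_wallset",
    "wall_distance",
    "wall_potential",
    "wall_forces",
    "wall_energy",
    "smooth_min",
]

_SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)

# atom names treated as backbone when picking aromatic side-chain atoms
_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}


class WallConstructionError(RuntimeError):
    pass


def smooth_min(distances: np.ndarray, beta: float, axis: int = -1) -> np.ndarray:
    """Soft minimum -(1/beta) log sum exp(-beta d), overflow-safe.

    Converges to the hard minimum from below as ``beta -> inf``; with a
    single entry it equals that entry exactly.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    d = np.asarray(distances, dtype=float)
    return -logsumexp(-beta * d, axis=axis) / beta


@dataclass
class WallSet:
    """The five level-set walls plus their potential parameters."""

    z_lo: float
    z_hi: float
    center_xy: np.ndarray                 # (2,) hemisphere axis position
    r_upper: float                        # wall-3 radius (extracellular)
    r_lower: float                        # wall-4 radius (cytoplasmic)
    ca_points: np.ndarray                 # (m, 3) wall-5 sources; may be empty
    r_p: float = 0.2                      # wall offset / LJ-minimum distance, nm
    beta: float = 50.0                    # soft-min sharpness, nm^-1
    epsilon: float = 1.0                  # well depth, kJ/mol
    sigma_rep: float = 0.25               # repulsive-wall length scale, nm
    sigma_attr: float | None = None       # zero-crossing of walls 3-5; default r_p/2
    d_rep: float = 0.7                    # repulsive cutoff, nm
    attr_cutoff_factor: float = 1.5       # attractive cutoff = factor * r_p
    f_max: float = 1000.0                 # force cap, kJ mol^-1 nm^-1
    d_floor: float = 1e-6                 # evaluation floor for d <= 0
    active: np.ndarray = field(default_factory=lambda: np.ones(5, dtype=bool))
    wall_atom_indices: np.ndarray | None = None

    def __post_init__(self):
        self.center_xy = np.asarray(self.center_xy, dtype=float)
        self.ca_points = np.asarray(self.ca_points, dtype=float).reshape(-1, 3)
        if self.z_hi - self.z_lo <= 0:
            raise ValueError("z_hi must exceed z_lo")
        if self.r_p <= 0 or self.f_max <= 0:
            raise ValueError("r_p and f_max must be positive")
        if self.sigma_attr is None:
            # well below r_p/2^(1/6): the radial shift delta then softens
            # the core so confined atoms between wall and protein trace see
            # gentle, not diverging, repulsion
            self.sigma_attr = self.r_p / 2.0
        if self.sigma_attr > self.r_p / _SIXTH_ROOT_2 + 1e-12:
            raise ValueError("sigma_attr must not exceed r_p/2^(1/6)")
        if len(self.ca_points) == 0:
            self.active = self.active.copy()
            self.active[4] = False

    # softened-LJ re-parameterization: shift the radial coordinate by delta
    # so the minimum falls at d = r_p while V crosses zero at d = sigma_attr
    @property
    def _lj_delta(self) -> float:
        return (self.r_p - _SIXTH_ROOT_2 * self.sigma_attr) / (_SIXTH_ROOT_2 - 1.0)

    @property
    def _lj_sigma(self) -> float:
        return self.sigma_attr + self._lj_delta

    @property
    def attr_cutoff(self) -> float:
        return self.attr_cutoff_factor * self.r_p

    def cutoff_of(self, wall_index: np.ndarray) -> np.ndarray:
        """Per-wall force/energy cutoff distance (1-based indices)."""
        return np.where(np.asarray(wall_index) <= 2, self.d_rep, self.attr_cutoff)

    # ------------------------------------------------------------------
    # level-set evaluation
    # ------------------------------------------------------------------
    def phi_values(self, points: np.ndarray) -> np.ndarray:
        """(n, 5) level-set values; +inf where a wall is inactive or the
        point lies outside that wall's z-zone."""
        return self._phi(points, with_grad=False)

    def phi_and_gradients(self, points: np.ndarray):
        return self._phi(points, with_grad=True)

    def _phi(self, points: np.ndarray, with_grad: bool):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(pts)
        z = pts[:, 2]
        upper = z >= self.z_hi
        lower = z <= self.z_lo
        slab = ~upper & ~lower
        vals = np.full((n, 5), np.inf)
        grads = np.zeros((n, 5, 3)) if with_grad else None

        # membrane wall (tube around the Calpha trace), evaluated at every
        # z so that the allowed region outside the slab is the union of the
        # half-space above/below the plane and the protein tube -- the
        # planar walls have a "hole" where the protein passes through
        phi5 = None
        if self.active[4]:
            diff = pts[:, None, :] - self.ca_points[None, :, :]   # (n, m, 3)
            dists = np.linalg.norm(diff, axis=2)                  # (n, m)
            phi5 = self.r_p - smooth_min(dists, self.beta, axis=1)
            if with_grad:
                w = softmax(-self.beta * dists, axis=1)
                units = diff / np.maximum(dists, 1e-12)[:, :, None]
                g5 = -np.einsum("nm,nmd->nd", w, units)
                norms = np.maximum(np.linalg.norm(g5, axis=1), 1e-12)[:, None]
                g5 = g5 / norms

        for widx, mask, plane_phi, plane_grad in (
            (0, upper, z - self.z_hi, np.array([0.0, 0.0, 1.0])),
            (1, lower, self.z_lo - z, np.array([0.0, 0.0, -1.0])),
        ):
            if not self.active[widx] or not mask.any():
                continue
            if phi5 is None:
                vals[mask, widx] = plane_phi[mask]
                if with_grad:
                    grads[mask, widx] = plane_grad
            else:
                tube_wins = mask & (phi5 > plane_phi)
                plane_wins = mask & ~tube_wins
                vals[plane_wins, widx] = plane_phi[plane_wins]
                vals[tube_wins, 4] = phi5[tube_wins]
                if with_grad:
                    grads[plane_wins, widx] = plane_grad
                    grads[tube_wins, 4] = g5[tube_wins]

        for widx, mask, zc, radius in (
            (2, upper, self.z_hi, self.r_upper),
            (3, lower, self.z_lo, self.r_lower),
        ):
            if not self.active[widx] or radius <= 0 or not mask.any():
                continue
            center = np.array([self.center_xy[0], self.center_xy[1], zc])
            rel = pts[mask] - center
            dist = np.linalg.norm(rel, axis=1)
            vals[mask, widx] = radius - dist
            if with_grad:
                safe = np.maximum(dist, 1e-12)[:, None]
                grads[mask, widx] = -rel / safe

        if phi5 is not None and slab.any():
            vals[slab, 4] = phi5[slab]
            if with_grad:
                grads[slab, 4] = g5[slab]

        return (vals, grads) if with_grad else vals

    def distance(self, points: np.ndarray):
        """d = min_i phi_i and the 1-based arg-min wall index (ties to the
        lowest index; 0 when no wall is defined at a point)."""
        vals = self.phi_values(points)
        idx = np.argmin(vals, axis=1)
        d = vals[np.arange(len(vals)), idx]
        index = np.where(np.isfinite(d), idx + 1, 0)
        return d, index

    # ------------------------------------------------------------------
    def droplet_bounding_box(self, side: str = "upper"):
        cx, cy = self.center_xy
        if side == "upper":
            r = self.r_upper
            return (np.array([cx - r, cy - r, self.z_hi]),
                    np.array([cx + r, cy + r, self.z_hi + r]))
        if side == "lower":
            r = self.r_lower
            return (np.array([cx - r, cy - r, self.z_lo - r]),
                    np.array([cx + r, cy + r, self.z_lo]))
        raise ValueError("side must be 'upper' or 'lower'")


# ----------------------------------------------------------------------
# potentials and forces
# ----------------------------------------------------------------------

def wall_potential(d, wall_index, wallset: WallSet):
    """Shifted boundary potential V_i(d) in kJ/mol (vectorized).

    Walls 1-2: purely repulsive eps*(sigma/d)^6, energy-shifted to zero at
    d_rep.  Walls 3-5: softened LJ with minimum at r_p, shifted to zero at
    1.5 r_p.  Distances at or below zero are evaluated at a small floor;
    the finite force cap, not the potential, governs dynamics there.
    """
    d = np.asarray(d, dtype=float)
    idx = np.broadcast_to(np.asarray(wall_index), d.shape)
    out = np.zeros_like(d)
    dd = np.maximum(d, wallset.d_floor)

    rep = (idx >= 1) & (idx <= 2) & (d <= wallset.d_rep)
    if rep.any():
        s6 = wallset.sigma_rep ** 6
        out[rep] = wallset.epsilon * (s6 / dd[rep] ** 6 - s6 / wallset.d_rep ** 6)

    att = (idx >= 3) & (idx <= 5) & (d <= wallset.attr_cutoff)
    if att.any():
        out[att] = _soft_lj(dd[att], wallset) - _soft_lj(
            np.array(wallset.attr_cutoff), wallset
        )
    return out if out.shape else float(out)


def _soft_lj(d, wallset: WallSet):
    x = wallset._lj_sigma / (np.asarray(d) + wallset._lj_delta)
    return 4.0 * wallset.epsilon * (x ** 12 - x ** 6)


def _force_magnitude_unshifted(d, idx, wallset: WallSet):
    """-dV/dd for the unshifted potentials, vectorized over atoms."""
    d = np.asarray(d, dtype=float)
    out = np.zeros_like(d)
    rep = (idx >= 1) & (idx <= 2)
    if rep.any():
        s6 = wallset.sigma_rep ** 6
        out[rep] = 6.0 * wallset.epsilon * s6 / d[rep] ** 7
    att = (idx >= 3) & (idx <= 5)
    if att.any():
        sig, delta = wallset._lj_sigma, wallset._lj_delta
        r = d[att] + delta
        out[att] = 4.0 * wallset.epsilon * (12.0 * sig ** 12 / r ** 13 - 6.0 * sig ** 6 / r ** 7)
    return out


def wall_force_magnitude(d, wall_index, wallset: WallSet):
    """Shifted, capped scalar force (positive = pushing away from the wall).

    Shifting subtracts the unshifted value at the cutoff so the force is
    continuous there; the magnitude is clamped to +-f_max, so any atom
    pressed against a steep wall feels exactly f_max.
    """
    d = np.asarray(d, dtype=float)
    idx = np.broadcast_to(np.asarray(wall_index), d.shape)
    cut = wallset.cutoff_of(idx)
    inside = np.isfinite(d) & (d <= cut) & (idx >= 1)
    out = np.zeros_like(d)
    if inside.any():
        dd = np.maximum(d[inside], wallset.d_floor)
        f = _force_magnitude_unshifted(dd, idx[inside], wallset)
        f -= _force_magnitude_unshifted(cut[inside], idx[inside], wallset)
        f = np.clip(f, -wallset.f_max, wallset.f_max)
        out[inside] = f
    return out if out.shape else float(out)


def wall_forces(positions: np.ndarray, wallset: WallSet,
                indices: np.ndarray | None = None) -> np.ndarray:
    """(n, 3) forces on wall-coupled atoms; rows outside the coupled list
    (or beyond all cutoffs) are zero.

    The force acts along the gradient of the arg-min level set, i.e. toward
    the allowed region for repulsion and toward the wall on the attractive
    branch.
    """
    positions = np.atleast_2d(positions)
    forces = np.zeros_like(positions, dtype=float)
    if indices is None:
        indices = wallset.wall_atom_indices
    if indices is None:
        indices = np.arange(len(positions))
    indices = np.asarray(indices, dtype=int)
    if len(indices) == 0:
        return forces
    pts = positions[indices]
    vals, grads = wallset.phi_and_gradients(pts)
    k = np.argmin(vals, axis=1)
    rows = np.arange(len(pts))
    d = vals[rows, k]
    mag = wall_force_magnitude(d, k + 1, wallset)
    forces[indices] = mag[:, None] * grads[rows, k]
    return forces


def _cap_distance(wallset: WallSet, wall_index: int) -> float:
    """Distance below which the shifted force saturates at f_max (0 when
    the wall's soft core never reaches the cap).  Cached per wall."""
    cache = getattr(wallset, "_cap_d", None)
    if cache is None:
        cache = wallset._cap_d = {}
    if wall_index not in cache:
        lo = wallset.d_floor
        hi = float(wallset.cutoff_of(np.array([wall_index]))[0])
        if _force_magnitude_unshifted(np.array([lo]), np.array([wall_index]),
                                      wallset)[0] - _force_magnitude_unshifted(
                np.array([hi]), np.array([wall_index]), wallset)[0] \
                <= wallset.f_max:
            cache[wall_index] = 0.0
        else:
            for _ in range(80):   # bisection on the monotone repulsive core
                mid = 0.5 * (lo + hi)
                f = wall_force_magnitude(mid, wall_index, wallset)
                if f >= wallset.f_max:
                    lo = mid
                else:
                    hi = mid
            cache[wall_index] = hi
    return cache[wall_index]


def capped_wall_potential(d, wall_index, wallset: WallSet):
    """Boundary potential consistent with the capped force: below the
    saturation distance the potential continues linearly with slope
    f_max, i.e. it is the integral of the force actually applied."""
    d = np.asarray(d, dtype=float)
    idx = np.broadcast_to(np.asarray(wall_index), d.shape)
    out = wall_potential(d, idx, wallset)
    out = np.atleast_1d(np.asarray(out, dtype=float))
    dd = np.atleast_1d(d)
    ii = np.atleast_1d(idx)
    for w in np.unique(ii[ii >= 1]):
        dcap = _cap_distance(wallset, int(w))
        if dcap <= 0:
            continue
        mask = (ii == w) & (dd < dcap)
        if mask.any():
            vcap = wall_potential(dcap, int(w), wallset)
            out[mask] = vcap + wallset.f_max * (dcap - dd[mask])
    return out if out.shape != (1,) or np.ndim(d) else float(out[0])


def wall_energy(positions: np.ndarray, wallset: WallSet,
                indices: np.ndarray | None = None) -> float:
    """Total boundary energy of the coupled atoms (cap-consistent form,
    matching the forces the integrator actually applies)."""
    positions = np.atleast_2d(positions)
    if indices is None:
        indices = wallset.wall_atom_indices
    if indices is None:
        indices = np.arange(len(positions))
    indices = np.asarray(indices, dtype=int)
    if len(indices) == 0:
        return 0.0
    d, idx = wallset.distance(positions[indices])
    ok = np.isfinite(d) & (idx >= 1)
    return float(np.sum(capped_wall_potential(d[ok], idx[ok], wallset)))


def wall_distance(points: np.ndarray, wallset: WallSet):
    """Convenience wrapper: min_i phi_i(point) and the arg-min wall index."""
    return wallset.distance(points)


# ----------------------------------------------------------------------
# construction
# ----------------------------------------------------------------------

def build_walls(
    structure,
    membrane_thickness: float = 3.1,
    water_margin: float = 2.0,
    r_p: float = 0.2,
    beta: float = 50.0,
    aromatic_margin: float = 0.8,
    **potential_params,
) -> WallSet:
    """Construct the five walls around a membrane protein structure.

    The membrane slab is centered on the protein center of mass; the
    hemisphere radii are chosen so the smallest protein-atom-to-surface
    distance outside the slab equals ``water_margin``.  Wall 5 sources are
    the initial transmembrane Calpha positions.  The wall-coupled atom list
    collects all water atoms, all Calpha atoms, and side-chain atoms of
    TRP/TYR residues whose Cbeta starts within ``aromatic_margin`` nm of
    the membrane-wall zero surface.
    """
    prot = structure.protein_mask
    if not prot.any():
        raise WallConstructionError("structure has no protein atoms")
    coords = structure.coords
    masses = structure.mass
    com = np.average(coords[prot], axis=0, weights=masses[prot])
    z_hi = com[2] + membrane_thickness / 2.0
    z_lo = com[2] - membrane_thickness / 2.0

    radii = []
    for zc, above in ((z_hi, True), (z_lo, False)):
        mask = prot & ((coords[:, 2] >= zc) if above else (coords[:, 2] <= zc))
        if not mask.any():
            raise WallConstructionError(
                "no protein atoms outside the membrane slab on the "
                + ("extracellular" if above else "cytoplasmic") + " side"
            )
        center = np.array([com[0], com[1], zc])
        radii.append(np.max(np.linalg.norm(coords[mask] - center, axis=1)) + water_margin)

    ca_map = structure.ca_indices()
    ca_idx = np.array(sorted(ca_map.values()), dtype=int)
    ca_all = coords[ca_idx]
    in_slab = (ca_all[:, 2] >= z_lo) & (ca_all[:, 2] <= z_hi)
    ca_points = ca_all[in_slab]

    wallset = WallSet(
        z_lo=z_lo,
        z_hi=z_hi,
        center_xy=com[:2],
        r_upper=radii[0],
        r_lower=radii[1],
        ca_points=ca_points,
        r_p=r_p,
        beta=beta,
        **potential_params,
    )

    coupled = set(np.flatnonzero(structure.is_water))
    coupled.update(ca_idx.tolist())
    # membrane-facing aromatic side chains
    aromatic = np.isin(structure.res_name, ["TRP", "TYR"]) & prot
    for key in structure.residue_keys():
        res_mask = (structure.chain_id == key[0]) & (structure.res_id == key[1])
        if not (aromatic & res_mask).any():
            continue
        cb = np.flatnonzero(res_mask & (structure.name == "CB"))
        if len(cb) == 0:
            continue
        if len(wallset.ca_points):
            dists = np.linalg.norm(wallset.ca_points - coords[cb[0]], axis=1)
            sm = smooth_min(dists, beta)
            if abs(sm - r_p) <= aromatic_margin:
                side = np.flatnonzero(
                    res_mask & ~np.isin(structure.name, sorted(_BACKBONE_NAMES))
                )
                coupled.update(side.tolist())
    wallset.wall_atom_indices = np.array(sorted(coupled), dtype=int)
    return wallset


def hemisphere_wallset(
    radius: float,
    z0: float = 0.0,
    center_xy=(0.0, 0.0),
    **potential_params,
) -> WallSet:
    """Degenerate wall set for standalone droplet tests: one plane (wall 1)
    at ``z0`` plus the upper hemisphere (wall 3) of the given radius."""
    ws = WallSet(
        z_lo=z0 - 1.0,
        z_hi=z0,
        center_xy=np.asarray(center_xy, dtype=float),
        r_upper=radius,
        r_lower=0.0,
        ca_points=np.empty((0, 3)),
        **potential_params,
    )
    ws.active = np.array([True, False, True, False, False])
    return ws
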