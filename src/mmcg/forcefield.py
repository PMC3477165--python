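"""Energy terms and analytic forces of the hybrid MM/CG potential.

The total potential decomposes into an atomistic part (harmonic bonds and
angles, periodic dihedrals, Lennard-Jones and Coulomb with a shifted-force
cutoff) acting on the MM, interface, water and ligand atoms; a
structure-based (Go) part acting on the coarse-grained Calpha beads; a
coupling part of the same Go functional forms tying CG beads to
interface Calpha/Cbeta atoms; and the boundary-wall energy.

Go-model forms
--------------
* consecutive beads: harmonic, (K_b/2) (r - b)^2 with the native distance b;
* native contacts: Morse-type, V(r) = V0 [ (1 - exp(-B (r - b)))^2 - 1 ],
  so the well depth below the dissociated (flat, zero) limit is exactly V0
  and the minimum sits at the native distance.  The range coefficient B is
  tied to the native distance by B = B_const + 6/b (nm^-1), with
  B_const = 5 for membrane proteins and B_const = 0 recovering the original
  soluble-protein parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .units import COULOMB
from . import boundaries as _bnd

__all__ = [
    "EnergyReport",
    "OverlapError",
    "go_bonded_energy",
    "go_morse_energy",
    "angle_energy",
    "dihedral_energy",
    "mm_energy",
    "coupling_energy",
    "total_energy",
    "nonbonded_pairs",
]

# term/pair classes for the energy decomposition
CLS_MM, CLS_I, CLS_MM_I = 0, 1, 2


class OverlapError(ValueError):
    """Atoms closer than the hard overlap floor (1e-4 nm)."""


@dataclass
class EnergyReport:
    """Per-term potential energies (kJ/mol) following the MM/CG split."""

    e_mm: float = 0.0
    e_i: float = 0.0
    e_mm_i: float = 0.0
    e_cg: float = 0.0
    e_cg_i: float = 0.0
    e_wall: float = 0.0

    @property
    def total(self) -> float:
        return (self.e_mm + self.e_i + self.e_mm_i
                + self.e_cg + self.e_cg_i + self.e_wall)

    def as_dict(self) -> dict:
        return {
            "E_MM": self.e_mm,
            "E_I": self.e_i,
            "E_MM/I": self.e_mm_i,
            "E_CG": self.e_cg,
            "E_CG/I": self.e_cg_i,
            "E_wall": self.e_wall,
            "total": self.total,
        }


# ----------------------------------------------------------------------
# Go-model terms
# ----------------------------------------------------------------------

def _pair_geometry(positions, pairs):
    rij = positions[pairs[:, 1]] - positions[pairs[:, 0]]
    r = np.sqrt(np.einsum("ij,ij->i", rij, rij))
    return rij, r


def _scatter_pair_forces(forces, pairs, fvec):
    """Accumulate +fvec on j and -fvec on i (bincount beats ufunc.at)."""
    n = len(forces)
    for c in range(3):
        forces[:, c] += np.bincount(pairs[:, 1], weights=fvec[:, c], minlength=n)
        forces[:, c] -= np.bincount(pairs[:, 0], weights=fvec[:, c], minlength=n)


def go_bonded_energy(positions, pairs, k, b0):
    """Harmonic bonds between consecutive CG beads.

    Returns (energy, forces); zero energy exactly at the native distances.
    """
    forces = np.zeros_like(positions)
    if len(pairs) == 0:
        return 0.0, forces
    rij, r = _pair_geometry(positions, pairs)
    if np.any(r < 1e-10):
        bad = pairs[np.argmin(r)]
        raise OverlapError(f"coincident beads {bad[0]} and {bad[1]}")
    dr = r - b0
    energy = 0.5 * np.sum(k * dr ** 2)
    # dV/dr = k dr; force on j is -dV/dr * rij_hat
    fmag = -(k * dr) / r
    fvec = fmag[:, None] * rij
    _scatter_pair_forces(forces, pairs, fvec)
    return float(energy), forces


def go_morse_energy(positions, pairs, b0, big_b, v0):
    """Morse-type native-contact term; V(b0) = -v0, V(inf) -> 0."""
    forces = np.zeros_like(positions)
    if len(pairs) == 0:
        return 0.0, forces
    rij, r = _pair_geometry(positions, pairs)
    if np.any(r < 1e-10):
        bad = pairs[np.argmin(r)]
        raise OverlapError(f"coincident beads {bad[0]} and {bad[1]}")
    ex = np.exp(-big_b * (r - b0))
    energy = np.sum(v0 * ((1.0 - ex) ** 2 - 1.0))
    dvdr = 2.0 * v0 * big_b * ex * (1.0 - ex)
    fmag = -dvdr / r
    fvec = fmag[:, None] * rij
    _scatter_pair_forces(forces, pairs, fvec)
    return float(energy), forces


# ----------------------------------------------------------------------
# atomistic MM terms
# ----------------------------------------------------------------------

def _bond_terms(positions, idx, k, r0):
    forces = np.zeros_like(positions)
    if len(idx) == 0:
        return np.zeros(0), forces
    rij, r = _pair_geometry(positions, idx)
    dr = r - r0
    energies = 0.5 * k * dr ** 2
    fmag = -(k * dr) / r
    fvec = fmag[:, None] * rij
    _scatter_pair_forces(forces, idx, fvec)
    return energies, forces


def angle_energy(positions, triples, k, theta0):
    """Harmonic angle term 0.5 K (theta - theta0)^2; theta0 in radians."""
    forces = np.zeros_like(positions)
    if len(triples) == 0:
        return np.zeros(0), forces
    i, j, l = triples[:, 0], triples[:, 1], triples[:, 2]
    u = positions[i] - positions[j]
    v = positions[l] - positions[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos_t = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.maximum(np.sqrt(1.0 - cos_t ** 2), 1e-8)
    dtheta = theta - theta0
    energies = 0.5 * k * dtheta ** 2
    coef = (k * dtheta / sin_t)
    dcos_di = (v / (nu * nv)[:, None]) - (cos_t / nu ** 2)[:, None] * u
    dcos_dl = (u / (nu * nv)[:, None]) - (cos_t / nv ** 2)[:, None] * v
    fi = coef[:, None] * dcos_di
    fl = coef[:, None] * dcos_dl
    np.add.at(forces, i, fi)
    np.add.at(forces, l, fl)
    np.add.at(forces, j, -(fi + fl))
    return energies, forces


def dihedral_energy(positions, quads, k, mult, phase):
    """Periodic dihedral K (1 + cos(n phi - phase)); phase in radians."""
    forces = np.zeros_like(positions)
    if len(quads) == 0:
        return np.zeros(0), forces
    i, j, l, m = quads.T
    b1 = positions[j] - positions[i]
    b2 = positions[l] - positions[j]
    b3 = positions[m] - positions[l]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    phi = np.arctan2(
        np.einsum("ij,ij->i", np.cross(n1, n2), b2) / np.maximum(nb2, 1e-12),
        np.einsum("ij,ij->i", n1, n2),
    )
    energies = k * (1.0 + np.cos(mult * phi - phase))
    dvdphi = -k * mult * np.sin(mult * phi - phase)
    sq1 = np.maximum(np.einsum("ij,ij->i", n1, n1), 1e-24)
    sq2 = np.maximum(np.einsum("ij,ij->i", n2, n2), 1e-24)
    dphi_di = (-nb2 / sq1)[:, None] * n1
    dphi_dm = (nb2 / sq2)[:, None] * n2
    s12 = (np.einsum("ij,ij->i", b1, b2) / nb2 ** 2)[:, None]
    s32 = (np.einsum("ij,ij->i", b3, b2) / nb2 ** 2)[:, None]
    dphi_dj = -(1.0 + s12) * dphi_di + s32 * dphi_dm
    dphi_dl = s12 * dphi_di - (1.0 + s32) * dphi_dm
    for atoms, grad in ((i, dphi_di), (j, dphi_dj), (l, dphi_dl), (m, dphi_dm)):
        np.add.at(forces, atoms, -dvdphi[:, None] * grad)
    return energies, forces


def nonbonded_pairs(positions, topology, cutoff):
    """All unexcluded atomistic pairs within the cutoff (brute-force KD-tree
    scan; the dynamics module maintains a skin-buffered version)."""
    idx = topology.atomistic_indices
    if len(idx) < 2:
        return np.empty((0, 2), dtype=int)
    tree = cKDTree(positions[idx])
    local = tree.query_pairs(cutoff, output_type="ndarray")
    pairs = idx[local]
    return topology.filter_exclusions(pairs)


_CLS_FROM_SUM = np.array([CLS_MM, CLS_MM_I, CLS_I])


@njit(cache=True, fastmath=False)
def _nonbonded_kernel(positions, pairs, sigma, epsilon, charge, iface,
                      cutoff, coulomb_const, forces, e_cls):
    """Fused shifted-force LJ + Coulomb loop over candidate pairs.

    Energies are accumulated per region class (MM / I / MM-I) into e_cls.
    Returns the index of the first overlapping pair, or -1.
    """
    cut2 = cutoff * cutoff
    inv_c = 1.0 / cutoff
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = positions[j, 0] - positions[i, 0]
        dy = positions[j, 1] - positions[i, 1]
        dz = positions[j, 2] - positions[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > cut2:
            continue
        r = np.sqrt(r2)
        if r < 1e-4:
            return p
        inv_r = 1.0 / r
        sig = 0.5 * (sigma[i] + sigma[j])
        eps = np.sqrt(epsilon[i] * epsilon[j])
        qq = coulomb_const * charge[i] * charge[j]

        e = 0.0
        dvdr = 0.0
        if eps > 0.0:
            x6 = (sig * inv_r) ** 6
            x6c = (sig * inv_c) ** 6
            dlj = 4.0 * eps * (-12.0 * x6 * x6 + 6.0 * x6) * inv_r
            dljc = 4.0 * eps * (-12.0 * x6c * x6c + 6.0 * x6c) * inv_c
            e += (4.0 * eps * ((x6 * x6 - x6) - (x6c * x6c - x6c))
                  - dljc * (r - cutoff))
            dvdr += dlj - dljc
        if qq != 0.0:
            e += qq * (inv_r - inv_c + (r - cutoff) * inv_c * inv_c)
            dvdr += qq * (inv_c * inv_c - inv_r * inv_r)

        cls = iface[i] + iface[j]
        if cls == 0:
            e_cls[0] += e
        elif cls == 1:
            e_cls[2] += e
        else:
            e_cls[1] += e

        fmag = -dvdr * inv_r
        fx = fmag * dx
        fy = fmag * dy
        fz = fmag * dz
        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz
    return -1


def _iface_indicator(topology):
    """Cached 0/1 per-atom indicator of interface membership."""
    ind = getattr(topology, "_iface_int", None)
    if ind is None or len(ind) != topology.n_atoms:
        ind = (np.asarray(topology.region_labels) == "I").astype(np.int8)
        topology._iface_int = ind
    return ind


def mm_energy(positions, topology, cutoff: float = 1.6, pairs=None):
    """Atomistic energy of the MM + I + water + ligand atoms.

    Returns (per-class energies ndarray[3], forces).  Nonbonded pair terms
    use a shifted-force cutoff (energy and force both continuous and zero
    at the cutoff); bonded terms (harmonic bonds/angles, periodic
    dihedrals) are classified MM / I / MM-I by the regions of the atoms
    they touch.  Pairs closer than 1e-4 nm raise :class:`OverlapError`.
    """
    e_cls = np.zeros(3)
    forces = np.zeros_like(positions)

    eb, f = _bond_terms(positions, topology.mm_bond_idx, topology.mm_bond_k,
                        topology.mm_bond_r0)
    np.add.at(e_cls, topology.mm_bond_cls, eb)
    forces += f
    ea, f = angle_energy(positions, topology.mm_angle_idx, topology.mm_angle_k,
                         topology.mm_angle_theta0)
    np.add.at(e_cls, topology.mm_angle_cls, ea)
    forces += f
    ed, f = dihedral_energy(positions, topology.mm_dihedral_idx,
                            topology.mm_dihedral_k, topology.mm_dihedral_mult,
                            topology.mm_dihedral_phase)
    np.add.at(e_cls, topology.mm_dihedral_cls, ed)
    forces += f

    if pairs is None:
        pairs = nonbonded_pairs(positions, topology, cutoff)
    if len(pairs):
        bad = _nonbonded_kernel(
            positions, np.ascontiguousarray(pairs, dtype=np.int64),
            topology.lj_sigma, topology.lj_epsilon, topology.charge,
            _iface_indicator(topology), cutoff, COULOMB, forces, e_cls,
        )
        if bad >= 0:
            i, j = pairs[bad]
            raise OverlapError(f"atoms {i} and {j} overlap (r < 1e-4 nm)")
    return e_cls, forces


def coupling_energy(positions, topology):
    """CG <-> interface coupling: same functional forms as the CG terms."""
    e1, f1 = go_bonded_energy(positions, topology.coupling_bond_idx,
                              topology.coupling_bond_k, topology.coupling_bond_b0)
    e2, f2 = go_morse_energy(positions, topology.coupling_contact_idx,
                             topology.coupling_contact_b0,
                             topology.coupling_contact_B,
                             topology.coupling_contact_v0)
    return e1 + e2, f1 + f2


def cg_energy(positions, topology):
    """Go-model energy of the CG region (bonded + Morse contacts)."""
    e1, f1 = go_bonded_energy(positions, topology.go_bond_idx,
                              topology.go_bond_k, topology.go_bond_b0)
    e2, f2 = go_morse_energy(positions, topology.go_contact_idx,
                             topology.go_contact_b0, topology.go_contact_B,
                             topology.go_contact_v0)
    return e1 + e2, f1 + f2


def total_energy(positions, topology, wallset=None, cutoff: float = 1.6,
                 pairs=None):
    """Full MM/CG potential energy report and total forces."""
    report = EnergyReport()
    e_cls, forces = mm_energy(positions, topology, cutoff=cutoff, pairs=pairs)
    report.e_mm, report.e_i, report.e_mm_i = map(float, e_cls)

    e_cg, f = cg_energy(positions, topology)
    report.e_cg = e_cg
    forces += f
    e_ci, f = coupling_energy(positions, topology)
    report.e_cg_i = e_ci
    forces += f

    if wallset is not None:
        report.e_wall = _bnd.wall_energy(positions, wallset)
        forces += _bnd.wall_forces(positions, wallset)
    return report, forces
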