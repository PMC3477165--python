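"""System partitioning and hybrid-topology construction.

A residue is assigned wholly to one region: **MM** if any of its atoms lies
within ``mm_cutoff`` (default 0.5 nm) of a ligand atom, **I** (interface)
if it is not MM but lies within ``interface_cutoff`` (default 0.6 nm,
atom-to-atom) of an MM residue, and **CG** otherwise.  Waters and the
ligand carry their own labels and are treated atomistically alongside the
MM region.

The hybrid topology then instantiates

* Go bonded terms between sequence-consecutive CG beads (b = native
  distance) and Morse contacts between non-consecutive beads closer than
  the native-contact cutoff, with B = B_const + 6/b;
* coupling terms between CG beads and the interface: harmonic bonds to
  sequence-adjacent interface Calphas and Morse contacts to interface
  Calpha/Cbeta atoms within the contact cutoff (glycine contributes its
  Calpha only);
* atomistic bonds/angles/dihedrals and LJ/charge parameters for the
  MM + I + water + ligand atoms from a flat text parameter table;
* SHAKE constraints for every bond containing hydrogen, plus the H-H
  constraint that makes three-site waters rigid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Structure

__all__ = [
    "RegionAssignment",
    "HybridTopology",
    "GoParams",
    "MMParameters",
    "MissingParameterError",
    "assign_regions",
    "build_hybrid_topology",
    "select_ligand",
    "default_parameter_file",
]

MM, I, CG, WATER, LIGAND = "MM", "I", "CG", "WATER", "LIGAND"


def _maybe_native(token: str) -> float | None:
    """Equilibrium values may be the literal ``native``, meaning: use the
    input-structure geometry of each term instance (rigid synthetic
    molecules whose reference geometry is generated, not tabulated)."""
    return None if token.lower() == "native" else float(token)


class MissingParameterError(KeyError):
    pass


def select_ligand(structure: Structure, resname: str | None = None) -> np.ndarray:
    """Atom indices of the ligand (by residue name, or the ligand flags)."""
    if resname is not None:
        return np.flatnonzero(structure.res_name == resname)
    return np.flatnonzero(structure.is_ligand)


# ----------------------------------------------------------------------
# region assignment
# ----------------------------------------------------------------------

@dataclass
class RegionAssignment:
    atom_labels: np.ndarray                       # (n,) str
    residue_labels: dict                          # (chain, res_id) -> label
    cg_bead_indices: np.ndarray                   # Calpha atom index per CG residue
    interface_ca_indices: np.ndarray
    interface_cb_indices: np.ndarray

    @property
    def atomistic_mask(self) -> np.ndarray:
        return np.isin(self.atom_labels, [MM, I, WATER, LIGAND])


def assign_regions(
    structure: Structure,
    ligand_selection: np.ndarray,
    mm_cutoff: float = 0.5,
    interface_cutoff: float = 0.6,
) -> RegionAssignment:
    """Label every atom MM / I / CG / WATER / LIGAND.

    Distances are atom-to-atom minima; the assignment is residue-granular
    for the protein and therefore invariant under rigid motion of the
    whole system.
    """
    ligand_selection = np.asarray(ligand_selection, dtype=int)
    if ligand_selection.size == 0:
        raise ValueError("ligand selection is empty")
    labels = np.full(structure.n_atoms, CG, dtype="U6")
    labels[structure.is_water] = WATER
    labels[ligand_selection] = LIGAND

    prot = structure.protein_mask
    prot_idx = np.flatnonzero(prot)
    residue_labels: dict = {}
    if len(prot_idx):
        lig_tree = cKDTree(structure.coords[ligand_selection])
        dist_to_lig, _ = lig_tree.query(structure.coords[prot_idx])
        res_keys = [
            (str(structure.chain_id[i]), int(structure.res_id[i])) for i in prot_idx
        ]
        res_min: dict = {}
        for key, d in zip(res_keys, dist_to_lig):
            res_min[key] = min(res_min.get(key, np.inf), d)
        mm_residues = {k for k, d in res_min.items() if d < mm_cutoff}
        if not mm_residues:
            warnings.warn(
                "no protein residue within the MM cutoff of the ligand; "
                "MM region contains only ligand and waters",
                stacklevel=2,
            )
        mm_atom_idx = np.array(
            [i for i, k in zip(prot_idx, res_keys) if k in mm_residues], dtype=int
        )
        if len(mm_atom_idx):
            mm_tree = cKDTree(structure.coords[mm_atom_idx])
            dist_to_mm, _ = mm_tree.query(structure.coords[prot_idx])
            i_residues = set()
            for key, d in zip(res_keys, dist_to_mm):
                if key not in mm_residues and d < interface_cutoff:
                    i_residues.add(key)
        else:
            i_residues = set()
        for i, key in zip(prot_idx, res_keys):
            if key in mm_residues:
                labels[i] = MM
                residue_labels[key] = MM
            elif key in i_residues:
                labels[i] = I
                residue_labels[key] = I
            else:
                labels[i] = CG
                residue_labels[key] = CG

    ca_map = structure.ca_indices()
    cg_beads = [ca_map[k] for k in structure.residue_keys()
                if residue_labels.get(k) == CG and k in ca_map]
    iface_ca = [ca_map[k] for k in structure.residue_keys()
                if residue_labels.get(k) == I and k in ca_map]
    iface_cb = [
        i
        for i in np.flatnonzero(prot & (structure.name == "CB"))
        if residue_labels.get((str(structure.chain_id[i]), int(structure.res_id[i]))) == I
    ]
    return RegionAssignment(
        atom_labels=labels,
        residue_labels=residue_labels,
        cg_bead_indices=np.array(cg_beads, dtype=int),
        interface_ca_indices=np.array(iface_ca, dtype=int),
        interface_cb_indices=np.array(iface_cb, dtype=int),
    )


# ----------------------------------------------------------------------
# MM parameter table
# ----------------------------------------------------------------------

@dataclass
class MMParameters:
    """Flat force-field table keyed by atom name (trailing digits ignored).

    File format: whitespace-delimited records tagged ATOM / BOND / ANGLE /
    DIHEDRAL::

        ATOM     <name> <mass> <sigma nm> <epsilon kJ/mol> <charge e>
        BOND     <n1> <n2> <K_r kJ/mol/nm^2> <r0 nm>
        ANGLE    <n1> <n2> <n3> <K_theta kJ/mol/rad^2> <theta0 deg>
        DIHEDRAL <n1> <n2> <n3> <n4> <K kJ/mol> <multiplicity> <phase deg>
    """

    atoms: dict = field(default_factory=dict)
    bonds: dict = field(default_factory=dict)
    angles: dict = field(default_factory=dict)
    dihedrals: dict = field(default_factory=dict)

    @staticmethod
    def _type_of(name: str) -> str:
        return name.rstrip("0123456789")

    @classmethod
    def from_file(cls, path: str | Path) -> "MMParameters":
        params = cls()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            tok = line.split()
            tag = tok[0].upper()
            try:
                if tag == "ATOM":
                    params.atoms[tok[1]] = {
                        "mass": float(tok[2]),
                        "sigma": float(tok[3]),
                        "epsilon": float(tok[4]),
                        "charge": float(tok[5]),
                    }
                elif tag == "BOND":
                    params.bonds[tuple(sorted(tok[1:3]))] = (
                        float(tok[3]), _maybe_native(tok[4]))
                elif tag == "ANGLE":
                    key = tuple(tok[1:4])
                    t0 = _maybe_native(tok[5])
                    val = (float(tok[4]), None if t0 is None else np.deg2rad(t0))
                    params.angles[key] = val
                    params.angles[key[::-1]] = val
                elif tag == "DIHEDRAL":
                    key = tuple(tok[1:5])
                    val = (float(tok[5]), int(tok[6]), np.deg2rad(float(tok[7])))
                    params.dihedrals[key] = val
                    params.dihedrals[key[::-1]] = val
                else:
                    raise ValueError(f"unknown record tag {tag!r}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
        return params

    def atom(self, name: str) -> dict:
        t = name if name in self.atoms else self._type_of(name)
        if t not in self.atoms:
            raise MissingParameterError(
                f"no ATOM parameters for atom name {name!r} (type {t!r})")
        return self.atoms[t]

    def bond(self, n1: str, n2: str):
        key = tuple(sorted((self._type_of(n1), self._type_of(n2))))
        if key not in self.bonds:
            raise MissingParameterError(f"no BOND parameters for {key}")
        return self.bonds[key]

    def angle(self, n1, n2, n3):
        return self.angles.get((self._type_of(n1), self._type_of(n2), self._type_of(n3)))

    def dihedral(self, n1, n2, n3, n4):
        return self.dihedrals.get(tuple(self._type_of(x) for x in (n1, n2, n3, n4)))


def default_parameter_file() -> Path:
    """Path of the minimal self-consistent parameter set shipped for the
    synthetic test systems (pseudo-atom bundle, 5-atom ligand, SPC water)."""
    return Path(__file__).parent / "data" / "toy_ff.par"


# ----------------------------------------------------------------------
# hybrid topology
# ----------------------------------------------------------------------

@dataclass
class GoParams:
    k_b: float = 1000.0     # consecutive-bead force constant, kJ/mol/nm^2
    v0: float = 5.3         # Morse well depth, kJ/mol
    b_const: float = 5.0    # membrane rule B = b_const + 6/b; 0 = soluble rule


def _empty(shape, dtype=float):
    return np.empty(shape, dtype=dtype)


@dataclass
class HybridTopology:
    n_atoms: int
    region_labels: np.ndarray
    cg_bead_indices: np.ndarray
    atomistic_indices: np.ndarray

    go_bond_idx: np.ndarray = field(default_factory=lambda: _empty((0, 2), int))
    go_bond_k: np.ndarray = field(default_factory=lambda: _empty(0))
    go_bond_b0: np.ndarray = field(default_factory=lambda: _empty(0))
    go_contact_idx: np.ndarray = field(default_factory=lambda: _empty((0, 2), int))
    go_contact_b0: np.ndarray = field(default_factory=lambda: _empty(0))
    go_contact_B: np.ndarray = field(default_factory=lambda: _empty(0))
    go_contact_v0: np.ndarray = field(default_factory=lambda: _empty(0))

    coupling_bond_idx: np.ndarray = field(default_factory=lambda: _empty((0, 2), int))
    coupling_bond_k: np.ndarray = field(default_factory=lambda: _empty(0))
    coupling_bond_b0: np.ndarray = field(default_factory=lambda: _empty(0))
    coupling_contact_idx: np.ndarray = field(default_factory=lambda: _empty((0, 2), int))
    coupling_contact_b0: np.ndarray = field(default_factory=lambda: _empty(0))
    coupling_contact_B: np.ndarray = field(default_factory=lambda: _empty(0))
    coupling_contact_v0: np.ndarray = field(default_factory=lambda: _empty(0))

    mm_bond_idx: np.ndarray = field(default_factory=lambda: _empty((0, 2), int))
    mm_bond_k: np.ndarray = field(default_factory=lambda: _empty(0))
    mm_bond_r0: np.ndarray = field(default_factory=lambda: _empty(0))
    mm_bond_cls: np.ndarray = field(default_factory=lambda: _empty(0, int))
    mm_angle_idx: np.ndarray = field(default_factory=lambda: _empty((0, 3), int))
    mm_angle_k: np.ndarray = field(default_factory=lambda: _empty(0))
    mm_angle_theta0: np.ndarray = field(default_factory=lambda: _empty(0))
    mm_angle_cls: np.ndarray = field(default_factory=lambda: _empty(0, int))
    mm_dihedral_idx: np.ndarray = field(default_factory=lambda: _empty((0, 4), int))
    mm_dihedral_k: np.ndarray = field(default_factory=lambda: _empty(0))
    mm_dihedral_mult: np.ndarray = field(default_factory=lambda: _empty(0, int))
    mm_dihedral_phase: np.ndarray = field(default_factory=lambda: _empty(0))
    mm_dihedral_cls: np.ndarray = field(default_factory=lambda: _empty(0, int))

    lj_sigma: np.ndarray = field(default_factory=lambda: _empty(0))
    lj_epsilon: np.ndarray = field(default_factory=lambda: _empty(0))
    charge: np.ndarray = field(default_factory=lambda: _empty(0))

    exclusion_keys: np.ndarray = field(default_factory=lambda: _empty(0, np.int64))
    constraint_idx: np.ndarray = field(default_factory=lambda: _empty((0, 2), int))
    constraint_d0: np.ndarray = field(default_factory=lambda: _empty(0))

    @property
    def n_constraints(self) -> int:
        return len(self.constraint_idx)

    def pair_key(self, pairs: np.ndarray) -> np.ndarray:
        lo = np.minimum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
        hi = np.maximum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
        return lo * self.n_atoms + hi

    def filter_exclusions(self, pairs: np.ndarray) -> np.ndarray:
        if len(pairs) == 0 or len(self.exclusion_keys) == 0:
            return pairs
        return pairs[~np.isin(self.pair_key(pairs), self.exclusion_keys)]


def build_hybrid_topology(
    structure: Structure,
    regions: RegionAssignment,
    go_params: GoParams | None = None,
    native_contact_cutoff: float = 1.2,
    mm_params: MMParameters | None = None,
    bond_detect_cutoff: float = 0.2,
    ligand_bond_cutoff: float = 0.7,
) -> HybridTopology:
    """Instantiate every interaction term of the hybrid potential from the
    native (input) structure and the region assignment."""
    go = go_params or GoParams()
    if mm_params is None:
        mm_params = MMParameters.from_file(default_parameter_file())
    coords = structure.coords
    n = structure.n_atoms
    top = HybridTopology(
        n_atoms=n,
        region_labels=regions.atom_labels.copy(),
        cg_bead_indices=regions.cg_bead_indices.copy(),
        atomistic_indices=np.flatnonzero(regions.atomistic_mask),
    )

    # ---------------- Go model on the CG beads ----------------
    ca_map = structure.ca_indices()
    keys = [k for k in structure.residue_keys() if k in ca_map]
    label_of = {k: regions.residue_labels.get(k) for k in keys}

    def _native(i, j):
        b = float(np.linalg.norm(coords[i] - coords[j]))
        if b < 1e-6:
            raise ValueError(f"zero native distance between atoms {i} and {j}")
        return b

    go_bonds, cpl_bonds = [], []
    for k1, k2 in zip(keys[:-1], keys[1:]):
        if k1[0] != k2[0] or k2[1] - k1[1] != 1:
            continue
        pair = (ca_map[k1], ca_map[k2])
        lab = (label_of[k1], label_of[k2])
        if lab == (CG, CG):
            go_bonds.append(pair)
        elif CG in lab and I in lab:
            cpl_bonds.append(pair)
    if go_bonds:
        top.go_bond_idx = np.array(go_bonds, dtype=int)
        top.go_bond_b0 = np.array([_native(i, j) for i, j in go_bonds])
        top.go_bond_k = np.full(len(go_bonds), go.k_b)
    if cpl_bonds:
        top.coupling_bond_idx = np.array(cpl_bonds, dtype=int)
        top.coupling_bond_b0 = np.array([_native(i, j) for i, j in cpl_bonds])
        top.coupling_bond_k = np.full(len(cpl_bonds), go.k_b)

    # Morse contacts between non-consecutive CG beads
    beads = regions.cg_bead_indices
    bead_keys = [
        (str(structure.chain_id[i]), int(structure.res_id[i])) for i in beads
    ]
    contacts = []
    if len(beads) > 1:
        tree = cKDTree(coords[beads])
        for a, b in tree.query_pairs(native_contact_cutoff, output_type="ndarray"):
            ka, kb = bead_keys[a], bead_keys[b]
            if ka[0] == kb[0] and abs(ka[1] - kb[1]) == 1:
                continue  # bonded neighbors carry the harmonic term
            contacts.append((beads[a], beads[b]))
    if contacts:
        idx = np.array(contacts, dtype=int)
        b0 = np.array([_native(i, j) for i, j in idx])
        top.go_contact_idx = idx
        top.go_contact_b0 = b0
        top.go_contact_B = go.b_const + 6.0 / b0
        top.go_contact_v0 = np.full(len(idx), go.v0)

    # CG bead <-> interface Calpha/Cbeta Morse coupling
    iface_targets = np.concatenate(
        [regions.interface_ca_indices, regions.interface_cb_indices]
    ).astype(int)
    cpl_contacts = []
    bonded_cpl = {tuple(sorted(p)) for p in cpl_bonds}
    if len(beads) and len(iface_targets):
        tree = cKDTree(coords[iface_targets])
        for bi, bead in enumerate(beads):
            for t in tree.query_ball_point(coords[bead], native_contact_cutoff):
                pair = (int(bead), int(iface_targets[t]))
                if tuple(sorted(pair)) in bonded_cpl:
                    continue
                cpl_contacts.append(pair)
    if cpl_contacts:
        idx = np.array(cpl_contacts, dtype=int)
        b0 = np.array([_native(i, j) for i, j in idx])
        top.coupling_contact_idx = idx
        top.coupling_contact_b0 = b0
        top.coupling_contact_B = go.b_const + 6.0 / b0
        top.coupling_contact_v0 = np.full(len(idx), go.v0)

    # ---------------- atomistic terms ----------------
    _build_mm_terms(structure, regions, top, mm_params,
                    bond_detect_cutoff, ligand_bond_cutoff)
    return top


def _term_class(labels) -> int:
    labs = set(labels)
    if labs == {I}:
        return CLS_I_LOCAL
    if I in labs:
        return CLS_MM_I_LOCAL
    return CLS_MM_LOCAL


CLS_MM_LOCAL, CLS_I_LOCAL, CLS_MM_I_LOCAL = 0, 1, 2


def _build_mm_terms(structure, regions, top, mm_params,
                    bond_detect_cutoff, ligand_bond_cutoff):
    coords = structure.coords
    labels = regions.atom_labels
    atomistic = np.flatnonzero(regions.atomistic_mask)

    # bond detection: intra-residue distance rule plus the consecutive
    # Calpha-Calpha backbone link between atomistic protein residues
    bonds: list[tuple[int, int]] = []
    res_atoms = structure.residue_atom_indices()
    for key, idx in res_atoms.items():
        idx = idx[np.isin(idx, atomistic)]
        if len(idx) < 2:
            continue
        cut = ligand_bond_cutoff if structure.is_ligand[idx[0]] else bond_detect_cutoff
        hyd = np.char.upper(structure.element[idx].astype(str)) == "H"
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if hyd[a] and hyd[b]:
                    continue  # H-H is never a covalent bond
                i, j = int(idx[a]), int(idx[b])
                if np.linalg.norm(coords[i] - coords[j]) < cut:
                    bonds.append((i, j))
    ca_map = structure.ca_indices()
    keys = [k for k in structure.residue_keys() if k in ca_map]
    for k1, k2 in zip(keys[:-1], keys[1:]):
        if k1[0] != k2[0] or k2[1] - k1[1] != 1:
            continue
        if regions.residue_labels.get(k1) in (MM, I) and \
           regions.residue_labels.get(k2) in (MM, I):
            bonds.append((ca_map[k1], ca_map[k2]))

    is_h = np.char.upper(structure.element.astype(str)) == "H"
    bond_idx, bond_k, bond_r0, bond_cls = [], [], [], []
    constraints: list[tuple[int, int, float]] = []
    for i, j in bonds:
        k_r, r0 = mm_params.bond(structure.name[i], structure.name[j])
        if r0 is None:
            r0 = float(np.linalg.norm(coords[i] - coords[j]))
        if is_h[i] or is_h[j]:
            constraints.append((i, j, r0))
        else:
            bond_idx.append((i, j))
            bond_k.append(k_r)
            bond_r0.append(r0)
            bond_cls.append(_term_class(labels[[i, j]]))

    # angles from the bond graph (constrained bonds included)
    neighbors: dict[int, set[int]] = {}
    for i, j in bonds:
        neighbors.setdefault(i, set()).add(j)
        neighbors.setdefault(j, set()).add(i)
    angle_idx, angle_k, angle_t0, angle_cls = [], [], [], []
    water_hh: list[tuple[int, int, float]] = []
    seen_angles = set()
    for j, nbrs in neighbors.items():
        for i in nbrs:
            for k in nbrs:
                if i >= k:
                    continue
                akey = (i, j, k)
                if akey in seen_angles:
                    continue
                seen_angles.add(akey)
                rec = mm_params.angle(structure.name[i], structure.name[j],
                                      structure.name[k])
                if rec is None:
                    continue
                k_t, t0 = rec
                if t0 is None:
                    u = coords[i] - coords[j]
                    w = coords[k] - coords[j]
                    t0 = float(np.arccos(np.clip(
                        np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w)),
                        -1.0, 1.0)))
                if structure.is_water[j] and is_h[i] and is_h[k]:
                    # rigid water: replace the angle by an H-H constraint
                    _, r_oh = mm_params.bond(structure.name[i], structure.name[j])
                    water_hh.append((i, k, 2.0 * r_oh * np.sin(t0 / 2.0)))
                    continue
                angle_idx.append((i, j, k))
                angle_k.append(k_t)
                angle_t0.append(t0)
                angle_cls.append(_term_class(labels[[i, j, k]]))

    # dihedrals along bonded paths i-j-k-l
    dih_idx, dih_k, dih_m, dih_p, dih_cls = [], [], [], [], []
    seen_dih = set()
    for j, k in bonds:
        for i in neighbors.get(j, ()):
            if i == k:
                continue
            for l in neighbors.get(k, ()):
                if l == j or l == i:
                    continue
                dkey = (i, j, k, l) if i < l else (l, k, j, i)
                if dkey in seen_dih:
                    continue
                seen_dih.add(dkey)
                rec = mm_params.dihedral(structure.name[i], structure.name[j],
                                         structure.name[k], structure.name[l])
                if rec is None:
                    continue
                kd, mult, phase = rec
                dih_idx.append((i, j, k, l))
                dih_k.append(kd)
                dih_m.append(mult)
                dih_p.append(phase)
                dih_cls.append(_term_class(labels[[i, j, k, l]]))

    constraints.extend(water_hh)

    top.mm_bond_idx = np.array(bond_idx, dtype=int).reshape(-1, 2)
    top.mm_bond_k = np.array(bond_k)
    top.mm_bond_r0 = np.array(bond_r0)
    top.mm_bond_cls = np.array(bond_cls, dtype=int)
    top.mm_angle_idx = np.array(angle_idx, dtype=int).reshape(-1, 3)
    top.mm_angle_k = np.array(angle_k)
    top.mm_angle_theta0 = np.array(angle_t0)
    top.mm_angle_cls = np.array(angle_cls, dtype=int)
    top.mm_dihedral_idx = np.array(dih_idx, dtype=int).reshape(-1, 4)
    top.mm_dihedral_k = np.array(dih_k)
    top.mm_dihedral_mult = np.array(dih_m, dtype=int).reshape(-1)
    top.mm_dihedral_phase = np.array(dih_p)
    top.mm_dihedral_cls = np.array(dih_cls, dtype=int)

    if constraints:
        carr = np.array([(i, j) for i, j, _ in constraints], dtype=int)
        top.constraint_idx = carr
        top.constraint_d0 = np.array([d for _, _, d in constraints])

    # LJ / charges for atomistic atoms; zero elsewhere
    n = structure.n_atoms
    top.lj_sigma = np.zeros(n)
    top.lj_epsilon = np.zeros(n)
    top.charge = np.zeros(n)
    for i in atomistic:
        rec = mm_params.atom(structure.name[i])
        top.lj_sigma[i] = rec["sigma"]
        top.lj_epsilon[i] = rec["epsilon"]
        top.charge[i] = rec["charge"]

    # exclusions: 1-2 (bonds + constraints) and 1-3 pairs
    excl = set()
    all_bonded = bonds + [(i, j) for i, j, _ in constraints]
    graph: dict[int, set[int]] = {}
    for i, j in all_bonded:
        graph.setdefault(i, set()).add(j)
        graph.setdefault(j, set()).add(i)
        excl.add((min(i, j), max(i, j)))
    for j, nbrs in graph.items():
        for i in nbrs:
            for k in nbrs:
                if i < k:
                    excl.add((i, k))
    if excl:
        pairs = np.array(sorted(excl), dtype=int)
        top.exclusion_keys = top.pair_key(pairs)

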