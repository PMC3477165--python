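"""Structures, trajectories, PDB/XYZ I/O and synthetic test systems.

The in-memory :class:`Structure` is a flat, array-backed container (one
entry per atom) holding everything the simulator needs: coordinates in nm,
masses, partial charges and water/ligand flags.  PDB files are parsed and
written through :mod:`biotite`; the Angstrom <-> nm conversion happens only
here, at the I/O boundary.

The module also generates the synthetic systems used throughout the test
suite: ideal-geometry helical bundles standing in for a transmembrane
receptor, and rigid three-site water droplets confined by a wall set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as _struc
from biotite.structure.io.pdb import PDBFile

from .units import ANGSTROM_PER_NM, NM_PER_ANGSTROM, mass_of

WATER_RESNAMES = {"HOH", "SOL", "WAT"}

__all__ = [
    "Structure",
    "Trajectory",
    "PDBParseError",
    "StructureValidationError",
    "CapacityError",
    "read_pdb",
    "write_pdb",
    "write_trajectory",
    "read_trajectory",
    "generate_toy_bundle",
    "generate_water_droplet",
    "concat_structures",
]


class PDBParseError(ValueError):
    """Raised for malformed PDB records; carries the offending line number."""


class StructureValidationError(ValueError):
    """Raised when a Structure violates its invariants."""


class CapacityError(RuntimeError):
    """Raised when water placement cannot fit the requested molecule count."""

    def __init__(self, requested: int, placed: int):
        self.requested = requested
        self.placed = placed
        super().__init__(
            f"could only place {placed} of {requested} waters before the "
            f"attempt budget was exhausted"
        )


@dataclass
class Structure:
    """Array-backed molecular structure.  Coordinates are in nm."""

    serial: np.ndarray        # (n,) int
    name: np.ndarray          # (n,) str atom names
    element: np.ndarray       # (n,) str
    res_name: np.ndarray      # (n,) str
    res_id: np.ndarray        # (n,) int
    chain_id: np.ndarray      # (n,) str
    coords: np.ndarray        # (n, 3) float, nm
    mass: np.ndarray          # (n,) float, amu
    charge: np.ndarray        # (n,) float, e
    is_water: np.ndarray      # (n,) bool
    is_ligand: np.ndarray     # (n,) bool

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def protein_mask(self) -> np.ndarray:
        return ~(self.is_water | self.is_ligand)

    def copy(self) -> "Structure":
        return Structure(**{k: getattr(self, k).copy() for k in self.__dataclass_fields__})

    # residues ----------------------------------------------------------
    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, res_id) pairs."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_id, self.res_id):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def residue_atom_indices(self) -> dict[tuple[str, int], np.ndarray]:
        out: dict[tuple[str, int], list[int]] = {}
        for i, (c, r) in enumerate(zip(self.chain_id, self.res_id)):
            out.setdefault((str(c), int(r)), []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}

    def ca_indices(self) -> dict[tuple[str, int], int]:
        """Alpha-carbon atom index of each protein residue."""
        out: dict[tuple[str, int], int] = {}
        prot = self.protein_mask
        for i in np.flatnonzero(prot):
            if self.name[i] == "CA":
                key = (str(self.chain_id[i]), int(self.res_id[i]))
                if key in out:
                    raise StructureValidationError(
                        f"residue {key} has more than one alpha-carbon"
                    )
                out[key] = i
        return out

    # validation --------------------------------------------------------
    def validate(self) -> None:
        if self.n_atoms == 0:
            raise StructureValidationError("structure contains no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise StructureValidationError("non-finite coordinates")
        if np.any(self.is_water & self.is_ligand):
            raise StructureValidationError("atom flagged both water and ligand")
        # residue ids strictly increasing within a chain
        for chain in np.unique(self.chain_id):
            ids = self.res_id[self.chain_id == chain]
            # collapse consecutive duplicates (atoms of one residue)
            uniq = ids[np.concatenate(([True], np.diff(ids) != 0))]
            if np.any(np.diff(uniq) <= 0):
                raise StructureValidationError(
                    f"residue indices not strictly increasing in chain {chain!r}"
                )
        # every protein residue carries exactly one CA
        cas = self.ca_indices()
        prot = self.protein_mask
        for key in self.residue_keys():
            idx = np.flatnonzero(
                (self.chain_id == key[0]) & (self.res_id == key[1]) & prot
            )
            if len(idx) and key not in cas:
                raise StructureValidationError(
                    f"protein residue {key} has no alpha-carbon atom"
                )


@dataclass
class Trajectory:
    """A sequence of frames sharing one reference :class:`Structure`."""

    structure: Structure
    coords: np.ndarray                    # (n_frames, n_atoms, 3) nm
    times: np.ndarray                     # (n_frames,) ps
    velocities: np.ndarray | None = None  # (n_frames, n_atoms, 3) nm/ps
    energies: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.structure.n_atoms:
            raise ValueError("frame atom count does not match the reference structure")
        if len(self.times) != len(self.coords):
            raise ValueError("times and frames differ in length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.coords)


# ----------------------------------------------------------------------
# PDB input / output
# ----------------------------------------------------------------------

def _precheck_pdb_lines(path: Path) -> int:
    """Light column sanity check; returns the number of atom records.

    Biotite's parser is authoritative; this pass only exists to attribute
    an error to a line number when a coordinate field is mangled.
    """
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                n += 1
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(
                        f"{path}, line {lineno}: atom record too short for coordinates"
                    )
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"{path}, line {lineno}: unparsable coordinate field"
                    ) from None
    return n


def _structure_from_atom_array(arr: "_struc.AtomArray") -> Structure:
    n = arr.array_length()
    res_name = np.asarray(arr.res_name, dtype="U5")
    hetero = np.asarray(arr.hetero, dtype=bool)
    is_water = np.isin(res_name, sorted(WATER_RESNAMES))
    is_ligand = hetero & ~is_water
    element = np.asarray(arr.element, dtype="U3")
    mass = np.array([mass_of(e) for e in element])
    return Structure(
        serial=np.arange(1, n + 1),
        name=np.asarray(arr.atom_name, dtype="U5"),
        element=element,
        res_name=res_name,
        res_id=np.asarray(arr.res_id, dtype=int),
        chain_id=np.asarray(arr.chain_id, dtype="U2"),
        coords=np.asarray(arr.coord, dtype=float) * NM_PER_ANGSTROM,
        mass=mass,
        charge=np.zeros(n),
        is_water=is_water,
        is_ligand=is_ligand,
    )


def read_pdb(path: str | Path, validate: bool = True) -> Structure:
    """Read a PDB file into a :class:`Structure` (coordinates in nm).

    Water residues (HOH/SOL/WAT) and non-water HETATM residues are flagged
    as water and ligand respectively.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    n_records = _precheck_pdb_lines(path)
    if n_records == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # biotite raises several parse error types
        raise PDBParseError(f"{path}: {exc}") from exc
    structure = _structure_from_atom_array(arr)
    if validate:
        structure.validate()
    return structure


def _atom_array_from_structure(structure: Structure, coords_nm: np.ndarray) -> "_struc.AtomArray":
    n = structure.n_atoms
    arr = _struc.AtomArray(n)
    arr.coord = np.asarray(coords_nm, dtype=np.float32) * ANGSTROM_PER_NM
    arr.chain_id = structure.chain_id.astype("U4")
    arr.res_id = structure.res_id.astype(int)
    arr.res_name = structure.res_name.astype("U5")
    arr.atom_name = structure.name.astype("U6")
    arr.element = structure.element.astype("U2")
    arr.hetero = (structure.is_water | structure.is_ligand).astype(bool)
    return arr


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure to a PDB file (nm converted back to Angstrom)."""
    if structure.n_atoms == 0:
        raise ValueError("refusing to write an empty structure")
    pdb = PDBFile()
    pdb.set_structure(_atom_array_from_structure(structure, structure.coords))
    pdb.write(str(Path(path)))


def write_trajectory(trajectory: Trajectory, path: str | Path, stride: int = 1) -> None:
    """Write frames to a multi-model PDB (.pdb) or multi-frame XYZ (.xyz).

    Frame times are stamped in a ``REMARK 250 TIME`` line (PDB) or in the
    XYZ comment line.  ``stride`` keeps every stride-th frame.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    path = Path(path)
    frames = trajectory.coords[::stride]
    times = trajectory.times[::stride]
    if path.suffix.lower() == ".xyz":
        _write_xyz(trajectory.structure, frames, times, path)
        return
    arrays = [
        _atom_array_from_structure(trajectory.structure, f) for f in frames
    ]
    pdb = PDBFile()
    pdb.set_structure(_struc.stack(arrays))
    # stamp times next to each MODEL line
    lines, k = [], 0
    for line in pdb.lines:
        lines.append(line)
        if line.startswith("MODEL"):
            lines.append(f"REMARK 250 TIME {times[k]:.6f} PS")
            k += 1
    pdb.lines = lines
    pdb.write(str(path))


def _write_xyz(structure: Structure, frames: np.ndarray, times: np.ndarray, path: Path) -> None:
    with open(path, "w") as fh:
        for f, t in zip(frames, times):
            fh.write(f"{structure.n_atoms}\n")
            fh.write(f"t= {t:.6f} ps\n")
            for name, xyz in zip(structure.name, f * ANGSTROM_PER_NM):
                fh.write(f"{name:<4s} {xyz[0]:12.5f} {xyz[1]:12.5f} {xyz[2]:12.5f}\n")


def read_trajectory(path: str | Path, reference: Structure | None = None) -> Trajectory:
    """Read a multi-model PDB or XYZ trajectory written by this package."""
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        if reference is None:
            raise ValueError("XYZ trajectories need a reference structure")
        frames, times = [], []
        with open(path) as fh:
            while True:
                head = fh.readline()
                if not head.strip():
                    break
                n = int(head)
                comment = fh.readline().split()
                times.append(float(comment[1]) if len(comment) >= 2 else float(len(times)))
                coords = np.array(
                    [[float(x) for x in fh.readline().split()[1:4]] for _ in range(n)]
                )
                frames.append(coords * NM_PER_ANGSTROM)
        return Trajectory(reference, np.array(frames), np.array(times))

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    if isinstance(stack, _struc.AtomArray):
        stack = _struc.stack([stack])
    structure = reference or _structure_from_atom_array(stack[0])
    times = [
        float(line.split()[3])
        for line in pdb.lines
        if line.startswith("REMARK 250 TIME")
    ]
    if len(times) != stack.stack_depth():
        times = list(range(stack.stack_depth()))
    return Trajectory(
        structure,
        np.asarray(stack.coord, dtype=float) * NM_PER_ANGSTROM,
        np.asarray(times, dtype=float),
    )


# ----------------------------------------------------------------------
# Synthetic systems
# ----------------------------------------------------------------------

# ideal alpha-helix parameters for the Calpha trace
HELIX_RISE = 0.15        # nm per residue
HELIX_RADIUS = 0.23      # nm
HELIX_TWIST = 100.0      # degrees per residue
CA_CB_LENGTH = 0.153     # nm

_RESIDUE_POOL = ["ALA", "LEU", "VAL", "PHE", "GLY", "TRP", "TYR", "SER", "ILE", "MET"]


def generate_toy_bundle(
    n_helices: int,
    residues_per_helix: int,
    seed: int = 0,
    with_ligand: bool = False,
    bundle_radius_scale: float = 0.5,
    ligand_arm: float | None = None,
) -> Structure:
    """Build an ideal-geometry helical bundle standing in for a membrane
    receptor, optionally with a small rigid ligand in the central pore.

    Each helix is an ideal alpha-helical Calpha trace (rise 0.15 nm/residue,
    radius 0.23 nm, 100 deg/residue) with a pseudo-Cbeta on every non-glycine
    residue, the axes parallel to z and arranged on a circle of radius
    ``bundle_radius_scale * sqrt(n_helices)`` nm.  The ligand is five carbon
    atoms: a center plus four tetrahedral arms; the default arm length
    scales with the bundle radius so the ligand fills the pore and contacts
    the pocket-lining residues.  Everything is a pure function of the
    arguments, including the seed.
    """
    if n_helices < 1:
        raise ValueError("n_helices must be >= 1")
    if residues_per_helix < 4:
        raise ValueError("residues_per_helix must be >= 4")
    rng = np.random.default_rng(seed)

    names, elements, res_names, res_ids, chain_ids, coords = [], [], [], [], [], []
    is_water, is_ligand = [], []
    chains = [chr(ord("A") + h) for h in range(n_helices)]
    bundle_radius = 0.0 if n_helices == 1 else bundle_radius_scale * np.sqrt(n_helices)
    half_length = HELIX_RISE * (residues_per_helix - 1) / 2.0

    res_counter = 0
    for h in range(n_helices):
        ang = 2 * np.pi * h / n_helices
        axis = np.array([bundle_radius * np.cos(ang), bundle_radius * np.sin(ang), 0.0])
        phase = rng.uniform(0, 2 * np.pi)
        for k in range(residues_per_helix):
            res_counter += 1
            theta = phase + np.deg2rad(HELIX_TWIST) * k
            ca = axis + np.array(
                [
                    HELIX_RADIUS * np.cos(theta),
                    HELIX_RADIUS * np.sin(theta),
                    HELIX_RISE * k - half_length,
                ]
            )
            res_name = _RESIDUE_POOL[rng.integers(len(_RESIDUE_POOL))]
            for atom_name, pos in _residue_atoms(res_name, ca, axis):
                names.append(atom_name)
                elements.append("C")
                res_names.append(res_name)
                res_ids.append(k + 1)
                chain_ids.append(chains[h])
                coords.append(pos)
                is_water.append(False)
                is_ligand.append(False)

    if with_ligand:
        if ligand_arm is None:
            # reach from the pore center toward the inner helix surface,
            # leaving a van-der-Waals-sized gap (tetrahedral arms project
            # onto the xy plane with factor sqrt(2/3))
            ligand_arm = max(0.2, (bundle_radius - HELIX_RADIUS - 0.3)
                             / np.sqrt(2.0 / 3.0))
        tet = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) / np.sqrt(3.0)
        lig = np.vstack([[0.0, 0.0, 0.0], tet * ligand_arm])
        for i, pos in enumerate(lig):
            names.append(f"C{i + 1}")
            elements.append("C")
            res_names.append("LIG")
            res_ids.append(1)
            chain_ids.append("X")
            coords.append(pos)
            is_water.append(False)
            is_ligand.append(True)

    n = len(names)
    structure = Structure(
        serial=np.arange(1, n + 1),
        name=np.array(names, dtype="U5"),
        element=np.array(elements, dtype="U3"),
        res_name=np.array(res_names, dtype="U5"),
        res_id=np.array(res_ids, dtype=int),
        chain_id=np.array(chain_ids, dtype="U2"),
        coords=np.array(coords, dtype=float),
        mass=np.array([mass_of(e) for e in elements]),
        charge=np.zeros(n),
        is_water=np.zeros(n, dtype=bool),
        is_ligand=np.array(is_ligand, dtype=bool),
    )
    structure.validate()
    return structure


def _residue_atoms(res_name, ca, axis):
    yield "CA", ca
    if res_name != "GLY":
        radial = ca - axis
        radial[2] = 0.0
        norm = np.linalg.norm(radial)
        direction = radial / norm if norm > 1e-12 else np.array([1.0, 0.0, 0.0])
        yield "CB", ca + CA_CB_LENGTH * direction


# rigid three-site water geometry (SPC): O-H 0.1 nm, H-O-H 109.47 deg
WATER_OH = 0.1
WATER_ANGLE_DEG = 109.47


def _water_sites(o_pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """O, H, H coordinates for a randomly oriented rigid water at o_pos."""
    # random orthonormal frame
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    v = np.cross(u, rng.normal(size=3))
    v /= np.linalg.norm(v)
    half = np.deg2rad(WATER_ANGLE_DEG) / 2
    h1 = o_pos + WATER_OH * (np.cos(half) * u + np.sin(half) * v)
    h2 = o_pos + WATER_OH * (np.cos(half) * u - np.sin(half) * v)
    return np.vstack([o_pos, h1, h2])


def generate_water_droplet(
    n_waters: int,
    wallset,
    side: str = "upper",
    min_spacing: float = 0.26,
    seed: int = 0,
    exclusion_points: np.ndarray | None = None,
    exclusion_radius: float = 0.25,
    wall_margin: float = 0.25,
    max_attempts_per_water: int = 20000,
) -> Structure:
    """Place rigid 3-site waters inside a wall-bounded droplet region.

    Oxygen positions are drawn by rejection sampling: a candidate must lie
    strictly inside the positive level-set region (with ``wall_margin`` nm
    clearance from the walls so that no molecule starts on the repulsive
    ramp), at least ``exclusion_radius`` from every exclusion point
    (protein atoms), and at least ``min_spacing`` from every previously
    accepted oxygen.  Deterministic for a fixed seed.
    """
    if n_waters < 1:
        raise ValueError("n_waters must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = wallset.droplet_bounding_box(side)
    placed: list[np.ndarray] = []
    attempts_left = max_attempts_per_water * n_waters
    while len(placed) < n_waters and attempts_left > 0:
        attempts_left -= 1
        cand = rng.uniform(lo, hi)
        d, _ = wallset.distance(cand[None, :])
        if d[0] < wall_margin:
            continue
        if exclusion_points is not None and len(exclusion_points):
            if np.min(np.linalg.norm(exclusion_points - cand, axis=1)) < exclusion_radius:
                continue
        if placed and np.min(np.linalg.norm(np.array(placed) - cand, axis=1)) < min_spacing:
            continue
        placed.append(cand)
    if len(placed) < n_waters:
        raise CapacityError(n_waters, len(placed))

    coords = np.vstack([_water_sites(p, rng) for p in placed])
    n = 3 * n_waters
    return Structure(
        serial=np.arange(1, n + 1),
        name=np.array(["OW", "HW1", "HW2"] * n_waters, dtype="U5"),
        element=np.array(["O", "H", "H"] * n_waters, dtype="U3"),
        res_name=np.array(["HOH"] * n, dtype="U5"),
        res_id=np.repeat(np.arange(1, n_waters + 1), 3),
        chain_id=np.array(["W"] * n, dtype="U2"),
        coords=coords,
        mass=np.array([mass_of(e) for e in ["O", "H", "H"] * n_waters]),
        charge=np.zeros(n),
        is_water=np.ones(n, dtype=bool),
        is_ligand=np.zeros(n, dtype=bool),
    )


def concat_structures(*parts: Structure) -> Structure:
    """Concatenate structures (e.g. protein bundle + water droplet)."""
    fields_ = {}
    for name in Structure.__dataclass_fields__:
        arrays = [getattr(p, name) for p in parts]
        if name == "serial":
            fields_[name] = np.arange(1, sum(len(a) for a in arrays) + 1)
        else:
            fields_[name] = np.concatenate(arrays)
    return Structure(**fields_)
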