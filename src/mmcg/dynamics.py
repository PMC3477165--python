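"""Time integration: stochastic (Langevin) dynamics with SHAKE constraints.

The integrator is a leapfrog with an impulse Langevin thermostat: after the
kick by the systematic force, velocities are relaxed by ``exp(-gamma dt)``
(``gamma = 1/tau``, the inverse of the friction time constant) and receive
Gaussian noise scaled so the stationary velocity distribution satisfies
fluctuation-dissipation at the target temperature.  With ``gamma = 0`` the
step is exactly velocity-Verlet/leapfrog, which the NVE conservation tests
rely on.  SHAKE is applied after every position update and the velocities
are recomputed from the constrained displacement, keeping rigid waters
rigid to the requested tolerance throughout a run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from numba import njit
from scipy.spatial import cKDTree

from .units import KB
from .structure_io import Structure, Trajectory
from .partitioning import (
    RegionAssignment, HybridTopology, GoParams, MMParameters,
    assign_regions, build_hybrid_topology, select_ligand,
)
from . import forcefield as ff
from . import boundaries as bnd

logger = logging.getLogger("mmcg")

__all__ = [
    "RunConfig",
    "SimulationState",
    "System",
    "init_velocities",
    "shake",
    "sd_step",
    "minimize",
    "simulate",
    "run",
    "build_system",
    "solvent_only_regions",
]


@dataclass
class RunConfig:
    """Simulation settings; the defaults are the production values of the
    scheme (2 fs steps, 300 K, inverse friction constant 0.4 ps, 1.6 nm
    interaction cutoffs, 0.5/0.6 nm region cutoffs)."""

    timestep: float = 0.002            # ps
    n_steps: int = 0
    temperature: float = 300.0         # K
    tau: float = 0.4                   # inverse friction constant, ps
    seed: int = 1
    cutoff: float = 1.6                # nonbonded + Go cutoff, nm
    mm_cutoff: float = 0.5
    interface_cutoff: float = 0.6
    native_contact_cutoff: float = 1.2
    go_k_b: float = 1000.0
    go_v0: float = 5.3
    go_b_const: float = 5.0
    membrane_thickness: float = 3.1
    water_margin: float = 2.0
    r_p: float = 0.2
    wall_beta: float = 50.0
    shake_tol: float = 1e-6
    shake_max_iter: int = 500
    minimize_steps: int = 200
    minimize_fmax: float = 200.0       # kJ/mol/nm convergence threshold
    output_stride: int = 100
    save_velocities: bool = False
    neighbor_skin: float = 0.2
    neighbor_every: int = 10
    pdb: str | None = None
    ligand_resname: str | None = None
    parameter_file: str | None = None
    trajectory_path: str | None = None

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def go_params(self) -> GoParams:
        return GoParams(k_b=self.go_k_b, v0=self.go_v0, b_const=self.go_b_const)


@dataclass
class SimulationState:
    positions: np.ndarray
    velocities: np.ndarray
    forces: np.ndarray
    masses: np.ndarray
    n_dof: int
    time: float = 0.0
    step: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    energy: "ff.EnergyReport | None" = None

    @property
    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.masses * np.sum(self.velocities ** 2, axis=1)))

    @property
    def temperature(self) -> float:
        if self.n_dof <= 0:
            return 0.0
        return 2.0 * self.kinetic_energy / (self.n_dof * KB)


class ShakeError(RuntimeError):
    pass


def init_velocities(masses: np.ndarray, temperature: float, seed=None,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Maxwell-Boltzmann velocities with the center-of-mass drift removed."""
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("all masses must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    if temperature <= 0:
        return np.zeros((len(masses), 3))
    sigma = np.sqrt(KB * temperature / masses)
    v = rng.normal(size=(len(masses), 3)) * sigma[:, None]
    v -= np.average(v, axis=0, weights=masses)
    return v


@njit(cache=True)
def _shake_kernel(pos, r_old, i_all, j_all, inv_mi, inv_mj, d0,
                  tol, max_iter):
    """Gauss-Seidel SHAKE sweeps; returns (iterations, worst violation).

    iterations = -1 signals non-convergence.
    """
    m = len(i_all)
    worst = 0.0
    for it in range(max_iter):
        worst = 0.0
        for c in range(m):
            i = i_all[c]
            j = j_all[c]
            rx = pos[j, 0] - pos[i, 0]
            ry = pos[j, 1] - pos[i, 1]
            rz = pos[j, 2] - pos[i, 2]
            r2 = rx * rx + ry * ry + rz * rz
            viol = abs(np.sqrt(r2) - d0[c]) / d0[c]
            if viol > worst:
                worst = viol
            if viol > tol:
                ox = r_old[c, 0]
                oy = r_old[c, 1]
                oz = r_old[c, 2]
                denom = 2.0 * (ox * rx + oy * ry + oz * rz) \
                    * (inv_mi[c] + inv_mj[c])
                if abs(denom) < 1e-12:
                    denom = 1e-12
                g = (r2 - d0[c] * d0[c]) / denom
                pos[i, 0] += g * ox * inv_mi[c]
                pos[i, 1] += g * oy * inv_mi[c]
                pos[i, 2] += g * oz * inv_mi[c]
                pos[j, 0] -= g * ox * inv_mj[c]
                pos[j, 1] -= g * oy * inv_mj[c]
                pos[j, 2] -= g * oz * inv_mj[c]
        if worst < tol:
            return it + 1, worst
    return -1, worst


def shake(positions_old: np.ndarray, positions_new: np.ndarray,
          constraint_idx: np.ndarray, constraint_d0: np.ndarray,
          masses: np.ndarray, tol: float = 1e-6,
          max_iter: int = 500) -> np.ndarray:
    """Iteratively project ``positions_new`` onto the constraint manifold.

    Corrections are applied along the pre-step bond vectors with mass
    weighting (classic SHAKE, Gauss-Seidel sweeps).  Convergence means
    every bond length is within relative ``tol`` of its target; failure
    raises :class:`ShakeError` with the worst violation.
    """
    if len(constraint_idx) == 0:
        return positions_new
    pos = np.ascontiguousarray(positions_new, dtype=float).copy()
    i_all = np.ascontiguousarray(constraint_idx[:, 0], dtype=np.int64)
    j_all = np.ascontiguousarray(constraint_idx[:, 1], dtype=np.int64)
    r_old = np.ascontiguousarray(
        positions_old[j_all] - positions_old[i_all], dtype=float)
    iters, worst = _shake_kernel(
        pos, r_old, i_all, j_all,
        1.0 / masses[i_all], 1.0 / masses[j_all],
        np.ascontiguousarray(constraint_d0, dtype=float),
        tol, max_iter,
    )
    if iters < 0:
        raise ShakeError(
            f"SHAKE did not converge in {max_iter} iterations; worst "
            f"relative violation {worst:.3e}")
    return pos


# ----------------------------------------------------------------------
# the assembled system
# ----------------------------------------------------------------------

def solvent_only_regions(structure: Structure) -> RegionAssignment:
    """Region assignment for a pure water (droplet) system."""
    labels = np.where(structure.is_water, "WATER", "LIGAND").astype("U6")
    return RegionAssignment(
        atom_labels=labels,
        residue_labels={},
        cg_bead_indices=np.empty(0, dtype=int),
        interface_ca_indices=np.empty(0, dtype=int),
        interface_cb_indices=np.empty(0, dtype=int),
    )


class NeighborList:
    """Skin-buffered Verlet list over the atomistic atoms, rebuilt from a
    KD-tree every ``every`` steps or when any atom moved more than half the
    skin.  Energies computed from the list match a brute-force scan because
    pairs beyond the true cutoff are distance-masked at evaluation time."""

    def __init__(self, topology: HybridTopology, cutoff: float,
                 skin: float = 0.2, every: int = 10):
        self.topology = topology
        self.cutoff = cutoff
        self.skin = skin
        self.every = every
        self._pairs = None
        self._ref_positions = None
        self._age = 0

    def pairs(self, positions: np.ndarray) -> np.ndarray:
        rebuild = self._pairs is None or self._age >= self.every
        if not rebuild and self._ref_positions is not None:
            disp = np.max(np.linalg.norm(
                positions[self.topology.atomistic_indices]
                - self._ref_positions, axis=1)) if len(self.topology.atomistic_indices) else 0.0
            rebuild = disp > 0.5 * self.skin
        if rebuild:
            idx = self.topology.atomistic_indices
            if len(idx) < 2:
                self._pairs = np.empty((0, 2), dtype=int)
            else:
                tree = cKDTree(positions[idx])
                local = tree.query_pairs(self.cutoff + self.skin,
                                         output_type="ndarray")
                self._pairs = self.topology.filter_exclusions(idx[local])
            self._ref_positions = positions[self.topology.atomistic_indices].copy()
            self._age = 0
        self._age += 1
        return self._pairs


@dataclass
class System:
    """Structure + topology + walls, with a single force/energy entry point."""

    structure: Structure
    regions: RegionAssignment
    topology: HybridTopology
    wallset: "bnd.WallSet | None" = None
    cutoff: float = 1.6
    neighbor_skin: float = 0.2
    neighbor_every: int = 10

    def __post_init__(self):
        self._nlist = NeighborList(self.topology, self.cutoff,
                                   self.neighbor_skin, self.neighbor_every)
        # dynamical atoms: atomistic region plus the CG beads; anything else
        # (e.g. side-chain atoms of CG residues) is frozen decoration
        mask = np.zeros(self.structure.n_atoms, dtype=bool)
        mask[self.topology.atomistic_indices] = True
        mask[self.topology.cg_bead_indices] = True
        self.active_mask = mask

    @property
    def n_dof(self) -> int:
        return 3 * int(self.active_mask.sum()) - self.topology.n_constraints

    def evaluate(self, positions: np.ndarray, use_neighbor_list: bool = True):
        pairs = self._nlist.pairs(positions) if use_neighbor_list else None
        report, forces = ff.total_energy(
            positions, self.topology, wallset=self.wallset,
            cutoff=self.cutoff, pairs=pairs,
        )
        forces[~self.active_mask] = 0.0
        return report, forces

    def make_state(self, config: RunConfig,
                   positions: np.ndarray | None = None) -> SimulationState:
        pos = self.structure.coords.copy() if positions is None else positions.copy()
        rng = np.random.default_rng(config.seed)
        vel = init_velocities(self.structure.mass, config.temperature, rng=rng)
        vel[~self.active_mask] = 0.0
        report, forces = self.evaluate(pos)
        return SimulationState(
            positions=pos, velocities=vel, forces=forces,
            masses=self.structure.mass.copy(), n_dof=self.n_dof,
            rng=rng, energy=report,
        )


# ----------------------------------------------------------------------
# integration
# ----------------------------------------------------------------------

def sd_step(state: SimulationState, system: System, config: RunConfig) -> SimulationState:
    """One Langevin-leapfrog step (in place); returns the state.

    kick -> friction/noise (Ornstein-Uhlenbeck velocity update) -> drift ->
    SHAKE -> force refresh.  The noise amplitude sqrt((1-a^2) kB T / m)
    with a = exp(-gamma dt) makes the free-particle velocity variance
    converge to kB T / m exactly.
    """
    dt = config.timestep
    gamma = 1.0 / config.tau if config.tau > 0 else 0.0
    top = system.topology
    m = state.masses[:, None]
    active = system.active_mask

    if not np.all(np.isfinite(state.forces)):
        bad = int(np.flatnonzero(~np.isfinite(state.forces).all(axis=1))[0])
        raise FloatingPointError(f"non-finite force on atom {bad}")

    v = state.velocities
    v = v + (state.forces / m) * dt
    if gamma > 0.0:
        a = np.exp(-gamma * dt)
        v = a * v
        if config.temperature > 0.0:
            noise = state.rng.normal(size=v.shape)
            v = v + np.sqrt((1.0 - a * a) * KB * config.temperature / state.masses)[:, None] * noise
    v[~active] = 0.0

    new_pos = state.positions + v * dt
    new_pos[~active] = state.positions[~active]
    if top.n_constraints:
        constrained = shake(
            state.positions, new_pos, top.constraint_idx, top.constraint_d0,
            state.masses, tol=config.shake_tol,
            max_iter=config.shake_max_iter,
        )
        v = v + (constrained - new_pos) / dt
        new_pos = constrained

    if not np.all(np.isfinite(new_pos)):
        bad = int(np.flatnonzero(~np.isfinite(new_pos).all(axis=1))[0])
        raise FloatingPointError(f"non-finite position for atom {bad}")

    state.positions = new_pos
    state.velocities = v
    state.energy, state.forces = system.evaluate(new_pos)
    state.time += dt
    state.step += 1
    return state


def minimize(system: System, positions: np.ndarray, config: RunConfig) -> np.ndarray:
    """Steepest-descent relaxation with adaptive step size; constrained
    bonds are re-projected with SHAKE after every accepted move."""
    top = system.topology
    pos = positions.copy()
    report, forces = system.evaluate(pos, use_neighbor_list=False)
    energy = report.total
    step = 0.001
    for _ in range(config.minimize_steps):
        fmax = np.max(np.linalg.norm(forces, axis=1)) if len(forces) else 0.0
        if fmax < config.minimize_fmax:
            break
        trial = pos + step * forces / max(fmax, 1e-12)
        if top.n_constraints:
            trial = shake(pos, trial, top.constraint_idx, top.constraint_d0,
                          system.structure.mass, tol=config.shake_tol,
                          max_iter=config.shake_max_iter)
        trial_report, trial_forces = system.evaluate(trial, use_neighbor_list=False)
        if trial_report.total < energy:
            pos, energy, forces = trial, trial_report.total, trial_forces
            step = min(step * 1.2, 0.05)
        else:
            step *= 0.5
            if step < 1e-8:
                break
    return pos


def simulate(system: System, state: SimulationState, config: RunConfig,
             n_steps: int | None = None, collect_stride: int | None = None,
             save_velocities: bool | None = None) -> Trajectory:
    """Advance ``n_steps`` and collect a trajectory (frame 0 included)."""
    n_steps = config.n_steps if n_steps is None else n_steps
    stride = config.output_stride if collect_stride is None else collect_stride
    save_v = config.save_velocities if save_velocities is None else save_velocities

    frames = [state.positions.copy()]
    times = [state.time]
    vels = [state.velocities.copy()] if save_v else None
    energies = [_frame_energy(state)]
    for k in range(n_steps):
        sd_step(state, system, config)
        if (k + 1) % stride == 0:
            frames.append(state.positions.copy())
            times.append(state.time)
            energies.append(_frame_energy(state))
            if save_v:
                vels.append(state.velocities.copy())
        if (k + 1) % 1000 == 0:
            logger.info(
                "step %d t=%.3f ps T=%.1f K Epot=%.2f kJ/mol",
                state.step, state.time, state.temperature,
                state.energy.total if state.energy else float("nan"),
            )
    return Trajectory(
        system.structure,
        np.array(frames),
        np.array(times),
        velocities=np.array(vels) if save_v else None,
        energies=energies,
    )


def _frame_energy(state: SimulationState) -> dict:
    rec = state.energy.as_dict() if state.energy else {}
    rec["kinetic"] = state.kinetic_energy
    rec["temperature"] = state.temperature
    return rec


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------

def build_system(structure: Structure, config: RunConfig,
                 ligand_selection: np.ndarray | None = None,
                 mm_params: MMParameters | None = None,
                 with_walls: bool = True) -> System:
    """partition -> topology -> walls, per the run configuration."""
    if ligand_selection is None:
        ligand_selection = select_ligand(structure, config.ligand_resname)
    if mm_params is None and config.parameter_file:
        mm_params = MMParameters.from_file(config.parameter_file)
    if len(ligand_selection):
        regions = assign_regions(structure, ligand_selection,
                                 config.mm_cutoff, config.interface_cutoff)
    else:
        regions = solvent_only_regions(structure)
    topology = build_hybrid_topology(
        structure, regions, go_params=config.go_params(),
        native_contact_cutoff=config.native_contact_cutoff,
        mm_params=mm_params,
    )
    wallset = None
    if with_walls and structure.protein_mask.any():
        wallset = bnd.build_walls(
            structure,
            membrane_thickness=config.membrane_thickness,
            water_margin=config.water_margin,
            r_p=config.r_p,
            beta=config.wall_beta,
        )
    return System(structure, regions, topology, wallset, cutoff=config.cutoff,
                  neighbor_skin=config.neighbor_skin,
                  neighbor_every=config.neighbor_every)


def run(structure: Structure, config: RunConfig,
        ligand_selection: np.ndarray | None = None,
        mm_params: MMParameters | None = None,
        wallset: "bnd.WallSet | None" = None,
        do_minimize: bool = True):
    """Full pipeline: partition, topology, walls, minimization, velocity
    initialization and ``n_steps`` of stochastic dynamics.

    Returns ``(trajectory, state, system)``; reproducible bit-for-bit for a
    fixed config and seed.
    """
    stage = "partition/topology"
    try:
        system = build_system(structure, config, ligand_selection, mm_params,
                              with_walls=wallset is None)
        if wallset is not None:
            system.wallset = wallset
        stage = "minimize"
        pos = minimize(system, structure.coords, config) if do_minimize \
            else structure.coords.copy()
        stage = "dynamics"
        state = system.make_state(config, positions=pos)
        trajectory = simulate(system, state, config)
    except Exception as exc:
        raise RuntimeError(f"simulation failed during stage '{stage}': {exc}") from exc
    if config.trajectory_path:
        from .structure_io import write_trajectory
        write_trajectory(trajectory, config.trajectory_path)
    return trajectory, state, system


# ----------------------------------------------------------------------
# checkpoints
# ----------------------------------------------------------------------

def save_checkpoint(state: SimulationState, path: str | Path) -> None:
    np.savez(
        path,
        positions=state.positions, velocities=state.velocities,
        forces=state.forces, masses=state.masses,
        meta=np.array([state.time, float(state.step), float(state.n_dof)]),
        rng_state=np.frombuffer(
            json.dumps(state.rng.bit_generator.state).encode(), dtype=np.uint8),
    )


def load_checkpoint(path: str | Path) -> SimulationState:
    data = np.load(path)
    rng = np.random.default_rng()
    rng.bit_generator.state = json.loads(bytes(data["rng_state"]).decode())
    time_, step, n_dof = data["meta"]
    return SimulationState(
        positions=data["positions"], velocities=data["velocities"],
        forces=data["forces"], masses=data["masses"], n_dof=int(n_dof),
        time=float(time_), step=int(step), rng=rng,
    )
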