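import numpy as np
import pytest

import mmcg
from mmcg import dynamics as dyn
from mmcg import forcefield as ff
from mmcg.units import KB
from mmcg.partitioning import HybridTopology
from conftest import all_cg_regions, make_structure


def harmonic_dimer_system(k=1000.0, b0=0.4, start=0.45):
    s = make_structure([[0.0, 0, 0], [start, 0, 0]], ["CA", "CA"],
                       ["C", "C"], [1, 2])
    top = HybridTopology(
        n_atoms=2, region_labels=np.array(["CG", "CG"]),
        cg_bead_indices=np.arange(2),
        atomistic_indices=np.empty(0, dtype=int))
    top.go_bond_idx = np.array([[0, 1]])
    top.go_bond_k = np.array([k])
    top.go_bond_b0 = np.array([b0])
    top.lj_sigma = np.zeros(2)
    top.lj_epsilon = np.zeros(2)
    top.charge = np.zeros(2)
    return dyn.System(s, all_cg_regions(s), top, wallset=None)


def free_system(n_atoms=500, mass=18.0):
    coords = np.arange(n_atoms * 3, dtype=float).reshape(n_atoms, 3) * 2.0
    s = make_structure(coords, ["CA"] * n_atoms, ["C"] * n_atoms,
                       np.arange(1, n_atoms + 1))
    s.mass[:] = mass
    top = HybridTopology(
        n_atoms=n_atoms, region_labels=np.full(n_atoms, "CG"),
        cg_bead_indices=np.arange(n_atoms),
        atomistic_indices=np.empty(0, dtype=int))
    top.lj_sigma = np.zeros(n_atoms)
    top.lj_epsilon = np.zeros(n_atoms)
    top.charge = np.zeros(n_atoms)
    return dyn.System(s, all_cg_regions(s), top, wallset=None)


class TestInitVelocities:
    def test_equipartition_at_large_n(self):
        masses = np.full(1000, 18.0)
        v = dyn.init_velocities(masses, 300.0, seed=1)
        ke = 0.5 * np.sum(masses[:, None] * v ** 2)
        t_kin = 2 * ke / (3 * 1000 * KB)
        assert abs(t_kin - 300.0) / 300.0 < 0.05

    def test_zero_temperature_gives_zero(self):
        assert not dyn.init_velocities(np.ones(5), 0.0, seed=1).any()

    def test_deterministic_per_seed(self):
        a = dyn.init_velocities(np.ones(10), 300.0, seed=7)
        b = dyn.init_velocities(np.ones(10), 300.0, seed=7)
        assert np.array_equal(a, b)

    def test_com_momentum_removed(self):
        masses = np.linspace(1, 20, 50)
        v = dyn.init_velocities(masses, 300.0, seed=2)
        np.testing.assert_allclose((masses[:, None] * v).sum(axis=0), 0.0,
                                   atol=1e-12)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            dyn.init_velocities(np.array([1.0, 0.0]), 300.0, seed=1)


class TestShake:
    def test_stretched_water_corrected(self, droplet_system):
        top = droplet_system.topology
        water = droplet_system.structure
        old = water.coords.copy()
        new = old.copy()
        # stretch every O-H by 1% radially from the oxygen
        for o in range(0, water.n_atoms, 3):
            for h in (o + 1, o + 2):
                new[h] = old[o] + 1.01 * (old[h] - old[o])
        corrected = dyn.shake(old, new, top.constraint_idx, top.constraint_d0,
                              water.mass, tol=1e-8)
        r = np.linalg.norm(corrected[top.constraint_idx[:, 1]]
                           - corrected[top.constraint_idx[:, 0]], axis=1)
        np.testing.assert_allclose(r, top.constraint_d0, rtol=1e-6)

    def test_satisfied_constraints_untouched(self, droplet_system):
        top = droplet_system.topology
        coords = droplet_system.structure.coords
        out = dyn.shake(coords, coords.copy(), top.constraint_idx,
                        top.constraint_d0, droplet_system.structure.mass)
        np.testing.assert_allclose(out, coords, atol=1e-12)

    def test_mass_weighting_moves_hydrogen_more(self):
        old = np.array([[0.0, 0, 0], [0.1, 0, 0]])
        new = np.array([[0.0, 0, 0], [0.12, 0, 0]])
        masses = np.array([15.9994, 1.008])
        out = dyn.shake(old, new, np.array([[0, 1]]), np.array([0.1]), masses)
        assert abs(out[1, 0] - new[1, 0]) > abs(out[0, 0] - new[0, 0])

    def test_nonconvergence_reports_violation(self):
        old = np.array([[0.0, 0, 0], [0.1, 0, 0]])
        new = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(dyn.ShakeError, match="violation"):
            dyn.shake(old, new, np.array([[0, 1]]), np.array([0.1]),
                      np.ones(2), max_iter=1)


class TestSDStep:
    def test_nve_energy_conservation_harmonic(self):
        system = harmonic_dimer_system()
        cfg = dyn.RunConfig(timestep=0.001, temperature=0.0,
                            tau=float("inf"), seed=1)
        state = system.make_state(cfg)
        pes, kes = [state.energy.total], [state.kinetic_energy]
        for _ in range(10000):
            dyn.sd_step(state, system, cfg)
            pes.append(state.energy.total)
            kes.append(state.kinetic_energy)
        pes, kes = np.array(pes), np.array(kes)
        # time-centered leapfrog energy: PE(x_n) + (KE_{n-1/2}+KE_{n+1/2})/2
        e = pes[1:-1] + 0.5 * (kes[1:-1] + kes[2:])
        drift = abs(e[-200:].mean() - e[:200].mean()) / abs(e.mean())
        assert drift < 1e-5

    def test_reduces_to_velocity_verlet_when_gamma_zero(self):
        system = harmonic_dimer_system()
        cfg = dyn.RunConfig(timestep=0.001, temperature=0.0,
                            tau=float("inf"), seed=1)
        state = system.make_state(cfg)
        # independent velocity-Verlet (leapfrog-equivalent trajectory)
        pos = system.structure.coords.copy()
        vel = np.zeros_like(pos)
        m = system.structure.mass[:, None]
        _, f = system.evaluate(pos)
        for _ in range(500):
            dyn.sd_step(state, system, cfg)
            # leapfrog reference
            vel = vel + f / m * cfg.timestep
            pos = pos + vel * cfg.timestep
            _, f = system.evaluate(pos)
        np.testing.assert_allclose(state.positions, pos, atol=1e-12)

    def test_free_particle_velocity_variance(self):
        system = free_system(n_atoms=500)
        cfg = dyn.RunConfig(timestep=0.002, temperature=300.0, tau=0.4, seed=3)
        state = system.make_state(cfg)
        samples = []
        for k in range(3000):
            dyn.sd_step(state, system, cfg)
            if k > 500:
                samples.append(np.mean(state.velocities ** 2))
        var = np.mean(samples)
        expected = KB * 300.0 / 18.0
        assert abs(var - expected) / expected < 0.05

    def test_velocity_decay_at_zero_temperature(self):
        system = free_system(n_atoms=10)
        cfg = dyn.RunConfig(timestep=0.002, temperature=0.0, tau=0.4, seed=1)
        state = system.make_state(cfg)
        state.velocities[:] = 1.0
        n = int(5 * 0.4 / cfg.timestep)           # integrate over 5 tau
        for _ in range(n):
            dyn.sd_step(state, system, cfg)
        expected = np.exp(-n * cfg.timestep / 0.4)
        assert np.allclose(state.velocities, expected, rtol=1e-10)

    def test_nonfinite_force_names_atom(self):
        system = harmonic_dimer_system()
        cfg = dyn.RunConfig(timestep=0.001, seed=1)
        state = system.make_state(cfg)
        state.forces[1, 0] = np.nan
        with pytest.raises(FloatingPointError, match="atom 1"):
            dyn.sd_step(state, system, cfg)


class TestThermostatAndStability:
    def test_long_run_temperature_within_3_percent(self, bundle,
                                                   bundle_regions,
                                                   bundle_topology):
        system = dyn.System(bundle, bundle_regions, bundle_topology,
                            wallset=None)
        cfg = dyn.RunConfig(timestep=0.002, temperature=300.0, tau=0.4,
                            seed=5)
        pos = dyn.minimize(system, bundle.coords, cfg)
        state = system.make_state(cfg, positions=pos)
        temps = []
        for k in range(15000):                   # 30 ps
            dyn.sd_step(state, system, cfg)
            if k > 2500:
                temps.append(state.temperature)
        assert abs(np.mean(temps) - 300.0) / 300.0 < 0.03

    def test_constraint_drift_over_run(self, droplet_system):
        system = droplet_system
        top = system.topology
        cfg = dyn.RunConfig(timestep=0.002, temperature=300.0, seed=2)
        pos = dyn.minimize(system, system.structure.coords, cfg)
        state = system.make_state(cfg, positions=pos)
        for _ in range(1000):
            dyn.sd_step(state, system, cfg)
            r = np.linalg.norm(state.positions[top.constraint_idx[:, 1]]
                               - state.positions[top.constraint_idx[:, 0]],
                               axis=1)
            assert np.max(np.abs(r - top.constraint_d0) / top.constraint_d0) \
                < 1e-5


class TestRunPipeline:
    def test_zero_steps_yields_single_frame(self, bundle):
        cfg = dyn.RunConfig(n_steps=0, seed=1, membrane_thickness=1.2,
                            minimize_steps=5)
        traj, state, system = dyn.run(bundle, cfg)
        assert traj.n_frames == 1
        assert state.step == 0

    def test_same_seed_bitwise_reproducible(self, bundle):
        cfg = dyn.RunConfig(n_steps=200, seed=9, output_stride=50,
                            membrane_thickness=1.2, minimize_steps=10)
        t1, s1, _ = dyn.run(bundle, cfg)
        t2, s2, _ = dyn.run(bundle, cfg)
        assert np.array_equal(s1.positions, s2.positions)
        assert [e["total"] for e in t1.energies] \
            == [e["total"] for e in t2.energies]

    def test_neighbor_list_matches_brute_force(self, droplet_system):
        system = droplet_system
        cfg = dyn.RunConfig(timestep=0.002, temperature=300.0, seed=6)
        state = system.make_state(cfg)
        for k in range(40):
            dyn.sd_step(state, system, cfg)
            r_list, _ = system.evaluate(state.positions,
                                        use_neighbor_list=True)
            r_brute, _ = system.evaluate(state.positions,
                                         use_neighbor_list=False)
            assert r_list.total == pytest.approx(r_brute.total, rel=1e-9)

    def test_checkpoint_round_trip_continues_identically(self, tmp_path,
                                                         bundle):
        cfg = dyn.RunConfig(n_steps=100, seed=3, output_stride=100,
                            membrane_thickness=1.2, minimize_steps=10)
        _, state_a, system = dyn.run(bundle, cfg)
        dyn.save_checkpoint(state_a, tmp_path / "chk.npz")
        restored = dyn.load_checkpoint(tmp_path / "chk.npz")
        np.testing.assert_array_equal(restored.positions, state_a.positions)
        # continuing with an independently rebuilt system stays identical
        # (each state needs its own neighbor-list cache)
        system_b = dyn.build_system(bundle, cfg)
        for _ in range(50):
            dyn.sd_step(state_a, system, cfg)
            dyn.sd_step(restored, system_b, cfg)
        np.testing.assert_array_equal(restored.positions, state_a.positions)

    def test_hybrid_stability_short_run(self):
        """Calpha RMSD of a receptor-sized bundle stays small over a 10 ps
        hybrid run at 300 K (the Go model holds the fold)."""
        from mmcg import analysis as ana
        big = mmcg.generate_toy_bundle(7, 30, seed=1, with_ligand=True)
        cfg = dyn.RunConfig(n_steps=5000, seed=11, output_stride=250)
        traj, _, _ = dyn.run(big, cfg)
        series = ana.rmsd(traj, big.coords, selection=["CA"])
        assert series.values.max() < 0.3

    def test_stage_error_is_labeled(self, bundle):
        cfg = dyn.RunConfig(n_steps=0, seed=1, membrane_thickness=1.2,
                            parameter_file="/nonexistent/table.par")
        with pytest.raises(RuntimeError, match="partition/topology"):
            dyn.run(bundle, cfg)
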