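import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mmcg
from mmcg import forcefield as ff
from mmcg.units import COULOMB
from mmcg.partitioning import HybridTopology, build_hybrid_topology
from mmcg.dynamics import solvent_only_regions
from conftest import all_cg_regions, make_structure


def numerical_forces(energy_fn, positions, atoms=None, h=1e-6):
    """Central finite differences of a scalar energy function."""
    atoms = range(len(positions)) if atoms is None else atoms
    out = np.zeros_like(positions)
    for a in atoms:
        for d in range(3):
            plus = positions.copy()
            minus = positions.copy()
            plus[a, d] += h
            minus[a, d] -= h
            out[a, d] = -(energy_fn(plus) - energy_fn(minus)) / (2 * h)
    return out


def assert_forces_match(energy_fn, analytic, positions, atoms=None,
                        rtol=1e-5):
    num = numerical_forces(energy_fn, positions, atoms)
    sel = list(range(len(positions))) if atoms is None else list(atoms)
    scale = max(np.max(np.abs(num[sel])), 1.0)
    np.testing.assert_allclose(analytic[sel], num[sel], atol=rtol * scale)


class TestGoBonded:
    def test_zero_at_native(self):
        pos = np.array([[0.0, 0, 0], [0.4, 0, 0]])
        e, f = ff.go_bonded_energy(pos, np.array([[0, 1]]),
                                   np.array([1000.0]), np.array([0.4]))
        assert e == 0.0
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_stretched_pair_energy(self):
        # (K_b/2) * delta^2 = 500 * 1e-4 = 0.05 kJ/mol
        pos = np.array([[0.0, 0, 0], [0.41, 0, 0]])
        e, _ = ff.go_bonded_energy(pos, np.array([[0, 1]]),
                                   np.array([1000.0]), np.array([0.4]))
        assert e == pytest.approx(0.05)

    def test_forces_match_finite_differences_on_chain(self):
        rng = np.random.default_rng(4)
        pos = np.cumsum(0.38 * rng.normal(size=(10, 3)), axis=0)
        pairs = np.column_stack([np.arange(9), np.arange(1, 10)])
        k = np.full(9, 1000.0)
        b0 = np.full(9, 0.38)
        _, analytic = ff.go_bonded_energy(pos, pairs, k, b0)
        assert_forces_match(
            lambda p: ff.go_bonded_energy(p, pairs, k, b0)[0], analytic, pos,
            rtol=1e-6)

    def test_coincident_beads_rejected(self):
        pos = np.zeros((2, 3))
        with pytest.raises(ff.OverlapError):
            ff.go_bonded_energy(pos, np.array([[0, 1]]),
                                np.array([1.0]), np.array([0.4]))


class TestGoMorse:
    def test_well_depth_at_native(self):
        pos = np.array([[0.0, 0, 0], [0.5, 0, 0]])
        e, f = ff.go_morse_energy(pos, np.array([[0, 1]]), np.array([0.5]),
                                  np.array([17.0]), np.array([5.3]))
        assert e == pytest.approx(-5.3)
        np.testing.assert_allclose(f, 0.0, atol=1e-9)

    def test_dissociation_limit(self):
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        e, _ = ff.go_morse_energy(pos, np.array([[0, 1]]), np.array([0.5]),
                                  np.array([10.0]), np.array([5.3]))
        assert abs(e) < 1e-6

    @settings(max_examples=25, deadline=None)
    @given(b0=st.floats(0.3, 1.2), big_b=st.floats(5.0, 20.0))
    def test_grid_scan_depth_equals_v0(self, b0, big_b):
        r = np.arange(0.05, 6.0, 1e-3)
        v = 5.3 * ((1 - np.exp(-big_b * (r - b0))) ** 2 - 1)
        # package evaluation at the analytic minimum and at dissociation
        for rr, expect in ((b0, -5.3), (6.0, 0.0)):
            pos = np.array([[0.0, 0, 0], [rr, 0, 0]])
            e, _ = ff.go_morse_energy(pos, np.array([[0, 1]]),
                                      np.array([b0]), np.array([big_b]),
                                      np.array([5.3]))
            assert e == pytest.approx(expect, abs=1e-3)
        # well depth = dissociated limit minus minimum
        assert v[-1] - v.min() == pytest.approx(5.3, rel=1e-3)

    def test_forces_match_finite_differences(self):
        rng = np.random.default_rng(9)
        pos = rng.uniform(-0.5, 0.5, size=(6, 3)) * 2
        pairs = np.array([[0, 3], [1, 4], [2, 5], [0, 5]])
        b0 = np.array([0.5, 0.7, 0.6, 0.8])
        bb = 5 + 6 / b0
        v0 = np.full(4, 5.3)
        _, analytic = ff.go_morse_energy(pos, pairs, b0, bb, v0)
        assert_forces_match(
            lambda p: ff.go_morse_energy(p, pairs, b0, bb, v0)[0],
            analytic, pos)


def _two_atom_topology(sigma, eps, charge):
    top = HybridTopology(
        n_atoms=2, region_labels=np.array(["MM", "MM"]),
        cg_bead_indices=np.empty(0, dtype=int),
        atomistic_indices=np.arange(2))
    top.lj_sigma = np.full(2, sigma)
    top.lj_epsilon = np.full(2, eps)
    top.charge = np.array(charge, dtype=float)
    return top


class TestMMEnergy:
    def test_lj_minimum_energy_and_force(self):
        sigma, eps, cutoff = 0.33, 0.5, 1.6
        top = _two_atom_topology(sigma, eps, [0.0, 0.0])
        r_min = sigma * 2 ** (1 / 6)
        pos = np.array([[0.0, 0, 0], [r_min, 0, 0]])
        e_cls, forces = ff.mm_energy(pos, top, cutoff=cutoff)
        # shifted-force constants evaluated independently
        x6c = (sigma / cutoff) ** 6
        dljc = 4 * eps * (-12 * x6c ** 2 + 6 * x6c) / cutoff
        expected = -eps - 4 * eps * (x6c ** 2 - x6c) - dljc * (r_min - cutoff)
        assert e_cls.sum() == pytest.approx(expected, rel=1e-9)
        # at the LJ minimum only the small truncation shift-force remains
        assert abs(forces[0, 0] + dljc) < 1e-9
        assert abs(forces[1, 0] - dljc) < 1e-9

    def test_coulomb_hand_value(self):
        top = _two_atom_topology(0.3, 0.0, [1.0, -1.0])
        r, rc = 0.5, 1.6
        pos = np.array([[0.0, 0, 0], [r, 0, 0]])
        e_cls, _ = ff.mm_energy(pos, top, cutoff=rc)
        expected = -COULOMB * (1 / r - 1 / rc + (r - rc) / rc ** 2)
        assert e_cls.sum() == pytest.approx(expected, rel=1e-12)

    def test_pair_terms_vanish_beyond_cutoff(self):
        top = _two_atom_topology(0.33, 0.5, [0.5, -0.5])
        pos = np.array([[0.0, 0, 0], [1.7, 0, 0]])
        e_cls, forces = ff.mm_energy(pos, top, cutoff=1.6)
        assert e_cls.sum() == 0.0
        np.testing.assert_array_equal(forces, 0.0)

    def test_overlap_detected(self):
        top = _two_atom_topology(0.33, 0.5, [0.0, 0.0])
        pos = np.array([[0.0, 0, 0], [5e-5, 0, 0]])
        with pytest.raises(ff.OverlapError):
            ff.mm_energy(pos, top, cutoff=1.6)

    def test_forces_match_finite_differences_water_cluster(self, droplet):
        water, _ = droplet
        regions = solvent_only_regions(water)
        top = build_hybrid_topology(water, regions)
        sub = water.coords[:30]  # 10 waters
        top30 = build_hybrid_topology(
            make_small := _first_waters(water, 10), solvent_only_regions(make_small))
        _, analytic = ff.mm_energy(sub, top30, cutoff=1.6)
        assert_forces_match(
            lambda p: ff.mm_energy(p, top30, cutoff=1.6)[0].sum(),
            analytic, sub, atoms=range(0, 30, 3))

    def test_dihedral_forces_match_finite_differences(self, tmp_path):
        from mmcg.partitioning import MMParameters
        table = tmp_path / "dih.par"
        table.write_text(
            "ATOM X 12.0 0.3 0.0 0.0\n"
            "BOND X X 1000.0 native\n"
            "ANGLE X X X 10.0 native\n"
            "DIHEDRAL X X X X 4.0 3 30.0\n")
        params = MMParameters.from_file(table)
        rng = np.random.default_rng(2)
        pos = np.array([[0.0, 0, 0], [0.15, 0, 0], [0.25, 0.12, 0],
                        [0.3, 0.2, 0.12]])
        s = make_structure(pos, ["X1", "X2", "X3", "X4"], ["C"] * 4,
                           [1, 1, 1, 1], res_names=["LIG"] * 4,
                           is_ligand=[True] * 4)
        regions = solvent_only_regions(s)
        top = build_hybrid_topology(s, regions, mm_params=params,
                                    ligand_bond_cutoff=0.2)
        assert len(top.mm_dihedral_idx) == 1
        jitter = pos + 0.01 * rng.normal(size=pos.shape)
        _, analytic = ff.mm_energy(jitter, top, cutoff=1.6)
        assert_forces_match(
            lambda p: ff.mm_energy(p, top, cutoff=1.6)[0].sum(),
            analytic, jitter)


def _first_waters(water, n):
    import copy
    s = water.copy()
    keep = slice(0, 3 * n)
    for name in s.__dataclass_fields__:
        setattr(s, name, getattr(s, name)[keep])
    return s


class TestCouplingAndTotal:
    def test_native_configuration_is_go_minimum(self, bundle,
                                                bundle_topology):
        e_b, f_b = ff.go_bonded_energy(
            bundle.coords, bundle_topology.go_bond_idx,
            bundle_topology.go_bond_k, bundle_topology.go_bond_b0)
        e_c, f_c = ff.cg_energy(bundle.coords, bundle_topology)
        e_cpl, f_cpl = ff.coupling_energy(bundle.coords, bundle_topology)
        assert abs(e_b) < 1e-20
        n_contacts = len(bundle_topology.go_contact_idx)
        n_cpl = len(bundle_topology.coupling_contact_idx)
        assert e_c == pytest.approx(-5.3 * n_contacts)
        assert e_cpl == pytest.approx(-5.3 * n_cpl)
        assert np.max(np.abs(f_c + f_cpl)) < 1e-6

    def test_coupling_matches_naive_resummation(self, bundle,
                                                bundle_topology):
        rng = np.random.default_rng(1)
        pos = bundle.coords + 0.02 * rng.normal(size=bundle.coords.shape)
        e, _ = ff.coupling_energy(pos, bundle_topology)
        top = bundle_topology
        expected = 0.0
        for (i, j), k, b in zip(top.coupling_bond_idx, top.coupling_bond_k,
                                top.coupling_bond_b0):
            expected += 0.5 * k * (np.linalg.norm(pos[j] - pos[i]) - b) ** 2
        for (i, j), b, bb, v0 in zip(top.coupling_contact_idx,
                                     top.coupling_contact_b0,
                                     top.coupling_contact_B,
                                     top.coupling_contact_v0):
            r = np.linalg.norm(pos[j] - pos[i])
            expected += v0 * ((1 - np.exp(-bb * (r - b))) ** 2 - 1)
        assert e == pytest.approx(expected, rel=1e-12)

    def test_removing_coupling_decouples_cg_from_interface(
            self, bundle, bundle_regions, bundle_topology):
        import dataclasses
        bare = dataclasses.replace(
            bundle_topology,
            coupling_bond_idx=np.empty((0, 2), dtype=int),
            coupling_bond_k=np.empty(0), coupling_bond_b0=np.empty(0),
            coupling_contact_idx=np.empty((0, 2), dtype=int),
            coupling_contact_b0=np.empty(0), coupling_contact_B=np.empty(0),
            coupling_contact_v0=np.empty(0))
        pos = bundle.coords.copy()
        beads = bundle_topology.cg_bead_indices
        _, f0 = ff.total_energy(pos, bare)
        moved = pos.copy()
        moved[bundle_regions.interface_ca_indices] += 0.05
        _, f1 = ff.total_energy(moved, bare)
        np.testing.assert_allclose(f0[beads], f1[beads], atol=1e-10)

    def test_report_total_is_sum_of_terms(self, bundle, bundle_topology):
        report, _ = ff.total_energy(bundle.coords, bundle_topology)
        parts = (report.e_mm + report.e_i + report.e_mm_i + report.e_cg
                 + report.e_cg_i + report.e_wall)
        assert report.total == pytest.approx(parts, rel=1e-12)

    def test_translation_invariance_of_internal_terms(self, bundle,
                                                      bundle_topology):
        r0, _ = ff.total_energy(bundle.coords, bundle_topology)
        r1, _ = ff.total_energy(bundle.coords + np.array([1.0, -2.0, 0.5]),
                                bundle_topology)
        assert r1.total == pytest.approx(r0.total, abs=1e-8)

    def test_internal_forces_sum_to_zero(self, bundle, bundle_topology):
        rng = np.random.default_rng(8)
        pos = bundle.coords + 0.02 * rng.normal(size=bundle.coords.shape)
        _, forces = ff.total_energy(pos, bundle_topology)
        net = forces.sum(axis=0)
        assert np.all(np.abs(net) < 1e-8 * len(pos))

    def test_total_forces_match_finite_differences(self, bundle,
                                                   bundle_topology):
        rng = np.random.default_rng(3)
        pos = bundle.coords + 0.01 * rng.normal(size=bundle.coords.shape)
        _, analytic = ff.total_energy(pos, bundle_topology)
        atoms = rng.choice(len(pos), 10, replace=False)
        assert_forces_match(
            lambda p: ff.total_energy(p, bundle_topology)[0].total,
            analytic, pos, atoms=atoms)
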