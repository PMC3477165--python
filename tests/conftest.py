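import numpy as np
import pytest

import mmcg
from mmcg import boundaries as bnd
from mmcg import dynamics as dyn
from mmcg.structure_io import Structure
from mmcg.units import mass_of


def make_structure(coords, names, elements, res_ids, chain_ids=None,
                   res_names=None, is_water=None, is_ligand=None):
    """Hand-rolled Structure for small fixtures."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    chain_ids = chain_ids if chain_ids is not None else ["A"] * n
    res_names = res_names if res_names is not None else ["ALA"] * n
    return Structure(
        serial=np.arange(1, n + 1),
        name=np.asarray(names, dtype="U5"),
        element=np.asarray(elements, dtype="U3"),
        res_name=np.asarray(res_names, dtype="U5"),
        res_id=np.asarray(res_ids, dtype=int),
        chain_id=np.asarray(chain_ids, dtype="U2"),
        coords=coords,
        mass=np.array([mass_of(e) for e in elements]),
        charge=np.zeros(n),
        is_water=(np.asarray(is_water, dtype=bool) if is_water is not None
                  else np.zeros(n, dtype=bool)),
        is_ligand=(np.asarray(is_ligand, dtype=bool) if is_ligand is not None
                   else np.zeros(n, dtype=bool)),
    )


def all_cg_regions(structure):
    """RegionAssignment treating every protein residue as CG."""
    from mmcg.partitioning import RegionAssignment
    ca = np.array(sorted(structure.ca_indices().values()), dtype=int)
    labels = np.full(structure.n_atoms, "CG", dtype="U6")
    return RegionAssignment(
        atom_labels=labels,
        residue_labels={k: "CG" for k in structure.residue_keys()},
        cg_bead_indices=ca,
        interface_ca_indices=np.empty(0, dtype=int),
        interface_cb_indices=np.empty(0, dtype=int),
    )


@pytest.fixture(scope="session")
def bundle():
    """Small hybrid fixture: 3 helices x 12 residues + central ligand."""
    return mmcg.generate_toy_bundle(3, 12, seed=1, with_ligand=True)


@pytest.fixture(scope="session")
def bundle_regions(bundle):
    return mmcg.assign_regions(bundle, mmcg.select_ligand(bundle))


@pytest.fixture(scope="session")
def bundle_topology(bundle, bundle_regions):
    return mmcg.build_hybrid_topology(bundle, bundle_regions)


@pytest.fixture(scope="session")
def droplet():
    """Small water droplet (40 waters) with its hemisphere wall set."""
    ws = bnd.hemisphere_wallset(1.2)
    water = mmcg.generate_water_droplet(40, ws, seed=7, wall_margin=0.2)
    ws.wall_atom_indices = np.arange(water.n_atoms)
    return water, ws


@pytest.fixture(scope="session")
def droplet_system(droplet):
    water, ws = droplet
    regions = dyn.solvent_only_regions(water)
    topology = mmcg.build_hybrid_topology(water, regions)
    return dyn.System(water, regions, topology, wallset=ws)
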