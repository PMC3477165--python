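# mmcg — hybrid molecular-mechanics / coarse-grained simulation

`mmcg` simulates membrane receptor–ligand complexes with a hybrid
resolution scheme: the ligand, the binding-site residues (**MM** region),
an interface shell (**I** region) and the hydration waters are treated
atomistically, while the rest of the protein is reduced to one bead per
residue at the Cα position, governed by a structure-based (Gō) model.
Instead of an explicit lipid bilayer, five level-set "walls" confine the
system: two planes at the lipid-head heights, two hemispherical outer
walls that cap a droplet of water around the binding site, and a membrane
wall that hugs the transmembrane Cα trace.  This makes desk-scale
dynamics of a receptor–ligand complex cheap while keeping atomistic
detail exactly where ligand binding happens.

It is aimed at people who want to prototype or study this class of
multiscale model — the partitioning rules, the boundary potentials, the
CG/atomistic coupling — on reproducible synthetic systems, not at
production simulation of real force fields.

## The model

The potential energy splits by region:

```
E = E_MM + E_I + E_MM/I + E_CG + E_CG/I + E_wall   (+ stochastic-dynamics term)
```

* `E_MM`, `E_I`, `E_MM/I` — classical MM terms (harmonic bonds/angles,
  periodic dihedrals, Lennard-Jones + Coulomb with a 1.6 nm shifted-force
  cutoff) over the atomistic atoms, read from a flat parameter table.
* `E_CG` — Gō model on the Cα beads: harmonic bonds between consecutive
  beads, `V = (K_b/2)(r − b_ij)²`, and Morse-type native contacts

  `V(r) = V₀[(1 − e^(−B_ij (r − b_ij)))² − 1]`,

  with well depth `V₀ = 5.3 kJ/mol`, native distance `b_ij`, and range
  coefficient `B_ij = 5 + 6/b_ij (nm⁻¹)` (the membrane rule; `B_ij =
  6/b_ij` recovers the soluble-protein variant).
* `E_CG/I` — the same functional forms coupling CG beads to interface
  Cα/Cβ atoms.
* `E_wall` — boundary potentials `V_i(d)` of the distance `d = min φ_i`
  to the nearest wall: purely repulsive for the planar walls (cutoff
  0.7 nm), softened Lennard-Jones with its minimum at `r_p = 0.2 nm` for
  the hemispheres and the membrane wall (cutoff `1.5 r_p`); forces are
  shifted to vanish continuously at the cutoffs and capped at
  1000 kJ mol⁻¹ nm⁻¹.
* The solvent/thermal term is realized as Langevin (stochastic) dynamics:
  leapfrog with friction `γ = 1/τ` (`τ = 0.4 ps`) and matching noise at
  300 K, 2 fs steps, SHAKE on all hydrogen-containing bonds (waters are
  rigid three-site molecules).

A residue is MM if any of its atoms is within 0.5 nm of the ligand, I if
within 0.6 nm of an MM residue, and CG otherwise.

Everything needed for experimentation ships with the package: generators
for ideal-geometry helix bundles (with a rigid pocket ligand) and for
wall-confined water droplets, plus analysis tools (RMSD, per-residue
RMSF, velocity autocorrelation, O–O radial distribution, pair-distance
series).

## Worked example

```python
import mmcg
from mmcg import dynamics as dyn, analysis as ana

# a 7-helix bundle standing in for a receptor, ligand in the pore
receptor = mmcg.generate_toy_bundle(7, 30, seed=1, with_ligand=True)
regions = mmcg.assign_regions(receptor, mmcg.select_ligand(receptor))
print({label: sum(v == label for v in regions.residue_labels.values())
       for label in ("MM", "I", "CG")})

# 5 ps of stochastic dynamics at 300 K (partition -> topology -> walls
# -> minimize -> dynamics)
cfg = dyn.RunConfig(n_steps=2500, seed=1, output_stride=125)
traj, state, system = dyn.run(receptor, cfg)
print({k: round(v, 1) for k, v in state.energy.as_dict().items()})
print(round(ana.rmsd(traj, receptor.coords, selection=["CA"]).values[-1], 3))
```

prints

```
{'MM': 7, 'I': 31, 'CG': 172}
{'E_MM': 12.2, 'E_I': 36.6, 'E_MM/I': 17.6, 'E_CG': -5610.5,
 'E_CG/I': -3836.1, 'E_wall': 767.9, 'total': -8612.3}
0.085
```

Seven residues line the pocket atomistically (MM), 31 bridge to the Gō
frame (I), and 172 are CG beads.  The large negative `E_CG`/`E_CG/I`
terms are the native-contact wells holding the fold; the Cα RMSD after
5 ps is 0.085 nm — the hybrid model keeps the structure near its native
geometry while the binding site moves atomistically.

The same pipeline is available from a shell:

```bash
mmcg partition --pdb receptor.pdb --ligand LIG
mmcg run --config run.yaml --seed 1
mmcg analyze rmsd --traj traj.pdb --ref receptor.pdb --sel CA
```

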