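# Methods

This note documents the model implemented by `mmcg`, the choices made
where the published description leaves freedom, what the synthetic test
systems do and do not emulate, and the numerical conventions the tests
rely on.

## Regions and topology

Partitioning is residue-granular: a protein residue is **MM** when the
minimum atom–atom distance between any of its atoms and any ligand atom
is below `mm_cutoff` (0.5 nm), **I** when it is not MM but within
`interface_cutoff` (0.6 nm, atom-to-atom) of an MM residue, and **CG**
otherwise.  Waters and the ligand are labeled separately and treated
atomistically together with the MM region.  Because only interatomic
distances enter, the assignment is invariant under rigid motion, and
enlarging `mm_cutoff` can only grow the MM set.

The CG region is represented by one bead per residue at the Cα position.
Topology construction instantiates:

* harmonic bonds between sequence-consecutive CG beads with the native
  distance as equilibrium value and force constant `K_b`
  (default 1000 kJ mol⁻¹ nm⁻²; the published scheme does not print this
  constant, so it is explicit configuration);
* Morse-type contacts between all other CG bead pairs whose native
  distance is below `native_contact_cutoff` (default 1.2 nm, again a
  configuration value — consistent with common structure-based-model
  practice and below the 1.6 nm interaction cutoff), with
  `B = B_const + 6/b` and `B_const = 5` nm⁻¹ for the membrane variant;
* coupling terms of the same two forms between CG beads and the
  interface: bonds to sequence-adjacent I-region Cα atoms, contacts to
  I-region Cα and Cβ atoms within the contact cutoff.  Glycine has no
  Cβ and contributes its Cα only.
* atomistic terms for MM + I + waters + ligand from a flat text table
  (`ATOM`/`BOND`/`ANGLE`/`DIHEDRAL` records keyed by atom name with
  trailing digits stripped).  Bonds are detected from the input
  geometry (intra-residue pairs below 0.2 nm, never H–H; a wider 0.7 nm
  rule for the synthetic ligand; consecutive Cα–Cα links between
  atomistic protein residues).  Angles and dihedrals are instantiated
  wherever a matching record exists.  Equilibrium values may be declared
  `native`, meaning the input-structure geometry of each instance —
  used for generated rigid bodies that have no tabulated geometry.
* SHAKE constraints for every bond containing hydrogen; for three-site
  waters the H–O–H angle is replaced by the equivalent H–H distance
  constraint, so waters are rigid.

Exclusions cover 1–2 (bonded or constrained) and 1–3 pairs; 1–4 pairs
interact at full strength.  Lennard-Jones combination is
Lorentz–Berthelot.  Side-chain pseudo-atoms of CG residues are frozen
decoration: the CG model is the Cα bead alone.

## Nonbonded truncation

All LJ and Coulomb pair terms use a 1.6 nm cutoff with *shifted-force*
truncation: both the energy and its derivative go continuously to zero
at the cutoff.  A plain energy shift leaves a Coulomb force
discontinuity of order 10 kJ mol⁻¹ nm⁻¹ per crossing pair, which
measurably heats a droplet under 2 fs Langevin dynamics; the
shifted-force form removes that heat source at the price of slightly
distorting pair interactions near the cutoff.  No reaction field, Ewald
summation or periodic images are used — the droplet geometry is finite
by construction.

## Boundary walls

Five level-set fields define the confining geometry.  The membrane slab
(thickness 3.1 nm by default) is centered on the protein center of
mass.  Each wall is defined in its own z-zone: above the slab, wall 1
(plane, `φ₁ = z − z_hi`) and wall 3 (hemisphere of radius `r₃`); below,
walls 2 and 4; inside, wall 5 (`φ₅ = r_p − softmin_j |r − c_j|` over the
initial transmembrane Cα positions, `r_p = 0.2 nm`).  The hemisphere
radii are chosen so the smallest distance from any protein atom outside
the slab to the wall surface equals the water margin (2.0 nm) — this
carves out the hydration droplet.  The region above/below each plane is
treated as the *union* of the half-space and the membrane-wall tube
(pointwise maximum of the two level sets), i.e. the planes have a hole
where the protein passes through; without it the composite field would
jump at the slab boundary next to the protein.

The soft minimum is an overflow-safe log-sum-exp,
`softmin(d) = −(1/β) log Σ e^(−β d_j)` with `β = 50 nm⁻¹`, which is
infinitely differentiable and converges to the hard minimum as β grows.
This replaces the (unpublished) smoothing of the original scheme and
serves the same purpose: no discontinuities in the membrane wall.

Potentials: walls 1–2 carry `V = ε(σ/d)⁶` (purely repulsive,
`σ = 0.25 nm`, energy-shifted to zero at the 0.7 nm cutoff); walls 3–5
carry a softened Lennard-Jones `V = 4ε[(σ'/(d+Δ))¹² − (σ'/(d+Δ))⁶]`
re-parameterized so its minimum sits exactly at `d = r_p` and it crosses
zero at `σ_attr` (default `r_p/2`; the positive radial shift Δ is what
makes the core *soft* — at `σ_attr = r_p·2^(−1/6)` the form would
degenerate to plain LJ with a diverging core), cut at `1.5 r_p`.  `ε`
defaults to 1 kJ/mol; neither `ε` nor `σ` is printed in the published
scheme, so both are configuration.  Forces are force-shifted to vanish
continuously at their cutoffs and clamped to `F_max = 1000`
kJ mol⁻¹ nm⁻¹; with default parameters the clamp engages only for the
steep planar walls (the softened core stays below it).  One consequence
of force-shifting with the short `1.5 r_p` cutoff is that the shifted
soft-wall force never points outward: the wall confines monotonically
and releases smoothly at the cutoff, rather than weakly adhering.

Wall-coupled atoms are all water atoms, all Cα (MM and CG), and the
side-chain atoms of TRP/TYR residues whose Cβ starts within 0.8 nm of
the membrane-wall zero surface.

Reported wall energies use the *cap-consistent* potential: below the
distance where the shifted force saturates at `F_max`, the potential
continues linearly with slope `F_max`, so the report is the integral of
the force actually applied.  The pure shifted potential (used to locate
the minimum at `r_p`) is available separately.

Known limitation: where the arg-min wall *type* changes (e.g. plane →
membrane tube along the slab boundary), the force law changes at equal
`d`, so |F| is discontinuous across the handoff surface.  This is
inherent to the "potential of the closest wall" construction; each
wall's own `V(d)` and shifted force are continuous everywhere,
including at their cutoffs, and the Langevin integrator tolerates the
measure-zero handoffs.

## Integration

Leapfrog with an impulse Langevin thermostat: kick by the systematic
force, velocity relaxation by `a = e^(−γΔt)` with `γ = 1/τ`
(`τ = 0.4 ps`), Gaussian noise of variance `(1 − a²)k_BT/m`, drift,
then SHAKE.  With `γ = 0` (pass `tau=inf`) the step is exactly
velocity-Verlet/leapfrog.  Velocities after SHAKE are recomputed from
the constrained displacement; there is no separate velocity-constraint
(RATTLE) pass.  Temperature uses `n_dof = 3N_dynamic − n_constraints`
(each distance constraint removes one degree of freedom; a rigid water
keeps 6).  On 200 non-interacting rigid waters over 10 ps the
thermostat gives 299.0 ± 2.6 K at a 300 K target.

Energy-conservation checks use the time-centered leapfrog estimator
`E_n = PE(x_n) + (KE_{n−1/2} + KE_{n+1/2})/2`; the naive sum of
half-step KE and on-step PE oscillates at O(ωΔt) and hides the true
drift, which is below 1e-4 relative over 10 ps at a 0.5 fs step on the
toy system.

Minimization before dynamics is steepest descent with an adaptive step
and SHAKE re-projection after every accepted move.  Nonbonded pairs
come from a KD-tree Verlet list with a 0.2 nm skin, rebuilt every 10
steps or whenever any atom has moved half the skin; listed-pair
energies match a brute-force scan to 1e-9 relative.  The inner pair
loop and the SHAKE sweeps are numba kernels.  Runs are bit-for-bit
reproducible for a fixed seed.

## Synthetic systems

The toy bundle is an ideal-geometry stand-in for a transmembrane
receptor: per helix, an ideal α-helical Cα trace (rise 0.15 nm/residue,
radius 0.23 nm, 100°/residue) plus a pseudo-Cβ on non-glycine residues,
axes parallel to z on a circle of radius `0.5·√n_helices` nm (roughly
1 nm axis-to-axis spacing, as in real helix packing).  The optional
ligand is five carbons — a center plus four tetrahedral arms whose
default length scales with the bundle radius so the ligand contacts the
pocket-lining residues, giving a non-trivial MM/I/CG split.  Residue
names are drawn reproducibly from a fixed pool so that glycine (no Cβ)
and TRP/TYR (wall-coupled side chains) cases are exercised.  The
accompanying parameter table uses soft generic constants (bonds
2×10⁴ kJ mol⁻¹ nm⁻², modest angle constants) chosen for stable 2 fs
integration of pseudo-atoms, plus standard three-site water parameters
(O–H 0.1 nm, H–O–H 109.47°, O charge −0.82 e, O–O LJ σ 0.3166 nm,
ε 0.650 kJ/mol).

What the bundle does *not* emulate: real side chains and their packing,
a full atomistic force field (the MM region is deliberately minimal and
therefore floppier than a real binding site), loop regions, or a real
fold's contact topology.  Tests passing on it validate the scheme's
machinery — partitioning, coupling, walls, integration — not the
accuracy of any particular protein model.

Water droplets are generated by rejection sampling of oxygen positions
inside the positive level-set region (0.15–0.25 nm clearance from the
walls so no molecule starts on the repulsive ramp), at least 0.26 nm
O–O apart and outside a protein exclusion radius, with random rigid
orientations; generation is a pure function of the seed.  The droplet
used for water-dynamics studies holds 200 waters in a 1.7 nm-radius
hemisphere — a liquid-density droplet (the placed density is ≈30 nm⁻³
and the equilibrated local structure reproduces the three-site-water
O–O RDF first-peak position, 0.275 nm).  It does, however, have a large
surface fraction and collective droplet modes that bulk water lacks.

## Analysis conventions

RMSD superposes each frame on the reference (Kabsch) before measuring;
RMSF optionally aligns frames, then averages per-atom fluctuations over
each residue's selected atoms.  The VACF is averaged over atoms and all
time origins by FFT and normalized to C(0) = 1; for droplets the
selection's center-of-mass velocity can be removed per frame so
collective drift does not count as single-particle correlation.  The
**decorrelation time** is the first lag beyond which the smoothed
(0.05 ps boxcar) |C(t)| stays below 2% of C(0) — the level at which a
plotted correlation curve reads as zero.  A first-zero-crossing rule
would instead report the ~0.15–0.2 ps initial decay of liquid water,
which is a different quantity from "correlation is lost".  The droplet
O–O RDF normalizes with the convex-hull density and restricts reference
atoms to those deeper than `r_max` inside the hull, so every counted
shell lies within the droplet (edge correction); extremum positions are
the first maximum and the first following *local* minimum, since a
droplet g(r) also decays globally at large r.

## Problem sizes used in the validation suite

Deterministic wall/potential checks run on grids of 1e-4–1e-5 nm
resolution.  Dynamical checks use a 3×12-helix bundle (NVE drift,
reproducibility), a 5×20 bundle (RMSF region ordering), a 7×30 bundle
(stability, wall margin), and 40–200-water droplets (thermostat,
SHAKE drift, containment, VACF: 5 ps equilibration + 20 ps production
at 2 fs).  These sizes give converged answers for the properties tested
while keeping the whole suite desk-scale.
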