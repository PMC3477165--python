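# Minimal self-consistent MM parameter set for the synthetic test systems
# (pseudo-atom helix bundle, 5-atom rigid ligand, SPC water).
#
# ATOM     name  mass      sigma(nm)  epsilon(kJ/mol)  charge(e)
# BOND     n1 n2 K_r(kJ/mol/nm^2)  r0(nm)
# ANGLE    n1 n2 n3 K_theta(kJ/mol/rad^2)  theta0(deg)
# DIHEDRAL n1 n2 n3 n4 K(kJ/mol) multiplicity phase(deg)
# Atom names are matched with trailing digits stripped (HW1 -> HW, C3 -> C).

ATOM  CA  12.011   0.336    0.40     0.0
ATOM  CB  12.011   0.350    0.35     0.0
ATOM  C   12.011   0.350    0.30     0.0
ATOM  OW  15.9994  0.316557 0.650194 -0.82
ATOM  HW  1.008    0.0      0.0       0.41

# pseudo-backbone of the toy bundle: Calpha-Calpha virtual bonds at the
# ideal-helix spacing, Calpha-Cbeta side-chain stubs
BOND  CA CA  20000.0  0.383
BOND  CA CB  20000.0  0.153
# SPC water (the O-H bonds become SHAKE constraints; the angle record
# supplies the rigid H-H distance)
BOND  OW HW  345000.0  0.1
ANGLE HW OW HW  383.0  109.47
# rigid 5-atom ligand: generated geometry is the reference ("native")
BOND  C C   20000.0  native
ANGLE C C C  300.0  native
# toy backbone angle at the ideal-helix Calpha geometry
ANGLE CA CA CA  100.0  90.4
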