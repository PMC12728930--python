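# Vina-style scoring parameters and AutoDock atom-type tables.
#
# term_weights: the five published Vina pairwise term weights
# (gauss1, gauss2, repulsion, hydrophobic, hbond).
# vdw_radii: AutoDock Rii/2 van der Waals radii, Angstrom.
# Properties: hydrophobic atoms contribute to the hydrophobic ramp;
# acceptor/donor flags gate the hbond ramp. Hydrogens carry no
# pairwise interaction terms (HD is used for donor perception and
# hydrogen-bond geometry only).

term_weights:
  gauss1: -0.035579
  gauss2: -0.005156
  repulsion: 0.840245
  hydrophobic: -0.035069
  hbond: -0.587439

cutoff: 8.0

atom_types:
  C:  {element: C,  radius: 2.00, hydrophobic: true,  acceptor: false, donor: false}
  A:  {element: C,  radius: 2.00, hydrophobic: true,  acceptor: false, donor: false}
  N:  {element: N,  radius: 1.75, hydrophobic: false, acceptor: false, donor: true}
  NA: {element: N,  radius: 1.75, hydrophobic: false, acceptor: true,  donor: false}
  O:  {element: O,  radius: 1.60, hydrophobic: false, acceptor: false, donor: true}
  OA: {element: O,  radius: 1.60, hydrophobic: false, acceptor: true,  donor: false}
  S:  {element: S,  radius: 2.00, hydrophobic: false, acceptor: false, donor: false}
  SA: {element: S,  radius: 2.00, hydrophobic: false, acceptor: true,  donor: false}
  P:  {element: P,  radius: 2.10, hydrophobic: false, acceptor: false, donor: false}
  F:  {element: F,  radius: 1.54, hydrophobic: true,  acceptor: false, donor: false}
  Cl: {element: Cl, radius: 2.04, hydrophobic: true,  acceptor: false, donor: false}
  Br: {element: Br, radius: 2.17, hydrophobic: true,  acceptor: false, donor: false}
  I:  {element: I,  radius: 2.36, hydrophobic: true,  acceptor: false, donor: false}
  H:  {element: H,  radius: 1.00, hydrophobic: false, acceptor: false, donor: false}
  HD: {element: H,  radius: 1.00, hydrophobic: false, acceptor: false, donor: false}
  HS: {element: H,  radius: 1.00, hydrophobic: false, acceptor: false, donor: false}
  M:  {element: X,  radius: 1.20, hydrophobic: false, acceptor: false, donor: false}

# Covalent radii (Angstrom) for geometric bond perception; a pair is
# bonded when r <= (r_cov_i + r_cov_j) * tolerance.
bond_tolerance: 1.3
covalent_radii:
  H: 0.31
  C: 0.76
  N: 0.71
  O: 0.66
  F: 0.57
  P: 1.07
  S: 1.05
  Cl: 1.02
  Br: 1.20
  I: 1.39
  X: 1.20
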