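# Methods

## Problem setting and model

A receptor-bound carbohydrate is treated as a rigid scaffold inside a
rigid receptor. A candidate moiety R is attached at one reactive center
(an exocyclic hydroxyl oxygen, or an amino nitrogen handled
identically), and the only degrees of freedom searched are torsional:
the two linkage torsions — φ about the (ring C)–(exocyclic O) bond and
ψ about the (exocyclic O)–(attachment atom) bond — plus the moiety's
internal rotatable bonds. This is deliberate: the scaffold's pose is
taken from the cocomplex structure, so the mimetic inherits it, and the
search space stays small enough for exhaustive cross-checks on toy
systems.

## Ethyl-cap grafting

Each library fragment is built with a temporary ethyl cap R–CH₂CH₃ in
which CH₂ plays the role of the exocyclic oxygen and CH₃ the ring
carbon. Alignment is fully determined by the scaffold and the cap's
internal geometry, in three steps:

1. translate so the CH₃ carbon coincides with the ring carbon (checked
   to ≤ 1e-6 Å);
2. rotate so the CH₂→CH₃ direction is parallel to the (exocyclic
   O)→(ring C) direction (checked to ≤ 1e-4°) — CH₂ then sits on the
   linkage axis where the oxygen is;
3. fix the residual spin about that axis by eclipsing the attachment
   atom with a deterministic reference neighbor of the ring carbon
   (the ring oxygen when present, else the lowest-index heavy
   neighbor): φ starts at exactly 0°. If the attachment atom is
   collinear with the cap axis, its first heavy substituent defines the
   spin instead.

Because no step depends on the fragment's input pose, grafting is
invariant to the moiety's global orientation (verified to ~1e-14 Å over
random rotations/translations). After alignment the moiety is
translated so CH₂ lands exactly on the oxygen; the cap atoms and the
hydroxyl hydrogen are deleted, and the new O–R bond therefore inherits
the cap's CH₂–R bond length and local angles — the geometry the
fragment was built (and would be charge-fitted) with. The eclipsed 0°
start is intentional and crude; the GA owns this angle afterwards.

Net-charge repair splits the deviation from the formal charge evenly
over the two linkage atoms only. Deviations beyond 0.5 au against a
declared formal charge are treated as assembly errors. When no fitted
charge table is supplied, a per-AutoDock-type empirical fallback
charges the moiety before repair; it is a crude stand-in meant to keep
the pipeline runnable, not a charge model.

## Scoring function

Pairwise part: the published Vina functional forms and weights

| term        | form (d = surface distance, Å)          | weight    |
|-------------|------------------------------------------|-----------|
| gauss1      | exp(−(d/0.5)²)                           | −0.035579 |
| gauss2      | exp(−((d−3)/2)²)                         | −0.005156 |
| repulsion   | d² for d < 0                             | 0.840245  |
| hydrophobic | ramp 1→0 over d ∈ [0.5, 1.5]             | −0.035069 |
| hbond       | ramp 1→0 over d ∈ [−0.7, 0]              | −0.587439 |

with d = r − R_i − R_j using the AutoDock Rii/2 radii (shipped in
`data/vina.yaml`, editable). Pairs are collected between the moiety and
the receptor, the moiety and the carbohydrate core, and within the
moiety, inside an 8 Å center-distance cutoff. Covalently connected
pairs separated by three bonds or fewer (including across the new
linkage) are excluded — the usual 1-2/1-3/1-4 rule; without it the
linkage's bonded and geminal pairs dominate the score. Hydrogens carry
no pairwise terms. Two flags are context-dependent, following Vina's
atom typing: a carbon bonded to any N/O/S/P is not hydrophobic, and an
N/O atom is a donor when it carries a hydrogen. Vina's N_rot-dependent
normalization is omitted; torsional costs are handled explicitly (see
entropy below), avoiding double counting.

CHI extension: each labeled linkage torsion adds a periodic penalty.
The shipped anomeric profile is the cosine series

    E(φ) = 0.6 · (1.5 − 2 cos φ + cos 2φ)   kcal/mol

with exact minima E = 0 at φ = ±60° (the gauche wells the exo-anomeric
effect favors), 2.7 kcal/mol at trans and a 0.3 kcal/mol shoulder at
syn. The barrier heights are chosen to dominate typical sub-kcal/mol
dispersive preferences without overwhelming steric clashes; α and β
variants default to the same symmetric profile, and a mild 3-fold
staggered profile (amplitude 0.5 kcal/mol) covers non-anomeric linkage
torsions. All profiles live in `data/chi_profiles.yaml` and are
user-overridable; `chi_weight = 0` recovers the pure Vina sum exactly.
The φ branch is labeled `anomeric` automatically when the ring carbon
carries a second oxygen (i.e. the center is the anomeric position).

Entropy: interaction energies compared against experimental binding
free energies are corrected by +0.6 kcal/mol per restricted rotatable
bond (configurable 0–1 kcal/mol), the conventional rotamer-based
estimate of the ligand's conformational entropy loss on binding.

## Genetic algorithm

Chromosome: the torsion vector, each gene on [−180°, 180°). Operators:
tournament selection of size 2, uniform per-gene crossover (rate 0.8),
Gaussian mutation wrapped to the circle (rate 0.25, σ = 25° by default;
half of the mutation draws use σ/10 so converged minima get polished to
sub-degree precision), elitism of one, and a per-generation fraction
(default 10%) of random immigrants — fresh uniform individuals that
keep other basins of the multimodal torsional landscape in play.
Early stop when the best fitness improves by less than `convergence_tol`
over `convergence_window` generations. Fixed seeds reproduce the trace
bitwise. On enumerable landscapes (one torsion) the GA endpoint agrees
with an exhaustive 1° scan to well under a degree.

Torsions are applied root-to-leaf along the pose tree so child
rotations compose correctly; each branch stores an explicit four-atom
dihedral reference, and the rotation sense is verified by
re-measurement rather than trusted to a sign convention.

## Monosaccharide identification and template mapping

Sugar rings are found as 5/6-membered cycles containing exactly one
oxygen. The ring is oriented anomeric-carbon-first (the ring-oxygen
neighbor bearing an exocyclic O/N); exocyclic substituents are walked
breadth-first, with any oxygen terminating the walk (its hydrogens are
taken, anything heavier beyond it — another residue or a grafted
moiety — is not). Stereochemistry is perceived per ring carbon as the
sign of det[v_prev−c, v_next−c, v_exo−c] with prev/next the ordered
ring neighbors and v_exo the highest-priority exocyclic substituent
(O/N > C > H): invariant to atom order and rigid motion, sign-flipped
by mirror reflection.

Template matching is a full isomorphism of element-labeled heavy-atom
graphs (networkx VF2) with the additional requirements that ring
carbons land on the template's numbered carbons and that every stereo
descriptor agrees; atom names in the input are ignored entirely.
Multiple templates matching one residue is an error, never a silent
pick. Matched atoms receive the template's canonical types and partial
charges (hydrogens inherit from their parent heavy atom's template
hydrogens); unmatched atoms are flagged as moiety in the log.

The shipped templates (Glc, Gal, Man, Fuc, GlcNAc in α/β) are generated
by `scripts/make_templates.py` from the package's own idealized chair
realizations, with mock GLYCAM-like type labels and internally
consistent charges summing exactly to the formal charge. They exist so
the matching machinery is fully testable; real force-field templates
plug in through the same text format and are the intended production
input.

## Toy fixtures: what they emulate, and what they do not

`make_toy_pyranose` builds an ideal ⁴C₁ chair (ring torsions ≈ ±55°,
uniform 1.53 Å ring bonds, tetrahedral substituent frames, axial /
equatorial patterns per sugar, mirror reflection for L-fucose). It
reproduces the topology, stereochemistry and rough geometry of a
pyranose, not force-field bond lengths or anomeric fine structure.
`make_toy_pocket` is a concave shell of typed atoms, not a protein
fold; `make_pseudo_trajectory` applies i.i.d. Gaussian jitter to the
ligand, which has the right first moments (E[RMSD²] = 3σ²) but none of
the correlated motion of MD. Tests passing on these fixtures therefore
validate the algorithms and their contracts — geometry, invariances,
search, bookkeeping — not predictive accuracy on real complexes.

The exo-anomeric contrast fixture deserves a note. It is a
β-galactoside with a phenyl aglycone in an engineered pocket whose
pure-Vina optimum is the trans φ rotamer. Engineering it robustly
exploits a geometric fact: the aglycone's para carbon (and the ring
centroid) lie on the O1–Cipso axis, so their positions depend on φ
only, never on the ring spin ψ. The pocket is therefore built from a
dense hydrophobic cone capping the trans-rotamer para position, a
sparser cone at the gauche(−60°) position, and two single-atom steric
blockers at mid-φ para positions that wall off the stacking basin
between the wells. Exhaustive (φ,ψ) scans confirm the design: the
chi-off global optimum is trans, the chi-on optimum gauche, with
≳0.2 kcal/mol separation from the nearest competing basin.

## Numerical choices

- Bond perception: r ≤ (covalent radius sum) × 1.3; H–H never bonds;
  pairs closer than 0.5 Å are an error (clash), not a bond.
- PDBQT round-trips are exact to the printed precision (coordinates and
  charges at 3 decimals).
- Ensemble statistics use the population standard deviation; even frame
  selection takes indices ⌊i·m/k⌋.
- R² is reported both as squared Pearson correlation and from the OLS
  fit (identical for a simple linear regression; both are emitted for
  transparency). Zero-variance inputs yield an explicit "undefined",
  never 0 or NaN.
- RMSD applies no superposition: pose comparisons are meant to happen
  in a common (crystallographic) frame, so align structures upstream.
- H-bond geometry for bridging waters: donor–acceptor ≤ 3.5 Å and
  D–H···A ≥ 120°, both configurable; any N/O with a hydrogen may
  donate, any N/O may accept.
- ΔG from K_D uses RT ln K_D at 298.15 K.

## Validation problem sizes

The shipped test suite runs the scoring oracle on 20 random ≤30-atom
complexes, the GA-vs-grid comparison on 25 single-torsion problems, the
with/without-CHI contrast over 100 GA runs (50 per arm), grafting
invariance over 50 random orientations, charge repair over 1000 random
vectors, template recovery over 100 shuffled realizations, the
correlation recovery over 200 replicates of 200 synthetic records, and
a full 3-moiety end-to-end screen twice to confirm determinism. The
suite completes in a few minutes on a single CPU.

## Known limitations

- Rigid receptor and rigid carbohydrate core: induced fit is out of
  scope; poses that require backbone or scaffold motion will be missed.
- The empirical fallback charges are placeholders; quantitative work
  needs fitted (RESP-style) charge tables supplied by the user.
- Metal ions are kept as generic receptor atoms; the scoring function
  has no specific metal-coordination term.
- The moiety protonation rules (ionize amines and carboxylates by
  default) are SMARTS heuristics, not a pKa model.
- GB/PBSA desolvation energies are consumed from external tables, never
  computed here.
- Shipped templates are mock-parameterized; matching is exact
  isomorphism, so residues with missing heavy atoms do not match
  (by design — partial occupancy handling is a possible extension).
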