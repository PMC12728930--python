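# glycograft

Structure-based design of **glycomimetics**: carbohydrate ligands
decorated with drug-like moieties to improve the affinity and
drug-likeness of protein–carbohydrate interactions, which are typically
weak (K_D in the high µM–mM range). The endogenous, receptor-bound
carbohydrate supplies specificity and anchors the ligand; glycograft
grafts candidate fragments onto a chosen reactive center (a hydroxyl or
amino position on the sugar), finds each fragment's most likely
orientation in the binding site with a genetic algorithm, and scores it
with a carbohydrate-aware scoring function.

## What it does

- **Moiety library** (`moiety_library`) — SMILES → 3D capped fragments
  (RDKit distance geometry + force-field relaxation). Every fragment
  carries a temporary ethyl cap R–CH₂CH₃: the CH₂ mimics the sugar's
  exocyclic oxygen and the CH₃ the ring carbon bearing it.
- **Grafting** (`grafting`) — superposes the cap onto the reactive
  center (CH₃ → ring carbon exactly; CH₂→CH₃ aligned with O→C),
  initializes the linkage torsion at 0° (eclipsed), deletes the cap and
  the hydroxyl hydrogen, forms the new O–R bond with the cap's bond
  geometry, and repairs any non-integral net charge by splitting the
  deviation evenly over the two linkage atoms.
- **Scoring** (`scoring`) — the published AutoDock Vina pairwise terms
  (gauss1, gauss2, repulsion, hydrophobic, H-bond) on surface distances
  with the AutoDock vdW radii, extended with **CHI torsional penalties**
  that encode the *exo*-anomeric preference of the glycosidic/aglycone
  φ angle for *gauche* rotamers (profile minima at φ = ±60°, a
  2.7 kcal/mol penalty at *trans*). A per-rotatable-bond entropy
  penalty (default 0.6 kcal/mol) corrects interaction energies before
  comparison with experiment.
- **GA pose search** (`ga_search`) — genetic algorithm over the moiety's
  torsional degrees of freedom (linkage φ/ψ plus internal rotatable
  bonds) against the rigid receptor; tournament selection, uniform
  crossover, wrapped Gaussian mutation, elitism, random immigrants.
- **Template mapping** (`glycam_map`) — identifies monosaccharides from
  3D structure alone (ring size, signed-volume stereo descriptors,
  exocyclic composition), matches them to force-field residue templates
  by subgraph isomorphism, transfers canonical types/charges, and flags
  everything else as moiety.
- **Analysis** (`analysis`) — heavy-atom RMSD (no superposition),
  φ-angle measurement/classification, bridging-water detection,
  entropy-corrected energy–affinity correlation (R²).
- **Fixtures** (`fixtures`) — deterministic toy systems (ideal chair
  pyranoses, synthetic pockets, pseudo-trajectories) so the whole
  pipeline is testable without downloads.

I/O is PDB and AutoDock PDBQT (including ROOT/BRANCH torsion trees).

## Worked example

The package's validation centerpiece in miniature: a β-galactoside with
an aromatic aglycone sits in a pocket whose pure-Vina optimum is the
*trans* φ rotamer. Without the CHI terms the GA lands on *trans*; with
them, the exo-anomeric penalty tips the search into the physically
correct *gauche* well:

```python
from glycograft.fixtures import make_chi_contrast_system
from glycograft.ga_search import GAParams, optimize_pose
from glycograft.scoring import ScoringParameters
from glycograft.analysis import classify_phi

cx = make_chi_contrast_system(seed=2)
for chi_w in (0.0, 1.0):
    p = GAParams(population_size=60, generations=80, seed=1,
                 mutation_rate=0.3, mutation_sigma=30.0,
                 immigrant_fraction=0.15, convergence_window=25,
                 convergence_tol=1e-3)
    pose, rec, _ = optimize_pose(cx, p, ScoringParameters(chi_weight=chi_w))
    print(f"chi_weight={chi_w}:  phi = {pose[0]:7.1f} deg "
          f"({classify_phi(pose[0])}),  score = {rec.total:.3f}")
```

prints

```
chi_weight=0.0:  phi =   177.8 deg (trans),  score = -0.854
chi_weight=1.0:  phi =   -55.1 deg (gauche),  score = -0.227
```

The score is the weighted Vina term sum plus the CHI penalty
(kcal/mol-like); φ is the dihedral (ring O, anomeric C, glycosidic O,
aglycone C), and `gauche` means |φ| ∈ (30°, 90°) — the rotamer the
exo-anomeric effect favors and crystal structures of such complexes
show.

A command-line interface covers the same pipeline:

```bash
glycograft make-fixtures --out fixtures/ --seed 1
glycograft build-library --smiles-table moieties.tsv --out lib/ --seed 1
glycograft screen --complex fixtures/pyranose.pdbqt --receptor fixtures/pocket.pdbqt \
                  --center fixtures/center_O3.txt --library lib/ --out results/ --seed 1
glycograft map --ligand fixtures/pyranose.pdbqt --log pdb2glycam.log
glycograft analyze --scores scores.tsv --affinities exp.tsv --entropy-per-bond 0.6
```

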