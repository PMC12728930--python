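"""Virtual moiety library: SMILES -> capped 3D fragments.

Each library member is a small drug-like fragment destined to be grafted
onto a hydroxyl (or amino) reactive center of a receptor-bound
carbohydrate.  Before grafting, a temporary ethyl group is appended to
the attachment atom R, forming R-CH2CH3: the inner CH2 carbon mimics the
exocyclic (side-group hydroxyl) oxygen of the sugar and the terminal CH3
carbon mimics the ring carbon bearing it.  The cap provides the
alignment frame for grafting and is deleted afterwards.

Cap atoms are flagged with the reserved residue name ``CAP`` (moiety
atoms use ``MOI``) so that a capped fragment written to PDBQT can be
recovered without side-car bookkeeping files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .structio import (Atom, MolecularStructure, Role, TorsionTree,
                       write_pdbqt, parse_pdbqt)

CAP_RESNAME = "CAP"
MOIETY_RESNAME = "MOI"


class ReactionClass(str, Enum):
    ALDEHYDE = "aldehyde"
    ACYL_HALIDE = "acyl_halide"
    ALKYL_HALIDE = "alkyl_halide"
    SULFONYL_HALIDE = "sulfonyl_halide"
    ALCOHOL = "alcohol"
    CLICK = "click"
    OTHER = "other"


@dataclass
class MoietySpec:
    identifier: str
    smiles: str
    attachment_atom: int = 0
    reaction_class: ReactionClass = ReactionClass.OTHER


@dataclass
class CappedMoiety:
    structure: MolecularStructure
    attachment_atom: int
    cap_ch2: int
    cap_ch3: int
    rotatable_bonds: TorsionTree = field(default_factory=TorsionTree)
    identifier: str = ""
    canonical_smiles: str = ""

    def cap_atom_indices(self) -> set[int]:
        """Cap carbons plus their hydrogens."""
        out = {self.cap_ch2, self.cap_ch3}
        for c in (self.cap_ch2, self.cap_ch3):
            for n in self.structure.neighbors(c):
                if self.structure.atoms[n].element == "H":
                    out.add(n)
        return out

    def validate(self) -> None:
        s = self.structure
        if frozenset((self.attachment_atom, self.cap_ch2)) not in s.bonds:
            raise ValueError("attachment atom not bonded to cap CH2")
        if frozenset((self.cap_ch2, self.cap_ch3)) not in s.bonds:
            raise ValueError("cap CH2 not bonded to cap CH3")
        for c in (self.cap_ch2, self.cap_ch3):
            if s.atoms[c].element != "C":
                raise ValueError("cap atoms must be carbons")


def _assign_autodock_type(atom: Chem.Atom) -> str:
    """Simplified AutoDock typing from RDKit perception.

    Aromatic carbons are A, aliphatic C; oxygens OA; nitrogens carrying a
    hydrogen are donors (N), bare nitrogens acceptors (NA); sulfur SA;
    hydrogens on N/O/S are polar (HD), the rest H.
    """
    sym = atom.GetSymbol()
    if sym == "C":
        return "A" if atom.GetIsAromatic() else "C"
    if sym == "O":
        return "OA"
    if sym == "N":
        return "N" if atom.GetTotalNumHs(includeNeighbors=True) > 0 else "NA"
    if sym == "S":
        return "SA"
    if sym == "H":
        heavy = atom.GetNeighbors()
        if heavy and heavy[0].GetSymbol() in ("N", "O", "S"):
            return "HD"
        return "H"
    if sym in ("F", "Cl", "Br", "I", "P"):
        return sym
    return "M"


_IONIZE_RULES = [
    # carboxylic acid -> carboxylate
    ("[CX3](=O)[OX2H1]", "[CX3](=O)[O-]"),
]


def _ionize(mol: Chem.Mol) -> Chem.Mol:
    """Deprotonate carboxylic acids and protonate aliphatic amines."""
    for smarts, _repl in _IONIZE_RULES:
        patt = Chem.MolFromSmarts(smarts)
        while mol.HasSubstructMatch(patt):
            match = mol.GetSubstructMatch(patt)
            rw = Chem.RWMol(mol)
            o = rw.GetAtomWithIdx(match[-1])
            o.SetFormalCharge(-1)
            o.SetNumExplicitHs(0)
            o.SetNoImplicit(True)
            mol = rw.GetMol()
            Chem.SanitizeMol(mol)
    amine = Chem.MolFromSmarts("[NX3;H2,H1;!$(NC=O);!$(N~[!#6;!#1])]")
    for (idx,) in mol.GetSubstructMatches(amine):
        a = mol.GetAtomWithIdx(idx)
        if a.GetIsAromatic():
            continue
        a.SetFormalCharge(1)
        a.SetNumExplicitHs(a.GetTotalNumHs() + 1)
    Chem.SanitizeMol(mol)
    return mol


def build_moiety_3d(spec: MoietySpec, seed: int = 0,
                    ionize: bool = True) -> CappedMoiety:
    """Build a 3D ethyl-capped fragment from a SMILES specification.

    The SMILES is parsed, the ethyl cap added at the attachment atom
    (replacing one hydrogen), explicit hydrogens generated, coordinates
    embedded with a distance-geometry method, and the geometry relaxed
    with a force-field minimizer.  Deterministic for a fixed seed.
    """
    mol = Chem.MolFromSmiles(spec.smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {spec.smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    if ionize:
        mol = _ionize(mol)
    att = spec.attachment_atom
    if att < 0 or att >= mol.GetNumAtoms():
        raise ValueError(f"attachment atom {att} out of range for {spec.smiles!r}")
    if mol.GetAtomWithIdx(att).GetTotalNumHs() < 1:
        raise ValueError(
            f"attachment atom {att} of {spec.smiles!r} has no replaceable hydrogen"
        )

    rw = Chem.RWMol(mol)
    ch2 = rw.AddAtom(Chem.Atom(6))
    ch3 = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(att, ch2, Chem.BondType.SINGLE)
    rw.AddBond(ch2, ch3, Chem.BondType.SINGLE)
    a = rw.GetAtomWithIdx(att)
    if a.GetNumExplicitHs() > 0:
        a.SetNumExplicitHs(a.GetNumExplicitHs() - 1)
    capped = rw.GetMol()
    Chem.SanitizeMol(capped)
    capped = Chem.AddHs(capped)

    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1) or 1
    if AllChem.EmbedMolecule(capped, params) != 0:
        raise ValueError(f"3D embedding failed for {spec.smiles!r}")

    ff_name = "MMFF94"
    try:
        props = AllChem.MMFFGetMoleculeProperties(capped)
        ff = AllChem.MMFFGetMoleculeForceField(capped, props)
    except Exception:
        ff = None
    if ff is None:
        ff = AllChem.UFFGetMoleculeForceField(capped)
        ff_name = "UFF"
    e_before = ff.CalcEnergy()
    ff.Minimize(maxIts=500)
    e_after = ff.CalcEnergy()
    if e_after > e_before + 1e-6:
        raise RuntimeError("minimization increased the force-field energy")

    AllChem.ComputeGasteigerCharges(capped)
    conf = capped.GetConformer()

    structure = MolecularStructure(
        provenance=(
            f"built from SMILES {spec.smiles!r} (ETKDGv3 seed {seed}, "
            f"{ff_name} relaxed, E {e_before:.2f} -> {e_after:.2f})"
        )
    )
    cap_set = {ch2, ch3}
    for rd_atom in capped.GetAtoms():
        i = rd_atom.GetIdx()
        in_cap = i in cap_set or (
            rd_atom.GetSymbol() == "H"
            and rd_atom.GetNeighbors()[0].GetIdx() in cap_set
        )
        q = float(rd_atom.GetDoubleProp("_GasteigerCharge"))
        if not np.isfinite(q):
            q = 0.0
        pos = conf.GetAtomPosition(i)
        structure.atoms.append(Atom(
            serial=i + 1,
            name=f"{rd_atom.GetSymbol()}{i + 1}",
            element=rd_atom.GetSymbol(),
            autodock_type=_assign_autodock_type(rd_atom),
            coords=np.array([pos.x, pos.y, pos.z]),
            charge=q,
            residue_id=("X", CAP_RESNAME if in_cap else MOIETY_RESNAME, 1),
            role=Role.MOIETY,
        ))
    for bond in capped.GetBonds():
        structure.add_bond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())

    # clash guard on non-bonded pairs
    xyz = structure.coords
    n = len(xyz)
    for i in range(n):
        for j in range(i + 1, n):
            if frozenset((i, j)) in structure.bonds:
                continue
            if np.linalg.norm(xyz[i] - xyz[j]) < 0.8:
                raise RuntimeError(
                    f"embedded geometry has a non-bonded contact < 0.8 A "
                    f"between atoms {i} and {j}"
                )

    cm = CappedMoiety(
        structure=structure, attachment_atom=att, cap_ch2=ch2, cap_ch3=ch3,
        identifier=spec.identifier, canonical_smiles=canonical,
    )
    cm.validate()
    return cm


def moiety_from_structure(structure: MolecularStructure) -> CappedMoiety:
    """Recover a CappedMoiety from a structure using the reserved CAP
    residue flags (e.g. after a PDBQT round trip)."""
    if not structure.bonds:
        from .structio import perceive_bonds
        structure.bonds = perceive_bonds(structure)
    cap_carbons = [
        i for i, a in enumerate(structure.atoms)
        if a.residue_id[1] == CAP_RESNAME and a.element == "C"
    ]
    if len(cap_carbons) != 2:
        raise ValueError("structure lacks the two reserved CAP carbons")
    c_a, c_b = cap_carbons
    heavy = lambda idx: [
        n for n in structure.neighbors(idx) if structure.atoms[n].element != "H"
    ]
    # CH3 has exactly one heavy neighbor (the CH2); CH2 has two.
    if len(heavy(c_a)) == 1 and c_b in heavy(c_a):
        ch3, ch2 = c_a, c_b
    elif len(heavy(c_b)) == 1 and c_a in heavy(c_b):
        ch3, ch2 = c_b, c_a
    else:
        raise ValueError("CAP carbons are not an intact terminal ethyl group")
    att = [n for n in heavy(ch2) if n != ch3]
    if len(att) != 1:
        raise ValueError("cap CH2 must bond exactly one moiety atom")
    cm = CappedMoiety(structure=structure, attachment_atom=att[0],
                      cap_ch2=ch2, cap_ch3=ch3)
    cm.validate()
    return cm


def export_moiety_pdbqt(moiety: CappedMoiety, merge_nonpolar_h: bool = True) -> str:
    """Serialize a capped moiety to PDBQT.

    With ``merge_nonpolar_h`` (the AutoDock united-atom convention for
    carbons) nonpolar hydrogens are dropped and their charges folded
    into the parent heavy atom; polar hydrogens (HD) are always kept.
    A REMARK SMILES line records the uncapped fragment identity.
    """
    s = moiety.structure
    if merge_nonpolar_h:
        keep = []
        extra = {i: 0.0 for i in range(len(s.atoms))}
        for i, a in enumerate(s.atoms):
            if a.element == "H" and a.autodock_type != "HD":
                parents = [n for n in s.neighbors(i)
                           if s.atoms[n].element != "H"]
                if parents:
                    extra[parents[0]] += a.charge
                    continue
            keep.append(i)
        merged = s.subset(keep)
        for new_i, old_i in enumerate(keep):
            merged.atoms[new_i].charge += extra[old_i]
        s = merged
    text = write_pdbqt(s, None)
    header = ""
    if moiety.canonical_smiles:
        header += f"REMARK  SMILES {moiety.canonical_smiles}\n"
    if moiety.identifier:
        header += f"REMARK  MOIETY {moiety.identifier}\n"
    return header + text


def load_moiety_pdbqt(text: str) -> CappedMoiety:
    structure, _tree = parse_pdbqt(text)
    cm = moiety_from_structure(structure)
    for line in text.splitlines():
        if line.startswith("REMARK  SMILES"):
            cm.canonical_smiles = line.split(maxsplit=2)[2].strip()
        elif line.startswith("REMARK  MOIETY"):
            cm.identifier = line.split(maxsplit=2)[2].strip()
    return cm


def build_library(specs: list[MoietySpec], out_dir: str | Path, seed: int = 0,
                  merge_nonpolar_h: bool = True) -> list[dict]:
    """Build each spec to 3D and write one PDBQT per moiety plus a
    manifest; per-moiety failures are recorded, not raised."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for k, spec in enumerate(specs):
        row = {"id": spec.identifier, "smiles": spec.smiles, "status": "ok",
               "file": f"{spec.identifier}.pdbqt", "error": ""}
        try:
            cm = build_moiety_3d(spec, seed=seed + k)
            (out_dir / row["file"]).write_text(
                export_moiety_pdbqt(cm, merge_nonpolar_h=merge_nonpolar_h))
        except Exception as exc:  # failure is data, not an abort
            row.update(status="failed", file="", error=str(exc))
        manifest.append(row)
    lines = ["id\tsmiles\tstatus\tfile\terror"]
    lines += ["\t".join(str(r[c]) for c in ("id", "smiles", "status", "file", "error"))
              for r in manifest]
    (out_dir / "manifest.tsv").write_text("\n".join(lines) + "\n")
    return manifest


def read_smiles_table(path: str | Path) -> list[MoietySpec]:
    """TSV columns: id, smiles, attachment_index, class."""
    specs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("id\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed SMILES table row: {line!r}")
        ident, smiles = parts[0], parts[1]
        att = int(parts[2]) if len(parts) > 2 and parts[2] else 0
        cls = ReactionClass(parts[3]) if len(parts) > 3 and parts[3] else ReactionClass.OTHER
        specs.append(MoietySpec(ident, smiles, att, cls))
    return specs


def validate_library(directory: str | Path) -> dict:
    """Inventory a directory of moiety PDBQT files.

    Uniqueness is judged on the canonical SMILES recorded at build time
    (REMARK SMILES); files lacking it fall back to a heavy-atom formula
    key.  Returns {n_unique, n_failed, duplicates, failures}.
    """
    directory = Path(directory)
    seen: dict[str, str] = {}
    duplicates = []
    failures = []
    n_total = 0
    for path in sorted(directory.glob("*.pdbqt")):
        n_total += 1
        try:
            text = path.read_text()
            cm = load_moiety_pdbqt(text)
            if cm.canonical_smiles:
                key = cm.canonical_smiles
            else:
                counts: dict[str, int] = {}
                for a in cm.structure.atoms:
                    if a.element != "H":
                        counts[a.element] = counts.get(a.element, 0) + 1
                key = "formula:" + "".join(f"{e}{counts[e]}" for e in sorted(counts))
            if key in seen:
                duplicates.append((path.name, seen[key]))
            else:
                seen[key] = path.name
        except Exception as exc:
            failures.append((path.name, str(exc)))
    return {
        "n_total": n_total,
        "n_unique": len(seen),
        "n_failed": len(failures),
        "duplicates": len(duplicates),
        "duplicate_pairs": duplicates,
        "failures": failures,
    }
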