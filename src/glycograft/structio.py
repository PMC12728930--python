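"""Molecular structure containers and PDB/PDBQT input/output.

The AutoDock PDBQT dialect is a PDB ATOM/HETATM layout with two extra
fields per atom record — the partial charge (columns 67-76) and the
AutoDock atom type (columns 78-79) — plus an optional torsion tree for
ligands (ROOT/ENDROOT, nested BRANCH/ENDBRANCH, TORSDOF).  Both
ROOT-wrapped flexible ligands and rigid receptor files without tree
records are accepted.

Coordinates are stored in Angstrom in a right-handed frame, exactly as
in PDB.  Atom indices are 0-based internally; the serial numbers of the
input are preserved for output.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.spatial import cKDTree


class ParseError(ValueError):
    """Malformed PDB/PDBQT input."""


def _load_params() -> dict:
    ref = importlib.resources.files("glycograft.data").joinpath("vina.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


_PARAMS = _load_params()
AUTODOCK_TYPES: dict[str, dict] = _PARAMS["atom_types"]
COVALENT_RADII: dict[str, float] = _PARAMS["covalent_radii"]
DEFAULT_BOND_TOLERANCE: float = float(_PARAMS["bond_tolerance"])

_WATER_RESNAMES = {"HOH", "WAT", "TIP", "SOL", "TIP3"}
_ION_RESNAMES = {"CA", "NA", "CL", "MG", "ZN", "MN", "K", "FE"}
_AMINO_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN",
}


class Role(str, Enum):
    PROTEIN = "protein"
    CARBOHYDRATE = "carbohydrate"
    MOIETY = "moiety"
    WATER = "water"
    ION = "ion"


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    autodock_type: str
    coords: np.ndarray
    charge: float = 0.0
    residue_id: tuple[str, str, int] = ("", "UNK", 1)  # (chain, name, number)
    role: Role = Role.MOIETY

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if self.autodock_type and self.autodock_type not in AUTODOCK_TYPES:
            raise ValueError(f"unknown AutoDock atom type {self.autodock_type!r}")
        if self.autodock_type:
            expect = AUTODOCK_TYPES[self.autodock_type]["element"]
            if expect != "X" and self.element != expect:
                raise ValueError(
                    f"atom {self.serial}: element {self.element!r} inconsistent "
                    f"with AutoDock type {self.autodock_type!r}"
                )

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class TorsionBranch:
    axis: tuple[int, int]           # (parent-side atom index, branch-side atom index)
    moved_atoms: frozenset[int]
    parent: int | None = None       # index into TorsionTree.branches, None = root
    # Four-atom dihedral reference (a_ref, axis0, axis1, b_ref) defining
    # the torsion value of this branch; filled in by tree construction.
    torsion_atoms: tuple[int, int, int, int] | None = None
    chi_class: str | None = None    # CHI profile name, if this linkage is penalized


@dataclass
class TorsionTree:
    root_atoms: frozenset[int] = frozenset()
    branches: list[TorsionBranch] = field(default_factory=list)

    @property
    def n_rot(self) -> int:
        """Number of rotatable bonds (GA chromosome length)."""
        return len(self.branches)

    def validate(self, n_atoms: int) -> None:
        seen: dict[int, int] = {}
        for bi, br in enumerate(self.branches):
            if not br.moved_atoms:
                raise ValueError(f"branch {bi} moves no atoms")
            if any(i < 0 or i >= n_atoms for i in br.moved_atoms | set(br.axis)):
                raise ValueError(f"branch {bi}: atom index out of range")
            if br.parent is not None:
                parent = self.branches[br.parent]
                if not br.moved_atoms < parent.moved_atoms:
                    raise ValueError(
                        f"branch {bi}: moved atoms not a strict subset of parent branch"
                    )
            for i in br.moved_atoms:
                seen[i] = bi
        covered = self.root_atoms | {i for br in self.branches for i in br.moved_atoms}
        if self.branches and covered != set(range(n_atoms)) and self.root_atoms:
            missing = set(range(n_atoms)) - covered
            if missing:
                raise ValueError(f"atoms {sorted(missing)} in neither root nor any branch")


@dataclass
class MolecularStructure:
    atoms: list[Atom] = field(default_factory=list)
    bonds: set[frozenset[int]] = field(default_factory=set)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, c in zip(self.atoms, xyz):
            a.coords = c.copy()

    def add_bond(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("self-bond")
        if not (0 <= i < len(self.atoms) and 0 <= j < len(self.atoms)):
            raise ValueError("bond index out of range")
        self.bonds.add(frozenset((i, j)))

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if i in b:
                (j,) = b - {i}
                out.append(j)
        return sorted(out)

    def net_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def copy(self) -> "MolecularStructure":
        return MolecularStructure(
            atoms=[a.copy() for a in self.atoms],
            bonds=set(self.bonds),
            provenance=self.provenance,
        )

    def subset(self, indices: Sequence[int]) -> "MolecularStructure":
        """New structure with the selected atoms, remapping bonds."""
        index_map = {old: new for new, old in enumerate(indices)}
        atoms = [self.atoms[i].copy() for i in indices]
        bonds = {
            frozenset((index_map[i], index_map[j]))
            for i, j in (tuple(b) for b in self.bonds)
            if i in index_map and j in index_map
        }
        return MolecularStructure(atoms=atoms, bonds=bonds, provenance=self.provenance)

    def validate(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if len(b) != 2:
                raise ValueError("self-bond in bond set")
            if any(i < 0 or i >= n for i in b):
                raise ValueError("bond index out of range")


def guess_element(name: str, resname: str = "") -> str:
    """Element symbol from a PDB atom name (columns 13-16 conventions)."""
    name = name.strip()
    if resname.strip().upper() in _ION_RESNAMES and name.upper() in (
        "CA", "NA", "CL", "MG", "ZN", "MN", "K", "FE"
    ):
        return name.capitalize()
    for two in ("Cl", "Br"):
        if name[:2].upper() == two.upper():
            return two
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def guess_role(residue_id: tuple[str, str, int], element: str = "") -> Role:
    resname = residue_id[1].strip().upper()
    if resname in _WATER_RESNAMES:
        return Role.WATER
    if resname in _ION_RESNAMES:
        return Role.ION
    if resname in _AMINO_RESNAMES:
        return Role.PROTEIN
    return Role.CARBOHYDRATE


# ---------------------------------------------------------------------------
# PDBQT / PDB parsing


def _parse_atom_record(line: str, lineno: int, pdbqt: bool) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip()
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    charge = 0.0
    adtype = ""
    if pdbqt:
        try:
            charge = float(line[66:76])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"line {lineno}: missing/invalid PDBQT charge field") from exc
        adtype = line[77:79].strip()
        if adtype not in AUTODOCK_TYPES:
            raise ParseError(f"line {lineno}: unknown AutoDock type token {adtype!r}")
        element = AUTODOCK_TYPES[adtype]["element"]
        if element == "X":
            element = guess_element(name, resname)
    else:
        element = line[76:78].strip() or guess_element(name, resname)
    residue_id = (chain, resname, resnum)
    return Atom(
        serial=serial, name=name, element=element, autodock_type=adtype,
        coords=np.array([x, y, z]), charge=charge, residue_id=residue_id,
        role=guess_role(residue_id, element),
    )


def parse_pdbqt(text: str) -> tuple[MolecularStructure, TorsionTree]:
    """Parse a PDBQT document into a structure and its torsion tree.

    Rigid files without ROOT/BRANCH records yield a tree whose root is
    every atom and which has no branches.
    """
    atoms: list[Atom] = []
    serial_to_index: dict[int, int] = {}
    root_atoms: set[int] = set()
    branches: list[TorsionBranch] = []
    # parse-time frames: (branch_index or None for root, serial pair, atom set)
    stack: list[dict] = []
    branch_axes: list[tuple[int, int]] = []   # serial pairs per branch
    branch_parent: list[int | None] = []
    branch_atoms: list[set[int]] = []
    saw_root = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        rec = raw[:6].strip().upper()
        if rec in ("ATOM", "HETATM"):
            atom = _parse_atom_record(raw, lineno, pdbqt=True)
            idx = len(atoms)
            atoms.append(atom)
            serial_to_index[atom.serial] = idx
            if stack:
                for frame in stack:
                    frame["atoms"].add(idx)
                if stack[-1]["branch"] is None:
                    root_atoms.add(idx)
            else:
                root_atoms.add(idx)
        elif raw.startswith("ROOT"):
            saw_root = True
            stack.append({"branch": None, "atoms": set()})
        elif raw.startswith("ENDROOT"):
            if not stack or stack[-1]["branch"] is not None:
                raise ParseError(f"line {lineno}: ENDROOT without matching ROOT")
            stack.pop()
        elif raw.startswith("BRANCH"):
            try:
                s1, s2 = (int(t) for t in raw.split()[1:3])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: malformed BRANCH record") from exc
            parent = None
            for frame in reversed(stack):
                if frame["branch"] is not None:
                    parent = frame["branch"]
                    break
            bi = len(branch_axes)
            branch_axes.append((s1, s2))
            branch_parent.append(parent)
            branch_atoms.append(set())
            stack.append({"branch": bi, "atoms": branch_atoms[bi]})
        elif raw.startswith("ENDBRANCH"):
            if not stack or stack[-1]["branch"] is None:
                raise ParseError(f"line {lineno}: ENDBRANCH without open BRANCH")
            stack.pop()
        # TORSDOF / REMARK / MODEL bookkeeping lines are ignored

    if stack:
        kind = "ROOT" if stack[-1]["branch"] is None else "BRANCH"
        raise ParseError(f"unbalanced {kind}: block opened but never closed")
    if not atoms:
        raise ParseError("no ATOM/HETATM records found")

    for bi, (s1, s2) in enumerate(branch_axes):
        for s in (s1, s2):
            if s not in serial_to_index:
                raise ParseError(f"BRANCH {s1} {s2}: unknown atom serial {s}")
        axis = (serial_to_index[s1], serial_to_index[s2])
        branches.append(
            TorsionBranch(axis=axis, moved_atoms=frozenset(branch_atoms[bi]),
                          parent=branch_parent[bi])
        )

    structure = MolecularStructure(atoms=atoms, provenance="pdbqt")
    if not saw_root and not branches:
        root_atoms = set(range(len(atoms)))
    tree = TorsionTree(root_atoms=frozenset(root_atoms), branches=branches)
    tree.validate(len(atoms))
    _fill_torsion_refs(structure, tree)
    return structure, tree


def _fill_torsion_refs(structure: MolecularStructure, tree: TorsionTree) -> None:
    """Choose deterministic four-atom references for each branch torsion."""
    if not tree.branches:
        return
    if not structure.bonds:
        structure.bonds = perceive_bonds(structure)
    for br in tree.branches:
        if br.torsion_atoms is not None:
            continue
        a0, a1 = br.axis
        structure.add_bond(a0, a1)
        ref_a = [n for n in structure.neighbors(a0) if n != a1 and n not in br.moved_atoms]
        ref_b = [n for n in structure.neighbors(a1) if n != a0 and n in br.moved_atoms]
        if ref_a and ref_b:
            br.torsion_atoms = (ref_a[0], a0, a1, ref_b[0])


def parse_pdb(text: str) -> MolecularStructure:
    """Parse a (single-model) PDB document; CONECT records become bonds."""
    atoms: list[Atom] = []
    serial_to_index: dict[int, int] = {}
    conect: list[tuple[int, int]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        rec = raw[:6].strip().upper()
        if rec in ("ATOM", "HETATM"):
            atom = _parse_atom_record(raw, lineno, pdbqt=False)
            serial_to_index[atom.serial] = len(atoms)
            atoms.append(atom)
        elif rec == "CONECT":
            fields = raw.split()[1:]
            if len(fields) >= 2:
                base = int(fields[0])
                for other in fields[1:]:
                    conect.append((base, int(other)))
        elif rec == "ENDMDL":
            break
    if not atoms:
        raise ParseError("no ATOM/HETATM records found")
    structure = MolecularStructure(atoms=atoms, provenance="pdb")
    for s1, s2 in conect:
        if s1 in serial_to_index and s2 in serial_to_index:
            structure.add_bond(serial_to_index[s1], serial_to_index[s2])
    return structure


def parse_multimodel_pdb(text: str) -> list[MolecularStructure]:
    """Split a MODEL/ENDMDL trajectory into per-frame structures."""
    chunks: list[str] = []
    current: list[str] = []
    in_model = False
    for raw in text.splitlines():
        rec = raw[:6].strip().upper()
        if rec == "MODEL":
            in_model = True
            current = []
        elif rec == "ENDMDL":
            chunks.append("\n".join(current))
            in_model = False
        elif in_model:
            current.append(raw)
    if not chunks:  # plain single-frame file
        return [parse_pdb(text)]
    return [parse_pdb(c) for c in chunks]


# ---------------------------------------------------------------------------
# Writers


def _format_atom_record(atom: Atom, pdbqt: bool) -> str:
    name = atom.name
    # PDB name alignment: element symbols of one letter start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    chain, resname, resnum = atom.residue_id
    rec = "ATOM"
    line = (
        f"{rec:<6}{atom.serial:>5} {name:<4}{resname:>4}{chain or 'A':>2}"
        f"{resnum:>4}    "
        f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}"
    )
    if pdbqt:
        if not atom.autodock_type:
            raise ValueError(f"atom {atom.serial} ({atom.name}) lacks an AutoDock type")
        line += f"    {atom.charge:6.3f} {atom.autodock_type:<2}"
    else:
        line += f"          {atom.element:>2}"
    return line


def write_pdbqt(structure: MolecularStructure, tree: TorsionTree | None = None) -> str:
    """Serialize to PDBQT.  Branch nesting is emitted depth-first so that
    the document reparses to an equal structure and tree."""
    lines = ["REMARK  glycograft PDBQT"]
    if structure.provenance:
        lines.append(f"REMARK  provenance: {structure.provenance}")
    n = len(structure.atoms)
    if tree is None or not tree.branches:
        for atom in structure.atoms:
            lines.append(_format_atom_record(atom, pdbqt=True))
        lines.append("END")
        return "\n".join(lines) + "\n"

    tree.validate(n)
    children: dict[int | None, list[int]] = {}
    for bi, br in enumerate(tree.branches):
        children.setdefault(br.parent, []).append(bi)

    def own_atoms(bi: int) -> list[int]:
        sub = set()
        for ci in children.get(bi, []):
            sub |= tree.branches[ci].moved_atoms
        return sorted(tree.branches[bi].moved_atoms - sub)

    serial = {i: structure.atoms[i].serial for i in range(n)}

    lines.append("ROOT")
    for i in sorted(tree.root_atoms):
        lines.append(_format_atom_record(structure.atoms[i], pdbqt=True))
    lines.append("ENDROOT")

    def emit(bi: int) -> None:
        a0, a1 = tree.branches[bi].axis
        lines.append(f"BRANCH {serial[a0]:>3} {serial[a1]:>3}")
        for i in own_atoms(bi):
            lines.append(_format_atom_record(structure.atoms[i], pdbqt=True))
        for ci in children.get(bi, []):
            emit(ci)
        lines.append(f"ENDBRANCH {serial[a0]:>3} {serial[a1]:>3}")

    for bi in children.get(None, []):
        emit(bi)
    lines.append(f"TORSDOF {len(tree.branches)}")
    return "\n".join(lines) + "\n"


def write_pdb(structure: MolecularStructure, conect: bool = False) -> str:
    lines = []
    for atom in structure.atoms:
        lines.append(_format_atom_record(atom, pdbqt=False))
    if conect:
        idx_to_serial = {i: a.serial for i, a in enumerate(structure.atoms)}
        adj: dict[int, list[int]] = {}
        for b in structure.bonds:
            i, j = tuple(b)
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)
        for i in sorted(adj):
            row = "".join(f"{idx_to_serial[j]:>5}" for j in sorted(adj[i]))
            lines.append(f"CONECT{idx_to_serial[i]:>5}{row}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_multimodel_pdb(frames: Iterable[MolecularStructure]) -> str:
    lines = []
    for k, frame in enumerate(frames, start=1):
        lines.append(f"MODEL {k:>8}")
        lines.append(write_pdb(frame).rstrip("\n").removesuffix("END").rstrip("\n"))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Bond perception


def perceive_bonds(structure: MolecularStructure,
                   tolerance: float = DEFAULT_BOND_TOLERANCE) -> set[frozenset[int]]:
    """Geometric bond perception from covalent radii.

    A pair is bonded iff its distance is at most the covalent-radius sum
    scaled by `tolerance`.  Hydrogen never bonds to hydrogen.  Atom pairs
    closer than 0.5 Angstrom are treated as clashes and raise.
    """
    xyz = structure.coords
    if len(xyz) == 0:
        return set()
    radii = np.array([
        COVALENT_RADII.get(a.element, COVALENT_RADII["X"]) for a in structure.atoms
    ])
    tree = cKDTree(xyz)
    rmax = 2.0 * radii.max() * tolerance
    bonds: set[frozenset[int]] = set()
    for i, j in tree.query_pairs(rmax):
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if d < 0.5:
            raise ValueError(
                f"atoms {structure.atoms[i].serial} and {structure.atoms[j].serial} "
                f"clash at {d:.3f} A"
            )
        if structure.atoms[i].element == "H" and structure.atoms[j].element == "H":
            continue
        if d <= (radii[i] + radii[j]) * tolerance:
            bonds.add(frozenset((i, j)))
    return bonds
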