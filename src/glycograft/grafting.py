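"""Grafting a capped moiety onto a reactive center of a bound carbohydrate.

The alignment uses the temporary ethyl cap R-CH2-CH3 built into every
library moiety: the terminal CH3 carbon is superimposed exactly onto the
ring carbon bearing the reactive hydroxyl, and the CH2->CH3 bond
direction is rotated onto the (exocyclic O)->(ring C) direction, so the
inner CH2 carbon mimics the exocyclic oxygen.  The residual spin about
the linkage axis is fixed by eclipsing the attachment atom with a
deterministic ring reference neighbor (phi = 0 deg start); the pose
genetic algorithm subsequently optimizes this torsion.  Because every
degree of freedom is set from the scaffold and the cap's internal
geometry, the grafted coordinates are independent of the input
orientation of the moiety.

After alignment the cap atoms and the hydroxyl hydrogen are deleted,
the new O-R bond is formed with the CH2-R bond geometry the cap was
built with, and any non-integral net charge is repaired by splitting
the deviation evenly over the two linkage atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _geometry as geom
from .moiety_library import CappedMoiety
from .structio import (MolecularStructure, Role, TorsionBranch, TorsionTree,
                       perceive_bonds)


@dataclass
class ReactiveCenter:
    residue_id: tuple[str, str, int]
    exocyclic_oxygen: int
    ring_carbon: int
    hydroxyl_h: int | None = None
    name: str = ""

    @classmethod
    def resolve(cls, scaffold: MolecularStructure, atom_name: str,
                residue_id: tuple[str, str, int] | None = None) -> "ReactiveCenter":
        """Locate a reactive center by exocyclic-oxygen atom name.

        The bonded ring carbon and (if present) the hydroxyl hydrogen are
        inferred from connectivity.  Amino reactive centers resolve the
        same way with the nitrogen in the oxygen slot.
        """
        if not scaffold.bonds:
            scaffold.bonds = perceive_bonds(scaffold)
        matches = [
            i for i, a in enumerate(scaffold.atoms)
            if a.name == atom_name
            and (residue_id is None or a.residue_id == residue_id)
        ]
        if not matches:
            raise ValueError(f"no atom named {atom_name!r} in scaffold")
        if len(matches) > 1:
            raise ValueError(
                f"atom name {atom_name!r} is ambiguous; give a residue id")
        o_idx = matches[0]
        o_atom = scaffold.atoms[o_idx]
        if o_atom.element not in ("O", "N"):
            raise ValueError(
                f"reactive center {atom_name!r} must be an oxygen or nitrogen, "
                f"got {o_atom.element}")
        carbons = [n for n in scaffold.neighbors(o_idx)
                   if scaffold.atoms[n].element == "C"]
        if not carbons:
            raise ValueError(f"reactive center {atom_name!r} lacks a bonded carbon")
        ring_c = carbons[0]
        hs = [n for n in scaffold.neighbors(o_idx)
              if scaffold.atoms[n].element == "H"]
        return cls(residue_id=o_atom.residue_id, exocyclic_oxygen=o_idx,
                   ring_carbon=ring_c, hydroxyl_h=hs[0] if hs else None,
                   name=atom_name)

    @classmethod
    def from_file(cls, path: str | Path, scaffold: MolecularStructure) -> "ReactiveCenter":
        """One-line reactive-center file: ``chain resname resnum atomname``."""
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"malformed reactive-center line: {line!r}")
            chain, resname, resnum, atomname = parts
            return cls.resolve(scaffold, atomname,
                               residue_id=(chain, resname, int(resnum)))
        raise ValueError("reactive-center file contains no specification line")


@dataclass
class ScaffoldComplex:
    """Rigid receptor plus the receptor-bound carbohydrate scaffold."""
    receptor: MolecularStructure
    scaffold: MolecularStructure
    waters: MolecularStructure | None = None


@dataclass
class GraftDiagnostics:
    cap_superposition_A: float = 0.0     # |CH3 - ring C| before deletion
    alignment_angle_deg: float = 0.0     # angle between O->C and CH2->CH3
    initial_phi_deg: float = 0.0         # eclipsed-start linkage torsion
    clash_flagged: bool = False          # moiety/receptor overlap left to GA


@dataclass
class GlycomimeticComplex:
    receptor: MolecularStructure
    ligand: MolecularStructure           # carbohydrate core + grafted moiety
    linkage: tuple[int, int]             # (exocyclic O index, attachment index)
    pose_tree: TorsionTree
    bridging_waters: MolecularStructure | None = None
    diagnostics: GraftDiagnostics = field(default_factory=GraftDiagnostics)

    @property
    def moiety_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.ligand.atoms) if a.role == Role.MOIETY]

    @property
    def core_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.ligand.atoms) if a.role != Role.MOIETY]

    def copy(self) -> "GlycomimeticComplex":
        return GlycomimeticComplex(
            receptor=self.receptor, ligand=self.ligand.copy(),
            linkage=self.linkage, pose_tree=self.pose_tree,
            bridging_waters=self.bridging_waters, diagnostics=self.diagnostics,
        )


def _ring_reference_atom(scaffold: MolecularStructure, center: ReactiveCenter) -> int:
    """Deterministic scaffold neighbor of the ring carbon used as the
    phi reference: prefer a ring oxygen, else the lowest-index heavy
    neighbor other than the reactive oxygen."""
    nbrs = [n for n in scaffold.neighbors(center.ring_carbon)
            if n != center.exocyclic_oxygen
            and scaffold.atoms[n].element != "H"]
    if not nbrs:
        raise ValueError("ring carbon has no reference neighbor")
    oxy = [n for n in nbrs if scaffold.atoms[n].element == "O"]
    return oxy[0] if oxy else nbrs[0]


def _is_rotatable(structure: MolecularStructure, i: int, j: int,
                  rings: list[set[int]]) -> bool:
    if any(i in r and j in r for r in rings):
        return False
    def heavy_deg(k, other):
        return sum(1 for n in structure.neighbors(k)
                   if n != other and structure.atoms[n].element != "H")
    return heavy_deg(i, j) >= 1 and heavy_deg(j, i) >= 1


def _moiety_torsion_tree(ligand: MolecularStructure, o_idx: int, att: int,
                         moiety_atoms: set[int], ref_atom: int,
                         ring_carbon: int, chi_class: str | None) -> TorsionTree:
    """Torsion tree over the two linkage torsions plus the moiety's
    internal rotatable bonds, rooted at the rigid carbohydrate core."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(len(ligand.atoms)))
    g.add_edges_from(tuple(b) for b in ligand.bonds)
    rings = [set(c) for c in nx.cycle_basis(g)]

    root = frozenset(set(range(len(ligand.atoms))) - moiety_atoms)
    branches: list[TorsionBranch] = []

    # phi: rotation about ring C - exocyclic O moves the whole moiety
    branches.append(TorsionBranch(
        axis=(ring_carbon, o_idx), moved_atoms=frozenset(moiety_atoms),
        parent=None, torsion_atoms=(ref_atom, ring_carbon, o_idx, att),
        chi_class=chi_class,
    ))

    def downstream(a: int, b: int) -> set[int]:
        """Atoms on b's side of bond a-b."""
        h = g.copy()
        h.remove_edge(a, b)
        return set(nx.node_connected_component(h, b))

    # psi: rotation about exocyclic O - attachment atom
    psi_moved = downstream(o_idx, att)
    psi_sub = [n for n in ligand.neighbors(att)
               if n != o_idx and ligand.atoms[n].element != "H"]
    if psi_moved - {att} and psi_sub:
        branches.append(TorsionBranch(
            axis=(o_idx, att), moved_atoms=frozenset(psi_moved - {att}),
            parent=0, torsion_atoms=(ring_carbon, o_idx, att, psi_sub[0]),
        ))

    # internal rotatable bonds, breadth-first from the attachment atom
    visited_bonds: set[frozenset[int]] = set()
    queue = [att]
    order: list[tuple[int, int]] = []
    seen = {att}
    while queue:
        u = queue.pop(0)
        for v in ligand.neighbors(u):
            if v not in moiety_atoms:
                continue
            b = frozenset((u, v))
            if b in visited_bonds:
                continue
            visited_bonds.add(b)
            if v not in seen:
                seen.add(v)
                queue.append(v)
                order.append((u, v))
    for u, v in order:
        if ligand.atoms[v].element == "H" or not _is_rotatable(ligand, u, v, rings):
            continue
        moved = downstream(u, v) - {v}
        moved &= moiety_atoms
        if not moved or all(ligand.atoms[m].element == "H" for m in moved):
            continue
        # parent = smallest enclosing branch (strict superset of moved)
        parent = 0
        best = None
        for bi, br in enumerate(branches):
            if moved < br.moved_atoms and (best is None or len(br.moved_atoms) < best):
                parent, best = bi, len(br.moved_atoms)
        u_ref = [n for n in ligand.neighbors(u) if n != v and n not in moved]
        v_ref = sorted(n for n in moved if frozenset((n, v)) in ligand.bonds)
        if not u_ref or not v_ref:
            continue
        branches.append(TorsionBranch(
            axis=(u, v), moved_atoms=frozenset(moved), parent=parent,
            torsion_atoms=(u_ref[0], u, v, v_ref[0]),
        ))
    tree = TorsionTree(root_atoms=root, branches=branches)
    tree.validate(len(ligand.atoms))
    return tree


def graft(scaffold_complex: ScaffoldComplex, center: ReactiveCenter,
          moiety: CappedMoiety, chi_class: str | None = "auto") -> GlycomimeticComplex:
    """Graft a capped moiety onto the reactive center of the scaffold.

    Returns the grafted complex with a pose torsion tree covering the
    two linkage torsions and the moiety's internal rotatable bonds.
    Receptor coordinates are shared, never copied or modified.
    """
    scaffold = scaffold_complex.scaffold
    if not scaffold.bonds:
        scaffold.bonds = perceive_bonds(scaffold)
    moiety.validate()

    o_idx = center.exocyclic_oxygen
    c_idx = center.ring_carbon
    if scaffold.atoms[o_idx].element not in ("O", "N"):
        raise ValueError("reactive center lacks an exocyclic oxygen/nitrogen")
    o_pos = scaffold.atoms[o_idx].coords
    c_pos = scaffold.atoms[c_idx].coords
    axis_u = geom.unit(c_pos - o_pos)          # O -> ring C direction
    ref_atom = _ring_reference_atom(scaffold, center)
    ref_pos = scaffold.atoms[ref_atom].coords

    m = moiety.structure.copy()
    xyz = m.coords
    ch2, ch3, att = moiety.cap_ch2, moiety.cap_ch3, moiety.attachment_atom

    # (1) translate CH3 onto the ring carbon
    xyz = xyz + (c_pos - xyz[ch3])
    # (2) rotate CH2->CH3 onto O->C (both then point toward the ring carbon)
    R = geom.align_vector_rotation(xyz[ch3] - xyz[ch2], axis_u)
    xyz = (xyz - c_pos) @ R.T + c_pos
    # (3) spin about the linkage axis: eclipse the attachment atom with
    # the ring reference neighbor (phi = 0 start).  If the attachment
    # atom sits on the axis (linear linkage), spin on its first heavy
    # substituent instead.
    spin_atom = att
    if np.linalg.norm(np.cross(axis_u, xyz[att] - c_pos)) < 1e-6:
        subs = [n for n in m.neighbors(att)
                if n != ch2 and m.atoms[n].element != "H"]
        if not subs:
            subs = [n for n in m.neighbors(att) if n != ch2]
        if subs:
            spin_atom = subs[0]
    if np.linalg.norm(np.cross(axis_u, xyz[spin_atom] - c_pos)) > 1e-6:
        allidx = np.arange(len(xyz))
        ext = np.vstack([xyz, ref_pos])
        ext = geom.set_dihedral(ext, allidx, len(xyz), ch3, ch2, spin_atom, 0.0)
        xyz = ext[:-1]

    cap_superpos = float(np.linalg.norm(xyz[ch3] - c_pos))
    align_angle = geom.angle_between_deg(xyz[ch3] - xyz[ch2], c_pos - o_pos)
    # (4) place the R group with the cap's CH2-R bond geometry: CH2 -> O
    xyz = xyz + (o_pos - xyz[ch2])

    m.set_coords(xyz)

    cap_atoms = moiety.cap_atom_indices()
    keep = [i for i in range(len(m.atoms)) if i not in cap_atoms]
    fragment = m.subset(keep)
    frag_att = keep.index(att)
    for a in fragment.atoms:
        a.role = Role.MOIETY

    # assemble ligand: scaffold core (minus hydroxyl H) + moiety fragment
    core_keep = [i for i in range(len(scaffold.atoms)) if i != center.hydroxyl_h]
    ligand = scaffold.subset(core_keep)
    for a in ligand.atoms:
        if a.role == Role.MOIETY:
            a.role = Role.CARBOHYDRATE
    core_map = {old: new for new, old in enumerate(core_keep)}
    offset = len(ligand.atoms)
    next_serial = max(a.serial for a in ligand.atoms) + 1
    for k, a in enumerate(fragment.atoms):
        a = a.copy()
        a.serial = next_serial + k
        ligand.atoms.append(a)
    for b in fragment.bonds:
        i, j = tuple(b)
        ligand.add_bond(i + offset, j + offset)

    new_o = core_map[o_idx]
    new_c = core_map[c_idx]
    new_ref = core_map[ref_atom]
    new_att = frag_att + offset
    ligand.add_bond(new_o, new_att)

    # receptor proximity check: overlaps are flagged for GA repair
    clash = False
    rec_xyz = scaffold_complex.receptor.coords
    if len(rec_xyz):
        rec_heavy = rec_xyz[[i for i, a in enumerate(scaffold_complex.receptor.atoms)
                             if a.element != "H"]]
        moi_heavy = np.array([ligand.atoms[i].coords
                              for i in range(offset, len(ligand.atoms))
                              if ligand.atoms[i].element != "H"]).reshape(-1, 3)
        if len(rec_heavy) and len(moi_heavy):
            from scipy.spatial.distance import cdist
            clash = bool((cdist(moi_heavy, rec_heavy) < 0.8).any())

    if chi_class == "auto":
        # anomeric if the ring carbon carries a second (ring) oxygen
        ring_oxygens = [n for n in scaffold.neighbors(c_idx)
                        if n != o_idx and scaffold.atoms[n].element == "O"]
        chi_class = "anomeric" if ring_oxygens else "generic"

    moiety_atoms = set(range(offset, len(ligand.atoms)))
    tree = _moiety_torsion_tree(ligand, new_o, new_att, moiety_atoms,
                                new_ref, new_c, chi_class)

    phi0 = geom.dihedral(ligand.atoms[new_ref].coords, ligand.atoms[new_c].coords,
                         ligand.atoms[new_o].coords, ligand.atoms[new_att].coords)

    diags = GraftDiagnostics(
        cap_superposition_A=cap_superpos,
        alignment_angle_deg=align_angle,
        initial_phi_deg=phi0,
        clash_flagged=clash,
    )
    return GlycomimeticComplex(
        receptor=scaffold_complex.receptor, ligand=ligand,
        linkage=(new_o, new_att), pose_tree=tree,
        bridging_waters=scaffold_complex.waters, diagnostics=diags,
    )


def redistribute_charge(ligand: MolecularStructure,
                        linkage: tuple[int, int],
                        target_charge: int | None = None) -> MolecularStructure:
    """Repair a non-integral net ligand charge by splitting the deviation
    evenly over the two linkage atoms.  All other charges untouched.

    The target is the declared formal charge when given, else the nearest
    integer.  A deviation beyond 0.5 au from the declared charge raises —
    grafting typically leaves residuals below 0.1 au, so more points at
    mis-assembled inputs."""
    o_idx, att_idx = linkage
    for i in (o_idx, att_idx):
        if i < 0 or i >= len(ligand.atoms):
            raise ValueError(f"linkage atom index {i} out of range")
    total = ligand.net_charge()
    target = round(total) if target_charge is None else int(target_charge)
    deviation = total - target
    if abs(deviation) > 0.5:
        raise ValueError(
            f"net charge deviation {deviation:+.3f} au exceeds 0.5; "
            "charges look mis-assembled")
    if deviation == 0.0:
        return ligand
    out = ligand.copy()
    out.atoms[o_idx].charge -= deviation / 2.0
    out.atoms[att_idx].charge -= deviation / 2.0
    return out


# Fallback empirical per-type charges used when no RESP table is given.
_FALLBACK_CHARGES = {
    "C": 0.05, "A": 0.00, "N": -0.35, "NA": -0.30, "O": -0.40, "OA": -0.40,
    "S": -0.15, "SA": -0.15, "P": 0.40, "F": -0.20, "Cl": -0.10, "Br": -0.10,
    "I": -0.05, "HD": 0.30, "H": 0.05, "HS": 0.10, "M": 1.0,
}


def read_charge_table(path: str | Path) -> dict:
    """Plain-text per-atom charges: ``serial_or_name charge`` per line."""
    table: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split()[:2]
        table[key] = float(value)
    return table


def assign_charges(complex_: GlycomimeticComplex,
                   resp_table: dict | None = None,
                   fallback: str = "empirical") -> GlycomimeticComplex:
    """Charge the grafted ligand: moiety atoms from a RESP table when
    given (keyed by serial or atom name), else from the empirical
    per-type fallback; carbohydrate atoms keep their template charges.
    Ends with an even-split net-charge repair over the linkage atoms."""
    out = complex_.copy()
    moiety_idx = out.moiety_indices
    if resp_table is not None:
        missing, used = [], set()
        for i in moiety_idx:
            a = out.ligand.atoms[i]
            for key in (str(a.serial), a.name):
                if key in resp_table:
                    a.charge = float(resp_table[key])
                    used.add(key)
                    break
            else:
                missing.append(a.name)
        if missing:
            raise ValueError(f"charge table is missing atoms: {missing}")
        extra = set(resp_table) - used
        if extra:
            raise ValueError(f"charge table has rows matching no moiety atom: {sorted(extra)}")
    elif fallback == "empirical":
        for i in moiety_idx:
            a = out.ligand.atoms[i]
            a.charge = _FALLBACK_CHARGES.get(a.autodock_type, 0.0)
    else:
        raise ValueError(f"unknown fallback scheme {fallback!r}")
    out.ligand = redistribute_charge(out.ligand, out.linkage)
    return out
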