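"""Monosaccharide identification and force-field template mapping.

Monosaccharides are identified directly from 3D structure — ring size,
ring-carbon configurations (signed tetrahedral volumes) and exocyclic
composition — never from residue or atom names, which avoids inheriting
carbohydrate nomenclature errors from deposited coordinates.  Identified
residues are matched against force-field residue templates by subgraph
isomorphism on the element-labeled heavy-atom graph, with stereo
descriptors required to agree; canonical atom types and partial charges
are then transferred onto the matched atoms, and everything that did not
match is flagged as a (non-carbohydrate) moiety atom.

The shipped template set (Glc, Gal, Man, Fuc, GlcNAc in alpha/beta)
carries mock-but-internally-consistent types and charges; real
force-field templates are licensing-external and plug in through the
same text format.

Stereo convention: for ring carbon Ck the descriptor is the sign of the
determinant det[v_prev - c, v_next - c, v_exo - c], where prev/next are
the ring neighbors in the O5 -> C1 -> C2 ... traversal (anomeric carbon
first) and v_exo is the highest-priority exocyclic substituent
(O/N > C > H).  The sign is invariant to atom order and rigid motion
and flips under mirror reflection.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .structio import MolecularStructure, Role, perceive_bonds


@dataclass
class TemplateResidue:
    name: str
    sugar: str
    anomeric_config: str                      # alpha | beta
    ring_size: int
    atoms: list[tuple[str, str, str, float]]  # (name, element, type, charge)
    bonds: list[tuple[str, str]]
    stereo_descriptors: dict[str, int]        # ring carbon name -> +-1

    def graph(self, heavy_only: bool = True) -> nx.Graph:
        g = nx.Graph()
        for name, element, ff_type, charge in self.atoms:
            if heavy_only and element == "H":
                continue
            g.add_node(name, element=element, ff_type=ff_type, charge=charge)
        for a, b in self.bonds:
            if a in g and b in g:
                g.add_edge(a, b)
        return g

    def charge_sum(self) -> float:
        return float(sum(c for *_x, c in self.atoms))

    def hydrogens_of(self, heavy_name: str) -> list[tuple[str, str, str, float]]:
        hnames = {a for a, b2 in self.bonds if b2 == heavy_name} | \
                 {b2 for a, b2 in self.bonds if a == heavy_name}
        return [rec for rec in self.atoms if rec[0] in hnames and rec[1] == "H"]

    def validate(self) -> None:
        g = self.graph(heavy_only=False)
        if not nx.is_connected(g):
            raise ValueError(f"template {self.name}: graph not connected")
        ring_o = [n for n, d in g.nodes(data=True)
                  if d["element"] == "O" and n.startswith("O5")]
        if len(ring_o) != 1:
            raise ValueError(f"template {self.name}: needs exactly one ring oxygen")


@dataclass
class ResidueAssignment:
    residue_id: tuple[str, str, int]
    matched_template: str | None
    atom_mapping: dict[int, str] = field(default_factory=dict)
    unmatched_atoms: set[int] = field(default_factory=set)


@dataclass
class SugarCandidate:
    ring_atoms: list[int]          # ordered: ring O, C1, ..., C(n-1)
    atoms: set[int]                # ring + exocyclic expansion
    stereo: dict[str, int]
    ring_size: int
    residue_id: tuple[str, str, int]


# ---------------------------------------------------------------------------
# Template file IO (artifact-defined text format)


def parse_template(text: str) -> TemplateResidue:
    name = sugar = anomeric = ""
    ring_size = 6
    atoms: list[tuple[str, str, str, float]] = []
    bonds: list[tuple[str, str]] = []
    stereo: dict[str, int] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        tag = parts[0].upper()
        if tag == "TEMPLATE":
            name = parts[1]
        elif tag == "SUGAR":
            sugar = parts[1]
        elif tag == "ANOMERIC":
            anomeric = parts[1]
        elif tag == "RING_SIZE":
            ring_size = int(parts[1])
        elif tag == "STEREO":
            stereo[parts[1]] = int(parts[2])
        elif tag == "ATOM":
            atoms.append((parts[1], parts[2], parts[3], float(parts[4])))
        elif tag == "BOND":
            bonds.append((parts[1], parts[2]))
        elif tag == "END":
            break
        else:
            raise ValueError(f"unknown template record {tag!r}")
    t = TemplateResidue(name=name, sugar=sugar, anomeric_config=anomeric,
                        ring_size=ring_size, atoms=atoms, bonds=bonds,
                        stereo_descriptors=stereo)
    t.validate()
    return t


def format_template(t: TemplateResidue) -> str:
    lines = [f"TEMPLATE {t.name}", f"SUGAR {t.sugar}",
             f"ANOMERIC {t.anomeric_config}", f"RING_SIZE {t.ring_size}"]
    for carbon, sign in sorted(t.stereo_descriptors.items()):
        lines.append(f"STEREO {carbon} {sign:+d}")
    for name, element, ff_type, charge in t.atoms:
        lines.append(f"ATOM {name:<4} {element:<2} {ff_type:<3} {charge:8.4f}")
    for a, b in t.bonds:
        lines.append(f"BOND {a} {b}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def load_templates(directory: str | Path | None = None) -> list[TemplateResidue]:
    """Load the shipped template set, or a user directory of *.txt files."""
    if directory is None:
        root = importlib.resources.files("glycograft.data").joinpath("templates")
        files = sorted(
            (f for f in root.iterdir() if f.name.endswith(".txt")),
            key=lambda f: f.name)
        return [parse_template(f.read_text()) for f in files]
    return [parse_template(p.read_text())
            for p in sorted(Path(directory).glob("*.txt"))]


# ---------------------------------------------------------------------------
# Identification


def _stereo_sign(coords: np.ndarray, c: int, prev_i: int, next_i: int,
                 exo_i: int) -> int:
    m = np.stack([coords[prev_i] - coords[c], coords[next_i] - coords[c],
                  coords[exo_i] - coords[c]])
    det = float(np.linalg.det(m))
    return 1 if det > 0 else -1


def identify_monosaccharides(ligand: MolecularStructure) -> list[SugarCandidate]:
    """Find 5/6-membered single-oxygen rings and orient/describe them.

    Each candidate carries the ring atoms ordered anomeric-carbon-first,
    the exocyclic expansion (substituents up to — and including — the
    next heavy atom past each exocyclic oxygen is NOT included; linkage
    oxygens terminate the expansion), and the per-ring-carbon stereo
    signs.  Ligands without sugar rings return an empty list.
    """
    if not ligand.bonds:
        ligand.bonds = perceive_bonds(ligand)
    g = nx.Graph()
    g.add_nodes_from(range(len(ligand.atoms)))
    g.add_edges_from(tuple(b) for b in ligand.bonds)
    coords = ligand.coords
    elem = [a.element for a in ligand.atoms]

    candidates = []
    ring_atom_pool: set[int] = set()
    rings = [r for r in nx.cycle_basis(g) if len(r) in (5, 6)]
    for ring in rings:
        oxy = [i for i in ring if elem[i] == "O"]
        if len(oxy) != 1 or any(elem[i] not in ("C", "O") for i in ring):
            continue
        ring_atom_pool |= set(ring)

    for ring in rings:
        oxy = [i for i in ring if elem[i] == "O"]
        if len(oxy) != 1 or any(elem[i] not in ("C", "O") for i in ring):
            continue
        o_ring = oxy[0]
        # order the cycle starting at the ring oxygen
        cyc = nx.cycle_basis(g.subgraph(ring))[0]
        k0 = cyc.index(o_ring)
        ordered = cyc[k0:] + cyc[:k0]
        nb1, nb2 = ordered[1], ordered[-1]

        def has_exo_hetero(ci: int) -> bool:
            return any(elem[n] in ("O", "N") for n in g.neighbors(ci)
                       if n not in ring)

        # anomeric carbon: the ring-O neighbor bearing an exocyclic O/N
        if has_exo_hetero(nb1) and not has_exo_hetero(nb2):
            pass
        elif has_exo_hetero(nb2) and not has_exo_hetero(nb1):
            ordered = [o_ring] + list(reversed(ordered[1:]))
        elif nb2 < nb1:
            ordered = [o_ring] + list(reversed(ordered[1:]))

        # exocyclic expansion: breadth-first over non-ring atoms.  An
        # oxygen terminates the walk (only its hydrogens are taken), so
        # linkage/glycosidic oxygens are included but whatever lies
        # beyond them — another residue or a grafted moiety — is not.
        atoms = set(ring)
        frontier = [ci for ci in ordered[1:]]
        while frontier:
            u = frontier.pop()
            for n in g.neighbors(u):
                if n in atoms or n in ring_atom_pool:
                    continue
                atoms.add(n)
                if elem[n] == "H":
                    continue
                if elem[n] == "O":
                    for nn in g.neighbors(n):
                        if nn not in atoms and elem[nn] == "H":
                            atoms.add(nn)
                else:
                    frontier.append(n)

        stereo: dict[str, int] = {}
        n_ring = len(ordered)
        for k in range(1, n_ring):
            ci = ordered[k]
            prev_i = ordered[k - 1]
            next_i = ordered[(k + 1) % n_ring]
            exo = [n for n in g.neighbors(ci) if n not in ring]
            if not exo:
                continue
            exo.sort(key=lambda n: (0 if elem[n] in ("O", "N")
                                    else (1 if elem[n] == "C" else 2), n))
            stereo[f"C{k}"] = _stereo_sign(coords, ci, prev_i, next_i, exo[0])

        candidates.append(SugarCandidate(
            ring_atoms=ordered, atoms=atoms, stereo=stereo,
            ring_size=len(ring),
            residue_id=ligand.atoms[o_ring].residue_id))
    return candidates


# ---------------------------------------------------------------------------
# Matching and transfer


def _candidate_graph(ligand: MolecularStructure,
                     candidate: SugarCandidate) -> nx.Graph:
    g = nx.Graph()
    for i in candidate.atoms:
        if ligand.atoms[i].element == "H":
            continue
        g.add_node(i, element=ligand.atoms[i].element)
    for b in ligand.bonds:
        i, j = tuple(b)
        if i in g and j in g:
            g.add_edge(i, j)
    return g


def match_template(candidate: SugarCandidate, templates: list[TemplateResidue],
                   ligand: MolecularStructure) -> ResidueAssignment:
    """Element-labeled isomorphism of the heavy-atom graphs plus stereo
    agreement.  Atom names in the input are ignored entirely.  Multiple
    identically matching templates raise (ambiguity is surfaced)."""
    if not templates:
        raise ValueError("no templates provided")
    cg = _candidate_graph(ligand, candidate)
    hits: list[tuple[TemplateResidue, dict[int, str]]] = []
    for t in templates:
        if t.ring_size != candidate.ring_size:
            continue
        tg = t.graph(heavy_only=True)
        if cg.number_of_nodes() != tg.number_of_nodes():
            continue
        gm = nx.algorithms.isomorphism.GraphMatcher(
            cg, tg,
            node_match=lambda a, b: a["element"] == b["element"])
        for mapping in gm.isomorphisms_iter():
            # ring carbons must land on the template's numbered carbons
            ok = True
            for k, ci in enumerate(candidate.ring_atoms[1:], start=1):
                want = f"C{k}"
                if mapping.get(ci) != want:
                    ok = False
                    break
                sign = candidate.stereo.get(want)
                if sign is not None and want in t.stereo_descriptors \
                        and sign != t.stereo_descriptors[want]:
                    ok = False
                    break
            if ok:
                hits.append((t, dict(mapping)))
                break
    if not hits:
        return ResidueAssignment(residue_id=candidate.residue_id,
                                 matched_template=None,
                                 unmatched_atoms=set(candidate.atoms))
    names = {t.name for t, _m in hits}
    if len(names) > 1:
        raise ValueError(
            f"ambiguous template match for residue {candidate.residue_id}: "
            f"{sorted(names)}")
    t, mapping = hits[0]
    return ResidueAssignment(residue_id=candidate.residue_id,
                             matched_template=t.name, atom_mapping=mapping,
                             unmatched_atoms=set())


def transfer_parameters(assignment: ResidueAssignment,
                        ligand: MolecularStructure,
                        templates: list[TemplateResidue]) -> list[str]:
    """Write template types and charges onto the mapped atoms; flag
    everything unmapped as moiety.  Returns the human-readable log."""
    log: list[str] = []
    if assignment.matched_template is None:
        for i in assignment.unmatched_atoms:
            ligand.atoms[i].role = Role.MOIETY
        log.append(f"residue {assignment.residue_id}: no template match; "
                   f"{len(assignment.unmatched_atoms)} atoms marked noncarbohydrate")
        return log
    t = {tt.name: tt for tt in templates}[assignment.matched_template]
    records = {name: (element, ff, q) for name, element, ff, q in t.atoms}
    log.append(f"residue {assignment.residue_id}: matched template {t.name} "
               f"({t.sugar} {t.anomeric_config})")
    mapped_heavy = set(assignment.atom_mapping)
    for i, tname in sorted(assignment.atom_mapping.items()):
        element, ff, q = records[tname]
        a = ligand.atoms[i]
        a.charge = q
        a.role = Role.CARBOHYDRATE
        a.name = tname
        log.append(f"  atom {a.serial:>4} -> {tname:<4} type {ff:<3} charge {q:+.4f}")
        # hydrogens riding on this heavy atom inherit template H parameters
        h_recs = t.hydrogens_of(tname)
        h_idx = [n for n in ligand.neighbors(i)
                 if ligand.atoms[n].element == "H"]
        for hi, hrec in zip(sorted(h_idx), h_recs):
            ha = ligand.atoms[hi]
            ha.charge = hrec[3]
            ha.role = Role.CARBOHYDRATE
            ha.name = hrec[0]
            log.append(f"  atom {ha.serial:>4} -> {hrec[0]:<4} type {hrec[2]:<3} "
                       f"charge {hrec[3]:+.4f}")
            mapped_heavy.add(hi)
    for i, a in enumerate(ligand.atoms):
        if i not in mapped_heavy and a.role != Role.CARBOHYDRATE:
            a.role = Role.MOIETY
            log.append(f"  atom {a.serial:>4} ({a.name}) marked noncarbohydrate")
    return log


def map_ligand(ligand: MolecularStructure,
               templates: list[TemplateResidue] | None = None,
               ) -> tuple[list[ResidueAssignment], list[str]]:
    """identify -> match -> transfer for every sugar ring in the ligand."""
    templates = templates if templates is not None else load_templates()
    log: list[str] = []
    assignments = []
    mapped: set[int] = set()
    for cand in identify_monosaccharides(ligand):
        asg = match_template(cand, templates, ligand)
        log.extend(transfer_parameters(asg, ligand, templates))
        assignments.append(asg)
        mapped |= set(asg.atom_mapping)
    if not assignments:
        log.append("no monosaccharide rings identified")
    return assignments, log
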