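"""Deterministic toy inputs for every pipeline stage.

Idealized chair pyranoses (parametric in sugar identity and anomeric
configuration), synthetic concave receptor pockets, capped test
moieties, pseudo-trajectories with Gaussian jitter, and an engineered
"exo-anomeric contrast" system whose pure-Vina optimum is the trans
rotamer of the aglycone phi angle.  All geometry is generated by code
from fixed rules, never read from checked-in binaries, so every test
input is auditable.  These are idealized geometries, not force-field
minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _geometry as geom
from .structio import Atom, MolecularStructure, Role, perceive_bonds

_TETRA_HALF = 54.75  # half the tetrahedral angle, degrees

# axial positions per sugar (ring carbon number), C6 flavor, mirror -> L-sugar
SUGARS = {
    "GLC":    {"axial": frozenset(), "c6": "CH2OH", "mirror": False, "nac": False},
    "GAL":    {"axial": frozenset({4}), "c6": "CH2OH", "mirror": False, "nac": False},
    "MAN":    {"axial": frozenset({2}), "c6": "CH2OH", "mirror": False, "nac": False},
    "FUC":    {"axial": frozenset({4}), "c6": "CH3", "mirror": True, "nac": False},
    "GLCNAC": {"axial": frozenset(), "c6": "CH2OH", "mirror": False, "nac": True},
}

# mock-but-consistent partial charges (au) by structural role
_CHARGES = {
    "ring_O": -0.47, "anomeric_C": 0.39, "ring_C": 0.17, "exo_O": -0.60,
    "HO": 0.42, "HC": 0.03, "C6": 0.17, "N": -0.50, "HN": 0.35,
    "C_carbonyl": 0.55, "O_carbonyl": -0.55, "C_methyl": 0.10,
}


def _tripod(bond_dir: np.ndarray, ref: np.ndarray) -> list[np.ndarray]:
    """Three unit substituent directions for an atom reached along
    `bond_dir` (tetrahedral: 109.47 deg from the incoming bond), splayed
    120 deg apart; the first lies in the plane of `ref`."""
    b = geom.unit(bond_dir)
    p1 = ref - np.dot(ref, b) * b
    if np.linalg.norm(p1) < 1e-8:
        p1 = np.array([1.0, 0.0, 0.0]) - b[0] * b
    p1 = geom.unit(p1)
    p2 = np.cross(b, p1)
    out = []
    for phi in (0.0, 120.0, 240.0):
        t = np.radians(phi)
        out.append(geom.unit(b / 3.0 + np.sqrt(8.0) / 3.0 *
                             (np.cos(t) * p1 + np.sin(t) * p2)))
    return out


@dataclass
class _Builder:
    atoms: list = None
    bonds: list = None

    def __post_init__(self):
        self.atoms = []
        self.bonds = []

    def add(self, name, element, adtype, xyz, charge, resname="PYR"):
        self.atoms.append(Atom(
            serial=len(self.atoms) + 1, name=name, element=element,
            autodock_type=adtype, coords=np.asarray(xyz, dtype=float),
            charge=charge, residue_id=("A", resname, 1),
            role=Role.CARBOHYDRATE))
        return len(self.atoms) - 1

    def bond(self, i, j):
        self.bonds.append((i, j))

    def build(self, provenance: str) -> MolecularStructure:
        s = MolecularStructure(atoms=self.atoms, provenance=provenance)
        for i, j in self.bonds:
            s.add_bond(i, j)
        return s


def make_toy_pyranose(gal_like: bool = False, anomeric: str = "beta",
                      sugar: str | None = None,
                      ) -> tuple[MolecularStructure, dict]:
    """Idealized 4C1-chair pyranose with a full hydroxyl set.

    Returns (structure, reactive_centers) where reactive_centers maps
    center names (O1..O4, O6 as available) to (oxygen index, ring carbon
    index, hydroxyl hydrogen index).  `gal_like` flips the C4 chirality
    (galactose-like); `sugar` selects a full sugar definition (GLC, GAL,
    MAN, FUC, GLCNAC) and overrides gal_like.
    """
    if sugar is None:
        sugar = "GAL" if gal_like else "GLC"
    sugar = sugar.upper()
    if sugar not in SUGARS:
        raise ValueError(f"unknown sugar {sugar!r}; options: {sorted(SUGARS)}")
    if anomeric not in ("alpha", "beta"):
        raise ValueError("anomeric must be 'alpha' or 'beta'")
    spec = SUGARS[sugar]

    # chair ring: O5 then C1..C5 around a puckered hexagon
    z0, bond = 0.25, 1.53
    radius = np.sqrt(bond * bond - 4 * z0 * z0) / 1.0
    ring_names = ["O5", "C1", "C2", "C3", "C4", "C5"]
    ring_xyz = []
    for k in range(6):
        th = np.radians(60.0 * k)
        ring_xyz.append(np.array([radius * np.cos(th), radius * np.sin(th),
                                  z0 * (-1.0) ** k]))

    b = _Builder()
    ring_idx = {}
    for name, xyz in zip(ring_names, ring_xyz):
        if name == "O5":
            i = b.add(name, "O", "OA", xyz, _CHARGES["ring_O"])
        else:
            key = "anomeric_C" if name == "C1" else "ring_C"
            i = b.add(name, "C", "C", xyz, _CHARGES[key])
        ring_idx[name] = i
    for k in range(6):
        b.bond(ring_idx[ring_names[k]], ring_idx[ring_names[(k + 1) % 6]])

    centers: dict[str, tuple[int, int, int | None]] = {}

    def exo_dirs(k: int) -> tuple[np.ndarray, np.ndarray]:
        """(axial, equatorial) unit directions at ring position k."""
        c = ring_xyz[k]
        u = geom.unit(ring_xyz[(k - 1) % 6] - c)
        v = geom.unit(ring_xyz[(k + 1) % 6] - c)
        s = -geom.unit(u + v)
        w = geom.unit(np.cross(u, v))
        a = np.radians(_TETRA_HALF)
        d1 = geom.unit(np.cos(a) * s + np.sin(a) * w)
        d2 = geom.unit(np.cos(a) * s - np.sin(a) * w)
        return (d1, d2) if abs(d1[2]) >= abs(d2[2]) else (d2, d1)

    def add_hydroxyl(cname: str, oname: str, direction: np.ndarray):
        c = ring_idx[cname]
        o_xyz = b.atoms[c].coords + 1.43 * direction
        o = b.add(oname, "O", "OA", o_xyz, _CHARGES["exo_O"])
        b.bond(c, o)
        u = geom.unit(direction)
        p = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(p) < 1e-6:
            p = np.cross(u, [1.0, 0.0, 0.0])
        p = geom.unit(p)
        h_dir = geom.unit(np.cos(np.radians(70.5)) * u + np.sin(np.radians(70.5)) * p)
        h = b.add("HO" + oname[1:], "H", "HD", o_xyz + 0.96 * h_dir, _CHARGES["HO"])
        b.bond(o, h)
        return o, h

    def add_h(cname: str, direction: np.ndarray, hname: str):
        c = ring_idx[cname]
        h = b.add(hname, "H", "H", b.atoms[c].coords + 1.09 * direction,
                  _CHARGES["HC"])
        b.bond(c, h)
        return h

    # C1 (anomeric): O1 axial for alpha, equatorial for beta
    for k, cname in ((1, "C1"), (2, "C2"), (3, "C3"), (4, "C4")):
        ax, eq = exo_dirs(k)
        if cname == "C1":
            o_dir, h_dir = (ax, eq) if anomeric == "alpha" else (eq, ax)
            o, h = add_hydroxyl("C1", "O1", o_dir)
            add_h("C1", h_dir, "H1")
            centers["O1"] = (o, ring_idx["C1"], h)
        elif cname == "C2" and spec["nac"]:
            _add_n_acetyl(b, ring_idx, eq, ax)
        else:
            num = int(cname[1])
            o_dir, h_dir = (ax, eq) if num in spec["axial"] else (eq, ax)
            o, h = add_hydroxyl(cname, f"O{num}", o_dir)
            add_h(cname, h_dir, f"H{num}")
            centers[f"O{num}"] = (o, ring_idx[cname], h)

    # C5: H plus the C6 arm (hydroxymethyl or methyl)
    ax5, eq5 = exo_dirs(5)
    c6_dir, h5_dir = eq5, ax5
    add_h("C5", h5_dir, "H5")
    c5 = ring_idx["C5"]
    c6_xyz = b.atoms[c5].coords + 1.53 * c6_dir
    c6 = b.add("C6", "C", "C", c6_xyz, _CHARGES["C6"])
    b.bond(c5, c6)
    tri = _tripod(c6_xyz - b.atoms[c5].coords, np.array([0.0, 0.0, 1.0]))
    if spec["c6"] == "CH2OH":
        o6_xyz = c6_xyz + 1.43 * tri[0]
        o6 = b.add("O6", "O", "OA", o6_xyz, _CHARGES["exo_O"])
        b.bond(c6, o6)
        h_dir = geom.unit(tri[0] + 0.8 * tri[1])
        ho6 = b.add("HO6", "H", "HD", o6_xyz + 0.96 * h_dir, _CHARGES["HO"])
        b.bond(o6, ho6)
        for m, t in enumerate(tri[1:], start=1):
            b.bond(c6, b.add(f"H6{m}", "H", "H", c6_xyz + 1.09 * t, _CHARGES["HC"]))
        centers["O6"] = (o6, c6, ho6)
    else:  # 6-deoxy: methyl
        for m, t in enumerate(tri, start=1):
            b.bond(c6, b.add(f"H6{m}", "H", "H", c6_xyz + 1.09 * t, _CHARGES["HC"]))

    structure = b.build(f"toy pyranose {sugar} {anomeric}")
    if spec["mirror"]:
        xyz = structure.coords
        xyz[:, 2] *= -1.0
        structure.set_coords(xyz)

    # exact integral net charge: absorb the remainder on C1
    total = structure.net_charge()
    structure.atoms[ring_idx["C1"]].charge -= total - round(total)
    structure.bonds = set(structure.bonds)
    return structure, centers


def _add_n_acetyl(b: _Builder, ring_idx: dict, eq: np.ndarray, ax: np.ndarray):
    """2-acetamido substitution at C2 (GlcNAc-like)."""
    c2 = ring_idx["C2"]
    n_xyz = b.atoms[c2].coords + 1.45 * eq
    n = b.add("N2", "N", "N", n_xyz, _CHARGES["N"])
    b.bond(c2, n)
    b.bond(c2, b.add("H2", "H", "H", b.atoms[c2].coords + 1.09 * ax, _CHARGES["HC"]))
    tri = _tripod(n_xyz - b.atoms[c2].coords, np.array([0.0, 0.0, 1.0]))
    hn = b.add("HN2", "H", "HD", n_xyz + 1.01 * tri[1], _CHARGES["HN"])
    b.bond(n, hn)
    c7_xyz = n_xyz + 1.35 * tri[0]
    c7 = b.add("C7", "C", "C", c7_xyz, _CHARGES["C_carbonyl"])
    b.bond(n, c7)
    tri7 = _tripod(c7_xyz - n_xyz, np.array([0.0, 0.0, 1.0]))
    o7 = b.add("O7", "O", "OA", c7_xyz + 1.23 * tri7[0], _CHARGES["O_carbonyl"])
    b.bond(c7, o7)
    c8_xyz = c7_xyz + 1.50 * tri7[1]
    c8 = b.add("C8", "C", "C", c8_xyz, _CHARGES["C_methyl"])
    b.bond(c7, c8)
    for m, t in enumerate(_tripod(c8_xyz - c7_xyz, np.array([0.0, 0.0, 1.0])),
                          start=1):
        b.bond(c8, b.add(f"H8{m}", "H", "H", c8_xyz + 1.09 * t, _CHARGES["HC"]))


def make_toy_pocket(seed: int = 0, n_atoms: int = 24) -> MolecularStructure:
    """Concave shell of typed atoms forming a bowl below the origin.

    The shell mixes hydrophobic carbons (C/A, including an adjacent
    patch), acceptor oxygens (OA) and donor nitrogens (N, each given a
    polar hydrogen pointing into the pocket).  Deterministic per seed.
    """
    if n_atoms < 10:
        raise ValueError("pocket needs at least 10 shell atoms")
    rng = np.random.default_rng(seed)
    R = 6.0
    golden = np.pi * (3.0 - np.sqrt(5.0))
    pattern = ["C", "A", "C", "OA", "C", "N", "A", "C", "OA", "C"]
    atoms: list[Atom] = []
    serial = 1
    for i in range(n_atoms):
        # spherical cap z in [-R, -0.35 R]
        z = -R + (0.65 * R) * (i + 0.5) / n_atoms
        r_xy = np.sqrt(max(R * R - z * z, 0.0))
        th = golden * i
        xyz = np.array([r_xy * np.cos(th), r_xy * np.sin(th), z])
        xyz = xyz + rng.normal(0.0, 0.25, size=3)
        t = pattern[i % len(pattern)]
        elem = {"C": "C", "A": "C", "OA": "O", "N": "N"}[t]
        atoms.append(Atom(serial=serial, name=f"{elem}{serial}", element=elem,
                          autodock_type=t, coords=xyz, charge=0.0,
                          residue_id=("P", "PKT", i + 1), role=Role.PROTEIN))
        serial += 1
        if t == "N":
            h_xyz = xyz + 1.0 * geom.unit(-xyz)
            atoms.append(Atom(serial=serial, name=f"H{serial}", element="H",
                              autodock_type="HD", coords=h_xyz, charge=0.3,
                              residue_id=("P", "PKT", i + 1), role=Role.PROTEIN))
            serial += 1
    s = MolecularStructure(atoms=atoms, provenance=f"toy pocket seed {seed}")
    s.bonds = perceive_bonds(s)
    return s


def make_pseudo_trajectory(complex_, n_frames: int, sigma: float,
                           seed: int = 0) -> list:
    """Pseudo-MD frames: i.i.d. Gaussian jitter of the ligand atoms with
    standard deviation sigma per coordinate, rigid receptor.  Frame 0 is
    the unjittered input."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    frames = []
    base = complex_.ligand.coords
    for k in range(n_frames):
        frame = complex_.copy()
        if k > 0 and sigma > 0:
            frame.ligand.set_coords(base + rng.normal(0.0, sigma, size=base.shape))
        frames.append(frame)
    return frames


def make_phenyl_moiety(seed: int = 0):
    """Capped phenyl fragment (benzene attached at a ring carbon)."""
    from .moiety_library import MoietySpec, build_moiety_3d
    return build_moiety_3d(MoietySpec("phenyl", "c1ccccc1", 0), seed=seed)


def make_chi_contrast_system(seed: int = 0):
    """Beta-galactoside with an aromatic aglycone in a pocket engineered
    so that the pure-Vina optimum of the anomeric phi angle is trans.

    A hydrophobic carbon patch is placed against the phenyl ring's
    position in the phi = 180 deg rotamer, rewarding trans when the CHI
    terms are off; with the CHI terms on, the exo-anomeric penalty
    (2.7 kcal/mol at trans) dominates and the gauche wells win.
    Returns the grafted complex, ready for GA search.
    """
    from .grafting import ReactiveCenter, ScaffoldComplex, graft
    from .scoring import apply_pose

    scaffold, centers = make_toy_pyranose(sugar="GAL", anomeric="beta")
    o_idx, c_idx, h_idx = centers["O1"]
    center = ReactiveCenter(residue_id=scaffold.atoms[o_idx].residue_id,
                            exocyclic_oxygen=o_idx, ring_carbon=c_idx,
                            hydroxyl_h=h_idx, name="O1")
    moiety = make_phenyl_moiety(seed=seed)

    empty_receptor = MolecularStructure(provenance="placeholder")
    cx = graft(ScaffoldComplex(receptor=empty_receptor, scaffold=scaffold),
               center, moiety)

    # phenyl position in the trans rotamer (psi at its grafted value)
    pose0 = np.array([180.0] + [0.0] * (cx.pose_tree.n_rot - 1))
    from .scoring import measure_pose
    cur = measure_pose(cx)
    pose0[1:] = cur[1:]
    xyz = apply_pose(cx, pose0)
    phen = [i for i in cx.moiety_indices if cx.ligand.atoms[i].element == "C"]
    ring_xyz = xyz[phen]
    centroid = ring_xyz.mean(axis=0)
    # ring normal via SVD; offset away from the sugar
    _, _, vt = np.linalg.svd(ring_xyz - centroid)
    normal = vt[2]
    sugar_centroid = np.array([a.coords for a in scaffold.atoms]).mean(axis=0)
    if np.dot(normal, centroid - sugar_centroid) < 0:
        normal = -normal

    # Probe clusters are anchored on the *para* carbon of the phenyl,
    # which lies on the O1-Cipso axis: its position depends on phi only,
    # so the reward cannot be recovered by spinning the ring (psi).  A
    # dense cone of hydrophobic carbons caps the para position of the
    # trans rotamer; a sparser cone rewards the gauche(-60 deg) rotamer.
    # Pure-Vina scoring therefore prefers trans; with the exo-anomeric
    # CHI penalty on (2.7 kcal/mol at trans), the gauche well wins.
    atoms = []
    serial = 1
    o1_pos = cx.ligand.coords[cx.linkage[0]]

    def para_cone(pose_phi, offsets, n_lateral):
        nonlocal serial
        p = pose0.copy()
        p[0] = pose_phi
        xyz_p = apply_pose(cx, p)
        ring_p = xyz_p[phen]
        centroid_p = ring_p.mean(axis=0)
        # para carbon: ring atom farthest from the linkage oxygen
        para = ring_p[int(np.argmax(np.linalg.norm(ring_p - o1_pos, axis=1)))]
        axis = geom.unit(para - centroid_p)
        perp1 = geom.unit(np.cross(axis, [0.0, 0.0, 1.0])
                          if abs(axis[2]) < 0.9 else np.cross(axis, [1.0, 0.0, 0.0]))
        perp2 = np.cross(axis, perp1)
        dirs = [axis]
        for k in range(n_lateral):
            t = 2 * np.pi * k / n_lateral
            dirs.append(geom.unit(np.cos(np.radians(50)) * axis
                                  + np.sin(np.radians(50))
                                  * (np.cos(t) * perp1 + np.sin(t) * perp2)))
        for off in offsets:
            for d in dirs:
                atoms.append(Atom(serial=serial, name=f"C{serial}", element="C",
                                  autodock_type="C", coords=para + off * d,
                                  charge=0.0, residue_id=("P", "PKT", serial),
                                  role=Role.PROTEIN))
                serial += 1

    para_cone(180.0, offsets=(3.9, 4.4, 5.0), n_lateral=8)
    para_cone(-60.0, offsets=(4.0,), n_lateral=2)

    # steric blockers at the para-carbon positions of mid-phi rotamers:
    # the para atom rides a ~5 A circle around the linkage axis, so a
    # blocker there excludes a ~+-25 deg band of phi regardless of psi
    for phi_block in (95.0, 110.0):
        p = pose0.copy()
        p[0] = phi_block
        ring_b = apply_pose(cx, p)[phen]
        para_b = ring_b[int(np.argmax(np.linalg.norm(ring_b - o1_pos, axis=1)))]
        atoms.append(Atom(serial=serial, name=f"C{serial}", element="C",
                          autodock_type="C", coords=para_b,
                          charge=0.0, residue_id=("P", "PKT", serial),
                          role=Role.PROTEIN))
        serial += 1

    receptor = MolecularStructure(atoms=atoms,
                                  provenance="engineered hydrophobic patch")
    cx.receptor = receptor
    return cx
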