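"""Carbohydrate-aware Vina-style scoring.

The pairwise part is the published AutoDock Vina functional form — two
attractive gaussians, a quadratic steric repulsion, and piecewise-linear
hydrophobic and hydrogen-bond ramps — evaluated on the surface distance
d = r - R_i - R_j with the AutoDock vdW radius table, over moiety <->
receptor and moiety <-> carbohydrate-core pairs within a cutoff, plus
intra-moiety pairs.  Covalently connected pairs (within the ligand,
including across the new linkage bond) are excluded when separated by
three bonds or fewer, the usual 1-2/1-3/1-4 exclusion.

On top of that sit CHI torsional penalties for the glycosidic/aglycone
linkage: the anomeric phi angle is biased toward gauche rotamers
(exo-anomeric effect) by a periodic cosine-series profile shipped in a
data file.  Setting chi_weight to zero recovers the pure Vina-style sum,
which is the with/without contrast used to validate the correction.

Hydrogens carry no pairwise terms (HD is used only for donor perception
and hydrogen-bond geometry).  The Vina N_rot-dependent normalization of
the docking score is deliberately omitted; torsional entropy is handled
explicitly by the per-rotatable-bond penalty at analysis time, which
avoids double counting.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.spatial.distance import cdist

from . import _geometry as geom
from .grafting import GlycomimeticComplex
from .structio import AUTODOCK_TYPES, MolecularStructure, _PARAMS

TERM_NAMES = ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond")


def _load_chi_profiles() -> dict:
    ref = importlib.resources.files("glycograft.data").joinpath("chi_profiles.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


DEFAULT_CHI_PROFILES = _load_chi_profiles()
DEFAULT_WEIGHTS = tuple(_PARAMS["term_weights"][t] for t in TERM_NAMES)


@dataclass
class ScoringParameters:
    term_weights: tuple[float, float, float, float, float] = DEFAULT_WEIGHTS
    cutoff: float = float(_PARAMS["cutoff"])
    chi_weight: float = 1.0
    chi_profiles: dict = field(default_factory=lambda: dict(DEFAULT_CHI_PROFILES))
    entropy_per_bond: float = 0.6        # kcal/mol per restricted rotatable bond
    include_intra: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.entropy_per_bond < 0:
            raise ValueError("entropy_per_bond must be non-negative")


@dataclass
class EnergyRecord:
    total: float
    per_term: dict[str, float]
    chi_penalty: float = 0.0
    entropy_penalty: float = 0.0
    frame_index: int = 0


def vina_terms(surface_distance: float, types: tuple[str, str],
               donor_flags: tuple[bool, bool] | None = None,
               acceptor_flags: tuple[bool, bool] | None = None,
               center_distance: float | None = None,
               cutoff: float | None = None,
               ) -> tuple[float, float, float, float, float]:
    """The five Vina pairwise terms at a surface distance d (Angstrom).

    gauss1 = exp(-(d/0.5)^2); gauss2 = exp(-((d-3)/2)^2);
    repulsion = d^2 for d < 0; hydrophobic ramps 1 -> 0 over d in
    [0.5, 1.5] when both atoms are hydrophobic; hbond ramps 1 -> 0 over
    d in [-0.7, 0] for donor/acceptor pairs.  Donor/acceptor gating
    defaults to the static type table but can be overridden with
    structure-derived flags.
    """
    d = float(surface_distance)
    if not np.isfinite(d):
        raise ValueError("non-finite surface distance")
    props = []
    for t in types:
        if t not in AUTODOCK_TYPES:
            raise ValueError(f"unknown atom type {t!r}")
        props.append(AUTODOCK_TYPES[t])
    if props[0]["element"] == "H" or props[1]["element"] == "H":
        return (0.0, 0.0, 0.0, 0.0, 0.0)
    if cutoff is not None:
        r = center_distance if center_distance is not None else d
        if r >= cutoff:
            return (0.0, 0.0, 0.0, 0.0, 0.0)
    g1 = float(np.exp(-((d / 0.5) ** 2)))
    g2 = float(np.exp(-(((d - 3.0) / 2.0) ** 2)))
    rep = d * d if d < 0 else 0.0
    dn = donor_flags or (props[0]["donor"], props[1]["donor"])
    ac = acceptor_flags or (props[0]["acceptor"], props[1]["acceptor"])
    if props[0]["hydrophobic"] and props[1]["hydrophobic"]:
        hyd = 1.0 if d <= 0.5 else (0.0 if d >= 1.5 else 1.5 - d)
    else:
        hyd = 0.0
    if (dn[0] and ac[1]) or (ac[0] and dn[1]):
        hb = 1.0 if d <= -0.7 else (0.0 if d >= 0.0 else d / -0.7)
    else:
        hb = 0.0
    return (g1, g2, rep, hyd, hb)


def chi_energy(phi_deg: float, linkage_class: str,
               profiles: dict | None = None) -> float:
    """CHI torsional penalty (kcal/mol, >= 0) for a linkage torsion.

    Profiles are truncated cosine series, periodic in 360 degrees; the
    anomeric profile has its minima in the gauche wells.
    """
    profiles = profiles if profiles is not None else DEFAULT_CHI_PROFILES
    if linkage_class not in profiles:
        raise KeyError(f"no CHI profile for linkage class {linkage_class!r}")
    prof = profiles[linkage_class]
    phi = np.radians(float(phi_deg))
    coeffs = prof["coefficients"]
    e = sum(a_k * np.cos(k * phi) for k, a_k in enumerate(coeffs))
    return float(prof.get("scale", 1.0) * e)


def entropy_penalty(n_rot: int, per_bond: float = 0.6) -> float:
    """Rotamer entropy cost: n_rot x per-bond penalty (kcal/mol),
    an unfavorable addition to interaction energies."""
    if n_rot < 0:
        raise ValueError("n_rot must be non-negative")
    return float(n_rot) * float(per_bond)


# ---------------------------------------------------------------------------
# Pose application


def apply_pose(complex_: GlycomimeticComplex, pose: np.ndarray) -> np.ndarray:
    """Ligand coordinates with the torsion vector applied root-to-leaf."""
    tree = complex_.pose_tree
    pose = np.asarray(pose, dtype=float)
    if pose.shape != (tree.n_rot,):
        raise ValueError(
            f"pose length {pose.shape} does not match rotatable-bond count "
            f"{tree.n_rot}")
    coords = complex_.ligand.coords
    for value, br in zip(pose, tree.branches):
        if br.torsion_atoms is None:
            raise ValueError("branch lacks torsion reference atoms")
        moved = np.fromiter(br.moved_atoms, dtype=int)
        p0, p1, p2, p3 = br.torsion_atoms
        coords = geom.set_dihedral(coords, moved, p0, p1, p2, p3, float(value))
    return coords


def measure_pose(complex_: GlycomimeticComplex,
                 coords: np.ndarray | None = None) -> np.ndarray:
    """Current torsion vector of the complex (degrees)."""
    coords = complex_.ligand.coords if coords is None else coords
    out = []
    for br in complex_.pose_tree.branches:
        p0, p1, p2, p3 = br.torsion_atoms
        out.append(geom.dihedral(coords[p0], coords[p1], coords[p2], coords[p3]))
    return np.array(out)


# ---------------------------------------------------------------------------
# Complex scoring


def _atom_flags(structure: MolecularStructure):
    """Per-atom (radius, hydrophobic, donor, acceptor, is_h) arrays.

    Two flags are context-dependent, following the published Vina atom
    typing: an N/O heavy atom is a donor when it carries a bonded
    hydrogen, and a carbon bonded to any heteroatom (N/O/S/P) loses its
    hydrophobic flag (polar carbon).
    """
    n = len(structure.atoms)
    radius = np.zeros(n)
    hyd = np.zeros(n, dtype=bool)
    don = np.zeros(n, dtype=bool)
    acc = np.zeros(n, dtype=bool)
    ish = np.zeros(n, dtype=bool)
    has_h = np.zeros(n, dtype=bool)
    has_hetero = np.zeros(n, dtype=bool)
    for b in structure.bonds:
        i, j = tuple(b)
        if structure.atoms[i].element == "H":
            has_h[j] = True
        if structure.atoms[j].element == "H":
            has_h[i] = True
        if structure.atoms[i].element in ("N", "O", "S", "P"):
            has_hetero[j] = True
        if structure.atoms[j].element in ("N", "O", "S", "P"):
            has_hetero[i] = True
    for i, a in enumerate(structure.atoms):
        t = a.autodock_type or "C"
        props = AUTODOCK_TYPES[t]
        radius[i] = props["radius"]
        hyd[i] = props["hydrophobic"] and not (a.element == "C" and has_hetero[i])
        acc[i] = props["acceptor"]
        don[i] = props["donor"] or (props["acceptor"] and a.element in ("N", "O")
                                    and has_h[i])
        ish[i] = props["element"] == "H" or a.element == "H"
    return radius, hyd, don, acc, ish


def _bond_path_gt3(structure: MolecularStructure, rows: list[int],
                   cols: list[int]) -> np.ndarray:
    """Boolean matrix over rows x cols: True where the shortest bond path
    is longer than three bonds — the 1-2/1-3/1-4 exclusion applied to
    covalently connected pairs (intra-moiety, and moiety <-> core across
    the new linkage)."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(len(structure.atoms)))
    g.add_edges_from(tuple(b) for b in structure.bonds)
    col_pos = {j: b for b, j in enumerate(cols)}
    far = np.ones((len(rows), len(cols)), dtype=bool)
    for a, i in enumerate(rows):
        lengths = nx.single_source_shortest_path_length(g, i, cutoff=3)
        for j, _l in lengths.items():
            if j in col_pos:
                far[a, col_pos[j]] = False
    return far


class ScoringSession:
    """Precomputed pair tables for repeated scoring of one complex
    (the GA inner loop).  Receptor and core are rigid; only the moiety
    moves with the pose."""

    def __init__(self, complex_: GlycomimeticComplex, params: ScoringParameters):
        self.complex = complex_
        self.params = params
        lig = complex_.ligand
        self.moiety_idx = np.array(complex_.moiety_indices, dtype=int)
        core_idx = np.array(complex_.core_indices, dtype=int)

        l_rad, l_hyd, l_don, l_acc, l_ish = _atom_flags(lig)
        mi = self.moiety_idx[~l_ish[self.moiety_idx]]
        self.mi = mi
        ci = core_idx[~l_ish[core_idx]]
        self.core_heavy = ci
        self.core_xyz = lig.coords[ci]

        rec = complex_.receptor
        r_rad, r_hyd, r_don, r_acc, r_ish = _atom_flags(rec)
        ri = np.arange(len(rec.atoms))[~r_ish]
        self.rec_xyz = rec.coords[ri] if len(rec.atoms) else np.zeros((0, 3))

        def pair_tables(idx_a, rad_a, hyd_a, don_a, acc_a, idx_b, rad_b, hyd_b,
                        don_b, acc_b):
            rsum = rad_a[idx_a][:, None] + rad_b[idx_b][None, :]
            hmask = hyd_a[idx_a][:, None] & hyd_b[idx_b][None, :]
            bmask = (don_a[idx_a][:, None] & acc_b[idx_b][None, :]) | (
                acc_a[idx_a][:, None] & don_b[idx_b][None, :])
            return rsum, hmask, bmask

        self.rec_tables = (*pair_tables(mi, l_rad, l_hyd, l_don, l_acc,
                                        ri, r_rad, r_hyd, r_don, r_acc), None)
        core_far = _bond_path_gt3(lig, list(mi), list(ci)) if len(ci) else \
            np.zeros((len(mi), 0), dtype=bool)
        self.core_tables = (*pair_tables(mi, l_rad, l_hyd, l_don, l_acc,
                                         ci, l_rad, l_hyd, l_don, l_acc),
                            core_far)
        if params.include_intra and len(mi) > 1:
            far = _bond_path_gt3(lig, list(mi), list(mi))
            rsum, hmask, bmask = pair_tables(mi, l_rad, l_hyd, l_don, l_acc,
                                             mi, l_rad, l_hyd, l_don, l_acc)
            iu = np.triu_indices(len(mi), k=1)
            keep = far[iu]
            self.intra = (iu[0][keep], iu[1][keep], rsum[iu][keep],
                          hmask[iu][keep], bmask[iu][keep])
        else:
            self.intra = None
        self.weights = np.asarray(params.term_weights, dtype=float)

    def _accumulate(self, r, rsum, hmask, bmask, allowed, terms):
        within = r < self.params.cutoff
        if allowed is not None:
            within = within & allowed
        if not within.any():
            return
        d = (r - rsum)[within]
        hm = hmask[within]
        bm = bmask[within]
        terms[0] += float(np.exp(-((d / 0.5) ** 2)).sum())
        terms[1] += float(np.exp(-(((d - 3.0) / 2.0) ** 2)).sum())
        neg = d < 0
        terms[2] += float((d[neg] ** 2).sum())
        if hm.any():
            dh = d[hm]
            terms[3] += float(np.clip(1.5 - dh, 0.0, 1.0).sum())
        if bm.any():
            db = d[bm]
            terms[4] += float(np.clip(db / -0.7, 0.0, 1.0).sum())

    def score(self, pose: np.ndarray | None = None,
              frame_index: int = 0) -> EnergyRecord:
        cx = self.complex
        coords = cx.ligand.coords if pose is None else apply_pose(cx, pose)
        moi_xyz = coords[self.mi]
        terms = np.zeros(5)
        if len(self.rec_xyz):
            r = cdist(moi_xyz, self.rec_xyz)
            self._accumulate(r, *self.rec_tables, terms)
        if len(self.core_heavy):
            r = cdist(moi_xyz, coords[self.core_heavy])
            self._accumulate(r, *self.core_tables, terms)
        if self.intra is not None:
            ia, ib, rsum, hm, bm = self.intra
            r = np.linalg.norm(moi_xyz[ia] - moi_xyz[ib], axis=1)
            self._accumulate(r, rsum, hm, bm, None, terms)

        chi = 0.0
        if self.params.chi_weight != 0.0:
            for br in cx.pose_tree.branches:
                if br.chi_class is None:
                    continue
                p0, p1, p2, p3 = br.torsion_atoms
                phi = geom.dihedral(coords[p0], coords[p1], coords[p2], coords[p3])
                chi += chi_energy(phi, br.chi_class, self.params.chi_profiles)
        chi *= self.params.chi_weight
        total = float(self.weights @ terms) + chi
        return EnergyRecord(
            total=total,
            per_term=dict(zip(TERM_NAMES, terms.tolist())),
            chi_penalty=chi,
            frame_index=frame_index,
        )


def score_complex(complex_: GlycomimeticComplex,
                  pose: np.ndarray | None = None,
                  params: ScoringParameters | None = None) -> EnergyRecord:
    """Score a grafted complex, optionally after applying a torsion pose.

    The score covers moiety <-> receptor and moiety <-> carbohydrate-core
    pairs within the cutoff, intra-moiety pairs separated by more than
    three bonds (when enabled), and the CHI penalties of the linkage
    torsions.  Deterministic.
    """
    params = params or ScoringParameters()
    return ScoringSession(complex_, params).score(pose)


# ---------------------------------------------------------------------------
# Ensemble rescoring


def select_even_frames(n_total: int, k: int) -> list[int]:
    """Indices floor(i * n/k) for i < k — even selection along a trajectory."""
    if k <= 0 or n_total <= 0:
        raise ValueError("need positive frame counts")
    k = min(k, n_total)
    return [(i * n_total) // k for i in range(k)]


def rescore_ensemble(frames, params: ScoringParameters | None = None):
    """Rescore a sequence of complexes frame by frame.

    Returns (mean, sd, records).  The sd is the population standard
    deviation over frames.  Atom counts must be consistent.
    """
    params = params or ScoringParameters()
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    n0 = len(frames[0].ligand.atoms)
    records = []
    for k, frame in enumerate(frames):
        if len(frame.ligand.atoms) != n0:
            raise ValueError(f"frame {k}: atom count changed ({len(frame.ligand.atoms)} vs {n0})")
        rec = score_complex(frame, pose=None, params=params)
        rec.frame_index = k
        records.append(rec)
    totals = np.array([r.total for r in records])
    return float(totals.mean()), float(totals.std()), records
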