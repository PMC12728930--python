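"""Structural and statistical evaluation of glycomimetic models.

Heavy-atom RMSD (no superposition — frames are assumed pre-aligned, as
when poses are compared within the crystallographic frame), phi-angle
measurement and rotamer classification, bridging-water detection, and
the energy-affinity correlation with the rotamer entropy correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from . import _geometry as geom
from .structio import MolecularStructure, Role, write_pdb

R_GAS_KCAL = 1.98720425864083e-3   # kcal/mol/K
T_STANDARD = 298.15                # K


@dataclass
class AffinityRecord:
    system_id: str
    dG_exp: float                  # kcal/mol, from solution binding assays
    E_pred: float
    n_rot: int = 0
    moiety_rmsd: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.dG_exp):
            raise ValueError(f"{self.system_id}: dG_exp must be finite")
        if self.n_rot < 0:
            raise ValueError(f"{self.system_id}: n_rot must be non-negative")


def dg_from_kd(kd_molar: float, temperature: float = T_STANDARD) -> float:
    """Binding free energy from a dissociation constant: RT ln K_D."""
    if kd_molar <= 0:
        raise ValueError("K_D must be positive")
    return R_GAS_KCAL * temperature * float(np.log(kd_molar))


def heavy_atom_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
                    atom_selection=None) -> float:
    """Root-mean-square deviation over paired atoms, no superposition.

    Hydrogens are excluded upstream by contract — pass heavy-atom
    selections.  Coordinates must already share a frame.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if atom_selection is not None:
        sel = np.asarray(atom_selection, dtype=int)
        a, b = a[sel], b[sel]
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] < 1:
        raise ValueError(f"selection shapes differ or empty: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def moiety_rmsd(complex_a, complex_b) -> float:
    """Heavy-atom RMSD of the grafted moiety between two complexes."""
    idx = [i for i in complex_a.moiety_indices
           if complex_a.ligand.atoms[i].element != "H"]
    return heavy_atom_rmsd(complex_a.ligand.coords, complex_b.ligand.coords, idx)


def measure_phi(complex_, coords: np.ndarray | None = None) -> float:
    """The glycosidic/aglycone phi dihedral of the linkage, degrees.

    Measured on (ring reference, ring carbon, exocyclic oxygen,
    attachment atom) — the torsion the exo-anomeric effect governs."""
    phi_branch = complex_.pose_tree.branches[0]
    if phi_branch.torsion_atoms is None:
        raise ValueError("linkage torsion atoms unresolved")
    coords = complex_.ligand.coords if coords is None else coords
    p0, p1, p2, p3 = phi_branch.torsion_atoms
    return geom.dihedral(coords[p0], coords[p1], coords[p2], coords[p3])


def classify_phi(phi_deg: float, gauche_band=(30.0, 90.0),
                 trans_min: float = 150.0) -> str:
    """gauche iff |phi| in the gauche band, trans iff |phi| beyond
    trans_min, otherwise 'other'.  Wraparound-safe."""
    a = abs(geom.wrap_angle(phi_deg))
    if gauche_band[0] < a < gauche_band[1]:
        return "gauche"
    if a > trans_min:
        return "trans"
    return "other"


# ---------------------------------------------------------------------------
# Bridging waters


def _polar_with_h(structure: MolecularStructure, indices):
    """(polar heavy indices, {heavy: [H indices]}) within a selection."""
    polar = [i for i in indices
             if structure.atoms[i].element in ("N", "O")]
    hmap = {i: [] for i in polar}
    for b in structure.bonds:
        i, j = tuple(b)
        if i in hmap and structure.atoms[j].element == "H":
            hmap[i].append(j)
        if j in hmap and structure.atoms[i].element == "H":
            hmap[j].append(i)
    return polar, hmap


def _hbonded(structure, donors, hmap, acceptors, xyz, d_max, angle_min) -> bool:
    """Any donor-H...acceptor contact meeting the geometric criteria, in
    either direction between the two polar sets."""
    def one_way(dset, hm, aset):
        for d in dset:
            for a in aset:
                if np.linalg.norm(xyz[d] - xyz[a]) > d_max:
                    continue
                for h in hm.get(d, []):
                    v1 = xyz[d] - xyz[h]
                    v2 = xyz[a] - xyz[h]
                    if geom.angle_between_deg(v1, v2) >= angle_min:
                        return True
        return False
    return one_way(donors[0], hmap[0], acceptors[1]) or \
        one_way(donors[1], hmap[1], acceptors[0])


def bridging_waters(structure: MolecularStructure, d_max: float = 3.5,
                    angle_min: float = 120.0) -> list[tuple[str, str, int]]:
    """Waters hydrogen-bonded simultaneously to ligand and receptor.

    A hydrogen bond requires donor-acceptor distance <= d_max and a
    D-H...A angle >= angle_min.  Roles must be assigned; returns the
    residue ids of the flagged waters.
    """
    from .structio import perceive_bonds
    if not structure.bonds:
        structure.bonds = perceive_bonds(structure)
    xyz = structure.coords
    by_role: dict[Role, list[int]] = {}
    for i, a in enumerate(structure.atoms):
        by_role.setdefault(a.role, []).append(i)
    ligand_idx = by_role.get(Role.CARBOHYDRATE, []) + by_role.get(Role.MOIETY, [])
    receptor_idx = by_role.get(Role.PROTEIN, [])
    lig_polar, lig_h = _polar_with_h(structure, ligand_idx)
    rec_polar, rec_h = _polar_with_h(structure, receptor_idx)

    waters: dict[tuple, list[int]] = {}
    for i in by_role.get(Role.WATER, []):
        waters.setdefault(structure.atoms[i].residue_id, []).append(i)

    flagged = []
    for rid, widx in sorted(waters.items(), key=lambda kv: kv[0][2]):
        w_polar, w_h = _polar_with_h(structure, widx)
        to_lig = _hbonded(structure, (w_polar, lig_polar), (w_h, lig_h),
                          (w_polar, lig_polar), xyz, d_max, angle_min)
        to_rec = _hbonded(structure, (w_polar, rec_polar), (w_h, rec_h),
                          (w_polar, rec_polar), xyz, d_max, angle_min)
        if to_lig and to_rec:
            flagged.append(rid)
    return flagged


# ---------------------------------------------------------------------------
# Correlation with experimental affinities


def correlate(records: list[AffinityRecord], use_entropy: bool = True,
              per_bond: float = 0.6) -> dict:
    """Ordinary least squares of the (optionally entropy-corrected)
    predicted energy against experimental binding free energy.

    Returns R2 (squared Pearson correlation; identical to the OLS R2
    for a simple linear fit — both are reported), slope, intercept, n,
    plus RMSD-stratified sub-fits (<2, 2-3, >3 Angstrom) when moiety
    RMSD values are present.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    x = np.array([r.E_pred + (per_bond * r.n_rot if use_entropy else 0.0)
                  for r in records])
    y = np.array([r.dG_exp for r in records])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"R2": None, "R2_pearson": None, "slope": None,
                "intercept": None, "n": len(records),
                "note": "zero variance; R2 undefined"}
    fit = stats.linregress(x, y)
    out = {
        "R2": float(fit.rvalue ** 2),
        "R2_pearson": float(stats.pearsonr(x, y).statistic ** 2),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n": len(records),
    }
    strata = {"lt2": lambda r: r.moiety_rmsd is not None and r.moiety_rmsd < 2.0,
              "2to3": lambda r: r.moiety_rmsd is not None and 2.0 <= r.moiety_rmsd <= 3.0,
              "gt3": lambda r: r.moiety_rmsd is not None and r.moiety_rmsd > 3.0}
    stratified = {}
    for key, pred in strata.items():
        sub = [r for r in records if pred(r)]
        if len(sub) >= 3:
            stratified[key] = correlate(sub, use_entropy, per_bond)["R2"]
        else:
            stratified[key] = None
    if any(r.moiety_rmsd is not None for r in records):
        out["stratified_R2"] = stratified
    return out


def merge_energy_tables(vc_table: pd.DataFrame,
                        external_table: pd.DataFrame | None = None,
                        entropy_per_bond: float = 0.6) -> list[AffinityRecord]:
    """Join per-system score and affinity tables into AffinityRecords.

    `vc_table` needs columns system_id, E_pred, dG_exp (or KD_molar) and
    optionally n_rot / moiety_rmsd.  An external energy table (e.g.
    GB/PBSA values computed elsewhere) may override E_pred on matching
    keys; missing externals leave the VC value, absent fields stay
    absent, never zero-filled.  Duplicate keys raise.
    """
    for name, tbl in (("vc", vc_table), ("external", external_table)):
        if tbl is not None and tbl["system_id"].duplicated().any():
            dups = tbl.loc[tbl["system_id"].duplicated(), "system_id"].tolist()
            raise ValueError(f"duplicate system_id in {name} table: {dups}")
    df = vc_table.set_index("system_id")
    ext = external_table.set_index("system_id") if external_table is not None else None
    records = []
    for sid, row in df.iterrows():
        e = row.get("E_pred", np.nan)
        if ext is not None and sid in ext.index:
            e = ext.loc[sid].get("E_pred", e)
        dg = row.get("dG_exp", np.nan)
        if not np.isfinite(dg) and np.isfinite(row.get("KD_molar", np.nan)):
            dg = dg_from_kd(float(row["KD_molar"]))
        if not (np.isfinite(dg) and np.isfinite(e)):
            continue
        records.append(AffinityRecord(
            system_id=str(sid), dG_exp=float(dg), E_pred=float(e),
            n_rot=int(row.get("n_rot", 0) or 0),
            moiety_rmsd=(float(row["moiety_rmsd"])
                         if np.isfinite(row.get("moiety_rmsd", np.nan)) else None),
        ))
    return records


# ---------------------------------------------------------------------------
# Output helpers


def write_complex_pdb(complex_) -> str:
    """Receptor + ligand (+ retained bridging waters) as one PDB."""
    merged = MolecularStructure(provenance="glycomimetic complex")
    serial = 1
    for src in (complex_.receptor, complex_.ligand, complex_.bridging_waters):
        if src is None:
            continue
        for a in src.atoms:
            a2 = a.copy()
            a2.serial = serial
            serial += 1
            merged.atoms.append(a2)
    return write_pdb(merged)


def plot_correlation(records: list[AffinityRecord], path: str | Path,
                     use_entropy: bool = True, per_bond: float = 0.6) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    x = np.array([r.E_pred + (per_bond * r.n_rot if use_entropy else 0.0)
                  for r in records])
    y = np.array([r.dG_exp for r in records])
    res = correlate(records, use_entropy, per_bond)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(x, y, s=18)
    if res["R2"] is not None:
        xs = np.linspace(x.min(), x.max(), 10)
        ax.plot(xs, res["slope"] * xs + res["intercept"], "k--", lw=1)
        ax.set_title(f"R$^2$ = {res['R2']:.2f} (n = {res['n']})")
    ax.set_xlabel("predicted interaction energy (kcal/mol)")
    ax.set_ylabel(r"experimental $\Delta G$ (kcal/mol)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
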