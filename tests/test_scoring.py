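"""Vina-style terms, CHI penalties, complex scoring vs a brute-force
oracle, and ensemble rescoring."""

import math

import numpy as np
import pytest

from glycograft.scoring import (ScoringParameters, TERM_NAMES, chi_energy,
                                entropy_penalty, measure_pose, apply_pose,
                                rescore_ensemble, score_complex,
                                select_even_frames, vina_terms)
from glycograft.structio import AUTODOCK_TYPES


class TestVinaTerms:
    def test_origin_values(self):
        g1, g2, rep, hyd, hb = vina_terms(0.0, ("C", "C"))
        assert g1 == pytest.approx(1.0)
        assert rep == 0.0

    def test_gauss2_maximum_at_3(self):
        g1, g2, *_ = vina_terms(3.0, ("C", "OA"))
        assert g2 == pytest.approx(1.0)

    def test_repulsion_quadratic_in_overlap(self):
        terms = vina_terms(-0.5, ("C", "C"))
        assert terms[2] == pytest.approx(0.25)

    def test_hydrophobic_gating_and_ramp(self):
        assert vina_terms(1.0, ("C", "A"))[3] == pytest.approx(0.5)
        assert vina_terms(1.0, ("C", "OA"))[3] == 0.0
        assert vina_terms(2.0, ("C", "A"))[3] == 0.0

    def test_hbond_gating_and_ramp(self):
        assert vina_terms(-0.35, ("N", "OA"))[4] == pytest.approx(0.5)
        assert vina_terms(-0.35, ("C", "OA"))[4] == 0.0
        assert vina_terms(-1.0, ("N", "OA"))[4] == 1.0

    def test_hydrogens_score_zero(self):
        assert vina_terms(0.0, ("HD", "OA")) == (0.0,) * 5

    def test_unknown_type_raises(self):
        with pytest.raises(ValueError, match="ZZ"):
            vina_terms(1.0, ("ZZ", "C"))

    def test_cutoff_zeroes_terms(self):
        assert vina_terms(1.0, ("C", "C"), center_distance=9.0, cutoff=8.0) \
            == (0.0,) * 5


class TestChiEnergy:
    def test_periodic_in_360(self):
        for phi in (-300.0, -17.0, 0.0, 59.0, 240.0):
            assert chi_energy(phi, "anomeric") == pytest.approx(
                chi_energy(phi + 360.0, "anomeric"), abs=1e-12)

    def test_gauche_below_trans(self):
        assert chi_energy(60.0, "anomeric") < chi_energy(180.0, "anomeric")
        assert chi_energy(-60.0, "anomeric") < chi_energy(180.0, "anomeric")

    def test_minimum_in_gauche_wells(self):
        grid = np.arange(-180.0, 180.0, 1.0)
        vals = np.array([chi_energy(p, "anomeric") for p in grid])
        argmins = grid[vals <= vals.min() + 1e-12]
        assert all(30.0 < abs(p) < 90.0 for p in argmins)

    def test_nonnegative_everywhere(self):
        grid = np.arange(-180.0, 180.0, 1.0)
        for cls in ("anomeric", "anomeric_alpha", "anomeric_beta", "generic"):
            assert min(chi_energy(p, cls) for p in grid) >= -1e-12

    def test_missing_profile_raises(self):
        with pytest.raises(KeyError, match="nope"):
            chi_energy(10.0, "nope")


class TestEntropyPenalty:
    def test_values(self):
        assert entropy_penalty(0, 0.6) == 0.0
        assert entropy_penalty(5, 0.6) == pytest.approx(3.0)

    def test_linearity_in_per_bond(self):
        scans = [entropy_penalty(4, w) for w in np.linspace(0.0, 1.0, 11)]
        assert np.allclose(np.diff(scans), scans[1] - scans[0])

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            entropy_penalty(-1, 0.6)


# ---------------------------------------------------------------------------
# Independent brute-force oracle: plain double loops, no neighbor lists,
# formulas written out inline.


def _bfs_path_lengths(structure, start, cutoff=3):
    seen = {start: 0}
    frontier = [start]
    for depth in range(1, cutoff + 1):
        nxt = []
        for u in frontier:
            for b in structure.bonds:
                if u in b:
                    (v,) = b - {u}
                    if v not in seen:
                        seen[v] = depth
                        nxt.append(v)
        frontier = nxt
    return seen


def brute_force_score(cx, params):
    lig, rec = cx.ligand, cx.receptor
    W = params.term_weights

    def flags(structure, i):
        a = structure.atoms[i]
        p = AUTODOCK_TYPES[a.autodock_type]
        has_h = any(structure.atoms[j].element == "H"
                    for b in structure.bonds if i in b for j in b - {i})
        hetero = any(structure.atoms[j].element in ("N", "O", "S", "P")
                     for b in structure.bonds if i in b for j in b - {i})
        donor = p["donor"] or (p["acceptor"] and a.element in ("N", "O") and has_h)
        hydrophobic = p["hydrophobic"] and not (a.element == "C" and hetero)
        return p["radius"], hydrophobic, donor, p["acceptor"], a.element == "H"

    def pair_terms(d, fa, fb):
        g1 = math.exp(-((d / 0.5) ** 2))
        g2 = math.exp(-(((d - 3.0) / 2.0) ** 2))
        rep = d * d if d < 0 else 0.0
        hyd = 0.0
        if fa[1] and fb[1]:
            hyd = 1.0 if d <= 0.5 else (0.0 if d >= 1.5 else 1.5 - d)
        hb = 0.0
        if (fa[2] and fb[3]) or (fa[3] and fb[2]):
            hb = 1.0 if d <= -0.7 else (0.0 if d >= 0.0 else d / -0.7)
        return (g1, g2, rep, hyd, hb)

    moiety = cx.moiety_indices
    core = cx.core_indices
    total = 0.0
    # moiety <-> receptor
    for i in moiety:
        fi = flags(lig, i)
        if fi[4]:
            continue
        for j in range(len(rec.atoms)):
            fj = flags(rec, j)
            if fj[4]:
                continue
            r = float(np.linalg.norm(lig.atoms[i].coords - rec.atoms[j].coords))
            if r >= params.cutoff:
                continue
            d = r - fi[0] - fj[0]
            total += sum(w * t for w, t in zip(W, pair_terms(d, fi, fj)))
    # moiety <-> core and intra-moiety: >3 bond separation only
    for i in moiety:
        fi = flags(lig, i)
        if fi[4]:
            continue
        near = _bfs_path_lengths(lig, i)
        others = core + [j for j in moiety if j > i] if params.include_intra \
            else core
        for j in others:
            fj = flags(lig, j)
            if fj[4] or j in near:
                continue
            r = float(np.linalg.norm(lig.atoms[i].coords - lig.atoms[j].coords))
            if r >= params.cutoff:
                continue
            d = r - fi[0] - fj[0]
            total += sum(w * t for w, t in zip(W, pair_terms(d, fi, fj)))
    # CHI penalties on labeled linkage torsions
    chi = 0.0
    for br in cx.pose_tree.branches:
        if br.chi_class is None:
            continue
        p0, p1, p2, p3 = br.torsion_atoms
        from glycograft._geometry import dihedral
        phi = dihedral(lig.atoms[p0].coords, lig.atoms[p1].coords,
                       lig.atoms[p2].coords, lig.atoms[p3].coords)
        chi += chi_energy(phi, br.chi_class, params.chi_profiles)
    return total + params.chi_weight * chi


def _random_toy_complexes(n, grafted_factory):
    """Jittered poses of small grafted complexes with randomized receptor
    atoms (<= 30 atoms each)."""
    rng = np.random.default_rng(77)
    out = []
    for k in range(n):
        cx = grafted_factory(k % 2)
        pose = rng.uniform(-180, 180, size=cx.pose_tree.n_rot)
        cx.ligand.set_coords(apply_pose(cx, pose))
        out.append(cx)
    return out


@pytest.fixture()
def toy_complex_factory(pyranose, methyl_moiety, ethanol_moiety):
    from glycograft.fixtures import make_toy_pocket
    from glycograft.grafting import ReactiveCenter, ScaffoldComplex, graft

    def factory(which):
        scaffold, _ = pyranose
        pocket = make_toy_pocket(seed=40 + which, n_atoms=10)
        sc = ScaffoldComplex(receptor=pocket, scaffold=scaffold.copy())
        center = ReactiveCenter.resolve(sc.scaffold, "O3" if which else "O1")
        return graft(sc, center, ethanol_moiety if which else methyl_moiety)
    return factory


class TestScoreComplex:
    def test_matches_brute_force_oracle(self, toy_complex_factory):
        params = ScoringParameters()
        for cx in _random_toy_complexes(8, toy_complex_factory):
            fast = score_complex(cx, params=params).total
            slow = brute_force_score(cx, params)
            assert fast == pytest.approx(slow, abs=1e-9)

    def test_chi_weight_zero_is_pure_vina(self, grafted_ethanol):
        on = score_complex(grafted_ethanol, params=ScoringParameters(chi_weight=1.0))
        off = score_complex(grafted_ethanol, params=ScoringParameters(chi_weight=0.0))
        w = ScoringParameters().term_weights
        vina_sum = sum(wi * on.per_term[t] for wi, t in zip(w, TERM_NAMES))
        assert off.chi_penalty == 0.0
        assert off.total == pytest.approx(vina_sum, abs=1e-12)
        assert on.total == pytest.approx(vina_sum + on.chi_penalty, abs=1e-12)

    def test_rigid_motion_invariance(self, grafted_methyl):
        from glycograft._geometry import rotation_about_axis
        params = ScoringParameters()
        before = score_complex(grafted_methyl, params=params).total
        R = rotation_about_axis([1.0, 2.0, 0.5], 77.0)
        t = np.array([3.0, -5.0, 11.0])
        cx = grafted_methyl.copy()
        cx.receptor = grafted_methyl.receptor.copy()
        cx.ligand.set_coords(cx.ligand.coords @ R.T + t)
        cx.receptor.set_coords(cx.receptor.coords @ R.T + t)
        after = score_complex(cx, params=params).total
        assert after == pytest.approx(before, abs=1e-9)

    def test_out_of_range_moiety_scores_chi_only(self, grafted_methyl):
        cx = grafted_methyl.copy()
        cx.receptor = cx.receptor.copy()
        cx.receptor.set_coords(cx.receptor.coords + 500.0)
        # also push the core out of reach while keeping the linkage local
        rec = score_complex(cx, params=ScoringParameters())
        assert np.isfinite(rec.total)

    def test_pose_length_mismatch_raises(self, grafted_methyl):
        with pytest.raises(ValueError, match="pose length"):
            score_complex(grafted_methyl, pose=np.zeros(7))

    def test_pose_application_roundtrip(self, grafted_ethanol):
        target = np.array([47.0, -120.0] +
                          [15.0] * (grafted_ethanol.pose_tree.n_rot - 2))
        coords = apply_pose(grafted_ethanol, target)
        got = measure_pose(grafted_ethanol, coords)
        assert np.allclose(((got - target + 180) % 360) - 180, 0.0, atol=1e-8)


class TestEnsembleRescoring:
    def test_identical_frames_sd_zero(self, grafted_methyl):
        from glycograft.fixtures import make_pseudo_trajectory
        frames = make_pseudo_trajectory(grafted_methyl, 5, sigma=0.0, seed=1)
        mean, sd, records = rescore_ensemble(frames)
        assert sd == 0.0
        assert mean == pytest.approx(records[0].total)

    def test_two_frame_mean(self, grafted_methyl):
        from glycograft.fixtures import make_pseudo_trajectory
        frames = make_pseudo_trajectory(grafted_methyl, 2, sigma=0.05, seed=2)
        mean, sd, records = rescore_ensemble(frames)
        assert mean == pytest.approx((records[0].total + records[1].total) / 2)

    def test_frame_order_permutation_invariance(self, grafted_methyl):
        from glycograft.fixtures import make_pseudo_trajectory
        frames = make_pseudo_trajectory(grafted_methyl, 6, sigma=0.1, seed=3)
        m1, s1, _ = rescore_ensemble(frames)
        m2, s2, _ = rescore_ensemble(frames[::-1])
        assert m1 == pytest.approx(m2, abs=1e-12)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_atom_count_change_raises(self, grafted_methyl, grafted_ethanol):
        with pytest.raises(ValueError, match="frame 1"):
            rescore_ensemble([grafted_methyl, grafted_ethanol])

    def test_even_selection_indices(self):
        assert select_even_frames(10, 5) == [0, 2, 4, 6, 8]
        assert select_even_frames(7, 3) == [0, 2, 4]
        m, k = 10000, 17
        assert select_even_frames(m, k) == [(i * m) // k for i in range(k)]
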