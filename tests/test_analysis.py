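"""RMSD, phi classification, bridging waters, and correlation machinery."""

import numpy as np
import pandas as pd
import pytest

from glycograft.analysis import (AffinityRecord, bridging_waters, classify_phi,
                                 correlate, dg_from_kd, heavy_atom_rmsd,
                                 measure_phi, merge_energy_tables)
from glycograft.structio import Atom, MolecularStructure, Role


class TestHeavyAtomRmsd:
    def test_identity(self):
        x = np.random.default_rng(1).normal(size=(5, 3))
        assert heavy_atom_rmsd(x, x) == 0.0

    def test_uniform_translation(self):
        x = np.zeros((4, 3))
        y = x + np.array([2.0, 0.0, 0.0])
        assert heavy_atom_rmsd(x, y) == pytest.approx(2.0)

    def test_single_displaced_atom(self):
        x = np.zeros((4, 3))
        y = x.copy()
        y[0, 0] = 2.0
        assert heavy_atom_rmsd(x, y) == pytest.approx(1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            heavy_atom_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            a, b, c = rng.normal(size=(3, 6, 3))
            dab = heavy_atom_rmsd(a, b)
            dba = heavy_atom_rmsd(b, a)
            assert dab == pytest.approx(dba)
            assert dab >= 0
            assert heavy_atom_rmsd(a, c) <= dab + heavy_atom_rmsd(b, c) + 1e-12


class TestPhi:
    def test_grafted_complex_phi(self, grafted_methyl):
        phi = measure_phi(grafted_methyl)
        assert -180.0 <= phi < 180.0

    @pytest.mark.parametrize("phi,expected", [
        (180.0, "trans"), (-170.0, "trans"), (60.0, "gauche"),
        (-60.0, "gauche"), (0.0, "other"), (120.0, "other"),
    ])
    def test_classification_bands(self, phi, expected):
        assert classify_phi(phi) == expected

    def test_wraparound_equivalence(self):
        for phi in (-250.0, 60.0, 185.0, 400.0):
            assert classify_phi(phi) == classify_phi(phi - 360.0)


class TestBridgingWaters:
    def _system(self, water_pos, with_receptor_contact=True,
                with_ligand_contact=True):
        """Ligand O at origin, receptor N at (5.6, 0, 0); a water between
        them donates to both when its hydrogens point outward."""
        atoms = [
            Atom(1, "O1", "O", "OA", [0.0, 0.0, 0.0],
                 residue_id=("A", "LIG", 1), role=Role.CARBOHYDRATE),
            Atom(2, "N1", "N", "N", [5.6, 0.0, 0.0],
                 residue_id=("B", "ALA", 1), role=Role.PROTEIN),
        ]
        wx = np.asarray(water_pos, dtype=float)
        atoms.append(Atom(3, "O", "O", "OA", wx,
                          residue_id=("W", "HOH", 1), role=Role.WATER))
        h1 = wx + 0.96 * np.array([-1.0, 0.0, 0.0])   # toward the ligand O
        h2 = wx + 0.96 * np.array([1.0, 0.0, 0.0])    # toward the receptor N
        if not with_ligand_contact:
            h1 = wx + 0.96 * np.array([0.0, 0.0, 1.0])
        if not with_receptor_contact:
            h2 = wx + 0.96 * np.array([0.0, 1.0, 0.0])
        atoms.append(Atom(4, "H1", "H", "HD", h1,
                          residue_id=("W", "HOH", 1), role=Role.WATER))
        atoms.append(Atom(5, "H2", "H", "HD", h2,
                          residue_id=("W", "HOH", 1), role=Role.WATER))
        s = MolecularStructure(atoms=atoms)
        s.add_bond(2, 3)
        s.add_bond(2, 4)
        return s

    def test_double_hbond_flagged(self):
        s = self._system([2.8, 0.0, 0.0])
        assert bridging_waters(s) == [("W", "HOH", 1)]

    def test_far_water_not_flagged(self):
        s = self._system([2.8, 6.0, 0.0])
        assert bridging_waters(s) == []

    def test_single_sided_water_not_flagged(self):
        s = self._system([2.8, 0.0, 0.0], with_receptor_contact=False)
        assert bridging_waters(s) == []

    def test_monotone_in_distance_cutoff(self):
        s = self._system([2.8, 0.0, 0.0])
        tight = bridging_waters(s, d_max=3.0)
        loose = bridging_waters(s, d_max=4.0)
        assert set(tight) <= set(loose)


class TestCorrelate:
    def _records(self, x, y, n_rot=None):
        return [AffinityRecord(f"s{k}", float(yy), float(xx),
                               n_rot=0 if n_rot is None else int(n_rot[k]))
                for k, (xx, yy) in enumerate(zip(x, y))]

    def test_exact_line_r2_one(self):
        x = np.arange(10.0)
        recs = self._records(x, 2.0 * x - 3.0)
        res = correlate(recs, use_entropy=False)
        assert res["R2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)
        assert res["R2_pearson"] == pytest.approx(res["R2"], abs=1e-12)

    def test_zero_per_bond_reduces_to_uncorrected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        y = x + rng.normal(0, 0.3, size=20)
        recs = self._records(x, y, n_rot=rng.integers(0, 8, size=20))
        a = correlate(recs, use_entropy=True, per_bond=0.0)
        b = correlate(recs, use_entropy=False)
        assert a["R2"] == pytest.approx(b["R2"], abs=1e-15)
        assert a["slope"] == pytest.approx(b["slope"], abs=1e-15)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = 1.5 * x + rng.normal(0, 0.5, size=30)
        base = correlate(self._records(x, y), use_entropy=False)["R2"]
        scaled = correlate(self._records(4.0 * x + 10.0, y),
                           use_entropy=False)["R2"]
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_zero_variance_reported_undefined(self):
        recs = self._records(np.ones(5), np.arange(5.0))
        res = correlate(recs, use_entropy=False)
        assert res["R2"] is None

    def test_synthetic_recovery_of_generating_r2(self):
        # dG = a*(E + w*n_rot) + noise with known population rho^2
        rng = np.random.default_rng(11)
        rho2 = 0.6
        n, reps = 200, 120
        r2s = []
        for _ in range(reps):
            e = rng.normal(-8.0, 2.0, size=n)
            nr = rng.integers(0, 9, size=n)
            x = e + 0.6 * nr
            sigma = np.sqrt(np.var(x) * (1 - rho2) / rho2)
            y = x + rng.normal(0.0, sigma, size=n)
            recs = [AffinityRecord(f"s{k}", float(y[k]), float(e[k]),
                                   n_rot=int(nr[k])) for k in range(n)]
            r2s.append(correlate(recs, use_entropy=True, per_bond=0.6)["R2"])
        se = np.std(r2s, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(r2s) - rho2) < 3 * se + 2 * (1 - rho2) / n

    def test_too_few_records_raises(self):
        with pytest.raises(ValueError):
            correlate(self._records([1, 2], [1, 2]), use_entropy=False)


class TestMergeTables:
    def _vc(self):
        return pd.DataFrame({
            "system_id": ["a", "b", "c"],
            "E_pred": [-5.0, -6.0, -7.0],
            "dG_exp": [-4.0, -5.5, -6.5],
            "n_rot": [1, 2, 3],
        })

    def test_vc_only(self):
        recs = merge_energy_tables(self._vc())
        assert [r.E_pred for r in recs] == [-5.0, -6.0, -7.0]
        assert all(r.moiety_rmsd is None for r in recs)

    def test_external_overrides_on_intersection(self):
        ext = pd.DataFrame({"system_id": ["b"], "E_pred": [-60.0]})
        recs = merge_energy_tables(self._vc(), ext)
        by_id = {r.system_id: r.E_pred for r in recs}
        assert by_id == {"a": -5.0, "b": -60.0, "c": -7.0}

    def test_duplicate_keys_raise(self):
        bad = pd.concat([self._vc(), self._vc().iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            merge_energy_tables(bad)

    def test_kd_conversion(self):
        df = pd.DataFrame({"system_id": ["a", "b", "c"],
                           "E_pred": [-5.0, -5.0, -5.0],
                           "KD_molar": [1e-6, 1e-6, 1e-6]})
        recs = merge_energy_tables(df)
        assert recs[0].dG_exp == pytest.approx(dg_from_kd(1e-6))
        assert dg_from_kd(1e-6) == pytest.approx(-8.18, abs=0.05)
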