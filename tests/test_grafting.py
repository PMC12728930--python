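"""Grafting geometry, charge repair, and charge assignment."""

import numpy as np
import pytest

from glycograft._geometry import dihedral, rotation_about_axis
from glycograft.grafting import (ReactiveCenter, ScaffoldComplex,
                                 assign_charges, graft, redistribute_charge)
from glycograft.structio import MolecularStructure, Role


class TestGraftGeometry:
    def test_methyl_onto_O3_construction(self, grafted_methyl, pyranose):
        scaffold, _ = pyranose
        lig = grafted_methyl.ligand
        heavy = [a for a in lig.atoms if a.element != "H"]
        core_heavy = [a for a in scaffold.atoms if a.element != "H"]
        assert len(heavy) == len(core_heavy) + 1      # one new carbon
        o_idx, att = grafted_methyl.linkage
        assert frozenset((o_idx, att)) in lig.bonds
        assert lig.atoms[o_idx].name == "O3"
        # the hydroxyl hydrogen is gone
        assert "HO3" not in [a.name for a in lig.atoms]

    def test_alignment_postconditions(self, grafted_methyl):
        d = grafted_methyl.diagnostics
        assert d.cap_superposition_A <= 1e-6
        assert abs(d.alignment_angle_deg) <= 1e-4
        assert abs(d.initial_phi_deg) <= 1e-4     # eclipsed start

    def test_new_bond_length_inherited_from_cap(self, pyranose, methyl_moiety,
                                                empty_receptor):
        scaffold, _ = pyranose
        cm = methyl_moiety
        cap_bond = float(np.linalg.norm(
            cm.structure.atoms[cm.cap_ch2].coords
            - cm.structure.atoms[cm.attachment_atom].coords))
        sc = ScaffoldComplex(receptor=empty_receptor, scaffold=scaffold.copy())
        cx = graft(sc, ReactiveCenter.resolve(sc.scaffold, "O3"), cm)
        o_idx, att = cx.linkage
        got = float(np.linalg.norm(cx.ligand.atoms[o_idx].coords
                                   - cx.ligand.atoms[att].coords))
        assert got == pytest.approx(cap_bond, abs=1e-9)

    def test_orientation_invariance(self, pyranose, phenyl_moiety, empty_receptor):
        scaffold, _ = pyranose
        sc = ScaffoldComplex(receptor=empty_receptor, scaffold=scaffold.copy())
        center = ReactiveCenter.resolve(sc.scaffold, "O2")
        ref = graft(sc, center, phenyl_moiety).ligand.coords
        rng = np.random.default_rng(21)
        for _ in range(8):
            m = phenyl_moiety
            rotated = m.structure.copy()
            axis = rng.normal(size=3)
            R = rotation_about_axis(axis, float(rng.uniform(0, 360)))
            rotated.set_coords(rotated.coords @ R.T + rng.uniform(-20, 20, 3))
            from glycograft.moiety_library import CappedMoiety
            m2 = CappedMoiety(structure=rotated, attachment_atom=m.attachment_atom,
                              cap_ch2=m.cap_ch2, cap_ch3=m.cap_ch3)
            got = graft(sc, center, m2).ligand.coords
            assert np.allclose(got, ref, atol=1e-6)

    def test_receptor_untouched(self, pyranose, methyl_moiety, pocket):
        scaffold, _ = pyranose
        before = pocket.coords.copy()
        sc = ScaffoldComplex(receptor=pocket, scaffold=scaffold.copy())
        cx = graft(sc, ReactiveCenter.resolve(sc.scaffold, "O3"), methyl_moiety)
        assert np.array_equal(cx.receptor.coords, before)

    def test_missing_cap_labels_raise(self, pyranose, methyl_moiety):
        scaffold, _ = pyranose
        from glycograft.moiety_library import CappedMoiety
        broken = CappedMoiety(structure=methyl_moiety.structure.copy(),
                              attachment_atom=0, cap_ch2=0, cap_ch3=0)
        sc = ScaffoldComplex(receptor=MolecularStructure(),
                             scaffold=scaffold.copy())
        with pytest.raises(ValueError):
            graft(sc, ReactiveCenter.resolve(sc.scaffold, "O3"), broken)

    def test_reactive_center_resolution_errors(self, pyranose):
        scaffold, _ = pyranose
        with pytest.raises(ValueError, match="no atom"):
            ReactiveCenter.resolve(scaffold.copy(), "O99")
        with pytest.raises(ValueError, match="oxygen or nitrogen"):
            ReactiveCenter.resolve(scaffold.copy(), "C1")

    def test_center_file_roundtrip(self, tmp_path, pyranose):
        scaffold, _ = pyranose
        f = tmp_path / "center.txt"
        f.write_text("# derivatization position\nA PYR 1 O4\n")
        c = ReactiveCenter.from_file(f, scaffold.copy())
        assert c.name == "O4"
        assert scaffold.atoms[c.exocyclic_oxygen].name == "O4"


class TestRedistributeCharge:
    def _ligand(self, charges):
        atoms = []
        from glycograft.structio import Atom
        for k, q in enumerate(charges):
            atoms.append(Atom(k + 1, f"C{k+1}", "C", "C",
                              [1.6 * k, 0.0, 0.0], charge=q))
        return MolecularStructure(atoms=atoms)

    def test_even_split_example(self):
        # +0.06 over integer, linkage charges (-0.40, +0.10) -> (-0.43, +0.07)
        lig = self._ligand([-0.40, 0.10, 0.36])
        out = redistribute_charge(lig, (0, 1))
        assert out.atoms[0].charge == pytest.approx(-0.43)
        assert out.atoms[1].charge == pytest.approx(0.07)
        assert out.atoms[2].charge == pytest.approx(0.36)
        assert out.net_charge() == pytest.approx(0.0, abs=1e-12)

    def test_integral_charge_unchanged(self):
        lig = self._ligand([-0.5, 0.25, 0.25])
        out = redistribute_charge(lig, (0, 1))
        assert [a.charge for a in out.atoms] == [-0.5, 0.25, 0.25]

    def test_negative_deviation_symmetric(self):
        lig = self._ligand([-0.04, -0.04, 0.0])
        out = redistribute_charge(lig, (0, 2))
        assert out.atoms[0].charge == pytest.approx(0.0)
        assert out.atoms[2].charge == pytest.approx(0.04)

    def test_total_shift_equals_minus_deviation(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            qs = rng.normal(0, 0.2, size=6)
            dev = qs.sum() - round(qs.sum())
            lig = self._ligand(list(qs))
            out = redistribute_charge(lig, (2, 5))
            shift = sum(b.charge - a.charge
                        for a, b in zip(lig.atoms, out.atoms))
            assert shift == pytest.approx(-dev, abs=1e-12)

    def test_large_deviation_raises(self):
        # against the declared formal charge of 0
        lig = self._ligand([0.61, 0.0, 0.0])
        with pytest.raises(ValueError, match="0.5"):
            redistribute_charge(lig, (0, 1), target_charge=0)


class TestAssignCharges:
    def test_table_values_applied(self, grafted_methyl):
        table = {str(grafted_methyl.ligand.atoms[i].serial): 0.05
                 for i in grafted_methyl.moiety_indices}
        out = assign_charges(grafted_methyl, resp_table=table)
        o_idx, att = out.linkage
        for i in out.moiety_indices:
            if i == att:
                continue
            assert out.ligand.atoms[i].charge == pytest.approx(0.05)
        assert out.ligand.net_charge() == pytest.approx(
            round(out.ligand.net_charge()), abs=1e-9)

    def test_fallback_scheme_gives_integral_net(self, grafted_methyl):
        out = assign_charges(grafted_methyl, resp_table=None)
        assert all(np.isfinite(a.charge) for a in out.ligand.atoms)
        net = out.ligand.net_charge()
        assert net == pytest.approx(round(net), abs=1e-9)

    def test_extra_table_row_raises(self, grafted_methyl):
        table = {str(grafted_methyl.ligand.atoms[i].serial): 0.05
                 for i in grafted_methyl.moiety_indices}
        table["ZZTOP"] = 1.0
        with pytest.raises(ValueError, match="ZZTOP"):
            assign_charges(grafted_methyl, resp_table=table)

    def test_missing_atom_raises(self, grafted_methyl):
        i0 = grafted_methyl.moiety_indices[0]
        table = {str(grafted_methyl.ligand.atoms[i].serial): 0.05
                 for i in grafted_methyl.moiety_indices[1:]}
        with pytest.raises(ValueError, match="missing"):
            assign_charges(grafted_methyl, resp_table=table)


def test_grafted_phi_measured_equals_zero(grafted_methyl):
    from glycograft.analysis import measure_phi
    assert abs(measure_phi(grafted_methyl)) <= 1e-4
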