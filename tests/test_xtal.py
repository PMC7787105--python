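"""Cell arithmetic, space groups, chi sections, Matthews analysis, reflection I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclophase.xtal import (P1, P212121, MATTHEWS_PROTEIN_CONSTANT,
                             ReflectionSet, SpaceGroup, UnitCell, cell_volume,
                             chi_for_order, d_spacing, generate_unique_hkl,
                             matthews, read_hkl, symmetry_equivalents,
                             unique_hkl, write_hkl)

PORTAL_CELL = UnitCell(119.85, 238.57, 265.61)  # orthorhombic ring crystal


class TestUnitCell:
    @pytest.mark.parametrize("cell,expected", [
        (UnitCell(1, 1, 1), 1.0),
        (UnitCell(2, 3, 4), 24.0),
        (PORTAL_CELL, 119.85 * 238.57 * 265.61),
    ])
    def test_orthorhombic_volume_is_edge_product(self, cell, expected):
        assert cell_volume(cell) == pytest.approx(expected, rel=1e-12)

    def test_triclinic_volume_against_gemmi(self):
        import gemmi

        cell = UnitCell(23.3, 31.1, 47.9, 81.0, 95.5, 102.2)
        ref = gemmi.UnitCell(23.3, 31.1, 47.9, 81.0, 95.5, 102.2).volume
        assert cell.volume() == pytest.approx(ref, rel=1e-10)

    @given(a=st.floats(1, 500), b=st.floats(1, 500), c=st.floats(1, 500))
    @settings(max_examples=25, deadline=None)
    def test_volume_invariant_under_cyclic_permutation(self, a, b, c):
        assert cell_volume(UnitCell(a, b, c)) == pytest.approx(
            cell_volume(UnitCell(b, c, a)), rel=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(a=-1, b=1, c=1), dict(a=1, b=0, c=1),
        dict(a=1, b=1, c=1, alpha=0.0), dict(a=1, b=1, c=1, gamma=180.0),
    ])
    def test_invalid_cells_rejected(self, bad):
        with pytest.raises(ValueError):
            UnitCell(**bad)

    def test_orthogonalization_roundtrip(self):
        cell = UnitCell(20, 30, 40, 80, 95, 110)
        frac = np.array([[0.1, 0.7, 0.3], [0.9, 0.2, 0.5]])
        assert np.allclose(cell.fractionalize(cell.orthogonalize(frac)), frac)


class TestDSpacing:
    @pytest.mark.parametrize("hkl,cell,expected", [
        ((0, 0, 2), PORTAL_CELL, 265.61 / 2),
        ((1, 0, 0), UnitCell(10, 20, 30), 10.0),
        ((0, 3, 0), PORTAL_CELL, 238.57 / 3),
    ])
    def test_axial_spacings(self, hkl, cell, expected):
        assert d_spacing(hkl, cell) == pytest.approx(expected, rel=1e-12)

    def test_friedel_mate_identical(self):
        cell = UnitCell(25, 35, 45, 85, 92, 99)
        for hkl in [(1, 2, 3), (-4, 0, 7), (2, -5, 1)]:
            assert d_spacing(hkl, cell) == d_spacing(tuple(-x for x in hkl), cell)

    def test_gemmi_oracle_triclinic(self):
        import gemmi

        cell = UnitCell(25, 35, 45, 85, 92, 99)
        g = gemmi.UnitCell(25, 35, 45, 85, 92, 99)
        for hkl in [(1, 2, 3), (5, -1, 2), (0, 0, 9)]:
            assert d_spacing(hkl, cell) == pytest.approx(
                g.calculate_d(list(hkl)), rel=1e-10)

    def test_zero_index_rejected(self):
        with pytest.raises(ValueError):
            d_spacing((0, 0, 0), PORTAL_CELL)


class TestChiSections:
    @pytest.mark.parametrize("n,chi", [
        (11, 32.7), (12, 30.0), (13, 27.7), (14, 25.7), (2, 180.0),
    ])
    def test_printed_sections(self, n, chi):
        assert chi_for_order(n) == chi

    @given(n=st.integers(1, 60))
    @settings(max_examples=60, deadline=None)
    def test_chi_times_n_is_full_turn_within_rounding(self, n):
        # reporting rounds to one decimal: up to 0.05 deg error per copy
        # (half-to-even at the boundary, hence the small cushion)
        assert chi_for_order(n) * n == pytest.approx(360.0, abs=0.0501 * n)

    def test_rejects_nonpositive_order(self):
        with pytest.raises(ValueError):
            chi_for_order(0)


class TestMatthews:
    def test_tridecamer_in_portal_cell(self):
        # one C13 ring of 59 kDa protomers per AU, z = 4: Vm ~ 2.48, ~50% solvent
        res = matthews(PORTAL_CELL, P212121, 13 * 59000.0)
        vm_oracle = PORTAL_CELL.volume() / (4 * 13 * 59000.0)
        assert res.vm == pytest.approx(vm_oracle, rel=1e-12)
        assert res.solvent_fraction == pytest.approx(
            1 - MATTHEWS_PROTEIN_CONSTANT / vm_oracle, rel=1e-12)
        assert 0.48 < res.solvent_fraction < 0.52

    def test_vm_definition(self):
        cell = UnitCell(10, 10, 10)
        mass = cell.volume() / (1 * 2.46)
        assert matthews(cell, P1, mass).vm == pytest.approx(2.46)

    def test_doubling_mass_halves_vm_and_lowers_solvent(self):
        r1 = matthews(PORTAL_CELL, P212121, 4.0e5)
        r2 = matthews(PORTAL_CELL, P212121, 8.0e5)
        assert r2.vm == pytest.approx(r1.vm / 2)
        assert r2.solvent_fraction < r1.solvent_fraction

    def test_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError):
            matthews(PORTAL_CELL, P212121, 0.0)


class TestSpaceGroups:
    def test_p212121_matches_gemmi(self):
        import gemmi

        ours = {(tuple(map(tuple, r)), tuple(t)) for r, t in P212121.ops}
        ref = set()
        for op in gemmi.SpaceGroup("P 21 21 21").operations():
            rot = tuple(tuple(x // 24 for x in row) for row in op.rot)
            ref.add((rot, tuple(x / 24 for x in op.tran)))
        assert ours == ref

    def test_group_closure(self):
        ops = P212121.ops
        for r1, t1 in ops:
            for r2, t2 in ops:
                r = r1 @ r2
                t = (r1 @ t2 + t1) % 1.0
                assert any(np.array_equal(r, r3) and np.allclose(t, t3 % 1.0)
                           for r3, t3 in ops)

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            SpaceGroup.from_symbol("C2")


class TestSymmetryEquivalents:
    def test_p1_friedel_only(self):
        assert symmetry_equivalents((1, 2, 3), P1) == {(1, 2, 3), (-1, -2, -3)}

    def test_p212121_general_position(self):
        eq = symmetry_equivalents((1, 2, 3), P212121)
        assert len(eq) == 8
        assert (1, 2, 3) in eq and (-1, -2, -3) in eq

    def test_axial_collapse(self):
        assert len(symmetry_equivalents((0, 0, 4), P212121)) == 2

    def test_unique_reduction_idempotent(self):
        hkl = np.array([[1, 2, 3], [-1, -2, -3], [1, -2, 3], [0, 0, 4]])
        once = unique_hkl(hkl, P212121)
        assert np.array_equal(unique_hkl(once, P212121), once)
        # every orbit collapses to a single representative
        assert len({tuple(h) for h in once[:3]}) == 1

    def test_generate_unique_within_window(self):
        cell = UnitCell(20, 24, 30)
        uniq = generate_unique_hkl(cell, P212121, 3.0, 15.0)
        d = cell.d_spacing(uniq)
        assert d.min() >= 3.0 and d.max() <= 15.0
        assert np.array_equal(np.unique(uniq, axis=0), np.unique(unique_hkl(uniq, P212121), axis=0))


class TestReflectionIO:
    def _sample(self):
        cell = UnitCell(20, 24, 30)
        hkl = generate_unique_hkl(cell, P212121, 5.0)
        rng = np.random.default_rng(3)
        f = rng.uniform(1, 1000, len(hkl))
        sig = 0.05 * f
        phase = rng.uniform(0, 360, len(hkl))
        fom = rng.uniform(0, 1, len(hkl))
        return ReflectionSet(cell, P212121, hkl, f, sig, phase, fom)

    def test_roundtrip_bit_identical(self, tmp_path):
        refl = self._sample()
        p1, p2 = tmp_path / "a.hkl", tmp_path / "b.hkl"
        write_hkl(refl, p1)
        again = read_hkl(p1)
        write_hkl(again, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert np.array_equal(again.hkl, refl.hkl)
        assert np.allclose(again.f, refl.f, rtol=1e-5)

    def test_amplitude_only_set(self, tmp_path):
        refl = self._sample()
        refl.phase[:] = np.nan
        path = tmp_path / "amp.hkl"
        write_hkl(refl, path)
        again = read_hkl(path)
        assert not again.has_phases

    def test_malformed_line_reports_location(self, tmp_path):
        path = tmp_path / "bad.hkl"
        path.write_text("# CELL 10 10 10 90 90 90\n# SPACEGROUP P1\n1 2 x 3.0 0.1\n")
        with pytest.raises(ValueError, match=":3"):
            read_hkl(path)

    def test_invariants_enforced(self):
        cell = UnitCell(10, 10, 10)
        with pytest.raises(ValueError):
            ReflectionSet(cell, P1, [[0, 0, 0]], [1.0])
        with pytest.raises(ValueError):
            ReflectionSet(cell, P1, [[1, 0, 0]], [-1.0])
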