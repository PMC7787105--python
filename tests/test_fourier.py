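"""Fourier engine: structure factors, map synthesis/inversion, Patterson, interpolation."""

import math

import numpy as np
import pytest

from cyclophase.fourier import (MapGrid, calc_structure_factors, grid_shape_for,
                                density_from_model, interpolate, invert_map,
                                low_pass, map_correlation, patterson_map,
                                read_ccp4, synthesize_map, write_ccp4,
                                _form_factor)
from cyclophase.models import AtomicModel
from cyclophase.xtal import P1, P212121, ReflectionSet, UnitCell


def random_model(n=12, seed=0, span=(3.0, 15.0)):
    rng = np.random.default_rng(seed)
    return AtomicModel(
        name=["CA"] * n, chain=["A"] * n, res_seq=list(range(1, n + 1)),
        res_name=["ALA"] * n, xyz=rng.uniform(*span, size=(n, 3)),
        b_iso=np.full(n, 30.0), element=(["C", "N", "O", "S"] * n)[:n])


CELL = UnitCell(20, 24, 28)


@pytest.fixture(scope="module")
def model_refl():
    model = random_model()
    return model, calc_structure_factors(model, CELL, P1, d_min=2.5)


def direct_sum(model, cell, sg, hkl):
    """Independent oracle: textbook direct summation over atoms and symmetry."""
    out = np.zeros(len(hkl), dtype=complex)
    frac = cell.fractionalize(model.xyz)
    s2 = 1.0 / cell.d_spacing(hkl) ** 2
    for j in range(len(model)):
        f = np.zeros(len(hkl))
        for a, b in _form_factor(str(model.element[j])):
            f += a * np.exp(-(b + model.b_iso[j]) * s2 / 4.0)
        for rot, tran in sg.ops:
            ph = 2j * math.pi * (hkl @ np.asarray(rot, float).T @ frac[j] + hkl @ tran)
            out += model.occupancy[j] * f * np.exp(ph)
    return out


class TestStructureFactors:
    def test_matches_direct_summation(self, model_refl):
        model, refl = model_refl
        ref = direct_sum(model, CELL, P1, refl.hkl)
        rel = np.abs(np.abs(ref) - refl.f) / np.abs(ref).mean()
        assert rel.max() < 0.01
        dphi = np.angle(np.exp(1j * (np.angle(ref) - np.radians(refl.phase))))
        assert np.abs(dphi).max() < 0.01

    def test_symmetry_expansion_consistent(self):
        # SF in P212121 equals the P1 SF of the explicitly expanded model
        model = random_model(8, seed=2)
        refl = calc_structure_factors(model, CELL, P212121, d_min=3.0)
        ref = direct_sum(model, CELL, P212121, refl.hkl)
        assert np.allclose(np.abs(ref), refl.f, rtol=0.01,
                           atol=0.01 * np.abs(ref).mean())

    def test_translation_shift_theorem(self, model_refl):
        model, refl = model_refl
        t = np.array([1.3, -2.1, 0.7])
        refl2 = calc_structure_factors(model.transformed(trans=t), CELL, P1,
                                       d_min=2.5)
        assert np.allclose(refl2.f, refl.f, rtol=0.01,
                           atol=0.01 * refl.f.mean())
        expected = np.radians(refl.phase) + 2 * math.pi * (
            refl.hkl @ CELL.fractionalize(t))
        dphi = np.angle(np.exp(1j * (np.radians(refl2.phase) - expected)))
        assert np.abs(dphi).max() < 0.01

    def test_single_atom_at_origin_has_zero_phases(self):
        model = AtomicModel(["CA"], ["A"], [1], ["ALA"], [[0.0, 0.0, 0.0]],
                            b_iso=[30.0], element=["C"])
        refl = calc_structure_factors(model, CELL, P1, d_min=3.0)
        dphi = np.angle(np.exp(1j * np.radians(refl.phase)))
        assert np.abs(dphi).max() < 1e-3

    def test_gemmi_cross_check(self, model_refl):
        import gemmi

        model, refl = model_refl
        st = gemmi.Structure()
        mdl = gemmi.Model("1")
        ch = gemmi.Chain("A")
        for i in range(len(model)):
            r = gemmi.Residue()
            r.name = "ALA"
            r.seqid = gemmi.SeqId(i + 1, " ")
            ch.add_residue(r)
            at = gemmi.Atom()
            at.name = "CA"
            at.pos = gemmi.Position(*model.xyz[i])
            at.b_iso = float(model.b_iso[i])
            at.element = gemmi.Element(str(model.element[i]))
            ch[-1].add_atom(at)
        mdl.add_chain(ch)
        st.add_model(mdl)
        st.cell = gemmi.UnitCell(CELL.a, CELL.b, CELL.c, 90, 90, 90)
        st.spacegroup_hm = "P 1"
        st.setup_entities()
        calc = gemmi.DensityCalculatorX()
        calc.d_min = 2.5
        calc.rate = 3.0
        calc.set_grid_cell_and_spacegroup(st)
        calc.put_model_density_on_grid(st[0])
        sf = gemmi.transform_map_to_f_phi(calc.grid)
        fg = np.array([abs(sf.get_value(*h)) for h in refl.hkl])
        assert np.corrcoef(fg, refl.f)[0, 1] > 0.999

    def test_unknown_element_warns_and_falls_back(self):
        model = AtomicModel(["X1"], ["A"], [1], ["UNK"], [[1.0, 1.0, 1.0]],
                            element=["Xx"])
        with pytest.warns(UserWarning, match="carbon"):
            calc_structure_factors(model, CELL, P1, d_min=4.0)


class TestSynthesisInversion:
    def test_roundtrip_identity(self, model_refl):
        _, refl = model_refl
        shape = grid_shape_for(CELL, 2.5, 3.0)
        grid = synthesize_map(refl, shape)
        back = invert_map(grid, 2.5)
        assert np.allclose(back.f, refl.f, rtol=1e-6)
        dphi = np.angle(np.exp(1j * np.radians(back.phase - refl.phase)))
        assert np.abs(dphi).max() < 1e-6

    def test_sg_expansion_equals_p1_synthesis(self):
        model = random_model(8, seed=2)
        refl_sg = calc_structure_factors(model, CELL, P212121, d_min=3.0)
        shape = grid_shape_for(CELL, 3.0, 3.0)
        map_sg = synthesize_map(refl_sg, shape)
        rho = density_from_model(model, CELL, P212121, shape)
        refl_p1 = invert_map(rho, 3.0)
        map_p1 = synthesize_map(refl_p1, shape)
        # residual difference is the finite sampling rate of the two routes
        assert map_correlation(map_sg, map_p1) > 0.9999

    def test_difference_coefficients(self, model_refl):
        _, refl = model_refl
        shape = grid_shape_for(CELL, 2.5, 3.0)
        zero = synthesize_map(refl, shape, coefficients="fo-fc", fc=refl)
        assert np.abs(zero.values).max() < 1e-9 * refl.f.max()
        two = synthesize_map(refl, shape, coefficients="2fo-fc", fc=refl)
        one = synthesize_map(refl, shape)
        assert map_correlation(two, one) > 1 - 1e-12

    def test_parseval(self, model_refl):
        _, refl = model_refl
        shape = grid_shape_for(CELL, 2.5, 3.0)
        grid = synthesize_map(refl, shape)
        # full-sphere sum: each stored index counts itself and its Friedel mate
        lhs = 2 * np.sum(refl.f ** 2)
        rho2 = np.mean(grid.values ** 2) * CELL.volume() ** 2
        assert rho2 == pytest.approx(lhs, rel=1e-6)

    def test_missing_phases_rejected(self, model_refl):
        _, refl = model_refl
        bad = refl.copy()
        bad.phase[0] = np.nan
        with pytest.raises(ValueError):
            synthesize_map(bad, grid_shape_for(CELL, 2.5, 3.0))

    def test_aliasing_guard(self, model_refl):
        _, refl = model_refl
        grid = synthesize_map(refl, grid_shape_for(CELL, 2.5, 3.0))
        with pytest.raises(ValueError):
            invert_map(grid, 0.9)


class TestPatterson:
    def test_centrosymmetric(self, model_refl):
        _, refl = model_refl
        pat = patterson_map(refl, d_min=2.5)
        v = pat.values
        flipped = np.roll(v[::-1, ::-1, ::-1], 1, axis=(0, 1, 2))
        assert np.abs(v - flipped).max() < 1e-8 * np.abs(v).max()

    def test_origin_peak_is_global_maximum(self, model_refl):
        _, refl = model_refl
        pat = patterson_map(refl, d_min=2.5)
        assert np.unravel_index(pat.values.argmax(), pat.shape) == (0, 0, 0)

    def test_two_atom_vector_peaks(self):
        cell = UnitCell(24, 24, 24)
        v = np.array([5.0, 3.0, 7.0])
        model = AtomicModel(["CA", "CA"], ["A", "A"], [1, 2], ["ALA"] * 2,
                            [[2.0, 2.0, 2.0], list(2.0 + v)],
                            b_iso=[25.0, 25.0], element=["C", "C"])
        refl = calc_structure_factors(model, cell, P1, d_min=2.5)
        pat = patterson_map(refl, d_min=2.5)
        # oracle: outside the origin peak, the strongest features must be the
        # interatomic vectors +/- v
        frac = pat.grid_frac_coords().reshape(-1, 3)
        frac = (frac + 0.5) % 1.0 - 0.5
        cart = cell.orthogonalize(frac)
        vals = pat.values.ravel().copy()
        vals[np.linalg.norm(cart, axis=1) < 3.0] = -np.inf
        top2 = cart[np.argsort(vals)[::-1][:2]]
        d = [min(np.linalg.norm(t - v), np.linalg.norm(t + v)) for t in top2]
        assert max(d) < 1.2  # within one voxel of +/- v


class TestMapUtilities:
    def test_correlation_trivials(self, model_refl):
        _, refl = model_refl
        grid = synthesize_map(refl, grid_shape_for(CELL, 2.5, 3.0))
        other = grid.copy()
        assert map_correlation(grid, other) == pytest.approx(1.0)
        other.values = -grid.values
        assert map_correlation(grid, other) == pytest.approx(-1.0)
        other.values = grid.values + 5.0
        assert map_correlation(grid, other) == pytest.approx(1.0)
        flat = grid.copy()
        flat.values = np.zeros_like(grid.values)
        with pytest.raises(ValueError):
            map_correlation(grid, flat)

    def test_interpolation_exact_at_nodes_and_linear_midpoints(self):
        vals = np.zeros((4, 4, 4))
        vals[1, 1, 1] = 1.0
        vals[2, 1, 1] = 3.0
        grid = MapGrid(UnitCell(4, 4, 4), vals)
        assert interpolate(grid, [[0.25, 0.25, 0.25]])[0] == pytest.approx(1.0)
        assert interpolate(grid, [[0.375, 0.25, 0.25]])[0] == pytest.approx(2.0)
        const = MapGrid(UnitCell(4, 4, 4), np.full((4, 4, 4), 7.5))
        assert interpolate(const, [[0.123, 0.77, 0.415]])[0] == pytest.approx(7.5)

    def test_low_pass_removes_high_frequencies(self):
        rng = np.random.default_rng(1)
        grid = MapGrid(UnitCell(40, 40, 40), rng.standard_normal((40, 40, 40)))
        out = low_pass(grid, resolution=8.0)
        F = np.fft.fftn(out.values)
        freqs = np.fft.fftfreq(40, d=1.0)
        sx, sy, sz = np.meshgrid(freqs, freqs, freqs, indexing="ij")
        s = np.sqrt(sx**2 + sy**2 + sz**2)
        assert np.abs(F[s > 1.0 / 8.0 + 1e-9]).max() < 1e-10 * np.abs(F).max()

    def test_ccp4_roundtrip(self, tmp_path, model_refl):
        _, refl = model_refl
        grid = synthesize_map(refl, grid_shape_for(CELL, 2.5, 3.0))
        path = tmp_path / "map.mrc"
        write_ccp4(grid, path)
        again = read_ccp4(path)
        assert again.shape == grid.shape
        assert again.cell.a == pytest.approx(CELL.a, abs=1e-4)
        # mode-2 float32 storage
        assert np.allclose(again.values, grid.values, atol=1e-5 * np.abs(grid.values).max())
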