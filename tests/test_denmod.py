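"""Density modification: masks, flattening, histogram matching, averaging, recombination."""

import math

import numpy as np
import pytest

from cyclophase import denmod as D
from cyclophase.fourier import MapGrid, calc_structure_factors, grid_shape_for
from cyclophase.models import cn_operators
from cyclophase.xtal import P1, P212121, ReflectionSet, UnitCell


class TestDMConfig:
    def test_defaults_are_the_reference_protocol(self):
        cfg = D.DMConfig()
        assert cfg.d_start == 7.9
        assert cfg.total_cycles == 104
        assert (cfg.solvent_mask_update_every, cfg.ncs_mask_update_every) == (50, 20)

    @pytest.mark.parametrize("kw", [
        dict(d_start=4.0, d_final=7.9),
        dict(solvent_mask_update_every=0),
        dict(solvent_fraction=1.5),
        dict(total_cycles=3, n_extension_steps=8),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            D.DMConfig(**kw)

    def test_extension_schedule_partitions_cycles(self):
        cfg = D.DMConfig(total_cycles=104, n_extension_steps=8)
        sched = D._extension_schedule(cfg, 4.0)
        assert sum(n for _, n in sched) == 104
        cuts = [d for d, _ in sched]
        assert cuts[0] == pytest.approx(7.9)   # hold block at the start
        assert all(a >= b for a, b in zip(cuts, cuts[1:]))  # non-increasing
        assert cuts[-1] == pytest.approx(4.0)
        # equal steps in 1/d across the extension blocks
        inv = np.diff([1 / d for d in cuts])
        assert np.allclose(inv, inv[0])


class TestMasks:
    def test_threshold_fraction(self, rng):
        grid = MapGrid(UnitCell(10, 10, 10), rng.standard_normal((12, 12, 12)))
        m = D.mask_from_em(grid, 0.25)
        assert m.values.mean() == pytest.approx(0.25, abs=0.01)
        assert set(np.unique(m.values)) <= {0.0, 1.0}

    def test_full_fraction_and_two_level(self):
        vals = np.zeros((8, 8, 8))
        vals[:4] = 1.0
        grid = MapGrid(UnitCell(8, 8, 8), vals)
        assert D.mask_from_em(grid, 1.0).values.mean() == 1.0
        half = D.mask_from_em(grid, 0.5)
        assert np.array_equal(half.values, vals)

    def test_constant_map_rejected(self):
        grid = MapGrid(UnitCell(8, 8, 8), np.ones((8, 8, 8)))
        with pytest.raises(ValueError):
            D.mask_from_em(grid, 0.5)

    def test_wedge_is_one_nth_and_tiles(self, rng):
        # cylindrical mask about z: the wedge must carve out 1/n of it
        cell = UnitCell(40, 40, 40)
        grid = MapGrid(cell, np.zeros((32, 32, 32)))
        frac = grid.grid_frac_coords().reshape(-1, 3)
        cart = cell.orthogonalize(frac)
        r = np.hypot(cart[:, 0] - 20, cart[:, 1] - 20)
        mask_vals = ((r > 5) & (r < 15) & (np.abs(cart[:, 2] - 20) < 8)).astype(float)
        mask = MapGrid(cell, mask_vals.reshape(32, 32, 32))
        for n in (2, 13):
            ops = cn_operators(n, [0, 0, 1], center=[20, 20, 20])
            w = D.wedge_mask(mask, ops)
            # voxel discretization broadens the wedge boundary
            assert w.values.sum() / mask.values.sum() == pytest.approx(1 / n, rel=0.2)
        with pytest.raises(ValueError):
            D.wedge_mask(mask, cn_operators(1, [0, 0, 1]))


class TestFlattenAndHistogram:
    def _map_and_mask(self, rng):
        grid = MapGrid(UnitCell(12, 12, 12), rng.standard_normal((10, 10, 10)))
        mask_vals = np.zeros((10, 10, 10))
        mask_vals[2:7, 2:7, 2:7] = 1.0
        return grid, MapGrid(UnitCell(12, 12, 12), mask_vals)

    def test_solvent_flatten(self, rng):
        grid, mask = self._map_and_mask(rng)
        out = D.solvent_flatten(grid, mask)
        solv = mask.values < 0.5
        # all solvent voxels share one value (variance at rounding level)
        assert out.values[solv].var() <= 1e-30
        assert np.array_equal(out.values[~solv], grid.values[~solv])
        again = D.solvent_flatten(out, mask)
        # idempotent up to the rounding of re-averaging identical values
        assert np.allclose(again.values, out.values, atol=1e-14)

    def test_histogram_match_reaches_reference(self, rng):
        grid, mask = self._map_and_mask(rng)
        ref = rng.gamma(2.0, 1.0, 4000)
        out = D.histogram_match(grid, mask, ref)
        sel = mask.values > 0.5
        got = np.sort(out.values[sel])
        want = np.quantile(ref, np.linspace(0, 1, len(got)))
        assert np.allclose(got, want, atol=np.ptp(ref) / 50)
        # rank order preserved exactly
        assert np.array_equal(np.argsort(grid.values[sel], kind="stable"),
                              np.argsort(out.values[sel], kind="stable"))

    def test_histogram_match_identity(self, rng):
        grid, mask = self._map_and_mask(rng)
        sel = mask.values > 0.5
        out = D.histogram_match(grid, mask, grid.values[sel])
        assert np.allclose(out.values[sel], grid.values[sel], atol=1e-9)

    def test_empty_protein_region_rejected(self, rng):
        grid, mask = self._map_and_mask(rng)
        empty = mask.copy()
        empty.values[:] = 0.0
        with pytest.raises(ValueError):
            D.histogram_match(grid, empty, np.arange(10.0))


def _symmetric_test_map(n=5):
    """A C5-symmetric density in a P1 box with its averaging mask and ops."""
    from cyclophase.models import expand_cn
    from cyclophase.synthetic import make_protomer
    from cyclophase.fourier import density_from_model

    prot = make_protomer(n_res=24, n_helices=2, seed=4)
    prot = prot.transformed(trans=np.array([12.0, 0.0, 0.0]))
    ring = expand_cn(prot, cn_operators(n, [0, 0, 1]))
    cell = UnitCell(60, 60, 60)
    ring = ring.transformed(trans=np.array([30.0, 30.0, 30.0]))
    grid = density_from_model(ring, cell, P1, (48, 48, 48))
    frac = grid.grid_frac_coords().reshape(-1, 3)
    cart = cell.orthogonalize(frac)
    r = np.hypot(cart[:, 0] - 30, cart[:, 1] - 30)
    mvals = ((r > 5) & (r < 20) & (np.abs(cart[:, 2] - 30) < 12)).astype(float)
    mask = MapGrid(cell, mvals.reshape(48, 48, 48))
    ops = cn_operators(n, [0, 0, 1], center=[30, 30, 30])
    return grid, mask, ops


class TestNcsAverage:
    def test_symmetric_map_is_fixed_point(self):
        grid, mask, ops = _symmetric_test_map()
        out, cc = D.ncs_average(grid, ops, mask)
        assert cc > 0.99
        sel = mask.values > 0.5
        diff = out.values[sel] - grid.values[sel]
        # interpolation leaves only small edge residuals
        assert np.sqrt((diff ** 2).mean()) < 0.05 * grid.values[sel].std()

    def test_averaging_reduces_independent_noise_nfold(self):
        grid, mask, ops = _symmetric_test_map()
        rng = np.random.default_rng(8)
        sigma = grid.values.std()
        noisy = grid.copy()
        noisy.values = grid.values + rng.normal(0, sigma, grid.shape)
        out, _ = D.ncs_average(noisy, ops, mask)
        sel = mask.values > 0.5
        resid_before = (noisy.values - grid.values)[sel].var()
        resid_after = (out.values - grid.values)[sel].var()
        n = ops.order
        assert resid_after < resid_before / n * 2.0  # ~n-fold, loose factor

    def test_random_map_has_no_ncs(self):
        grid, mask, ops = _symmetric_test_map()
        rng = np.random.default_rng(9)
        rand = grid.copy()
        rand.values = rng.standard_normal(grid.shape)
        _, cc = D.ncs_average(rand, ops, mask)
        assert abs(cc) < 0.1

    def test_scale_offset_invariance_of_cc(self):
        grid, mask, ops = _symmetric_test_map()
        _, cc1 = D.ncs_average(grid, ops, mask)
        scaled = grid.copy()
        scaled.values = 3.0 * grid.values + 11.0
        _, cc2 = D.ncs_average(scaled, ops, mask)
        assert cc1 == pytest.approx(cc2, abs=1e-9)


class TestPhaseRecombine:
    def _refl_pair(self, tiny_case, f_dm_from="truth"):
        refl = tiny_case.refl_truth
        obs = ReflectionSet(refl.cell, refl.sg, refl.hkl, refl.f)
        if f_dm_from == "truth":
            dm = refl.copy()
        else:
            from cyclophase.synthetic import make_protomer
            from cyclophase.fourier import calc_f_at

            other = make_protomer(n_res=180, n_helices=6, seed=55)
            other = other.transformed(trans=tiny_case.ring_center
                                      - other.centroid())
            fc = calc_f_at(other, refl.cell, refl.sg, refl.hkl)
            dm = ReflectionSet(refl.cell, refl.sg, refl.hkl, np.abs(fc), None,
                               np.degrees(np.angle(fc)) % 360.0)
        return obs, dm

    def test_perfect_agreement_gives_unit_fom(self, tiny_case):
        obs, dm = self._refl_pair(tiny_case, "truth")
        rec = D.phase_recombine(obs, dm)
        assert np.array_equal(rec.f, obs.f)          # amplitudes untouched
        assert np.array_equal(rec.phase, dm.phase)   # phases from the map
        assert rec.fom.min() > 0.99

    def test_unrelated_model_fom_is_low(self, tiny_case):
        obs, dm_t = self._refl_pair(tiny_case, "truth")
        _, dm_r = self._refl_pair(tiny_case, "random")
        fom_match = D.phase_recombine(obs, dm_t).fom.mean()
        fom_null = D.phase_recombine(obs, dm_r).fom.mean()
        assert fom_null < 0.55
        assert fom_null < 0.6 * fom_match

    def test_sigmaa_scheme_bounded(self, tiny_case):
        obs, dm = self._refl_pair(tiny_case, "random")
        rec = D.phase_recombine(obs, dm, weights="sigmaa")
        assert np.all((rec.fom >= 0) & (rec.fom <= 1))
        with pytest.raises(ValueError):
            D.phase_recombine(obs, dm, weights="nonsense")

    def test_index_mismatch_rejected(self, tiny_case):
        obs, dm = self._refl_pair(tiny_case, "truth")
        with pytest.raises(ValueError):
            D.phase_recombine(obs.select(obs.d > 5.0), dm)


class TestRunDM:
    def test_short_run_contract(self, tiny_case):
        cfg = D.DMConfig(total_cycles=6, n_extension_steps=2,
                         solvent_fraction=0.7, divergence_patience=1000)
        trace, final_map, refl_out = D.run_dm(
            tiny_case.refl_truth, cfg, tiny_case.em_map, tiny_case.ops_truth,
            tiny_case.em_to_crystal)
        # amplitudes are never modified by density modification
        assert np.array_equal(refl_out.f, tiny_case.refl_truth.f)
        assert len(trace.cycle) == 6
        assert all(a >= b for a, b in zip(trace.d_cut, trace.d_cut[1:]))
        assert np.all(np.isfinite(refl_out.phase))
        assert trace.final_ncs_cc > 0.8  # true phases stay strongly symmetric

    def test_missing_starting_phases_rejected(self, tiny_case):
        refl = tiny_case.refl_obs  # amplitudes only
        cfg = D.DMConfig(total_cycles=4, n_extension_steps=2)
        with pytest.raises(ValueError):
            D.run_dm(refl, cfg, tiny_case.em_map, tiny_case.ops_truth,
                     tiny_case.em_to_crystal)
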