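"""Density modification with EM-derived masks and cyclic NCS averaging.

The engine that turns a poor molecular-replacement map into an interpretable
one: iterate real-space expectations — flat solvent, an expected protein
density histogram, equivalence of the n NCS copies — and re-impose the
observed amplitudes in reciprocal space with Sim-weighted phase
recombination, while gradually extending the phased resolution from the
starting cutoff (default 7.9 A) down to the data limit.

Masks come from the cryo-EM side: the whole-complex mask (resampled into the
crystal through the placement transform) defines the solvent boundary; an
angular wedge of 360/n degrees of it is the asymmetric averaging unit. Both
are optionally re-derived from the evolving map on fixed cycle cadences
(defaults: solvent every 50 cycles, NCS mask every 20, total 104 cycles).

Amplitudes are never modified: density modification only updates phases and
figures of merit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from scipy.special import i0e, i1e

from .fourier import MapGrid, interpolate, map_correlation, synthesize_map
from .models import NCSOperatorSet
from .xtal import ReflectionSet

__all__ = [
    "DMConfig",
    "DMTrace",
    "Mask",
    "mask_from_em",
    "resample_to_crystal",
    "wedge_mask",
    "symmetry_expand_mask",
    "solvent_flatten",
    "histogram_match",
    "ncs_average",
    "phase_recombine",
    "run_dm",
    "DMDiverged",
]

Mask = MapGrid  # boolean-valued MapGrid (0/1)


class DMDiverged(RuntimeError):
    """NCS correlation fell for too many consecutive cycles; trace attached."""

    def __init__(self, message, trace):
        self.trace = trace
        super().__init__(message)


@dataclass
class DMConfig:
    """Protocol constants of the density-modification run.

    Defaults mirror the reference protocol: phase extension starting at
    7.9 A, solvent and averaging masks updated every 50 and 20 cycles, and a
    total of 104 cycles. ``n_extension_steps`` splits the extension into
    equal steps in 1/d; ``d_final`` of None means the data limit.
    """

    d_start: float = 7.9
    d_final: float | None = None
    total_cycles: int = 104
    solvent_mask_update_every: int = 50
    ncs_mask_update_every: int = 20
    solvent_fraction: float = 0.5
    n_extension_steps: int = 8
    weights: str = "sim"
    new_reflection_fom: float = 0.2
    histogram_matching: bool = True
    #: the averaging mask is fatter than the close-packed protein volume by
    #: this factor: a medium-resolution EM envelope includes a halo that the
    #: Matthews-based volume estimate misses
    mask_halo: float = 1.25
    reference_provider: object = None   # callable d_cut -> sample of densities
    divergence_patience: int = 10

    def __post_init__(self):
        if self.d_final is not None and self.d_start < self.d_final:
            raise ValueError("d_start must be >= d_final")
        if self.solvent_mask_update_every < 1 or self.ncs_mask_update_every < 1:
            raise ValueError("mask update cadences must be >= 1")
        if not 0.0 < self.solvent_fraction < 1.0:
            raise ValueError("solvent_fraction must be in (0, 1)")
        if self.total_cycles < self.n_extension_steps:
            raise ValueError("total_cycles must be >= n_extension_steps")


@dataclass
class DMTrace:
    """Per-cycle record of a density-modification run."""

    cycle: list = field(default_factory=list)
    d_cut: list = field(default_factory=list)
    ncs_cc: list = field(default_factory=list)
    mean_fom: list = field(default_factory=list)
    solvent_variance: list = field(default_factory=list)

    def append(self, cycle, d_cut, ncs_cc, mean_fom, solvent_variance):
        self.cycle.append(int(cycle))
        self.d_cut.append(float(d_cut))
        self.ncs_cc.append(float(ncs_cc))
        self.mean_fom.append(float(mean_fom))
        self.solvent_variance.append(float(solvent_variance))

    @property
    def final_ncs_cc(self) -> float:
        return self.ncs_cc[-1] if self.ncs_cc else float("nan")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            dict(cycle=self.cycle, d_cut=self.d_cut, ncs_cc=self.ncs_cc,
                 mean_fom=self.mean_fom, solvent_variance=self.solvent_variance)
        )


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def mask_from_em(em_map: MapGrid, target_volume_fraction: float) -> Mask:
    """Threshold an EM map so the mask covers exactly the target voxel fraction.

    The highest-density voxels are taken first. Raises on a constant map.
    """
    if not 0.0 < target_volume_fraction <= 1.0:
        raise ValueError("target_volume_fraction must be in (0, 1]")
    v = em_map.values
    if np.ptp(v) == 0:
        raise ValueError("cannot mask a constant map")
    if target_volume_fraction == 1.0:
        out = np.ones_like(v)
    else:
        thr = np.quantile(v, 1.0 - target_volume_fraction)
        out = (v > thr).astype(float)
    return MapGrid(em_map.cell, out, em_map.origin_frac.copy(), em_map.periodic)


def resample_to_crystal(grid_em: MapGrid, cell, shape, rot, trans) -> MapGrid:
    """Resample an EM-frame grid onto a crystal grid through a rigid transform.

    ``rot, trans`` carry EM-frame cartesian coordinates into the crystal
    frame; voxels mapping outside the EM box get 0.
    """
    rot = np.asarray(rot, dtype=float)
    trans = np.asarray(trans, dtype=float)
    out = MapGrid(cell, np.zeros(shape))
    frac = out.grid_frac_coords().reshape(-1, 3)
    # minimum image about the transformed EM-box center: the object may cross
    # the cell boundary, so each voxel picks the lattice translate of itself
    # closest to the ring
    center_frac = cell.fractionalize(trans)
    frac = frac - np.round(frac - center_frac)
    cart = cell.orthogonalize(frac)
    em_cart = (cart - trans) @ rot  # inverse rigid transform (rot orthogonal)
    em_frac = grid_em.cell.fractionalize(em_cart)
    inside = np.all((em_frac >= grid_em.origin_frac) &
                    (em_frac <= grid_em.origin_frac + 1.0 - 1.0 / np.array(grid_em.shape)),
                    axis=1)
    vals = np.zeros(len(frac))
    if inside.any():
        vals[inside] = interpolate(grid_em, em_frac[inside])
    out.values = vals.reshape(shape)
    return out


def symmetry_expand_mask(ring_mask: Mask, sg) -> Mask:
    """Union of a (crystal-frame) ring mask over all space-group copies."""
    shape = ring_mask.shape
    frac = ring_mask.grid_frac_coords().reshape(-1, 3)
    acc = np.zeros(len(frac))
    for rot, tran in sg.ops:
        img = frac @ np.asarray(rot, dtype=float).T + tran
        acc = np.maximum(acc, interpolate(ring_mask, img))
    out = ring_mask.copy()
    out.values = (acc.reshape(shape) > 0.5).astype(float)
    return out


def wedge_mask(full_mask: Mask, ops: NCSOperatorSet,
               reference_direction=(1.0, 0.0, 0.0)) -> Mask:
    """Angular wedge of 360/n degrees of a ring mask about the NCS axis.

    The wedge is the set of mask voxels whose azimuth about (axis, center)
    falls in [0, 360/n), measured from the projection of
    ``reference_direction`` onto the plane perpendicular to the axis. The n
    rotated copies of the wedge tile the full mask (overlap only at the
    angular boundaries).
    """
    n = ops.order
    if n < 2:
        raise ValueError("wedge requires NCS order >= 2")
    axis = np.asarray(ops.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ref = np.asarray(reference_direction, dtype=float)
    u1 = ref - (ref @ axis) * axis
    if np.linalg.norm(u1) < 1e-9:
        u1 = np.array([0.0, 1.0, 0.0]) - axis[1] * axis
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(axis, u1)
    cell = full_mask.cell
    sel = full_mask.values.reshape(-1) > 0.5
    frac = full_mask.grid_frac_coords().reshape(-1, 3)[sel]
    center = np.asarray(ops.center, dtype=float)
    frac = frac - np.round(frac - cell.fractionalize(center))  # minimum image
    v = cell.orthogonalize(frac) - center
    az = np.mod(np.arctan2(v @ u2, v @ u1), 2.0 * math.pi)
    inside = az < (2.0 * math.pi / n)
    out_vals = np.zeros(full_mask.values.size)
    idx = np.flatnonzero(sel)
    out_vals[idx[inside]] = 1.0
    out = full_mask.copy()
    out.values = out_vals.reshape(full_mask.shape)
    return out


# ---------------------------------------------------------------------------
# real-space modifications
# ---------------------------------------------------------------------------

def solvent_flatten(grid: MapGrid, protein_mask: Mask) -> MapGrid:
    """Set every voxel outside the protein mask to the solvent mean."""
    if grid.shape != protein_mask.shape:
        raise ValueError("mask grid mismatch")
    out = grid.copy()
    solvent = protein_mask.values < 0.5
    if solvent.any():
        out.values[solvent] = grid.values[solvent].mean()
    return out


def histogram_match(grid: MapGrid, protein_mask: Mask,
                    reference_values: np.ndarray) -> MapGrid:
    """Rank-preserving transform of protein-region densities to a reference CDF."""
    sel = protein_mask.values > 0.5
    if not sel.any():
        raise ValueError("empty protein region")
    ref = np.sort(np.asarray(reference_values, dtype=float).ravel())
    vals = grid.values[sel]
    order = np.argsort(vals, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(vals))
    q = ranks / max(len(vals) - 1, 1)
    matched = np.interp(q * (len(ref) - 1), np.arange(len(ref)), ref)
    out = grid.copy()
    out.values[sel] = matched
    return out


def ncs_average(grid: MapGrid, ops: NCSOperatorSet, ncs_mask: Mask,
                cc_mask: Mask | None = None, cc_max_voxels: int = 20000,
                order: int = 3):
    """Average each masked voxel over its n NCS images (periodic interpolation).

    Cubic-spline interpolation (default) keeps the repeated resampling from
    low-pass filtering the map, which matters when averaging is iterated many
    cycles. Returns ``(averaged_map, ncs_correlation)`` where the correlation
    is the mean pairwise Pearson correlation between the n images of the
    ``cc_mask`` voxels (default: the averaging mask itself) evaluated
    *before* averaging.
    """
    from scipy.ndimage import map_coordinates, spline_filter

    cell = grid.cell
    mode = "grid-wrap" if grid.periodic else "nearest"
    src = (spline_filter(grid.values, order=order, mode=mode)
           if order > 1 else grid.values)
    nvec = np.array(grid.shape)

    def sample(frac_pts):
        coords = ((frac_pts - grid.origin_frac) * nvec).T
        return map_coordinates(src, coords, order=order, mode=mode,
                               prefilter=False)

    # minimum-image unwrap about the ring center so rotations act on the
    # physically contiguous object, not on its wrapped lattice translates
    center_frac = cell.fractionalize(np.asarray(ops.center, dtype=float))
    sel = ncs_mask.values.reshape(-1) > 0.5
    frac = grid.grid_frac_coords().reshape(-1, 3)
    frac_sel = frac[sel] - np.round(frac[sel] - center_frac)
    cart = cell.orthogonalize(frac_sel)
    images = np.zeros((ops.order, int(sel.sum())))
    for k, op in enumerate(ops):
        images[k] = sample(cell.fractionalize(op.apply(cart)))
    out = grid.copy()
    out.values.reshape(-1)[sel] = images.mean(axis=0)

    # pairwise correlation on the cc region (subsampled deterministically)
    if cc_mask is not None and cc_mask is not ncs_mask:
        cc_sel = cc_mask.values.reshape(-1) > 0.5
        frac_cc = frac[cc_sel] - np.round(frac[cc_sel] - center_frac)
        cart_cc = cell.orthogonalize(frac_cc)
        imgs = np.zeros((ops.order, int(cc_sel.sum())))
        for k, op in enumerate(ops):
            imgs[k] = sample(cell.fractionalize(op.apply(cart_cc)))
    else:
        imgs = images
    if imgs.shape[1] > cc_max_voxels:
        imgs = imgs[:, :: int(np.ceil(imgs.shape[1] / cc_max_voxels))]
    centered = imgs - imgs.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    corr = (centered @ centered.T) / np.outer(norms, norms)
    n = ops.order
    iu = np.triu_indices(n, k=1)
    ncs_cc = float(corr[iu].mean()) if n > 1 else 1.0
    return out, ncs_cc


# ---------------------------------------------------------------------------
# reciprocal-space recombination
# ---------------------------------------------------------------------------

def _shell_bins(d: np.ndarray, n_shells: int = 15, min_per_shell: int = 10):
    """Resolution-shell assignment in s^2, merging shells that are too thin."""
    s2 = 1.0 / d ** 2
    edges = np.linspace(s2.min(), s2.max() * (1 + 1e-9), n_shells + 1)
    idx = np.clip(np.digitize(s2, edges) - 1, 0, n_shells - 1)
    # merge sparse shells into their lower-resolution neighbor
    for i in range(n_shells):
        if (idx == i).sum() < min_per_shell:
            idx[idx == i] = max(i - 1, 0)
    # re-label compactly
    labels = {v: j for j, v in enumerate(sorted(set(idx.tolist())))}
    return np.array([labels[v] for v in idx]), len(labels)


def phase_recombine(f_obs: ReflectionSet, f_dm: ReflectionSet,
                    n_shells: int = 15, weights: str = "sim") -> ReflectionSet:
    """Observed amplitudes + modified-map phases + figures of merit.

    The modified-map amplitudes are scaled to the observed ones per
    resolution shell; each reflection then receives a weight
    ``I1(X)/I0(X)`` with

    * ``weights="sim"``: ``X = 2 |Fo| |Fdm| / Sigma``, ``Sigma`` the shell
      mean of ``| |Fo|^2 - |Fdm|^2 |`` (unexplained intensity; classic Sim);
    * ``weights="sigmaa"``: ``X = 2 sA Eo Edm / (1 - sA^2)`` with normalized
      amplitudes E and the shell agreement ``sA = <Eo Edm>`` (less
      conservative when the modified amplitudes are systematically damped by
      masking and averaging).
    """
    if not np.array_equal(f_obs.hkl, f_dm.hkl):
        raise ValueError("f_obs and f_dm must share the same index order")
    if not np.all(np.isfinite(f_dm.phase)):
        raise ValueError("f_dm must be fully phased")
    d = f_obs.d
    idx, n_lab = _shell_bins(d, n_shells)
    fo = f_obs.f
    fdm = f_dm.f.copy()
    for i in range(n_lab):
        sel = idx == i
        denom = float((fdm[sel] ** 2).sum())
        scale = float((fo[sel] * fdm[sel]).sum()) / denom if denom > 0 else 1.0
        fdm[sel] *= scale
    if weights == "sim":
        sigma = np.ones_like(fo)
        resid = np.abs(fo ** 2 - fdm ** 2)
        for i in range(n_lab):
            sel = idx == i
            sigma[sel] = max(float(resid[sel].mean()), 1e-30)
        X = 2.0 * fo * fdm / sigma
    elif weights == "sigmaa":
        eo = fo.copy()
        ec = fdm.copy()
        sa = np.ones_like(fo)
        for i in range(n_lab):
            sel = idx == i
            mo = math.sqrt(max(float((fo[sel] ** 2).mean()), 1e-30))
            mc = math.sqrt(max(float((fdm[sel] ** 2).mean()), 1e-30))
            eo[sel] = fo[sel] / mo
            ec[sel] = fdm[sel] / mc
            sa[sel] = np.clip(float((eo[sel] * ec[sel]).mean()), 0.0, 0.995)
        X = 2.0 * sa * eo * ec / np.maximum(1.0 - sa ** 2, 1e-3)
    else:
        raise ValueError(f"unknown weighting scheme {weights!r}")
    fom = i1e(X) / i0e(X)   # exponentially-scaled ratio == I1/I0, stable
    return ReflectionSet(f_obs.cell, f_obs.sg, f_obs.hkl.copy(), fo.copy(),
                         f_obs.sigma.copy(), f_dm.phase.copy(), fom)


# ---------------------------------------------------------------------------
# the DM driver
# ---------------------------------------------------------------------------

def _read_f_at(values: np.ndarray, hkl: np.ndarray, volume: float) -> np.ndarray:
    """Complex F at given indices from a real-space map (one forward FFT)."""
    F = np.fft.ifftn(values) * volume
    shape = values.shape
    lin = ((hkl[:, 0] % shape[0]) * shape[1] + hkl[:, 1] % shape[1]) * shape[2] \
        + hkl[:, 2] % shape[2]
    return F.ravel()[lin]


def _read_f_symmetrized(values: np.ndarray, hkl: np.ndarray, cell,
                        sg) -> np.ndarray:
    """Crystal-symmetry-averaged F at unique indices.

    NCS averaging modifies one ring; its symmetry copies are reconstituted
    here in reciprocal space: for a symmetric map F(h R_s) = F(h)
    exp(-2 pi i h.tau_s), so averaging F_P1(h R_s) exp(+2 pi i h.tau_s) over
    the operators projects the modified map onto the crystal-symmetric
    subspace (equivalent to real-space symmetrization, at FFT cost).
    """
    F = np.fft.ifftn(values) * cell.volume()
    shape = values.shape
    out = np.zeros(len(hkl), dtype=complex)
    for rot, tran in sg.ops:
        h_img = hkl @ np.asarray(rot, dtype=int)
        lin = ((h_img[:, 0] % shape[0]) * shape[1] + h_img[:, 1] % shape[1]) \
            * shape[2] + h_img[:, 2] % shape[2]
        out += F.ravel()[lin] * np.exp(2j * math.pi * (hkl @ np.asarray(tran)))
    return out / sg.n_ops


def _extension_schedule(config: DMConfig, d_final: float):
    """(d_cut, n_cycles) pairs: equal steps in 1/d, cycles split evenly.

    The first block holds at ``d_start`` so the real-space constraints can
    consolidate the starting phases before any new shell is admitted; the
    remaining blocks extend to ``d_final``.
    """
    n = max(config.n_extension_steps, 1)
    if config.d_start <= d_final:
        return [(d_final, config.total_cycles)]
    inv = np.linspace(1.0 / config.d_start, 1.0 / d_final, n + 1)
    cuts = 1.0 / inv  # includes the hold block at d_start
    base = config.total_cycles // (n + 1)
    extra = config.total_cycles - base * (n + 1)
    out = []
    for i, d_cut in enumerate(cuts):
        out.append((float(d_cut), base + (1 if i >= (n + 1) - extra else 0)))
    return out


def _update_ring_mask(avg_map: MapGrid, old_ring: Mask, fraction: float) -> Mask:
    """Re-derive the ring mask from the current map near the previous mask."""
    spacing = float(np.mean(avg_map.pixel_size))
    smoothed = gaussian_filter(avg_map.values, sigma=max(2.0 / spacing, 1.0),
                               mode="wrap")
    region = binary_dilation(old_ring.values > 0.5, iterations=2)
    n_target = int(round(fraction * avg_map.values.size))
    vals = np.where(region, smoothed, -np.inf)
    flat = np.argsort(vals.ravel())[::-1][:n_target]
    out_vals = np.zeros(avg_map.values.size)
    out_vals[flat] = 1.0
    out = old_ring.copy()
    out.values = out_vals.reshape(avg_map.shape)
    return out


def run_dm(refl: ReflectionSet, config: DMConfig, em_map: MapGrid,
           ops: NCSOperatorSet, em_to_crystal, grid_shape=None,
           verbose: bool = False):
    """Run the full density-modification / phase-extension protocol.

    Parameters
    ----------
    refl
        Observed amplitudes to the final resolution; phases (and FOMs) must
        be present for reflections with d >= ``config.d_start`` (the starting
        phase set, e.g. from the placed partial model). Amplitudes are never
        altered.
    em_map
        EM-frame density of the isolated ring; thresholded into the solvent
        and averaging masks after resampling through ``em_to_crystal``
        (rot, trans).
    ops
        Crystal-frame Cn operator set (axis + center from the placement).

    Returns ``(trace, final_map, refl_out)``; raises :class:`DMDiverged` if
    the NCS correlation decreases for ``config.divergence_patience``
    consecutive cycles.
    """
    cell, sg = refl.cell, refl.sg
    d_final = config.d_final if config.d_final is not None else refl.d_min
    from .fourier import grid_shape_for

    shape = grid_shape if grid_shape is not None else grid_shape_for(cell, d_final, 3.0)
    d_all = refl.d
    start_mask = d_all >= config.d_start - 1e-9
    if not np.all(np.isfinite(refl.phase[start_mask])):
        raise ValueError("starting phases must cover every reflection with "
                         f"d >= {config.d_start} A")

    phase = refl.phase.copy()
    fom = np.where(np.isfinite(refl.fom), refl.fom, 1.0)
    fom[~start_mask] = 0.0
    z = sg.n_ops
    ring_fraction = min(config.mask_halo * (1.0 - config.solvent_fraction) / z,
                        0.9 / z)

    # EM density resampled into the crystal frame -> initial masks
    rot, trans = em_to_crystal
    em_on_crystal = resample_to_crystal(em_map, cell, shape, rot, trans)
    ring_mask = mask_from_em(em_on_crystal, ring_fraction)
    protein_mask = symmetry_expand_mask(ring_mask, sg)
    wedge = wedge_mask(ring_mask, ops)

    trace = DMTrace()
    drop_streak = 0
    cycle = 0
    admitted = start_mask.copy()
    for d_cut, n_cycles in _extension_schedule(config, d_final):
        step_best = -np.inf  # divergence is judged within one extension step
        new = (~admitted) & (d_all >= d_cut - 1e-9)
        if new.any():
            # newly admitted reflections: keep externally supplied phases if
            # any; otherwise phase them from the current map
            have = new & np.isfinite(refl.phase)
            need = new & ~np.isfinite(refl.phase)
            phase[have] = refl.phase[have]
            fom[have] = np.where(np.isfinite(refl.fom[have]), refl.fom[have], 1.0)
            if need.any():
                current = ReflectionSet(cell, sg, refl.hkl[admitted],
                                        refl.f[admitted], None,
                                        phase[admitted], fom[admitted])
                rho = synthesize_map(current, shape, use_fom=True)
                f_new = _read_f_symmetrized(rho.values, refl.hkl[need], cell, sg)
                phase[need] = np.degrees(np.angle(f_new)) % 360.0
                fom[need] = config.new_reflection_fom
            admitted |= new
        sel = admitted
        hkl_act = refl.hkl[sel]
        fo_act = refl.f[sel]
        for _ in range(n_cycles):
            cycle += 1
            work = ReflectionSet(cell, sg, hkl_act, fo_act, None,
                                 phase[sel], fom[sel])
            rho = synthesize_map(work, shape, use_fom=True)
            solv_var = float(rho.values[protein_mask.values < 0.5].var())
            rho = solvent_flatten(rho, protein_mask)
            if config.histogram_matching:
                if config.reference_provider is not None:
                    ref_vals = np.asarray(config.reference_provider(d_cut)).ravel()
                else:
                    # fall back to the EM density histogram inside the ring
                    ref_vals = em_on_crystal.values[ring_mask.values > 0.5]
                    cur = rho.values[protein_mask.values > 0.5]
                    ref_vals = (ref_vals - ref_vals.mean()) / max(ref_vals.std(), 1e-12)
                    ref_vals = ref_vals * cur.std() + cur.mean()
                rho = histogram_match(rho, protein_mask, ref_vals)
            rho, ncs_cc = ncs_average(rho, ops, ring_mask, cc_mask=wedge)
            f_dm_c = _read_f_symmetrized(rho.values, hkl_act, cell, sg)
            f_dm = ReflectionSet(cell, sg, hkl_act, np.abs(f_dm_c), None,
                                 np.degrees(np.angle(f_dm_c)) % 360.0)
            rec = phase_recombine(ReflectionSet(cell, sg, hkl_act, fo_act), f_dm,
                                  weights=config.weights)
            phase[sel] = rec.phase
            fom[sel] = rec.fom
            trace.append(cycle, d_cut, ncs_cc, float(fom[sel].mean()), solv_var)
            if verbose:
                print(f"cycle {cycle:3d} d={d_cut:5.2f} ncs_cc={ncs_cc:.4f} "
                      f"<fom>={fom[sel].mean():.3f}")
            # divergence guard: a material, persistent fall below the best
            # correlation seen at this resolution step (small drifts right
            # after admitting a new shell are part of normal convergence)
            step_best = max(step_best, ncs_cc)
            if ncs_cc < step_best - 0.02:
                drop_streak += 1
                if drop_streak >= config.divergence_patience:
                    raise DMDiverged(
                        f"NCS correlation fell below its running maximum for "
                        f"{drop_streak} consecutive cycles (cycle {cycle})",
                        trace)
            else:
                drop_streak = 0

            # mask updates on their cadences
            if cycle % config.ncs_mask_update_every == 0:
                wedge = wedge_mask(ring_mask, ops)
            if cycle % config.solvent_mask_update_every == 0:
                ring_mask = _update_ring_mask(rho, ring_mask, ring_fraction)
                protein_mask = symmetry_expand_mask(ring_mask, sg)
                wedge = wedge_mask(ring_mask, ops)

    refl_out = ReflectionSet(cell, sg, refl.hkl.copy(), refl.f.copy(),
                             refl.sigma.copy(), phase, fom)
    # reflections beyond the final cutoff (if d_final > data limit) stay
    # unphased; the final map is built from the phased set
    final_map = synthesize_map(refl_out.select(admitted), shape, use_fom=True)
    return trace, final_map, refl_out
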