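"""Synthetic Cn-ring "crystals" with fully known ground truth.

Generates desk-scale fixtures that emulate a portal-protein-like case: a
cyclic ring of alpha-helical polyalanine protomers placed in a P2₁2₁2₁ cell
with its symmetry axis in the ac plane, observed structure-factor amplitudes
computed from the ground-truth model, an EM-style map of the isolated ring at
a stated resolution and pixel size (optionally dilated by a magnification
error), and a partial model covering a stated fraction of the residues.

Shape realism is not a goal: protomers are seeded bundles of ideal helices.
What matters is that symmetry order, ring dimensions, partial-model fraction,
resolution limits and the magnification error are all exactly known, so every
downstream stage (self-rotation, placement, rigid-body, density modification)
can be validated quantitatively.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import fourier
from .fourier import MapGrid
from .models import (AtomicModel, NCSOperatorSet, cn_operators, expand_cn,
                     rescale_magnification, rotation_about_axis)
from .xtal import P212121, ReflectionSet, SpaceGroup, UnitCell

__all__ = [
    "SyntheticCase",
    "make_helix",
    "make_protomer",
    "make_ring_case",
    "simulate_em_map",
    "axis_from_angles",
    "PRESETS",
    "make_preset",
    "write_case",
]

# helix geometry constants (ideal alpha helix)
_RISE = 1.5          # A per residue along the helix axis
_TWIST = 100.0       # degrees per residue
_CA_RADIUS = 2.3     # A


def axis_from_angles(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Unit vector at polar angle theta from +z (the c axis) and azimuth phi from +x."""
    t, p = math.radians(theta_deg), math.radians(phi_deg)
    return np.array([math.sin(t) * math.cos(p), math.sin(t) * math.sin(p), math.cos(t)])


def make_helix(n_res: int, start=(0.0, 0.0, 0.0), direction=(0.0, 0.0, 1.0),
               chain: str = "A", res_start: int = 1, phase_deg: float = 0.0,
               b_iso: float = 60.0) -> AtomicModel:
    """Ideal polyalanine alpha-helix (atoms N, CA, C, O, CB per residue).

    CA atoms lie on a helix of radius 2.3 A with 1.5 A rise and 100 deg twist
    per residue; the other backbone atoms are placed at fixed offsets in the
    same helical parametrization (adequate at the >= 4 A resolutions this
    package targets). ``direction`` orients the helix axis; ``start`` is the
    position of the axis point of the first residue.
    """
    if n_res < 4:
        raise ValueError("a helix needs at least 4 residues")
    direction = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise ValueError("helix direction must be nonzero")
    direction = direction / nrm

    # atom placement in helix-local cylindrical coordinates:
    # (residue-offset dt, radius, extra z) per atom type
    atom_params = {
        "N": (-0.35, 1.60, 0.0),
        "CA": (0.00, _CA_RADIUS, 0.0),
        "C": (0.42, 1.65, 0.0),
        "O": (0.50, 2.10, 0.6),
        "CB": (0.05, 3.30, -0.5),
    }
    local = []
    names = []
    res_seq = []
    for i in range(n_res):
        for nm, (dt, rad, dz) in atom_params.items():
            t = i + dt
            ang = math.radians(_TWIST * t + phase_deg)
            local.append([rad * math.cos(ang), rad * math.sin(ang), _RISE * t + dz])
            names.append(nm)
            res_seq.append(res_start + i)
    local = np.array(local)

    # rotate local +z onto the requested direction (minimal rotation)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, direction)
    s = np.linalg.norm(v)
    c = float(z @ direction)
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else rotation_about_axis([1, 0, 0], math.pi)
    else:
        rot = rotation_about_axis(v / s, math.atan2(s, c))
    xyz = local @ rot.T + np.asarray(start, dtype=float)

    n_atoms = len(names)
    elements = [nm[0] for nm in names]
    return AtomicModel(names, [chain] * n_atoms, res_seq, ["ALA"] * n_atoms,
                       xyz, b_iso=np.full(n_atoms, b_iso), element=elements)


def _default_helix_lengths(n_res: int, n_helices: int, rng) -> list:
    """Deterministic helix lengths summing to n_res (longest first)."""
    base = n_res // n_helices
    lengths = [base] * n_helices
    for i in range(n_res - base * n_helices):
        lengths[i % n_helices] += 1
    # de-uniformize deterministically: move residues between pairs
    for i in range(n_helices // 2):
        shift = int(rng.integers(1, max(base // 3, 2)))
        if lengths[i] + shift >= 6 and lengths[-1 - i] - shift >= 6:
            lengths[i] += shift
            lengths[-1 - i] -= shift
    return sorted(lengths, reverse=True)


def make_protomer(n_res: int = 134, n_helices: int = 9, seed: int = 0,
                  helix_lengths=None, b_iso: float = 60.0) -> AtomicModel:
    """Seeded bundle of helices, centered at the origin, long axes near z.

    The bundle occupies a slab roughly (x: radial) x (y: tangential) suited to
    sit at a ring radius; helix positions and tilts come from the seed, so the
    protomer is reproducible and has no internal symmetry.
    """
    rng = np.random.default_rng(seed)
    if helix_lengths is None:
        helix_lengths = _default_helix_lengths(n_res, n_helices, rng)
    if sum(helix_lengths) != n_res:
        raise ValueError("helix lengths must sum to n_res")
    # 3 x ceil(n/3) raster in the (x, y) plane
    cols = 3
    pitch = 7.0
    parts = []
    res_at = 1
    for j, L in enumerate(helix_lengths):
        gx = (j % cols - 1) * pitch + rng.uniform(-1.5, 1.5)
        gy = (j // cols - (len(helix_lengths) - 1) // (2 * cols)) * pitch + rng.uniform(-1.5, 1.5)
        gz = -L * _RISE / 2.0 + rng.uniform(-3.0, 3.0)
        # varied tilts (as in real helix bundles) avoid a spurious common
        # helical pseudo-period along the ring axis
        tilt = math.radians(rng.uniform(5, 38))
        az = rng.uniform(0, 2 * math.pi)
        direction = np.array([math.sin(tilt) * math.cos(az),
                              math.sin(tilt) * math.sin(az),
                              math.cos(tilt)])
        if j % 2 == 1:
            direction = -direction  # antiparallel packing
            gz = -gz + L * _RISE * direction[2]
        h = make_helix(L, start=(gx, gy, gz), direction=direction, chain="A",
                       res_start=res_at, phase_deg=float(rng.uniform(0, 360)),
                       b_iso=b_iso)
        parts.append(h)
        res_at += L
    prot = AtomicModel.concat(parts)
    return prot.transformed(trans=-prot.centroid())


def _partial_helices(helix_lengths, fraction: float, rng) -> list:
    """Indices of helices whose total residue count best matches the fraction.

    Exhaustive over all subsets (few helices), so the delivered fraction is
    as close to the request as the helix granularity allows. Ties prefer
    fewer, longer helices — emulating a model builder who traces the longest,
    clearest helices first.
    """
    m = len(helix_lengths)
    target = fraction * sum(helix_lengths)
    best = None
    for bits in range(1, 1 << m):
        idx = [j for j in range(m) if bits >> j & 1]
        total = sum(helix_lengths[j] for j in idx)
        key = (abs(total - target), -sum(helix_lengths[j] ** 2 for j in idx),
               tuple(idx))
        if best is None or key < best[0]:
            best = (key, idx)
    return sorted(best[1])


def _min_contact(frac_sets, cell: UnitCell) -> float:
    """Minimum-image distance between the first copy and the others (A)."""
    M = cell.orthogonalization
    base = frac_sets[0]
    best = math.inf
    for other in frac_sets[1:]:
        diff = base[:, None, :] - other[None, :, :]
        diff -= np.round(diff)
        cart = diff @ M.T
        best = min(best, float(np.sqrt((cart ** 2).sum(axis=2).min())))
    return best


def _pack_ring(ring: AtomicModel, ext, cell_padding: float, sg, seed: int,
               min_contact: float = 3.2, max_inflate: int = 4):
    """Find a cell and ring center where the symmetry copies do not clash.

    Searches a seeded set of candidate center positions (period 1/2 in each
    fractional coordinate because of the allowed origin shifts), inflating
    the cell in steps if no clash-free position exists at the current size.
    """
    ca = ring.xyz[ring.ca_mask()][::3]
    rng = np.random.default_rng(seed + 101)
    for inflate in range(max_inflate + 1):
        pad = cell_padding * (1.0 + 0.35 * inflate)
        cell = UnitCell(ext[0] + pad, ext[1] + 1.35 * pad, ext[2] + 1.7 * pad)
        frac0 = cell.fractionalize(ca)
        cands = np.vstack([
            np.array([[0.27, 0.26, 0.28]]),
            rng.uniform(0.0, 0.5, size=(40, 3)),
        ])
        best = (-math.inf, None)
        for cand in cands:
            sets = []
            for r, t in sg.ops:
                sets.append((frac0 + cand) @ np.asarray(r, float).T + t)
            d = _min_contact(sets, cell)
            if d > best[0]:
                best = (d, cand)
            if d >= min_contact + 1.0:
                break
        if best[0] >= min_contact:
            return cell, best[1]
    return cell, best[1]  # best effort (documented: dense packing)


def simulate_em_map(model: AtomicModel, resolution: float, box: float,
                    pixel_size: float) -> MapGrid:
    """EM-style density of an isolated model: Gaussian atoms low-passed.

    The model is rendered in a non-periodic cubic box of edge ``box`` A
    centered on the coordinate origin, sampled at ``pixel_size`` A/voxel, and
    Fourier-filtered to ``resolution`` with a cosine edge.
    """
    if resolution <= 2.0 * pixel_size:
        raise ValueError("resolution must exceed twice the pixel size (Nyquist)")
    n = int(round(box / pixel_size))
    box = n * pixel_size  # exact integral grid
    half = box / 2.0
    ext = model.xyz.min(axis=0), model.xyz.max(axis=0)
    if np.any(ext[0] < -half + 2) or np.any(ext[1] > half - 2):
        raise ValueError("box too small for the model")
    from .xtal import P1

    cell = UnitCell(box, box, box)
    shifted = model.transformed(trans=np.array([half, half, half]))
    grid = fourier.density_from_model(shifted, cell, P1, (n, n, n), periodic=False)
    grid = fourier.low_pass(grid, resolution)
    grid.origin_frac = np.array([-0.5, -0.5, -0.5])
    grid.periodic = False
    return grid


@dataclass
class SyntheticCase:
    """A fully known ring crystal plus its EM-side inputs.

    ``truth_model`` lives in the crystal frame; ``em_*`` objects live in the
    EM frame (ring axis along z, centered at the origin, coordinates scaled
    by ``mag_error``). ``em_to_crystal`` is the ground-truth rigid transform
    (rot, trans) carrying ideal (unscaled) EM-frame coordinates into the
    crystal frame.
    """

    n: int
    cell: UnitCell
    sg: SpaceGroup
    truth_model: AtomicModel
    refl_obs: ReflectionSet          # amplitudes (noise per noise_level)
    refl_truth: ReflectionSet        # noiseless amplitudes + true phases
    em_map: MapGrid
    em_pixel_size: float
    em_resolution: float
    partial_model_em: AtomicModel    # partial ring, EM frame (mag_error applied)
    em_model: AtomicModel            # full ring, EM frame (mag_error applied)
    ops_truth: NCSOperatorSet        # crystal frame
    axis_theta: float
    axis_phi: float
    ring_center: np.ndarray          # crystal frame, cartesian
    em_to_crystal: tuple             # (rot 3x3, trans 3)
    mag_error: float
    partial_fraction_delivered: float
    d_min: float
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def axis(self) -> np.ndarray:
        return axis_from_angles(self.axis_theta, self.axis_phi)

    def truth_map(self, rate: float = 3.0) -> MapGrid:
        shape = fourier.grid_shape_for(self.cell, self.refl_truth.d_min, rate)
        return fourier.synthesize_map(self.refl_truth, shape)


def make_ring_case(n: int = 13, n_res: int = 134, n_helices: int = 9,
                   ring_radius: float = 40.0, cell_padding: float = 18.0,
                   axis_theta: float = 70.0, axis_phi: float = 0.0,
                   partial_fraction: float = 0.36, noise_level: float = 0.0,
                   mag_error: float = 1.0, em_resolution: float = 7.8,
                   em_pixel_size: float = 1.37, d_min: float = 4.0,
                   seed: int = 7) -> SyntheticCase:
    """Build a complete synthetic Cn ring crystal (see module docstring).

    ``noise_level`` is the relative sigma of multiplicative Gaussian amplitude
    noise (0 = noiseless); ``mag_error`` dilates the EM-frame objects, modeling
    a pixel-size miscalibration (e.g. 1.42/1.37).
    """
    if n < 1:
        raise ValueError("ring order must be >= 1")  # n=1: no-NCS null fixture
    if not 0.0 < partial_fraction <= 1.0:
        raise ValueError("partial_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)

    protomer = make_protomer(n_res=n_res, n_helices=n_helices, seed=seed)
    helix_lengths = _default_helix_lengths(n_res, n_helices,
                                           np.random.default_rng(seed))
    protomer = protomer.transformed(trans=np.array([ring_radius, 0.0, 0.0]))
    ops_em = cn_operators(n, axis=[0, 0, 1], center=[0, 0, 0])
    ring_em = expand_cn(protomer, ops_em)  # ideal EM frame (no mag error)

    # ---- crystal frame ----------------------------------------------------
    axis = axis_from_angles(axis_theta, axis_phi)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    s = np.linalg.norm(v)
    rot = (np.eye(3) if s < 1e-12 else
           rotation_about_axis(v / s, math.atan2(s, float(z @ axis))))
    ring_rot = ring_em.transformed(rot=rot)
    sg = P212121
    # choose cell size and ring position so the four symmetry copies pack
    # without steric clash (real ring crystals interleave; an arbitrary
    # placement interpenetrates)
    ext = ring_rot.xyz.max(axis=0) - ring_rot.xyz.min(axis=0)
    cell, center_frac = _pack_ring(ring_rot, ext, cell_padding, sg, seed)
    center = cell.orthogonalize(center_frac)
    truth = ring_rot.transformed(trans=center)
    ops_truth = cn_operators(n, axis=axis, center=center)

    refl_truth = fourier.calc_structure_factors(truth, cell, sg, d_min=d_min)
    f_obs = refl_truth.f.copy()
    if noise_level > 0:
        f_obs = np.clip(f_obs * (1.0 + noise_level * rng.standard_normal(len(f_obs))),
                        0.0, None)
    refl_obs = ReflectionSet(cell, sg, refl_truth.hkl.copy(), f_obs,
                             sigma=noise_level * refl_truth.f)

    # ---- EM side (with magnification error) -------------------------------
    em_model = (ring_em if mag_error == 1.0 else
                rescale_magnification(ring_em, mag_error, center=[0, 0, 0]))
    chosen = _partial_helices(helix_lengths, partial_fraction, rng)
    res_ranges = []
    at = 1
    for j, L in enumerate(helix_lengths):
        if j in chosen:
            res_ranges.append((at, at + L - 1))
        at += L
    keep = np.zeros(len(protomer), dtype=bool)
    for lo, hi in res_ranges:
        keep |= (protomer.res_seq >= lo) & (protomer.res_seq <= hi)
    partial_protomer = protomer.select(keep)
    partial_em = expand_cn(partial_protomer, ops_em)
    if mag_error != 1.0:
        partial_em = rescale_magnification(partial_em, mag_error, center=[0, 0, 0])
    delivered = partial_protomer.n_residues / protomer.n_residues

    ring_extent = 2.0 * np.abs(em_model.xyz).max() + 24.0
    box = max(ring_extent, 2.0 * em_resolution * 4)
    em_map = simulate_em_map(em_model, em_resolution, box, em_pixel_size)

    return SyntheticCase(
        n=n, cell=cell, sg=sg, truth_model=truth,
        refl_obs=refl_obs, refl_truth=refl_truth,
        em_map=em_map, em_pixel_size=em_pixel_size, em_resolution=em_resolution,
        partial_model_em=partial_em, em_model=em_model,
        ops_truth=ops_truth, axis_theta=axis_theta, axis_phi=axis_phi,
        ring_center=center, em_to_crystal=(rot, center), mag_error=mag_error,
        partial_fraction_delivered=delivered, d_min=d_min, seed=seed,
        params=dict(n=n, n_res=n_res, n_helices=n_helices,
                    ring_radius=ring_radius, cell_padding=cell_padding,
                    axis_theta=axis_theta, axis_phi=axis_phi,
                    partial_fraction=partial_fraction, noise_level=noise_level,
                    mag_error=mag_error, em_resolution=em_resolution,
                    em_pixel_size=em_pixel_size, d_min=d_min, seed=seed),
    )


#: Named generator presets. "portal" mirrors the full-size system (C13 ring,
#: ~180 A diameter, 536-residue protomer, 7.8 A EM map at 1.37 A/pixel);
#: "portal-mini" is the scaled-down variant (diameter ~90 A, 134-residue
#: protomer) used by the test suite; "c12-mini" is the dodecameric analog.
PRESETS = {
    "portal": dict(n=13, n_res=536, n_helices=9, ring_radius=75.0, d_min=3.74,
                   em_resolution=7.8, em_pixel_size=1.37, partial_fraction=0.36),
    "portal-mini": dict(n=13, n_res=134, n_helices=9, ring_radius=40.0, d_min=4.0,
                        em_resolution=7.8, em_pixel_size=1.37, partial_fraction=0.36),
    "c12-mini": dict(n=12, n_res=134, n_helices=9, ring_radius=40.0, d_min=4.0,
                     em_resolution=7.8, em_pixel_size=1.37, partial_fraction=0.36),
}


def make_preset(name: str, seed: int = 7, **overrides) -> SyntheticCase:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return make_ring_case(seed=seed, **kw)


def write_case(case: SyntheticCase, out_dir) -> dict:
    """Write truth.pdb, partial.pdb, data.hkl, em.mrc and case.json; returns manifest."""
    import os

    from .models import write_pdb
    from .xtal import write_hkl

    os.makedirs(out_dir, exist_ok=True)
    paths = {k: os.path.join(out_dir, v) for k, v in
             dict(truth="truth.pdb", partial="partial.pdb", data="data.hkl",
                  em="em.mrc", meta="case.json").items()}
    write_pdb(case.truth_model, paths["truth"])
    write_pdb(case.partial_model_em, paths["partial"])
    write_hkl(case.refl_obs, paths["data"])
    fourier.write_ccp4(case.em_map, paths["em"])
    with open(paths["meta"], "w") as fh:
        json.dump(dict(case.params,
                       partial_fraction_delivered=case.partial_fraction_delivered,
                       ring_center=list(map(float, case.ring_center)),
                       cell=[case.cell.a, case.cell.b, case.cell.c,
                             case.cell.alpha, case.cell.beta, case.cell.gamma]),
                  fh, indent=1, sort_keys=True)
    return paths
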