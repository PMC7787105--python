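"""FFT crystallography substrate: maps, structure factors, Patterson, correlation.

Conventions used throughout the package:

* ``F(h) = integral rho(x) exp(+2 pi i h.x) dV`` with x fractional, so an atom
  at fractional position t contributes ``f exp(2 pi i h.t)``.
* Map synthesis is the inverse sum ``rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x)``.
* F(000) is excluded everywhere; crystal maps are mean-zero by construction.
* Crystal maps wrap periodically; EM box maps do not.

Atomic scattering uses the International-Tables 4-Gaussian-plus-constant
coefficients (taken from gemmi's element tables at import time), applied as
isotropic Gaussians in real space with the atomic B added to each term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .models import AtomicModel
from .xtal import ReflectionSet, SpaceGroup, UnitCell, generate_unique_hkl, unique_hkl

__all__ = [
    "MapGrid",
    "grid_shape_for",
    "density_from_model",
    "calc_structure_factors",
    "synthesize_map",
    "invert_map",
    "patterson_map",
    "map_correlation",
    "interpolate",
    "low_pass",
    "read_ccp4",
    "write_ccp4",
]


# ---------------------------------------------------------------------------
# Map container
# ---------------------------------------------------------------------------

@dataclass
class MapGrid:
    """Real-space scalar field on a 3D grid over a unit cell or an EM box.

    ``values[i, j, k]`` sits at fractional coordinate
    ``origin_frac + (i/nx, j/ny, k/nz)``. Crystal maps are periodic; EM box
    maps are not and carry an explicit pixel size through their box cell.
    """

    cell: UnitCell
    values: np.ndarray
    origin_frac: np.ndarray = field(default_factory=lambda: np.zeros(3))
    periodic: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("map grid must be 3D with every dimension >= 2")
        self.origin_frac = np.asarray(self.origin_frac, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def pixel_size(self) -> np.ndarray:
        """Grid spacing along each cell axis (A per voxel)."""
        n = np.array(self.shape, dtype=float)
        return np.array([self.cell.a, self.cell.b, self.cell.c]) / n

    def copy(self) -> "MapGrid":
        return MapGrid(self.cell, self.values.copy(), self.origin_frac.copy(), self.periodic)

    def frac_to_grid(self, frac: np.ndarray) -> np.ndarray:
        frac = np.atleast_2d(np.asarray(frac, dtype=float))
        return (frac - self.origin_frac) * np.array(self.shape)

    def cart_to_grid(self, cart: np.ndarray) -> np.ndarray:
        return self.frac_to_grid(self.cell.fractionalize(cart))

    def grid_frac_coords(self) -> np.ndarray:
        """(nx,ny,nz,3) fractional coordinate of every voxel."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx) / nx, np.arange(ny) / ny, np.arange(nz) / nz, indexing="ij"
        )
        return np.stack([ii, jj, kk], axis=-1) + self.origin_frac


def grid_shape_for(cell: UnitCell, d_min: float, rate: float = 3.0) -> tuple:
    """FFT-friendly grid shape with spacing <= d_min / rate along each axis."""
    import scipy.fft

    out = []
    for length in (cell.a, cell.b, cell.c):
        n = int(math.ceil(length * rate / d_min))
        out.append(scipy.fft.next_fast_len(max(n, 4), real=True))
    return tuple(out)


def interpolate(grid: MapGrid, frac_points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at fractional coordinates; exact at grid nodes.

    Crystal maps wrap periodically; box maps clamp to the edge value.
    """
    pts = np.atleast_2d(np.asarray(frac_points, dtype=float))
    coords = grid.frac_to_grid(pts).T
    mode = "grid-wrap" if grid.periodic else "nearest"
    return map_coordinates(grid.values, coords, order=1, mode=mode, prefilter=False)


def map_correlation(a: MapGrid, b: MapGrid, mask: MapGrid | None = None) -> float:
    """Pearson correlation of two maps over all (or masked) voxels."""
    if a.shape != b.shape:
        raise ValueError(f"grid shapes differ: {a.shape} vs {b.shape}")
    x, y = a.values, b.values
    if mask is not None:
        sel = mask.values > 0.5
        if not sel.any():
            raise ValueError("empty mask")
        x, y = x[sel], y[sel]
    x = x.ravel() - x.mean()
    y = y.ravel() - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("map correlation undefined for a constant map")
    return float(x @ y / (nx * ny))


# ---------------------------------------------------------------------------
# Atomic density
# ---------------------------------------------------------------------------

def _it92_coefficients(symbol: str) -> np.ndarray:
    """(a_i, b_i) pairs, i = 1..5, with the IT92 constant folded into a 5th term."""
    import gemmi

    el = gemmi.Element(symbol.capitalize())
    if el.name == "X":
        raise KeyError(symbol)
    c = el.it92.get_coefs()  # a1..a4, b1..b4, c
    a = np.array([*c[0:4], c[8]])
    b = np.array([*c[4:8], 0.0])
    return np.stack([a, b], axis=1)


_FF_CACHE: dict = {}


def _form_factor(symbol: str) -> np.ndarray:
    key = symbol.capitalize()
    if key not in _FF_CACHE:
        try:
            _FF_CACHE[key] = _it92_coefficients(key)
        except KeyError:
            import warnings

            warnings.warn(f"unknown element {symbol!r}; using carbon form factor")
            _FF_CACHE[key] = _it92_coefficients("C")
    return _FF_CACHE[key]


def _expand_atoms(model: AtomicModel, cell: UnitCell, sg: SpaceGroup):
    """Fractional positions of all symmetry copies of the model's atoms."""
    frac = cell.fractionalize(model.xyz)
    parts = []
    for rot, tran in sg.ops:
        parts.append(frac @ np.asarray(rot, dtype=float).T + tran)
    frac_all = np.concatenate(parts) % 1.0
    n_ops = sg.n_ops
    occ = np.tile(model.occupancy, n_ops)
    b = np.tile(model.b_iso, n_ops)
    elem = np.tile(model.element, n_ops)
    return frac_all, occ, b, elem


def density_from_model(model: AtomicModel, cell: UnitCell, sg: SpaceGroup,
                       shape: tuple, b_extra: float = 0.0,
                       periodic: bool = True) -> MapGrid:
    """Sample Gaussian-atom electron density on a grid (symmetry-expanded).

    Each IT92 term of atom j contributes
    ``a_i (4 pi / (b_i + B_j))^(3/2) exp(-4 pi^2 r^2 / (b_i + B_j))``
    so that its Fourier transform is ``a_i exp(-(b_i + B_j) s^2 / 4)``.
    ``b_extra`` is added to every atomic B (resolution smearing / anti-alias).
    """
    if len(model) == 0:
        raise ValueError("empty model")
    frac, occ, b_iso, elem = _expand_atoms(model, cell, sg)
    b_iso = b_iso + b_extra
    shape = tuple(int(n) for n in shape)
    nvec = np.array(shape)
    M = cell.orthogonalization
    rho = np.zeros(shape)
    flat = rho.ravel()

    # group atoms by element and (rounded) B so each group shares coefficients
    keys = [(str(e), round(float(bb), 1)) for e, bb in zip(elem, b_iso)]
    uniq_keys = sorted(set(keys))
    key_arr = np.array([uniq_keys.index(k) for k in keys])
    for gi, (esym, bval) in enumerate(uniq_keys):
        sel = key_arr == gi
        pos = frac[sel]
        w = occ[sel]
        coeffs = _form_factor(esym)
        widths = coeffs[:, 1] + bval          # b_i + B
        if np.any(widths <= 0):
            raise ValueError("non-positive Gaussian width; B factor too negative")
        p = 4.0 * math.pi**2 / widths          # exponent factors
        amp = coeffs[:, 0] * (4.0 * math.pi / widths) ** 1.5
        # cutoff where the widest term falls to 1e-3 of its peak
        r_cut = math.sqrt(math.log(1e3) / p.min())
        spacing = np.array([cell.a, cell.b, cell.c]) / nvec
        half = np.ceil(r_cut / spacing).astype(int)
        offs = np.stack(np.meshgrid(*[np.arange(-h, h + 1) for h in half],
                                    indexing="ij"), axis=-1).reshape(-1, 3)
        for start in range(0, len(pos), 4000):
            pp = pos[start:start + 4000]
            ww = w[start:start + 4000]
            base = np.floor(pp * nvec).astype(int)            # (m,3)
            idx = base[:, None, :] + offs[None, :, :]          # (m,K,3)
            dfrac = idx / nvec - pp[:, None, :]
            cart = dfrac @ M.T
            r2 = np.einsum("mki,mki->mk", cart, cart)
            dens = np.zeros_like(r2)
            for ai, pi in zip(amp, p):
                dens += ai * np.exp(-pi * r2)
            dens *= ww[:, None]
            if periodic:
                idx = idx % nvec
            else:
                np.clip(idx, 0, nvec - 1, out=idx)
            lin = (idx[..., 0] * shape[1] + idx[..., 1]) * shape[2] + idx[..., 2]
            flat += np.bincount(lin.ravel(), weights=dens.ravel(), minlength=flat.size)
    return MapGrid(cell, rho, periodic=periodic)


# ---------------------------------------------------------------------------
# Structure factors <-> maps
# ---------------------------------------------------------------------------

def calc_structure_factors(model: AtomicModel, cell: UnitCell, sg: SpaceGroup,
                           d_min: float, rate: float = 4.0,
                           b_extra: float = 0.0) -> ReflectionSet:
    """Structure factors (amplitude + phase) of a model to ``d_min``.

    Gaussian-atom density is sampled on a fine grid (spacing d_min/rate) over
    all symmetry copies and inverted by FFT; the symmetry-unique reflections
    inside the resolution sphere are returned. F(000) is excluded.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    shape = grid_shape_for(cell, d_min, rate)
    rho = density_from_model(model, cell, sg, shape, b_extra=b_extra)
    return invert_map(rho, d_min, sg=sg, _check_rate=2.0)


def calc_f_at(model: AtomicModel, cell: UnitCell, sg: SpaceGroup,
              hkl: np.ndarray, rate: float = 4.0,
              b_extra: float = 0.0) -> np.ndarray:
    """Complex structure factors of a model at the given indices (FFT route)."""
    hkl = np.asarray(hkl, dtype=int)
    # the grid must resolve the atomic Gaussians even when only low-resolution
    # indices are requested, or their tails alias into the measured F
    d_min = min(float(cell.d_spacing(hkl).min()), 5.0)
    shape = grid_shape_for(cell, d_min, rate)
    rho = density_from_model(model, cell, sg, shape, b_extra=b_extra)
    F = np.fft.ifftn(rho.values) * cell.volume()
    lin = ((hkl[:, 0] % shape[0]) * shape[1] + hkl[:, 1] % shape[1]) * shape[2] \
        + hkl[:, 2] % shape[2]
    return F.ravel()[lin]


def _full_f_grid(refl: ReflectionSet, shape: tuple, coeff: np.ndarray) -> np.ndarray:
    """Scatter symmetry-expanded complex coefficients onto an FFT index grid."""
    shape = tuple(int(n) for n in shape)
    nvec = np.array(shape)
    hkl = refl.hkl
    hmax = np.abs(hkl).max(axis=0)
    if np.any(2 * hmax + 1 > nvec):
        raise ValueError(f"grid {shape} too coarse for indices up to {hmax}")
    G = np.zeros(shape, dtype=complex)
    filled = np.zeros(shape, dtype=bool)
    for rot, tran in refl.sg.ops:
        h_img = hkl @ np.asarray(rot, dtype=int)
        # F(h R) = F(h) exp(-2 pi i h.t)
        c_img = coeff * np.exp(-2j * math.pi * (hkl @ np.asarray(tran)))
        for sign in (1, -1):
            hh = sign * h_img
            cc = c_img if sign == 1 else np.conj(c_img)
            lin = ((hh[:, 0] % shape[0]) * shape[1] + hh[:, 1] % shape[1]) * shape[2] \
                + hh[:, 2] % shape[2]
            new = ~filled.ravel()[lin]
            G.ravel()[lin[new]] = cc[new]
            filled.ravel()[lin[new]] = True
    return G


def synthesize_map(refl: ReflectionSet, shape: tuple, coefficients: str = "fo",
                   fc: ReflectionSet | None = None, use_fom: bool = False) -> MapGrid:
    """Fourier synthesis of a phased reflection set.

    ``coefficients`` selects the amplitude term: ``fo`` (Fo exp(i phi)),
    ``2fo-fc`` or ``fo-fc`` (difference maps; ``fc`` must share the index
    order of ``refl``). With ``use_fom`` amplitudes are weighted by the
    figure of merit (NaN FOM treated as 1).
    """
    if not np.all(np.isfinite(refl.phase)):
        raise ValueError("map synthesis requires phases for every reflection")
    amp = refl.f.astype(float)
    if use_fom:
        w = np.where(np.isfinite(refl.fom), refl.fom, 1.0)
        amp = amp * w
    if coefficients != "fo":
        if fc is None:
            raise ValueError("difference coefficients require fc")
        if not np.array_equal(fc.hkl, refl.hkl):
            raise ValueError("fc must be indexed identically to refl")
        if coefficients == "2fo-fc":
            amp = 2.0 * amp - fc.f
        elif coefficients == "fo-fc":
            amp = amp - fc.f
        else:
            raise ValueError(f"unknown coefficient scheme {coefficients!r}")
    coeff = amp * np.exp(1j * np.radians(refl.phase))
    G = _full_f_grid(refl, shape, coeff)
    vol = refl.cell.volume()
    rho = np.real(np.fft.fftn(G)) / vol
    return MapGrid(refl.cell, rho)


def invert_map(grid: MapGrid, d_min: float, d_max: float = math.inf,
               sg: SpaceGroup | None = None,
               _check_rate: float = 2.0) -> ReflectionSet:
    """Forward FFT of a crystal map, reduced to the symmetry-unique set.

    Friedel symmetry holds exactly because the input map is real. Raises if
    the grid is too coarse to carry ``d_min`` without aliasing. The map is
    reduced under ``sg`` (default P1).
    """
    cell = grid.cell
    shape = grid.shape
    for n, length in zip(shape, (cell.a, cell.b, cell.c)):
        if n * d_min < _check_rate * length:
            raise ValueError(
                f"grid {shape} too coarse for d_min={d_min} A (aliasing)"
            )
    if sg is None:
        from .xtal import P1

        sg = P1
    F = np.fft.ifftn(grid.values) * cell.volume()
    hkl = generate_unique_hkl(cell, sg, d_min, d_max)
    shape = grid.shape
    lin = ((hkl[:, 0] % shape[0]) * shape[1] + hkl[:, 1] % shape[1]) * shape[2] \
        + hkl[:, 2] % shape[2]
    fvals = F.ravel()[lin]
    return ReflectionSet(cell, sg, hkl, np.abs(fvals), None,
                         np.degrees(np.angle(fvals)) % 360.0)


def patterson_map(refl: ReflectionSet, d_min: float | None = None,
                  d_max: float = math.inf, shape: tuple | None = None) -> MapGrid:
    """Patterson synthesis: FFT of |F|^2 with zero phases (origin-removed).

    The resolution window selects which amplitudes enter; the origin peak of
    the returned map remains the global maximum but the F(000) term is absent,
    so the map is mean-zero.
    """
    d = refl.d
    d_min = d_min if d_min is not None else float(d.min())
    sel = (d >= d_min) & (d <= d_max)
    if not np.any(sel):
        raise ValueError("empty resolution window for Patterson synthesis")
    sub = refl.select(sel)
    # Patterson symmetry is the point group: expand with zero translations
    pg = SpaceGroup(symbol=refl.sg.symbol,
                    ops=tuple((rot, np.zeros(3)) for rot, _ in refl.sg.ops))
    pat_refl = ReflectionSet(sub.cell, pg, sub.hkl, sub.f ** 2, None,
                             np.zeros(len(sub)))
    if shape is None:
        shape = grid_shape_for(refl.cell, d_min, rate=3.0)
    return synthesize_map(pat_refl, shape)


def low_pass(grid: MapGrid, resolution: float, edge_width: float = 0.1) -> MapGrid:
    """Low-pass filter a (box) map to ``resolution`` with a cosine edge.

    The cutoff is at s = 1/resolution with a raised-cosine roll-off of
    relative width ``edge_width``.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    shape = grid.shape
    lengths = np.array([grid.cell.a, grid.cell.b, grid.cell.c])
    freqs = [np.fft.fftfreq(n, d=length / n) for n, length in zip(shape, lengths)]
    sx, sy, sz = np.meshgrid(*freqs, indexing="ij")
    s = np.sqrt(sx**2 + sy**2 + sz**2)
    s_cut = 1.0 / resolution
    s0 = s_cut * (1.0 - edge_width)
    w = np.ones_like(s)
    ramp = (s >= s0) & (s <= s_cut)
    w[ramp] = 0.5 * (1.0 + np.cos(math.pi * (s[ramp] - s0) / max(s_cut - s0, 1e-12)))
    w[s > s_cut] = 0.0
    out = grid.copy()
    out.values = np.real(np.fft.ifftn(np.fft.fftn(grid.values) * w))
    return out


# ---------------------------------------------------------------------------
# CCP4 / MRC map I/O (mode 2, X fast / Z slow) via gemmi
# ---------------------------------------------------------------------------

def write_ccp4(grid: MapGrid, path) -> None:
    import gemmi

    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    c = grid.cell
    m.grid.unit_cell = gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_ccp4(path, periodic: bool = True) -> MapGrid:
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    u = m.grid.unit_cell
    cell = UnitCell(u.a, u.b, u.c, u.alpha, u.beta, u.gamma)
    values = np.array(m.grid, copy=True).astype(float)
    return MapGrid(cell, values, periodic=periodic)
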