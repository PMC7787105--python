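"""Self-rotation function (SRF) over chi sections: cyclic-NCS order and axis detection.

The SRF scores, for each rotation R, the overlap of the Patterson function
with a rotated copy of itself over a spherical shell around the origin:

    SRF(R) = sum_u P(u) P(R u),   r_min <= |u| <= r_max.

Rotations are organized in chi sections: all rotations with a fixed rotation
angle chi, mapped over axis directions (theta measured from the crystal
c axis, phi from a in the ab plane). An n-fold NCS axis peaks in the
chi = 360/n section; twofold axes — the crystallographic dyads, plus the n
directions generated by composing a perpendicular crystal dyad with the ring
rotations — populate chi = 180.

Two Patterson shells are used, matched to the two questions asked of the SRF:

* axis location (where is the peak of a section?) uses a short-vector shell
  (default 5-25 A): intra-protomer and neighbor-protomer vectors suffice and
  keep full (theta, phi) sections cheap;
* order discrimination (chi = 360/12 vs 360/13 vs 360/14) and equatorial
  twofold counting need long vectors: the angular width of an SRF peak is
  roughly resolution / vector-length, so separating sections 2-3 degrees
  apart requires vectors spanning the ring. The long shell reaches toward
  half the shortest cell edge and uses quasi-normalized (sharpened)
  amplitudes to suppress the smooth low-resolution ridge.

Scores are normalized so the identity rotation scores 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks as _sp_find_peaks

from .fourier import MapGrid, interpolate, patterson_map
from .models import rotation_about_axis
from .synthetic import axis_from_angles
from .xtal import ReflectionSet, chi_for_order

__all__ = [
    "SRFSection",
    "SRFPeak",
    "normalize_amplitudes",
    "rotation_overlap",
    "srf_section",
    "find_peaks",
    "count_axis_perpendicular_peaks",
    "detect_ncs_order",
    "stereographic_project",
    "NCSOrderAmbiguous",
]

# default resolution window (A); d_min=None means max(data limit, 4.0)
DEFAULT_D_MIN = 4.5
DEFAULT_D_MAX = 10.0
# integration shell: long vectors spanning the ring are what separate
# nearby chi sections (peak width ~ resolution / vector length)
LONG_R_MIN = 15.0
LONG_R_MAX_FRACTION = 0.48   # of the shortest cell edge
DEFAULT_STEP = 5.0
REFINE_STEP = 2.0
SECTION_MAX_POINTS = 60_000  # shell thinning for full (theta, phi) sections

_CRYST_DYADS = np.eye(3)  # a, b, c dyad directions (orthorhombic)


class NCSOrderAmbiguous(RuntimeError):
    """No candidate NCS order clearly dominates; the score table is attached."""

    def __init__(self, table):
        self.table = table
        super().__init__(f"NCS order ambiguous; score table: {table}")


@dataclass
class SRFPeak:
    theta: float
    phi: float
    chi: float
    height: float
    crystallographic: bool = False

    @property
    def axis(self) -> np.ndarray:
        return axis_from_angles(self.theta, self.phi)


@dataclass
class SRFSection:
    """SRF values on a (theta, phi) grid for one rotation angle chi."""

    chi: float
    theta: np.ndarray     # polar grid, degrees in [0, 90]
    phi: np.ndarray       # azimuth grid, degrees in [0, 360)
    values: np.ndarray    # (n_theta, n_phi), identity-normalized to 100
    d_min: float = DEFAULT_D_MIN
    d_max: float = DEFAULT_D_MAX


def normalize_amplitudes(refl: ReflectionSet, n_bins: int = 20) -> ReflectionSet:
    """Quasi-normalized amplitudes: F / sqrt(<F^2>) in resolution shells.

    Sharpens the Patterson so that long interatomic vectors contribute on an
    equal footing with the strong low-resolution terms.
    """
    s2 = 1.0 / refl.d ** 2
    edges = np.linspace(s2.min(), s2.max() * (1 + 1e-9), n_bins + 1)
    idx = np.clip(np.digitize(s2, edges) - 1, 0, n_bins - 1)
    f2 = refl.f ** 2
    means = np.ones(n_bins)
    for i in range(n_bins):
        sel = idx == i
        if sel.any():
            means[i] = max(f2[sel].mean(), 1e-30)
    return ReflectionSet(refl.cell, refl.sg, refl.hkl.copy(),
                         refl.f / np.sqrt(means[idx]))


class _ShellOverlap:
    """Cached Patterson shell for repeated rotation-overlap evaluation."""

    def __init__(self, patterson: MapGrid, r_min: float = 5.0,
                 r_max: float = 25.0, max_points: int = 300_000):
        self.grid = patterson
        frac = patterson.grid_frac_coords().reshape(-1, 3)
        frac = (frac + 0.5) % 1.0 - 0.5  # minimum image around the origin
        cart = patterson.cell.orthogonalize(frac)
        r = np.linalg.norm(cart, axis=1)
        sel = np.flatnonzero((r >= r_min) & (r <= r_max))
        if sel.size == 0:
            raise ValueError(f"empty Patterson shell [{r_min}, {r_max}] A")
        if sel.size > max_points:  # deterministic thinning
            sel = sel[:: int(np.ceil(sel.size / max_points))]
        self.cart = cart[sel]
        self.values = patterson.values.reshape(-1)[sel]
        self.norm = float(self.values @ self.values)
        self._frac_of = patterson.cell.fractionalize

    def score(self, rot: np.ndarray) -> float:
        rotated = self.cart @ np.asarray(rot, dtype=float).T
        vals = interpolate(self.grid, self._frac_of(rotated))
        return float(self.values @ vals)

    def normalized(self, rot: np.ndarray) -> float:
        return 100.0 * self.score(rot) / self.norm


def rotation_overlap(patterson: MapGrid, rot: np.ndarray,
                     r_min: float = 5.0, r_max: float = 25.0) -> float:
    """Patterson self-overlap score of one rotation (unnormalized)."""
    return _ShellOverlap(patterson, r_min, r_max).score(rot)


def _long_shell(refl: ReflectionSet, d_min=None, d_max=DEFAULT_D_MAX,
                r_min: float = LONG_R_MIN, r_max=None,
                max_points: int = 300_000) -> _ShellOverlap:
    """Long-vector shell over the sharpened Patterson (the workhorse shell)."""
    d_min = max(refl.d_min, 4.0) if d_min is None else d_min
    cell = refl.cell
    if r_max is None:
        r_max = LONG_R_MAX_FRACTION * min(cell.a, cell.b, cell.c)
    pat = patterson_map(normalize_amplitudes(refl), d_min=d_min, d_max=d_max)
    return _ShellOverlap(pat, r_min, r_max, max_points=max_points)


def _section_on(shell: _ShellOverlap, chi: float, step: float) -> SRFSection:
    theta = np.arange(0.0, 90.0 + 1e-9, step)
    phi = np.arange(0.0, 360.0, step)
    values = np.empty((len(theta), len(phi)))
    chi_rad = math.radians(chi)
    for i, th in enumerate(theta):
        for j, ph in enumerate(phi):
            rot = rotation_about_axis(axis_from_angles(th, ph), chi_rad)
            values[i, j] = shell.score(rot)
    values *= 100.0 / shell.norm
    return SRFSection(chi=chi, theta=theta, phi=phi, values=values)


def srf_section(refl: ReflectionSet, chi: float, angular_step: float = DEFAULT_STEP,
                d_min: float | None = None, d_max: float = DEFAULT_D_MAX,
                r_min: float = LONG_R_MIN, r_max: float | None = None,
                shell: "_ShellOverlap | None" = None) -> SRFSection:
    """Compute one chi section of the SRF on a (theta, phi) grid.

    ``angular_step`` should divide 90 and 360; if not, it is shrunk to the
    nearest divisor (with a warning). A precomputed ``shell``
    (:class:`_ShellOverlap`) may be passed to amortize the Patterson synthesis
    and shell extraction across sections.
    """
    step = float(angular_step)
    if (90.0 / step) % 1 > 1e-9 or (360.0 / step) % 1 > 1e-9:
        import warnings

        adjusted = 90.0 / math.ceil(90.0 / step)
        warnings.warn(f"angular step {step} does not divide 90/360; using {adjusted}")
        step = adjusted
    if shell is None:
        shell = _long_shell(refl, d_min=d_min, d_max=d_max, r_min=r_min,
                            r_max=r_max, max_points=SECTION_MAX_POINTS)
    return _section_on(shell, chi, step)


def _axis_distance_deg(v: np.ndarray, w: np.ndarray) -> float:
    """Angle between undirected axes (degrees, in [0, 90])."""
    c = abs(float(np.dot(v, w)) / (np.linalg.norm(v) * np.linalg.norm(w)))
    return math.degrees(math.acos(min(c, 1.0)))


def find_peaks(section: SRFSection, min_height_fraction: float = 0.25,
               merge_deg: float | None = None) -> list:
    """Local maxima of a section above a fraction of the section maximum.

    Maxima are detected on the (theta, phi) grid (phi wraps; the theta = 0
    pole is a single direction), merged when closer than about one grid step
    as undirected axes, and flagged when coincident with a crystallographic
    dyad direction (a, b or c). Sorted by height, highest first.
    """
    vals = section.values
    step = float(section.theta[1] - section.theta[0]) if len(section.theta) > 1 else 90.0
    merge_deg = merge_deg if merge_deg is not None else 1.2 * step
    vmax = vals.max()
    if vmax <= 0:
        return []
    thr = min_height_fraction * vmax
    nt, nphi = vals.shape
    cands = []
    for i in range(nt):
        for j in range(nphi):
            v = vals[i, j]
            if v < thr:
                continue
            neigh = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ii = i + di
                    if ii < 0:  # across the pole: phi flips by 180
                        ii, jj = -ii, (j + dj + nphi // 2) % nphi
                    elif ii >= nt:
                        continue
                    else:
                        jj = (j + dj) % nphi
                    neigh.append(vals[ii, jj])
            # plateau guard: a constant section has no peaks
            if v >= max(neigh) and v > min(neigh):
                cands.append((v, float(section.theta[i]), float(section.phi[j])))
    cands.sort(reverse=True)
    peaks: list[SRFPeak] = []
    for v, th, ph in cands:
        vec = axis_from_angles(th, ph)
        if any(_axis_distance_deg(vec, p.axis) <= merge_deg for p in peaks):
            continue
        cryst = any(_axis_distance_deg(vec, d) <= merge_deg for d in _CRYST_DYADS)
        peaks.append(SRFPeak(theta=th, phi=ph, chi=section.chi,
                             height=float(v), crystallographic=cryst))
    return peaks


def _refine_peak(shell: _ShellOverlap, peak: SRFPeak, chi: float,
                 span: float = DEFAULT_STEP, step: float = REFINE_STEP) -> SRFPeak:
    """One local refinement pass on a finer angular grid around a peak."""
    best = (peak.height, peak.theta, peak.phi)
    chi_rad = math.radians(chi)
    for th in np.arange(peak.theta - span, peak.theta + span + 1e-9, step):
        th_c, ph_off = (th, 0.0) if th >= 0 else (-th, 180.0)
        if th_c > 90.0:
            continue
        for ph in np.arange(peak.phi - span, peak.phi + span + 1e-9, step):
            rot = rotation_about_axis(axis_from_angles(th_c, (ph + ph_off) % 360.0),
                                      chi_rad)
            v = shell.normalized(rot)
            if v > best[0]:
                best = (v, th_c, (ph + ph_off) % 360.0)
    return SRFPeak(theta=best[1], phi=best[2], chi=chi, height=best[0],
                   crystallographic=peak.crystallographic)


def count_axis_perpendicular_peaks(refl: ReflectionSet, axis,
                                   step_deg: float = 1.0,
                                   prominence_floor: float = 5.0,
                                   prominence_fraction: float = 0.0,
                                   d_min=None, d_max=DEFAULT_D_MAX,
                                   shell: "_ShellOverlap | None" = None) -> int:
    """Count symmetry-distinct chi=180 peaks perpendicular to an NCS axis.

    Operationalizes the classic equatorial-twofold count for a Cn ring whose
    axis is perpendicular to a crystal dyad: composing that dyad with the n
    ring rotations yields n twofold directions on the great circle
    perpendicular to the ring axis, spaced 180/n degrees, one of which
    coincides with the crystal dyad itself (that one is counted, as it is an
    NCS twofold as well; the remaining crystallographic dyads are off the
    circle and excluded by construction).

    The SRF is profiled along the great circle on the long-vector shell and
    local maxima are counted when their (circular) prominence reaches
    ``prominence_floor`` (normalized score units; scores are identity = 100,
    so this is scale-free — genuine dyad peaks sit well above it while
    Fourier ripple stays below). ``prominence_fraction`` optionally adds a
    threshold relative to the strongest non-global peak prominence.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if shell is None:
        shell = _long_shell(refl, d_min=d_min, d_max=d_max)
    # great-circle basis perpendicular to the axis, anchored on the most
    # perpendicular crystal dyad (b for the standard ac-plane geometry)
    dy = _CRYST_DYADS[int(np.argmin(np.abs(_CRYST_DYADS @ axis)))]
    u1 = dy - (dy @ axis) * axis
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(axis, u1)
    ts = np.arange(0.0, 180.0, step_deg)
    prof = np.empty(len(ts))
    for i, t in enumerate(ts):
        v = math.cos(math.radians(t)) * u1 + math.sin(math.radians(t)) * u2
        prof[i] = shell.normalized(rotation_about_axis(v, math.pi))
    # circular peak detection (period 180 degrees in the undirected axis)
    ext = np.concatenate([prof, prof, prof])
    idx, props = _sp_find_peaks(ext, prominence=1e-6)
    sel = (idx >= len(prof)) & (idx < 2 * len(prof))
    proms = props["prominences"][sel]
    if len(proms) == 0:
        return 0
    order = np.argsort(proms)[::-1]
    ref = proms[order[1]] if len(proms) > 1 else proms[order[0]]
    thr = max(prominence_floor, prominence_fraction * ref)
    return int(np.sum(proms >= thr))


def detect_ncs_order(refl: ReflectionSet, candidate_orders=range(11, 15),
                     angular_step: float = DEFAULT_STEP,
                     d_min: float | None = None, d_max: float = DEFAULT_D_MAX,
                     ambiguity_margin: float = 0.02,
                     min_peak_height: float = 15.0):
    """Choose the cyclic NCS order by comparing chi = 360/n sections.

    Each candidate's chi = 360/n section is mapped on a 5-degree grid over
    the long-vector sharpened shell (where sections a few degrees apart in
    chi separate); the best non-crystallographic peak gets one 2-degree local
    refinement pass. Returns ``(n, best_peak, table)``; ``table`` maps each
    candidate to its scored peak. Raises :class:`NCSOrderAmbiguous` when the
    two best candidates lie within ``ambiguity_margin`` (relative) or nothing
    reaches ``min_peak_height`` — deciding then is the user's call, not the
    code's.
    """
    candidates = list(candidate_orders)
    if len(candidates) < 2:
        raise ValueError("need at least two candidate orders")
    shell = _long_shell(refl, d_min=d_min, d_max=d_max,
                        max_points=SECTION_MAX_POINTS)
    table = {}
    for n in candidates:
        chi = 360.0 / n
        section = _section_on(shell, chi, angular_step)
        peaks = [p for p in find_peaks(section, min_height_fraction=0.0)
                 if not p.crystallographic]
        if not peaks:
            table[n] = None
            continue
        refined = _refine_peak(shell, peaks[0], chi)
        table[n] = SRFPeak(theta=refined.theta, phi=refined.phi,
                           chi=round(chi, 1), height=refined.height)
    scored = sorted(((p.height, n) for n, p in table.items() if p is not None),
                    reverse=True)
    if not scored or scored[0][0] < min_peak_height:
        raise NCSOrderAmbiguous({n: (p.height if p else None)
                                 for n, p in table.items()})
    if len(scored) > 1 and scored[0][0] - scored[1][0] < ambiguity_margin * scored[0][0]:
        raise NCSOrderAmbiguous({n: (p.height if p else None)
                                 for n, p in table.items()})
    n_best = scored[0][1]
    return n_best, table[n_best], table


def stereographic_project(section: SRFSection):
    """Equal-angle projection of the theta <= 90 hemisphere onto the unit disk.

    Returns (x, y, value) arrays; theta = 0 maps to the center, theta = 90 to
    the rim, phi measured from +x counter-clockwise.
    """
    th, ph = np.meshgrid(np.radians(section.theta), np.radians(section.phi),
                         indexing="ij")
    r = np.tan(th / 2.0)
    return (r * np.cos(ph)).ravel(), (r * np.sin(ph)).ravel(), section.values.ravel()
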