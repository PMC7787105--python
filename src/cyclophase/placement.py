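"""Axis-constrained molecular replacement, rigid-body refinement, magnification diagnostics.

With the NCS axis orientation fixed by the self-rotation function, molecular
replacement for a Cn ring reduces to a one-parameter rotation search (the
spin angle psi about the axis, periodic in 360/n) combined with a
translation search. The translation scan is FFT-accelerated: the overlap
target ``sum_h w(h) |Fc(h, t)|^2`` is a Fourier series in t whose
coefficients come from products of the molecular transform at
symmetry-related indices, so one inverse FFT maps the whole cell; the top
candidates are then re-scored exactly with the Pearson correlation of
observed and calculated intensities.

Rigid-body refinement by protomer (derivative-free cyclic coordinate descent
over 3 translations + 3 rotations per chain, step halving, monotone accept)
supplies the magnification diagnostic: a uniform inward (or outward) radial
drift of all protomers after refinement is the signature of an EM pixel-size
calibration error, quantified as s = <r_start> / <r_refined>.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fourier import density_from_model, grid_shape_for, interpolate
from .models import AtomicModel, rotation_about_axis
from .synthetic import axis_from_angles
from .xtal import P1, ReflectionSet, SpaceGroup, UnitCell

__all__ = [
    "Placement",
    "RigidBodyReport",
    "align_axis",
    "search_placement",
    "rigid_body_refine",
    "magnification_diagnostic",
    "intensity_correlation",
    "calc_f_direct",
    "P212121_ORIGIN_SHIFTS",
]

# allowed origin shifts of P2(1)2(1)2(1) (fractional)
P212121_ORIGIN_SHIFTS = np.array(
    [[i / 2, j / 2, k / 2] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
)

DEFAULT_WINDOW = (20.0, 4.0)   # d_max, d_min of the scoring window (A)
MAX_SCORE_REFL = 6000


@dataclass
class Placement:
    """One candidate ring placement: spin angle, position, and its score."""

    psi: float                  # degrees in [0, 360/n)
    shift_frac: np.ndarray      # fractional position of the ring center
    score: float                # Pearson correlation of |Fo|^2 vs |Fc|^2
    fast_score: float = 0.0     # FFT translation-function value (ranking aid)


@dataclass
class RigidBodyReport:
    """Per-chain refinement summary plus the magnification inference."""

    chains: list
    rotations: list             # per-chain 3x3 (about the chain centroid)
    translations: list          # per-chain centroid displacement (A)
    radial_shifts: np.ndarray   # signed; negative = toward the ring axis
    tangential_shifts: np.ndarray
    r_start: np.ndarray         # chain centroid distance from the axis, before
    r_end: np.ndarray           # ... after refinement
    score_before: float
    score_after: float
    flagged: list = field(default_factory=list)  # chains reverted (divergence)

    @property
    def mean_radial_shift(self) -> float:
        return float(self.radial_shifts.mean())

    @property
    def magnification(self) -> float:
        """Inferred magnification of the starting model relative to the data.

        s > 1 means the starting (EM-derived) model is dilated — the chains
        all moved inward during refinement, as happens when the nominal EM
        pixel size is larger than the true calibrated one. Defined only for
        per-chain refinement of a ring (returns 1.0 when the chain centroids
        sit on the axis).
        """
        if self.r_end.mean() < 1.0:
            return 1.0
        return float(self.r_start.mean() / self.r_end.mean())


def magnification_diagnostic(report_or_s, object_diameter: float) -> float:
    """Diameter error (A, signed) implied by a magnification factor.

    ``s = 1.42/1.37`` on a 180 A particle gives ~ +6.57 A: the EM-derived
    model overstates the diameter by that much.
    """
    s = report_or_s.magnification if isinstance(report_or_s, RigidBodyReport) \
        else float(report_or_s)
    if s <= 0:
        raise ValueError("magnification factor must be positive")
    return object_diameter * (s - 1.0)


# ---------------------------------------------------------------------------
# scoring helpers
# ---------------------------------------------------------------------------

def _score_window(refl: ReflectionSet, d_max: float, d_min: float,
                  max_refl: int = MAX_SCORE_REFL) -> np.ndarray:
    """Indices of the scoring reflections (window + deterministic thinning)."""
    d = refl.d
    idx = np.flatnonzero((d >= d_min) & (d <= d_max))
    if idx.size == 0:
        raise ValueError(f"no reflections in the {d_max}-{d_min} A window")
    if idx.size > max_refl:
        idx = idx[:: int(np.ceil(idx.size / max_refl))]
    return idx


class _ShellNormalizer:
    """Per-resolution-shell intensity normalization (E^2-style).

    Dividing |F|^2 by its own shell mean removes the Wilson falloff that
    otherwise correlates any two structures in a wide resolution window, and
    makes the correlation insensitive to the partial model's overall scale
    and B per shell.
    """

    def __init__(self, cell: UnitCell, hkl: np.ndarray, n_shells: int = 15):
        s2 = 1.0 / cell.d_spacing(hkl) ** 2
        edges = np.linspace(s2.min(), s2.max() * (1 + 1e-9), n_shells + 1)
        self.sidx = np.clip(np.digitize(s2, edges) - 1, 0, n_shells - 1)
        self.mat = np.zeros((n_shells, len(hkl)))
        self.mat[self.sidx, np.arange(len(hkl))] = 1.0
        cnt = self.mat.sum(axis=1)
        cnt[cnt == 0] = 1.0
        self.inv_count = 1.0 / cnt

    def __call__(self, y: np.ndarray) -> np.ndarray:
        """Normalize intensities (N,) or (N, K) by their shell means."""
        Y = y if y.ndim == 2 else y[:, None]
        means = (self.mat @ Y) * self.inv_count[:, None]
        out = Y / np.maximum(means[self.sidx], 1e-300)
        return out.reshape(y.shape)


def intensity_correlation(f_obs: np.ndarray, f_calc: np.ndarray,
                          normalizer: "_ShellNormalizer | None" = None) -> float:
    """Pearson correlation of (shell-normalized) |F|^2 — the MR/refinement target."""
    x = np.asarray(f_obs, dtype=float) ** 2
    y = np.abs(np.asarray(f_calc)) ** 2
    if normalizer is not None:
        x = normalizer(x)
        y = normalizer(y)
    x = x - x.mean()
    y = y - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero variance in correlation")
    return float(x @ y / (nx * ny))


def _form_factor_curve(element: str, b_iso: float, s2: np.ndarray) -> np.ndarray:
    from .fourier import _form_factor

    coeffs = _form_factor(element)
    f = np.zeros_like(s2)
    for a, b in coeffs:
        f += a * np.exp(-(b + b_iso) * s2 / 4.0)
    return f


def calc_f_direct(model: AtomicModel, cell: UnitCell, sg: SpaceGroup,
                  hkl: np.ndarray) -> np.ndarray:
    """Direct-summation structure factors at arbitrary indices (small models)."""
    hkl = np.asarray(hkl, dtype=int)
    s2 = 1.0 / cell.d_spacing(hkl) ** 2
    frac = cell.fractionalize(model.xyz)
    out = np.zeros(len(hkl), dtype=complex)
    keys = [(str(e), round(float(b), 1)) for e, b in zip(model.element, model.b_iso)]
    for key in sorted(set(keys)):
        sel = np.array([k == key for k in keys])
        f = _form_factor_curve(key[0], key[1], s2)
        pos = frac[sel]
        occ = model.occupancy[sel]
        for rot, tran in sg.ops:
            h_img = hkl @ np.asarray(rot, dtype=float)
            phase = 2j * math.pi * (h_img @ pos.T + (hkl @ tran)[:, None])
            out += f * (np.exp(phase) @ occ)
    return out


def kabsch(moving: np.ndarray, fixed: np.ndarray):
    """Least-squares rigid transform (rot, trans) with rot @ moving + trans ~ fixed."""
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    rot = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return rot, cq - rot @ cp


def fit_ring_axis(model: AtomicModel):
    """Axis direction and center of a Cn ring from its chain centroids.

    The centroids of the n chains lie on a circle; the axis is the normal of
    the best-fit plane (SVD), oriented to have a non-negative z component,
    and the center is the centroid of centroids.
    """
    cents = np.array([model.chain_model(c).centroid() for c in model.chains])
    if len(cents) < 3:
        raise ValueError("need at least 3 chains to fit a ring axis")
    center = cents.mean(axis=0)
    _, _, vt = np.linalg.svd(cents - center)
    axis = vt[2]
    if axis[2] < 0 or (axis[2] == 0 and axis[0] < 0):
        axis = -axis
    return axis / np.linalg.norm(axis), center


# ---------------------------------------------------------------------------
# axis alignment
# ---------------------------------------------------------------------------

def align_axis(model: AtomicModel, model_axis, target) -> AtomicModel:
    """Rotate ``model`` (about its centroid) so ``model_axis`` points along ``target``.

    ``target`` is either a direction vector or a (theta, phi) pair in degrees.
    The minimal rotation is used; for the antiparallel degenerate case the
    rotation axis is chosen deterministically as the lowest-index basis vector
    perpendicular to the model axis.
    """
    v1 = np.asarray(model_axis, dtype=float)
    if np.linalg.norm(v1) == 0:
        raise ValueError("model axis must be nonzero")
    v1 = v1 / np.linalg.norm(v1)
    target = np.asarray(target, dtype=float)
    v2 = axis_from_angles(*target) if target.shape == (2,) else target
    if np.linalg.norm(v2) == 0:
        raise ValueError("target axis must be nonzero")
    v2 = v2 / np.linalg.norm(v2)
    cross = np.cross(v1, v2)
    s = np.linalg.norm(cross)
    c = float(v1 @ v2)
    if s < 1e-12:
        if c > 0:
            return model.copy()
        # antiparallel: rotate by pi about the first basis vector not parallel to v1
        for e in np.eye(3):
            if abs(float(e @ v1)) < 0.9:
                perp = e - (e @ v1) * v1
                rot = rotation_about_axis(perp / np.linalg.norm(perp), math.pi)
                break
    else:
        rot = rotation_about_axis(cross / s, math.atan2(s, c))
    cen = model.centroid()
    return model.transformed(rot=rot, trans=cen - rot @ cen)


# ---------------------------------------------------------------------------
# translation search (FFT) + exact rescoring
# ---------------------------------------------------------------------------

def _molecular_transform(model: AtomicModel, cell: UnitCell, d_min: float):
    """P1 FFT molecular transform of a model centered at the origin."""
    shape = grid_shape_for(cell, d_min, rate=3.0)
    rho = density_from_model(model, cell, P1, shape)
    return np.fft.ifftn(rho.values) * cell.volume(), shape


def _same_placement(cell: UnitCell, t1, t2, radius: float) -> bool:
    """True if two fractional positions coincide within ``radius`` (A),
    modulo the allowed P2(1)2(1)2(1) origin shifts."""
    d = (np.asarray(t1) - np.asarray(t2)) - P212121_ORIGIN_SHIFTS
    d -= np.round(d)
    cart = d @ cell.orthogonalization.T
    return bool((np.linalg.norm(cart, axis=1) < radius).any())


def _tf_grid_shape(cell: UnitCell, d_min: float):
    import scipy.fft

    return tuple(scipy.fft.next_fast_len(
        int(math.ceil(4.5 * length / d_min)), real=True)
        for length in (cell.a, cell.b, cell.c))


def _fc_at(fmol, shape, refl_hkl, sg, t_frac):
    """Fc(h, t) from the molecular transform for one translation."""
    total = np.zeros(len(refl_hkl), dtype=complex)
    for rot, tran in sg.ops:
        h_img = refl_hkl @ np.asarray(rot, dtype=int)
        lin = ((h_img[:, 0] % shape[0]) * shape[1] + h_img[:, 1] % shape[1]) \
            * shape[2] + h_img[:, 2] % shape[2]
        g = fmol.ravel()[lin]
        phase = 2j * math.pi * (h_img @ np.asarray(t_frac) + refl_hkl @ tran)
        total += g * np.exp(phase)
    return total


def _scatter_tf(tf_shape, h_list, coeff_pairs) -> np.ndarray:
    """Accumulate Fourier-series coefficients of a translation map and invert."""
    size = int(np.prod(tf_shape))
    re = np.zeros(size)
    im = np.zeros(size)
    for (a, b), coeff in coeff_pairs:
        k = h_list[a] - h_list[b]
        lin = ((k[:, 0] % tf_shape[0]) * tf_shape[1] + k[:, 1] % tf_shape[1]) \
            * tf_shape[2] + k[:, 2] % tf_shape[2]
        re += np.bincount(lin, weights=coeff.real, minlength=size)
        im += np.bincount(lin, weights=coeff.imag, minlength=size)
    C = (re + 1j * im).reshape(tf_shape)
    return np.real(np.fft.ifftn(C)) * size


def search_placement(model: AtomicModel, refl: ReflectionSet, axis, order: int,
                     psi_step: float = 1.0, d_max: float = DEFAULT_WINDOW[0],
                     d_min: float | None = None, n_keep: int = 10,
                     n_rescore: int = 3000, dedupe_radius: float = 5.0) -> list:
    """Axis-constrained MR search; returns placements ranked by intensity correlation.

    ``model`` must already be oriented (its ring axis along ``axis``); its
    centroid is taken as the rotation center. For each spin angle psi in
    [0, 360/order) two FFT maps are accumulated over the cell — the
    data-weighted overlap ``sum_h (|Fo|^2 - <|Fo|^2>) |Fc(t)|^2`` and the
    normalization ``sum_h |Fc(t)|^2`` — whose ratio approximates the
    intensity correlation (Wilson statistics make the Pearson denominator
    roughly proportional to the mean calculated intensity). The
    ``n_rescore`` best grid nodes per psi are then re-scored with the exact
    Pearson correlation of |F|^2 and the global list, deduplicated modulo
    the allowed P2(1)2(1)2(1) origin shifts, is returned highest first.
    """
    cell, sg = refl.cell, refl.sg
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    d_min = d_min if d_min is not None else max(refl.d_min, DEFAULT_WINDOW[1])
    idx = _score_window(refl, d_max, d_min)
    hkl = refl.hkl[idx]
    fo = refl.f[idx]
    norm = _ShellNormalizer(cell, hkl)
    x = norm(fo ** 2)
    x = x - x.mean()
    x_norm = np.linalg.norm(x)
    w = x  # fast-map weights: shell-normalized, centered observed intensities

    centered = model.transformed(trans=-model.centroid())
    tf_shape = _tf_grid_shape(cell, d_min)
    nvec = np.array(tf_shape)
    rots = [np.asarray(r, dtype=int) for r, _ in sg.ops]
    trans = [np.asarray(t) for _, t in sg.ops]
    pairs = [(a, b) for a in range(len(rots)) for b in range(len(rots))]
    results = []
    psi_max = 360.0 / order
    for psi in np.arange(0.0, psi_max, psi_step):
        spun = centered.transformed(rot=rotation_about_axis(axis, math.radians(psi)))
        fmol, fshape = _molecular_transform(spun, cell, d_min)
        g_list, h_list = [], []
        for rot, tau in zip(rots, trans):
            h_img = hkl @ rot
            lin = ((h_img[:, 0] % fshape[0]) * fshape[1] + h_img[:, 1] % fshape[1]) \
                * fshape[2] + h_img[:, 2] % fshape[2]
            g_list.append(fmol.ravel()[lin] * np.exp(2j * math.pi * (hkl @ tau)))
            h_list.append(h_img)
        # per-shell scale of the translation-averaged calculated intensity:
        # weighting by its inverse approximates shell-normalizing |Fc|^2
        # inside the FFT, which the exact rescoring then does properly
        avg_ic = np.zeros(len(hkl))
        for g in g_list:
            avg_ic += np.abs(g) ** 2
        inv_m = norm(avg_ic) / np.maximum(avg_ic, 1e-300)
        t_w = _scatter_tf(tf_shape, h_list,
                          [((a, b), (w * inv_m) * g_list[a] * np.conj(g_list[b]))
                           for a, b in pairs])
        t_1 = _scatter_tf(tf_shape, h_list,
                          [((a, b), inv_m * g_list[a] * np.conj(g_list[b]))
                           for a, b in pairs])
        fast = t_w / np.maximum(t_1, 1e-9 * t_1.max())

        top = np.argsort(fast.ravel())[::-1][:n_rescore]
        t_cand = np.stack(np.unravel_index(top, tf_shape), axis=1) / nvec  # (K,3)
        # exact Pearson rescoring, vectorized over candidates
        fc = np.zeros((len(hkl), len(top)), dtype=complex)
        for s in range(len(rots)):
            phase = np.exp(2j * math.pi * (h_list[s].astype(float) @ t_cand.T))
            fc += g_list[s][:, None] * phase
        y = norm(np.abs(fc) ** 2)
        y -= y.mean(axis=0, keepdims=True)
        scores = (x @ y) / np.maximum(np.linalg.norm(y, axis=0) * x_norm, 1e-300)
        order_k = np.argsort(scores)[::-1]
        kept = []
        for k in order_k:
            t = t_cand[k]
            if any(_same_placement(cell, t, c.shift_frac, dedupe_radius)
                   for c in kept):
                continue
            kept.append(Placement(psi=float(psi), shift_frac=t,
                                  score=float(scores[k]),
                                  fast_score=float(fast.ravel()[top[k]])))
            if len(kept) >= max(n_keep, 1):
                break
        results.extend(kept)
    results.sort(key=lambda p: p.score, reverse=True)
    # dedupe across psi values (same position within a spin-step tolerance)
    final = []
    for p in results:
        if any(abs(p.psi - q.psi) <= psi_step + 1e-9 and
               _same_placement(cell, p.shift_frac, q.shift_frac, dedupe_radius)
               for q in final):
            continue
        final.append(p)
    return final[:max(n_keep, 1)]


def apply_placement(model: AtomicModel, cell: UnitCell, axis, placement: Placement
                    ) -> AtomicModel:
    """Model positioned according to a search result (spin + translation)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    centered = model.transformed(trans=-model.centroid())
    spun = centered.transformed(
        rot=rotation_about_axis(axis, math.radians(placement.psi)))
    return spun.transformed(trans=cell.orthogonalize(placement.shift_frac))


# ---------------------------------------------------------------------------
# rigid-body refinement by protomer
# ---------------------------------------------------------------------------

class _RigidBodyEngine:
    """Cached per-chain structure-factor contributions for fast rescoring."""

    def __init__(self, model: AtomicModel, refl: ReflectionSet, idx: np.ndarray,
                 per_chain: bool = True):
        self.cell, self.sg = refl.cell, refl.sg
        self.hkl = refl.hkl[idx]
        self.fo = refl.f[idx]
        if per_chain:
            self.chains = model.chains
            self.models = {c: model.chain_model(c) for c in self.chains}
        else:
            self.chains = ["all"]
            self.models = {"all": model}
        self.h_img = [self.hkl @ np.asarray(r, dtype=float) for r, _ in self.sg.ops]
        self.tau_phase = [np.exp(2j * math.pi * (self.hkl @ np.asarray(t)))
                          for _, t in self.sg.ops]
        self.norm = _ShellNormalizer(self.cell, self.hkl)
        self.contrib = {c: self._chain_sf(self.models[c]) for c in self.chains}

    def _chain_sf(self, chain: AtomicModel) -> np.ndarray:
        """(n_ops, N_h) per-op chain contributions (translation phases included)."""
        s2 = 1.0 / self.cell.d_spacing(self.hkl) ** 2
        frac = self.cell.fractionalize(chain.xyz)
        out = np.zeros((len(self.sg.ops), len(self.hkl)), dtype=complex)
        keys = [(str(e), round(float(b), 1))
                for e, b in zip(chain.element, chain.b_iso)]
        for key in sorted(set(keys)):
            sel = np.array([k == key for k in keys])
            f = _form_factor_curve(key[0], key[1], s2)
            pos = frac[sel]
            occ = chain.occupancy[sel]
            for s in range(len(self.sg.ops)):
                phase = np.exp(2j * math.pi * (self.h_img[s] @ pos.T))
                out[s] += f * self.tau_phase[s] * (phase @ occ)
        return out

    def score(self, contrib=None) -> float:
        total = np.zeros(len(self.hkl), dtype=complex)
        for c in self.chains:
            arr = contrib[c] if contrib is not None else self.contrib[c]
            total += arr.sum(axis=0)
        return intensity_correlation(self.fo, total, self.norm)

    def translated(self, chain_id: str, delta_cart: np.ndarray) -> np.ndarray:
        """Chain contribution after a rigid translation (pure phase shift)."""
        dfrac = self.cell.fractionalize(delta_cart)
        out = np.empty_like(self.contrib[chain_id])
        for s in range(len(self.sg.ops)):
            out[s] = self.contrib[chain_id][s] * np.exp(
                2j * math.pi * (self.h_img[s] @ dfrac))
        return out

    def moved(self, chain_id: str, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
        """Chain contribution after a general rigid move (full re-summation)."""
        base = self.models[chain_id]
        cen = base.centroid()
        moved = base.transformed(rot=rot, trans=cen - rot @ cen + trans)
        return self._chain_sf(moved)


def rigid_body_refine(model: AtomicModel, refl: ReflectionSet, axis, center,
                      per_chain: bool = True, cycles: int = 2,
                      d_max: float = DEFAULT_WINDOW[0], d_min: float | None = None,
                      max_refl: int = 2500,
                      trans_step: float = 1.0, trans_tol: float = 0.02,
                      rot_step: float = 1.0, rot_tol: float = 0.05,
                      refine_rotations: bool = True,
                      max_trans: float | None = None,
                      max_rot: float | None = None):
    """Per-protomer rigid-body refinement against intensity correlation.

    Derivative-free cyclic coordinate descent: for each chain, translations
    along x/y/z (cheap phase-shift updates) then rotations about the chain
    centroid (re-summed), with step halving from ``trans_step`` (A) and
    ``rot_step`` (deg) down to the stated tolerances. A move is accepted only
    if the global score improves (monotone); a chain whose sub-refinement
    fails to improve is reverted and flagged.

    Returns ``(refined_model, RigidBodyReport)``; the report decomposes each
    chain-centroid displacement into radial / tangential components with
    respect to the ring axis through ``center`` and infers the magnification
    factor of the starting model.
    """
    d_min = d_min if d_min is not None else max(refl.d_min, DEFAULT_WINDOW[1])
    idx = _score_window(refl, d_max, d_min, max_refl=max_refl)
    eng = _RigidBodyEngine(model, refl, idx, per_chain=per_chain)
    score0 = eng.score()
    best_score = score0
    state = {c: dict(rot=np.eye(3), trans=np.zeros(3)) for c in eng.chains}
    flagged = []

    if not per_chain:
        # single rigid body: a 6-parameter Powell search handles the coupled
        # rotation/translation valley that axis-by-axis descent stalls in.
        # A low-resolution first pass widens the capture radius (errors of a
        # few Angstrom exceed the basin of attraction at the data limit).
        from scipy.optimize import minimize

        def rot_of(q):
            return (rotation_about_axis([1, 0, 0], math.radians(q[3]))
                    @ rotation_about_axis([0, 1, 0], math.radians(q[4]))
                    @ rotation_about_axis([0, 0, 1], math.radians(q[5])))

        q = np.zeros(6)
        bounds = None
        if max_trans is not None or max_rot is not None:
            # trust region: an incomplete model's score optimum is biased, so
            # a polish must stay near the (grid-accurate) starting placement
            mt = max_trans if max_trans is not None else 1e3
            mr = max_rot if max_rot is not None else 1e3
            bounds = [(-mt, mt)] * 3 + [(-mr, mr)] * 3
        stages = [(d_max, max(2.0 * d_min, 7.0), 600),
                  (d_max, d_min, min(max_refl, 1000))]
        eng = score0 = None
        for stage_dmax, stage_dmin, stage_nref in stages:
            idx = _score_window(refl, stage_dmax, stage_dmin,
                                max_refl=stage_nref)
            eng = _RigidBodyEngine(model, refl, idx, per_chain=False)
            cid = eng.chains[0]
            stage_start = eng.score({cid: eng.moved(cid, rot_of(q), q[:3])})
            if score0 is None:
                score0 = eng.score()

            def objective(qq):
                return -eng.score({cid: eng.moved(cid, rot_of(qq), qq[:3])})

            res = minimize(objective, q, method="Powell", bounds=bounds,
                           options=dict(xtol=max(trans_tol, 0.02), ftol=1e-6,
                                        maxfev=150))
            if -res.fun > stage_start:
                q = res.x
        state[cid] = dict(rot=rot_of(q), trans=np.asarray(q[:3], dtype=float))
        best_score = eng.score({cid: eng.moved(cid, rot_of(q), q[:3])})
        return _assemble_report(eng, state, axis, center, score0, best_score,
                                flagged)

    def chain_contrib(cid):
        st = state[cid]
        if np.allclose(st["rot"], np.eye(3)):
            return eng.translated(cid, st["trans"])
        return eng.moved(cid, st["rot"], st["trans"])

    current = {c: chain_contrib(c) for c in eng.chains}

    def total_score(cid, cand):
        saved = current[cid]
        current[cid] = cand
        s = eng.score(current)
        current[cid] = saved
        return s

    for _ in range(max(cycles, 1)):
        for cid in eng.chains:
            entry_score = best_score
            # translations (cheap)
            step = trans_step
            while step >= trans_tol:
                improved = False
                for ax in np.eye(3):
                    for sign in (1.0, -1.0):
                        cand_t = state[cid]["trans"] + sign * step * ax
                        cand = (eng.translated(cid, cand_t)
                                if np.allclose(state[cid]["rot"], np.eye(3))
                                else eng.moved(cid, state[cid]["rot"], cand_t))
                        s = total_score(cid, cand)
                        if s > best_score + 1e-12:
                            state[cid]["trans"] = cand_t
                            current[cid] = cand
                            best_score = s
                            improved = True
                if not improved:
                    step /= 2.0
            # rotations (re-summed; skip for translation-only refinement)
            if refine_rotations:
                step = rot_step
                while step >= rot_tol:
                    improved = False
                    for ax in np.eye(3):
                        for sign in (1.0, -1.0):
                            d_rot = rotation_about_axis(ax, math.radians(sign * step))
                            cand_r = d_rot @ state[cid]["rot"]
                            cand = eng.moved(cid, cand_r, state[cid]["trans"])
                            s = total_score(cid, cand)
                            if s > best_score + 1e-12:
                                state[cid]["rot"] = cand_r
                                current[cid] = cand
                                best_score = s
                                improved = True
                    if not improved:
                        step /= 2.0
            if best_score < entry_score - 1e-9:  # divergence guard
                state[cid] = dict(rot=np.eye(3), trans=np.zeros(3))
                current[cid] = eng.contrib[cid].copy()
                best_score = entry_score
                flagged.append(cid)

    return _assemble_report(eng, state, axis, center, score0, best_score, flagged)


def _assemble_report(eng, state, axis, center, score0, best_score, flagged):
    """Build the refined model and the per-group report from engine state."""
    parts = []
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    center = np.asarray(center, dtype=float)
    rots, transs, dr, dt, r0s, r1s = [], [], [], [], [], []
    for cid in eng.chains:
        st = state[cid]
        base = eng.models[cid]
        cen = base.centroid()
        parts.append(base.transformed(rot=st["rot"],
                                      trans=cen - st["rot"] @ cen + st["trans"]))
        rots.append(st["rot"])
        transs.append(st["trans"])
        v0 = cen - center
        v1 = (cen + st["trans"]) - center
        rad0 = v0 - (v0 @ axis) * axis
        rad1 = v1 - (v1 @ axis) * axis
        r0, r1 = np.linalg.norm(rad0), np.linalg.norm(rad1)
        r0s.append(r0)
        r1s.append(r1)
        dr.append(r1 - r0)
        disp = st["trans"]
        radial_comp = (disp @ (rad0 / r0)) if r0 > 0 else 0.0
        dt.append(math.sqrt(max(float(disp @ disp) - radial_comp ** 2, 0.0)))
    refined = AtomicModel.concat(parts)
    report = RigidBodyReport(
        chains=list(eng.chains), rotations=rots, translations=transs,
        radial_shifts=np.array(dr), tangential_shifts=np.array(dt),
        r_start=np.array(r0s), r_end=np.array(r1s),
        score_before=score0, score_after=best_score, flagged=flagged,
    )
    return refined, report
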