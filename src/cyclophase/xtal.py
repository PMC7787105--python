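"""Unit-cell and space-group arithmetic, reflection bookkeeping and Matthews analysis.

This module is the crystallographic substrate for the rest of the package:
triclinic cell metrics, the two space groups needed for ring crystals of this
kind (P1 and P2₁2₁2₁), symmetry-unique reflection sets with Friedel mates
merged, the chi-section arithmetic used to enumerate candidate cyclic NCS
orders, and Matthews-coefficient / solvent-content analysis.

Reflection data are stored column-wise (numpy arrays) rather than as one
object per reflection; a :class:`Reflection` view is provided for convenience.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "UnitCell",
    "SpaceGroup",
    "Reflection",
    "ReflectionSet",
    "MatthewsResult",
    "cell_volume",
    "d_spacing",
    "chi_for_order",
    "matthews",
    "symmetry_equivalents",
    "unique_hkl",
    "generate_unique_hkl",
    "read_hkl",
    "write_hkl",
    "read_mtz",
    "MATTHEWS_PROTEIN_CONSTANT",
]

#: Classic Matthews convention: solvent fraction = 1 - k / Vm with
#: k = 1.23 A^3/Da for protein crystals.
MATTHEWS_PROTEIN_CONSTANT = 1.23


# ---------------------------------------------------------------------------
# Unit cell
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell; lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError(f"cell lengths must be positive, got {(self.a, self.b, self.c)}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angles must lie in (0, 180), got {ang}")

    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            raise ValueError("degenerate unit cell (non-positive metric determinant)")
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def orthogonalization(self) -> np.ndarray:
        """3x3 matrix M with x_cart = M @ x_frac (PDB convention, a along x)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self.volume() / (self.a * self.b * self.c)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def fractionalization(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization)

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.orthogonalization.T

    def fractionalize(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ self.fractionalization.T

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray | float:
        """Resolution d (A) of one index triple or an (N,3) array of them."""
        hkl = np.asarray(hkl, dtype=float)
        single = hkl.ndim == 1
        h2 = np.atleast_2d(hkl)
        if np.any(np.all(h2 == 0, axis=1)):
            raise ValueError("d-spacing undefined for (0,0,0)")
        # reciprocal vectors are the rows of the inverse orthogonalization matrix
        s = h2 @ self.fractionalization
        d = 1.0 / np.linalg.norm(s, axis=1)
        return float(d[0]) if single else d


def cell_volume(cell: UnitCell) -> float:
    """Unit-cell volume in cubic Angstrom (standard triclinic formula)."""
    return cell.volume()


def d_spacing(hkl, cell: UnitCell):
    """Resolution of reflection ``hkl`` in cell ``cell`` (A)."""
    return cell.d_spacing(np.asarray(hkl))


# ---------------------------------------------------------------------------
# Space groups
# ---------------------------------------------------------------------------

def _op(rot, tran):
    return (np.array(rot, dtype=int), np.array(tran, dtype=float))


_SG_TABLES = {
    "P1": [_op(np.eye(3), [0, 0, 0])],
    # P 21 21 21, standard setting (international tables #19)
    "P212121": [
        _op(np.eye(3), [0, 0, 0]),
        _op([[-1, 0, 0], [0, -1, 0], [0, 0, 1]], [0.5, 0.0, 0.5]),
        _op([[1, 0, 0], [0, -1, 0], [0, 0, -1]], [0.5, 0.5, 0.0]),
        _op([[-1, 0, 0], [0, 1, 0], [0, 0, -1]], [0.0, 0.5, 0.5]),
    ],
}

_ALIASES = {
    "P1": "P1",
    "P 1": "P1",
    "P212121": "P212121",
    "P 21 21 21": "P212121",
    "P2(1)2(1)2(1)": "P212121",
}


@dataclass(frozen=True)
class SpaceGroup:
    """A space group as an explicit list of (rotation, translation) operators.

    Only P1 and P2₁2₁2₁ are supported; these are the groups in which cyclic
    ring crystals of the kind this package targets are handled.
    """

    symbol: str
    ops: tuple = field(compare=False, default=())

    @staticmethod
    def from_symbol(symbol: str) -> "SpaceGroup":
        key = _ALIASES.get(symbol.strip())
        if key is None:
            raise ValueError(f"unsupported space group {symbol!r}; supported: P1, P212121")
        return SpaceGroup(symbol=key, ops=tuple(_SG_TABLES[key]))

    @property
    def n_ops(self) -> int:
        return len(self.ops)

    def rotations(self) -> np.ndarray:
        """(n_ops, 3, 3) integer rotation parts."""
        return np.stack([r for r, _ in self.ops])

    def translations(self) -> np.ndarray:
        return np.stack([t for _, t in self.ops])


P1 = SpaceGroup.from_symbol("P1")
P212121 = SpaceGroup.from_symbol("P212121")


# ---------------------------------------------------------------------------
# chi sections and Matthews analysis
# ---------------------------------------------------------------------------

def chi_for_order(n: int) -> float:
    """Rotation angle chi (degrees) of the generator of Cn, to one decimal.

    A cyclic n-fold axis produces a self-rotation-function peak in the
    chi = 360/n section; e.g. n=13 -> 27.7, n=12 -> 30.0. Reported to one
    decimal, matching the usual program output convention.
    """
    n = int(n)
    if n < 1:
        raise ValueError("NCS order must be >= 1")
    return round(360.0 / n, 1)


class MatthewsResult(NamedTuple):
    vm: float               # Matthews coefficient, A^3 / Da
    solvent_fraction: float  # 1 - k / vm, k = 1.23
    z: int                  # symmetry copies per cell
    mass_au: float          # Da per asymmetric unit


def matthews(cell: UnitCell, sg: SpaceGroup, mass_au: float) -> MatthewsResult:
    """Matthews coefficient and solvent content for one AU of mass ``mass_au`` (Da)."""
    if mass_au <= 0:
        raise ValueError("asymmetric-unit mass must be positive")
    z = sg.n_ops
    vm = cell.volume() / (z * mass_au)
    solvent = 1.0 - MATTHEWS_PROTEIN_CONSTANT / vm
    return MatthewsResult(vm=vm, solvent_fraction=solvent, z=z, mass_au=mass_au)


# ---------------------------------------------------------------------------
# Reflection indexing
# ---------------------------------------------------------------------------

def symmetry_equivalents(hkl, sg: SpaceGroup) -> set:
    """All indices equivalent to ``hkl`` under the group rotations and Friedel."""
    h = np.asarray(hkl, dtype=int)
    out = set()
    for rot in sg.rotations():
        eq = tuple(int(x) for x in h @ rot)
        out.add(eq)
        out.add(tuple(-x for x in eq))
    return out


def unique_hkl(hkl: np.ndarray, sg: SpaceGroup) -> np.ndarray:
    """Map each index to its canonical symmetry-unique representative.

    The representative is the lexicographically largest member of the orbit
    under the group rotations plus Friedel inversion; this makes reduction
    idempotent and independent of input order.
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    rots = sg.rotations()  # (m,3,3)
    images = np.einsum("nj,mjk->mnk", hkl, rots)       # (m,N,3)
    images = np.concatenate([images, -images], axis=0)  # + Friedel
    # lexicographic max over orbit members
    best = images[0]
    for cand in images[1:]:
        gt = (
            (cand[:, 0] > best[:, 0])
            | ((cand[:, 0] == best[:, 0]) & (cand[:, 1] > best[:, 1]))
            | ((cand[:, 0] == best[:, 0]) & (cand[:, 1] == best[:, 1]) & (cand[:, 2] > best[:, 2]))
        )
        best = np.where(gt[:, None], cand, best)
    return best


def generate_unique_hkl(cell: UnitCell, sg: SpaceGroup, d_min: float,
                        d_max: float = math.inf) -> np.ndarray:
    """Enumerate the symmetry-unique reflection indices with d in [d_min, d_max]."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    hmax = int(math.floor(cell.a / d_min))
    kmax = int(math.floor(cell.b / d_min))
    lmax = int(math.floor(cell.c / d_min))
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = cell.d_spacing(hkl)
    hkl = hkl[(d >= d_min) & (d <= d_max)]
    uniq = np.unique(unique_hkl(hkl, sg), axis=0)
    # sort for reproducible ordering (descending d, then lexicographic)
    d = cell.d_spacing(uniq)
    order = np.lexsort((uniq[:, 2], uniq[:, 1], uniq[:, 0], -d))
    return uniq[order]


class Reflection(NamedTuple):
    """Row view of a ReflectionSet (phase/fom are NaN when absent)."""

    h: int
    k: int
    l: int
    f_obs: float
    sigma: float
    phase: float
    fom: float


@dataclass
class ReflectionSet:
    """Symmetry-unique structure-factor amplitudes with optional phases.

    Phases are stored in degrees in [0, 360); a NaN phase (and NaN fom) marks
    an unphased reflection. Friedel mates are merged: only the canonical
    member of each +/-h orbit is stored.
    """

    cell: UnitCell
    sg: SpaceGroup
    hkl: np.ndarray                 # (N,3) int
    f: np.ndarray                   # (N,) amplitudes, >= 0
    sigma: np.ndarray | None = None
    phase: np.ndarray | None = None  # degrees, NaN = absent
    fom: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        n = len(self.hkl)
        self.f = np.asarray(self.f, dtype=float).reshape(n)
        if np.any(self.f < 0):
            raise ValueError("amplitudes must be non-negative")
        if np.any(np.all(self.hkl == 0, axis=1)):
            raise ValueError("F(000) must not be part of a working reflection set")
        self.sigma = (
            np.zeros(n) if self.sigma is None else np.asarray(self.sigma, dtype=float).reshape(n)
        )
        if np.any(self.sigma < 0):
            raise ValueError("sigmas must be non-negative")
        self.phase = (
            np.full(n, np.nan) if self.phase is None
            else np.mod(np.asarray(self.phase, dtype=float).reshape(n), 360.0)
        )
        self.fom = (
            np.full(n, np.nan) if self.fom is None else np.asarray(self.fom, dtype=float).reshape(n)
        )

    # -- basic introspection ------------------------------------------------

    def __len__(self) -> int:
        return len(self.hkl)

    def __getitem__(self, i: int) -> Reflection:
        return Reflection(*self.hkl[i], self.f[i], self.sigma[i], self.phase[i], self.fom[i])

    @property
    def d(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    @property
    def d_min(self) -> float:
        return float(self.d.min())

    @property
    def d_max(self) -> float:
        return float(self.d.max())

    @property
    def has_phases(self) -> bool:
        return bool(np.any(np.isfinite(self.phase)))

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(
            self.cell, self.sg, self.hkl.copy(), self.f.copy(),
            self.sigma.copy(), self.phase.copy(), self.fom.copy(),
        )

    def select(self, mask: np.ndarray) -> "ReflectionSet":
        return ReflectionSet(
            self.cell, self.sg, self.hkl[mask], self.f[mask],
            self.sigma[mask], self.phase[mask], self.fom[mask],
        )

    def in_window(self, d_min: float, d_max: float = math.inf) -> "ReflectionSet":
        d = self.d
        return self.select((d >= d_min) & (d <= d_max))

    # -- complex structure factors -----------------------------------------

    def f_complex(self) -> np.ndarray:
        """F * exp(i*phi); raises if any reflection is unphased."""
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("reflection set has missing phases")
        return self.f * np.exp(1j * np.radians(self.phase))


# ---------------------------------------------------------------------------
# Reflection text table
# ---------------------------------------------------------------------------

_HKL_HEADER = "#  h   k   l          F       SIGF        PHI        FOM"


def write_hkl(refl: ReflectionSet, path) -> None:
    """Write the documented whitespace text table ``h k l F SIGF [PHI] [FOM]``.

    Floats are written as %.6g; the reader below round-trips them exactly.
    Cell and space group are recorded in comment headers.
    """
    c = refl.cell
    with open(path, "w") as fh:
        fh.write(f"# CELL {c.a:.6g} {c.b:.6g} {c.c:.6g} {c.alpha:.6g} {c.beta:.6g} {c.gamma:.6g}\n")
        fh.write(f"# SPACEGROUP {refl.sg.symbol}\n")
        fh.write(_HKL_HEADER + "\n")
        phased = np.isfinite(refl.phase)
        any_phase = bool(phased.any())
        for i in range(len(refl)):
            h, k, l = refl.hkl[i]
            row = f"{h:4d} {k:3d} {l:3d} {refl.f[i]:10.6g} {refl.sigma[i]:10.6g}"
            if any_phase:
                if phased[i]:
                    row += f" {refl.phase[i]:10.6g}"
                    row += f" {refl.fom[i]:10.6g}" if np.isfinite(refl.fom[i]) else ""
                else:
                    row += "          ."
            fh.write(row + "\n")


def read_hkl(path, cell: UnitCell | None = None, sg: SpaceGroup | None = None) -> ReflectionSet:
    """Read the reflection text table written by :func:`write_hkl`."""
    hkl, fs, sigs, phis, foms = [], [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                tok = s[1:].split()
                if tok[:1] == ["CELL"]:
                    cell = UnitCell(*map(float, tok[1:7]))
                elif tok[:1] == ["SPACEGROUP"]:
                    sg = SpaceGroup.from_symbol(" ".join(tok[1:]))
                continue
            tok = s.split()
            if len(tok) < 5:
                raise ValueError(f"{path}:{ln}: expected at least 'h k l F SIGF', got {s!r}")
            try:
                hkl.append([int(tok[0]), int(tok[1]), int(tok[2])])
                fs.append(float(tok[3]))
                sigs.append(float(tok[4]))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed field ({exc})") from None
            phi = fom = np.nan
            if len(tok) > 5 and tok[5] != ".":
                phi = float(tok[5])
                if len(tok) > 6:
                    fom = float(tok[6])
            phis.append(phi)
            foms.append(fom)
    if cell is None or sg is None:
        raise ValueError(f"{path}: no CELL/SPACEGROUP header and none supplied")
    return ReflectionSet(cell, sg, np.array(hkl), np.array(fs), np.array(sigs),
                         np.array(phis), np.array(foms))


def read_mtz(path, f_label: str = "FP", sig_label: str = "SIGFP") -> ReflectionSet:
    """Import amplitudes from an MTZ file through gemmi (optional convenience)."""
    import gemmi

    mtz = gemmi.read_mtz_file(str(path))
    cell = UnitCell(mtz.cell.a, mtz.cell.b, mtz.cell.c, mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma)
    sg = SpaceGroup.from_symbol(mtz.spacegroup.hm)
    data = np.array(mtz, copy=True)
    cols = [c.label for c in mtz.columns]
    hkl = data[:, [cols.index("H"), cols.index("K"), cols.index("L")]].astype(int)
    f = data[:, cols.index(f_label)]
    sig = data[:, cols.index(sig_label)] if sig_label in cols else None
    ok = np.isfinite(f)
    return ReflectionSet(cell, sg, unique_hkl(hkl[ok], sg), f[ok],
                         None if sig is None else sig[ok])
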