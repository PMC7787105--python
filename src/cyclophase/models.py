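"""Atomic models, PDB I/O, cyclic (Cn) symmetry expansion and magnification rescaling.

The central operation here is the construction of a Cn ring from a single
protomer: rotation matrices with generator angle 2*pi/n about a stated axis
and center, applied n times with chain renaming. This is the step that turns
a partial monomer built in a cryo-EM map into the ring-shaped search model
used for molecular replacement, and later supplies the NCS operators for
density averaging.

Coordinates are orthogonal Angstroms throughout; fractionalization happens
only in the Fourier engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "AtomicModel",
    "NCSOperator",
    "NCSOperatorSet",
    "rotation_about_axis",
    "cn_operators",
    "expand_cn",
    "rescale_magnification",
    "read_pdb",
    "write_pdb",
    "CHAIN_ALPHABET",
]

CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    chain: str
    res_seq: int
    res_name: str
    xyz: tuple
    occupancy: float = 1.0
    b_iso: float = 20.0
    element: str = "C"


class AtomicModel:
    """Ordered collection of atom records, stored column-wise.

    Parameters mirror PDB ATOM records. All arrays share the first dimension;
    ``xyz`` is (N, 3) in Angstrom.
    """

    def __init__(self, name, chain, res_seq, res_name, xyz, occupancy=None,
                 b_iso=None, element=None, serial=None):
        self.name = np.asarray(name, dtype=object)
        n = len(self.name)
        self.chain = np.asarray(chain, dtype=object).reshape(n)
        self.res_seq = np.asarray(res_seq, dtype=int).reshape(n)
        self.res_name = np.asarray(res_name, dtype=object).reshape(n)
        self.xyz = np.asarray(xyz, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite atom coordinates")
        self.occupancy = (np.ones(n) if occupancy is None
                          else np.asarray(occupancy, dtype=float).reshape(n))
        self.b_iso = (np.full(n, 20.0) if b_iso is None
                      else np.asarray(b_iso, dtype=float).reshape(n))
        if element is None:
            element = [str(nm)[0] for nm in self.name]
        self.element = np.asarray(element, dtype=object).reshape(n)
        if any(not e for e in self.element):
            raise ValueError("empty element symbol")
        self.serial = (np.arange(1, n + 1) if serial is None
                       else np.asarray(serial, dtype=int).reshape(n))

    # -- construction helpers ----------------------------------------------

    @staticmethod
    def from_records(records) -> "AtomicModel":
        return AtomicModel(
            name=[r.name for r in records],
            chain=[r.chain for r in records],
            res_seq=[r.res_seq for r in records],
            res_name=[r.res_name for r in records],
            xyz=[r.xyz for r in records],
            occupancy=[r.occupancy for r in records],
            b_iso=[r.b_iso for r in records],
            element=[r.element for r in records],
            serial=[r.serial for r in records],
        )

    @staticmethod
    def concat(parts) -> "AtomicModel":
        return AtomicModel(
            name=np.concatenate([p.name for p in parts]),
            chain=np.concatenate([p.chain for p in parts]),
            res_seq=np.concatenate([p.res_seq for p in parts]),
            res_name=np.concatenate([p.res_name for p in parts]),
            xyz=np.concatenate([p.xyz for p in parts]),
            occupancy=np.concatenate([p.occupancy for p in parts]),
            b_iso=np.concatenate([p.b_iso for p in parts]),
            element=np.concatenate([p.element for p in parts]),
        )

    # -- basic queries -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.name)

    def __getitem__(self, i: int) -> AtomRecord:
        return AtomRecord(int(self.serial[i]), str(self.name[i]), str(self.chain[i]),
                          int(self.res_seq[i]), str(self.res_name[i]),
                          tuple(self.xyz[i]), float(self.occupancy[i]),
                          float(self.b_iso[i]), str(self.element[i]))

    @property
    def chains(self):
        """Chain ids in order of first appearance."""
        seen, out = set(), []
        for c in self.chain:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    @property
    def n_residues(self) -> int:
        return len({(c, r) for c, r in zip(self.chain, self.res_seq)})

    def select(self, mask) -> "AtomicModel":
        mask = np.asarray(mask)
        return AtomicModel(self.name[mask], self.chain[mask], self.res_seq[mask],
                           self.res_name[mask], self.xyz[mask], self.occupancy[mask],
                           self.b_iso[mask], self.element[mask])

    def chain_model(self, chain_id: str) -> "AtomicModel":
        return self.select(self.chain == chain_id)

    def ca_mask(self) -> np.ndarray:
        return np.array([nm == "CA" for nm in self.name])

    def centroid(self) -> np.ndarray:
        return self.xyz.mean(axis=0)

    # -- transforms ---------------------------------------------------------

    def transformed(self, rot=None, trans=None) -> "AtomicModel":
        """Rigid transform x -> rot @ x + trans (copies the model)."""
        xyz = self.xyz
        if rot is not None:
            xyz = xyz @ np.asarray(rot, dtype=float).T
        if trans is not None:
            xyz = xyz + np.asarray(trans, dtype=float)
        out = self.copy()
        out.xyz = np.array(xyz)
        return out

    def copy(self) -> "AtomicModel":
        return AtomicModel(self.name.copy(), self.chain.copy(), self.res_seq.copy(),
                           self.res_name.copy(), self.xyz.copy(), self.occupancy.copy(),
                           self.b_iso.copy(), self.element.copy(), self.serial.copy())

    def with_chain_ids(self, mapping: dict) -> "AtomicModel":
        out = self.copy()
        out.chain = np.array([mapping.get(c, c) for c in self.chain], dtype=object)
        return out


# ---------------------------------------------------------------------------
# NCS operators
# ---------------------------------------------------------------------------

def rotation_about_axis(axis, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a (normalized) axis by ``angle_rad`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be nonzero")
    x, y, z = axis / norm
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


@dataclass(frozen=True)
class NCSOperator:
    """Proper rigid rotation x -> rot @ x + trans."""

    rot: np.ndarray
    trans: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rot, dtype=float)
        object.__setattr__(self, "rot", rot)
        object.__setattr__(self, "trans", np.asarray(self.trans, dtype=float))
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-10):
            raise ValueError("rotation part is not orthogonal")
        if np.linalg.det(rot) < 0:
            raise ValueError("improper rotation (det = -1)")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.rot.T + self.trans

    def compose(self, other: "NCSOperator") -> "NCSOperator":
        """self after other: x -> self(other(x))."""
        return NCSOperator(self.rot @ other.rot, self.rot @ other.trans + self.trans)


@dataclass(frozen=True)
class NCSOperatorSet:
    """The n operators of a Cn group about (axis, center); identity first."""

    order: int
    axis: np.ndarray
    center: np.ndarray
    ops: tuple

    def __iter__(self):
        return iter(self.ops)

    def __len__(self):
        return self.order

    def transformed(self, rot, trans) -> "NCSOperatorSet":
        """Conjugate the operator set by the rigid transform x -> rot x + trans.

        Used to carry ring operators built in the EM frame into the crystal
        frame after placement.
        """
        rot = np.asarray(rot, dtype=float)
        trans = np.asarray(trans, dtype=float)
        g = NCSOperator(rot, trans)
        ginv = NCSOperator(rot.T, -rot.T @ trans)
        return NCSOperatorSet(
            order=self.order,
            axis=rot @ np.asarray(self.axis, dtype=float),
            center=g.apply(np.asarray(self.center, dtype=float)),
            ops=tuple(g.compose(op).compose(ginv) for op in self.ops),
        )


def cn_operators(n: int, axis, center=(0.0, 0.0, 0.0)) -> NCSOperatorSet:
    """Cn operator set: rotation by 2*pi*k/n about ``axis`` through ``center``."""
    n = int(n)
    if n < 1:
        raise ValueError("order must be >= 1")
    axis = np.asarray(axis, dtype=float)
    if np.linalg.norm(axis) == 0:
        raise ValueError("axis must be nonzero")
    axis = axis / np.linalg.norm(axis)
    center = np.asarray(center, dtype=float)
    ops = []
    for k in range(n):
        rot = rotation_about_axis(axis, 2.0 * math.pi * k / n)
        ops.append(NCSOperator(rot, center - rot @ center))
    return NCSOperatorSet(order=n, axis=axis, center=center, ops=tuple(ops))


def expand_cn(monomer: AtomicModel, ops: NCSOperatorSet) -> AtomicModel:
    """Expand a protomer into a Cn ring; copy k is transformed by ops[k].

    Chains are renamed so each copy has unique ids: copy k of a single-chain
    protomer becomes chain k of 'ABC...'; multi-chain protomers cycle through
    the alphabet copy-major.
    """
    mono_chains = monomer.chains
    m = len(mono_chains)
    if ops.order * m > len(CHAIN_ALPHABET):
        raise ValueError(
            f"chain alphabet exhausted: need {ops.order * m} ids, have {len(CHAIN_ALPHABET)}"
        )
    parts = []
    for k, op in enumerate(ops):
        mapping = {c: CHAIN_ALPHABET[k * m + j] for j, c in enumerate(mono_chains)}
        parts.append(monomer.transformed(op.rot, op.trans).with_chain_ids(mapping))
    return AtomicModel.concat(parts)


def rescale_magnification(model: AtomicModel, factor: float, center) -> AtomicModel:
    """Scale all coordinates about ``center`` by ``factor``.

    Models an EM magnification (pixel-size) calibration error: a model built
    in a map with pixel size p_wrong instead of p_true is uniformly dilated by
    p_wrong / p_true and can be corrected by the inverse factor.
    """
    if factor <= 0:
        raise ValueError("magnification factor must be positive")
    center = np.asarray(center, dtype=float)
    out = model.copy()
    out.xyz = center + factor * (model.xyz - center)
    return out


# ---------------------------------------------------------------------------
# PDB I/O (fixed-width v3.3 ATOM records, via gemmi)
# ---------------------------------------------------------------------------

def write_pdb(model: AtomicModel, path) -> None:
    """Write fixed-width PDB ATOM records (wwPDB v3.3 columns)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "cyclophase"
    mdl = gemmi.Model("1")
    for cid in model.chains:
        ch = gemmi.Chain(str(cid))
        sub = model.select(model.chain == cid)
        last = None
        res = None
        for i in range(len(sub)):
            key = int(sub.res_seq[i])
            if res is None or key != last:
                res = gemmi.Residue()
                res.name = str(sub.res_name[i])
                res.seqid = gemmi.SeqId(key, " ")
                ch.add_residue(res)
                last = key
            at = gemmi.Atom()
            at.name = str(sub.name[i])
            at.pos = gemmi.Position(*sub.xyz[i])
            at.occ = float(sub.occupancy[i])
            at.b_iso = float(sub.b_iso[i])
            at.element = gemmi.Element(str(sub.element[i]))
            ch[-1].add_atom(at)
        mdl.add_chain(ch)
    st.add_model(mdl)
    st.setup_entities()
    st.write_pdb(str(path))


def read_pdb(path) -> AtomicModel:
    """Read ATOM/HETATM records from a PDB file into an AtomicModel."""
    import gemmi

    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse PDB file {path}: {exc}") from None
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    mdl = st[0]
    name, chain, res_seq, res_name, xyz, occ, b, elem = [], [], [], [], [], [], [], []
    for ch in mdl:
        for res in ch:
            for at in res:
                name.append(at.name)
                chain.append(ch.name)
                res_seq.append(res.seqid.num)
                res_name.append(res.name)
                xyz.append([at.pos.x, at.pos.y, at.pos.z])
                occ.append(at.occ)
                b.append(at.b_iso)
                elem.append(at.element.name)
    if not name:
        raise ValueError(f"{path}: no atoms found")
    return AtomicModel(name, chain, res_seq, res_name, xyz, occ, b, elem)
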