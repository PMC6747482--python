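"""Rigid-body mathematics: optimal superposition, RMSD, and rigid moves.

This module is pure math on labelled coordinate sets.  All downstream
machinery (template assembly, Monte Carlo refinement, clustering) funnels
its 3D arithmetic through the functions here so that numerical conventions
(proper rotations only, Å units) live in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CoordSet",
    "RigidTransform",
    "kabsch",
    "rmsd",
    "rotation_about_axis",
    "translate_span",
    "rotate_span_about_point",
    "rotate_span_about_axis",
]


@dataclass
class CoordSet:
    """Ordered atom labels plus their Cartesian coordinates in Å.

    ``labels[i]`` is a ``(residue_index, atom_name)`` tuple identifying
    ``xyz[i]``.  Coordinates are stored as an ``(n, 3)`` float array.
    """

    labels: list[tuple[int, str]]
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (n, 3) array")
        if len(self.labels) != len(self.xyz):
            raise ValueError(
                f"labels ({len(self.labels)}) and xyz ({len(self.xyz)}) differ in length"
            )
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    def copy(self) -> "CoordSet":
        return CoordSet(list(self.labels), self.xyz.copy())


@dataclass
class RigidTransform:
    """Proper rigid motion x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    # set when the optimal rotation is not unique (collinear/degenerate input)
    ambiguous: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if self.translation.shape != (3,):
            raise ValueError("translation must be a 3-vector")
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthogonal (max deviation {err:.2e})")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3])


def _check_matched(a: CoordSet, b: CoordSet) -> None:
    if len(a) != len(b):
        raise ValueError(f"atom count mismatch: {len(a)} vs {len(b)}")
    for la, lb in zip(a.labels, b.labels):
        if la != lb:
            raise ValueError(f"atom label mismatch: {la} vs {lb}")


def kabsch(mobile: CoordSet, target: CoordSet) -> tuple[RigidTransform, float]:
    """Least-squares superposition of ``mobile`` onto ``target``.

    Returns the proper rigid transform minimising the RMSD of the mobile
    atoms onto the target atoms, together with that minimum RMSD.  The
    SVD solution is sign-corrected on the smallest singular vector so the
    rotation is always proper (determinant +1); mirror images therefore
    superpose with a strictly positive residual.

    Fewer than 3 atoms, or a degenerate (collinear) point set, leaves the
    rotation underdetermined; the best available transform is returned
    with ``ambiguous=True`` (translation-only for < 2 atoms).
    """
    _check_matched(mobile, target)
    n = len(mobile)
    if n == 0:
        raise ValueError("cannot superpose empty coordinate sets")

    mc = mobile.xyz.mean(axis=0)
    tc = target.xyz.mean(axis=0)
    p = mobile.xyz - mc
    q = target.xyz - tc

    ambiguous = False
    if n == 1:
        rot = np.eye(3)
        ambiguous = True
    else:
        h = p.T @ q
        u, s, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        diag = np.diag([1.0, 1.0, d])
        rot = vt.T @ diag @ u.T
        # rank-deficient cross-covariance => rotation about the degenerate
        # direction is arbitrary (collinear or <3 atoms)
        if n < 3 or s[1] < 1e-9 * max(s[0], 1.0):
            ambiguous = True

    trans = tc - rot @ mc
    tf = RigidTransform(rot, trans, ambiguous=ambiguous)
    moved = tf.apply(mobile.xyz)
    val = float(np.sqrt(np.mean(np.sum((moved - target.xyz) ** 2, axis=1))))
    return tf, val


def rmsd(a: CoordSet, b: CoordSet, superpose: bool = True) -> float:
    """Root-mean-square deviation between matched atom sets, in Å.

    With ``superpose`` (default) the Kabsch minimum is returned; otherwise
    the raw coordinate RMSD.
    """
    _check_matched(a, b)
    if superpose:
        return kabsch(a, b)[1]
    return float(np.sqrt(np.mean(np.sum((a.xyz - b.xyz) ** 2, axis=1))))


def rotation_about_axis(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rotation matrix for angle ``theta`` (radians) about ``axis`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("rotation axis must be non-zero")
    x, y, z = axis / norm
    k = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(theta) * k + (1.0 - np.cos(theta)) * (k @ k)


def _span_mask(c: CoordSet, residues: Sequence[int]) -> np.ndarray:
    rset = set(int(r) for r in residues)
    if not rset:
        raise ValueError("empty residue span")
    present = {lab[0] for lab in c.labels}
    missing = rset - present
    if missing:
        raise ValueError(f"span residues not in coordinate set: {sorted(missing)}")
    return np.array([lab[0] in rset for lab in c.labels], dtype=bool)


def translate_span(c: CoordSet, residues: Sequence[int], v: np.ndarray) -> CoordSet:
    """Rigidly translate the atoms of ``residues`` by vector ``v``."""
    mask = _span_mask(c, residues)
    out = c.copy()
    out.xyz[mask] += np.asarray(v, dtype=float)
    return out


def rotate_span_about_point(
    c: CoordSet, residues: Sequence[int], point: np.ndarray, axis: np.ndarray, theta: float
) -> CoordSet:
    """Rigidly rotate the atoms of ``residues`` by ``theta`` about an axis through ``point``."""
    mask = _span_mask(c, residues)
    rot = rotation_about_axis(axis, theta)
    point = np.asarray(point, dtype=float)
    out = c.copy()
    out.xyz[mask] = (out.xyz[mask] - point) @ rot.T + point
    return out


def rotate_span_about_axis(
    c: CoordSet, residues: Sequence[int], p1: np.ndarray, p2: np.ndarray, theta: float
) -> CoordSet:
    """Rotate span atoms about the axis through anchor points ``p1`` -> ``p2``."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return rotate_span_about_point(c, residues, p1, p2 - p1, theta)
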