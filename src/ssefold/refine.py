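"""Gradient-free geometric relaxation of grouped rigid bodies.

Used to restore covalent backbone junctions after fragment assembly, to
close loops built by frame interpolation, and as the internal substitute
for force-field minimization: atoms are grouped into rigid bodies (whole
stems, single residues, ...), and body poses are adjusted by bounded
least squares against flat-bottom distance restraints plus a soft-sphere
clash term.  Internal geometry of each body is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.sparse import lil_matrix
from scipy.spatial import cKDTree

from .geometry import rotation_about_axis

__all__ = ["DistanceRestraint", "rigid_body_refine", "CLASH_DISTANCE"]

# heavy atoms of different residues closer than this are counted as clashing
CLASH_DISTANCE = 2.5


@dataclass(frozen=True)
class DistanceRestraint:
    """Flat-bottom distance restraint between two atoms (global indices)."""

    i: int
    j: int
    lower: float
    upper: float
    weight: float = 1.0

    def violation(self, d: float) -> float:
        if d < self.lower:
            return self.lower - d
        if d > self.upper:
            return d - self.upper
        return 0.0


def _rotvec_matrix(v: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        return np.eye(3)
    return rotation_about_axis(v, angle)


def rigid_body_refine(
    xyz: np.ndarray,
    bodies: list[np.ndarray],
    restraints: list[DistanceRestraint],
    fixed: set[int] = frozenset(),
    clash_weight: float = 1.0,
    clash_distance: float = CLASH_DISTANCE,
    clash_exempt: set[frozenset] | None = None,
    anchor_weight: float = 0.02,
    rounds: int = 2,
    max_nfev: int = 60,
) -> np.ndarray:
    """Refine body poses to satisfy restraints while avoiding clashes.

    ``bodies`` partitions (a subset of) atom indices into rigid groups;
    indices in ``fixed`` bodies do not move.  Returns new coordinates.
    Clash pairs are detected between atoms of different bodies within
    ``clash_distance``; ``clash_exempt`` pairs (frozenset of atom index
    pairs) are ignored (e.g. covalent junction atoms).

    A small anchor term keeps the refined pose close to the start, so a
    structure already satisfying every restraint is left essentially
    unchanged.
    """
    xyz = np.asarray(xyz, dtype=float).copy()
    clash_exempt = clash_exempt or set()
    free = [b for k, b in enumerate(bodies) if k not in fixed]
    if not free:
        return xyz
    body_of = np.full(len(xyz), -1, dtype=int)
    for k, b in enumerate(bodies):
        body_of[np.asarray(b, dtype=int)] = k
    free_ids = [k for k in range(len(bodies)) if k not in fixed]
    var_of_body = {k: v for v, k in enumerate(free_ids)}

    for _ in range(rounds):
        centers = {k: xyz[np.asarray(bodies[k])].mean(axis=0) for k in free_ids}

        # candidate clash pairs (atoms of different bodies)
        tree = cKDTree(xyz)
        cand = []
        for i, j in tree.query_pairs(clash_distance + 1.5):
            bi, bj = body_of[i], body_of[j]
            if bi < 0 or bj < 0 or bi == bj:
                continue
            if bi in fixed and bj in fixed:
                continue
            if frozenset((i, j)) in clash_exempt:
                continue
            cand.append((i, j))

        n_res = len(restraints) + len(cand) + 3 * len(free_ids)
        n_var = 6 * len(free_ids)

        r_i = np.array([r.i for r in restraints], dtype=int)
        r_j = np.array([r.j for r in restraints], dtype=int)
        r_lo = np.array([r.lower for r in restraints])
        r_hi = np.array([r.upper for r in restraints])
        r_w = np.array([r.weight for r in restraints])
        c_i = np.array([i for i, _ in cand], dtype=int)
        c_j = np.array([j for _, j in cand], dtype=int)

        def positions(x: np.ndarray) -> np.ndarray:
            out = xyz.copy()
            for k in free_ids:
                v = var_of_body[k]
                rot = _rotvec_matrix(x[6 * v:6 * v + 3])
                trans = x[6 * v + 3:6 * v + 6]
                idx = np.asarray(bodies[k])
                out[idx] = (xyz[idx] - centers[k]) @ rot.T + centers[k] + trans
            return out

        def resid(x: np.ndarray) -> np.ndarray:
            pos = positions(x)
            parts = []
            if len(r_i):
                d = np.linalg.norm(pos[r_i] - pos[r_j], axis=1)
                viol = np.clip(r_lo - d, 0.0, None) + np.clip(d - r_hi, 0.0, None)
                parts.append(r_w * viol)
            if len(c_i):
                dc = np.linalg.norm(pos[c_i] - pos[c_j], axis=1)
                parts.append(clash_weight * np.clip(clash_distance - dc, 0.0, None))
            anchors = np.empty(3 * len(free_ids))
            for k in free_ids:
                v = var_of_body[k]
                anchors[3 * v:3 * v + 3] = anchor_weight * x[6 * v + 3:6 * v + 6]
            parts.append(anchors)
            return np.concatenate(parts) if parts else np.zeros(0)

        sparsity = lil_matrix((n_res, n_var), dtype=int)
        row = 0
        for r in restraints:
            for a in (r.i, r.j):
                k = body_of[a]
                if k in var_of_body:
                    v = var_of_body[k]
                    sparsity[row, 6 * v:6 * v + 6] = 1
            row += 1
        for i, j in cand:
            for a in (i, j):
                k = body_of[a]
                if k in var_of_body:
                    v = var_of_body[k]
                    sparsity[row, 6 * v:6 * v + 6] = 1
            row += 1
        for k in free_ids:
            v = var_of_body[k]
            sparsity[row:row + 3, 6 * v + 3:6 * v + 6] = 1
            row += 3

        x0 = np.zeros(n_var)
        if len(r_i):
            d0 = np.linalg.norm(xyz[r_i] - xyz[r_j], axis=1)
            ok_restraints = bool(
                np.all((d0 >= r_lo - 0.02) & (d0 <= r_hi + 0.02))
            )
        else:
            ok_restraints = True
        if ok_restraints and not cand:
            break  # nothing to fix
        sol = least_squares(
            resid,
            x0,
            jac_sparsity=sparsity,
            method="trf",
            max_nfev=max_nfev,
            xtol=1e-8,
            ftol=1e-8,
        )
        xyz = positions(sol.x)
    return xyz
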