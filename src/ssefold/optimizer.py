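"""Simulated-annealing Monte Carlo refinement under restraints.

Movable elements (contiguous spans whose rigid motion breaks no helix)
are translated, rotated about a point, or rotated about the axis through
their anchors; moves are accepted by the Metropolis rule on a weighted
energy of chain connectivity, steric clashes, secondary-structure
maintenance, restraint violations and (optionally) the knowledge-based
potential.  The annealing protocol heats from low to high temperature
and then cools back down.

Pseudoknots enter exactly here: their base pairs are converted to
flat-bottom distance restraints, so the refinement pulls the crossing
stem together without ever needing a pseudoknot template.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .conformation import Conformation
from .geometry import (
    rotate_span_about_axis,
    rotate_span_about_point,
    translate_span,
)
from . import nucgeom
from .secstruct import MovableElement, SecondaryStructure

__all__ = [
    "Restraint",
    "AnnealSchedule",
    "OptimizerEnergy",
    "restraints_from_pseudoknot",
    "dca_restraint_count",
    "read_restraints",
    "write_restraints",
    "energy",
    "samc_optimize",
    "best_of",
]

log = logging.getLogger(__name__)

# base-pair restraint geometry, measured on the ideal helix fixture:
# C1'-C1' 10.78 Å across a pair, purine N1 to pyrimidine N3 2.83 Å
PAIR_C1C1_TARGET = (9.3, 12.3)  # 10.8 +- 1.5
PAIR_N1N3_TARGET = (2.0, 3.6)  # 2.8 +- 0.8

# covalent junction window used by the connectivity term
CONN_BOUNDS = (1.2, 2.0)
CLASH_DIST = 2.5
WC_C1C1 = (9.0, 11.6)
WC_N1N3 = (2.0, 3.6)


@dataclass(frozen=True)
class Restraint:
    """Base-pair or distance restraint between residues ``i < j`` (0-based).

    ``base_pair`` restraints carry the canonical pair windows on
    C1'-C1' (and N1-N3 when applicable); ``distance`` restraints carry
    explicit bounds on a chosen atom pair (default C1').
    """

    kind: str  # "base_pair" | "distance"
    i: int
    j: int
    lower: float = 0.0
    upper: float = 0.0
    atom: str = "C1'"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("restraint needs two distinct residues")
        if self.kind not in ("base_pair", "distance"):
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if self.kind == "distance" and not (0 <= self.lower <= self.upper):
            raise ValueError("distance restraint needs 0 <= lower <= upper")
        if self.weight <= 0:
            raise ValueError("restraint weight must be positive")


@dataclass
class AnnealSchedule:
    """Two-phase annealing: heat T_low -> T_high, then cool back down.

    Temperatures are in the (dimensionless) units of the energy
    function.  Each phase visits ``rungs`` geometrically spaced
    temperatures with ``sweeps`` Monte Carlo steps at each.
    """

    t_low: float = 0.05
    t_high: float = 5.0
    rungs: int = 10
    sweeps: int = 25

    def __post_init__(self) -> None:
        if not (0 < self.t_low < self.t_high):
            raise ValueError("need 0 < t_low < t_high")
        if self.rungs < 1 or self.sweeps < 0:
            raise ValueError("need rungs >= 1 and sweeps >= 0")

    def temperatures(self) -> list[float]:
        ratio = (self.t_high / self.t_low) ** (1.0 / max(self.rungs - 1, 1))
        up = [self.t_low * ratio**k for k in range(self.rungs)]
        return up + up[::-1]

    @property
    def total_steps(self) -> int:
        return 2 * self.rungs * self.sweeps


@dataclass
class OptimizerEnergy:
    """Term weights of the refinement energy (all >= 0)."""

    w_conn: float = 1.0
    w_clash: float = 0.3
    w_ss: float = 1.0
    w_restraint: float = 1.0
    w_stat: float = 0.0
    potential: object = None  # ScoringTables when w_stat > 0

    def __post_init__(self) -> None:
        for nm in ("w_conn", "w_clash", "w_ss", "w_restraint", "w_stat"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")


# ---------------------------------------------------------------------------
# restraint construction and I/O


def restraints_from_pseudoknot(pk_pairs) -> list[Restraint]:
    """One base-pair restraint per pseudoknot pair."""
    out = []
    for i, j in sorted(pk_pairs):
        i, j = min(i, j), max(i, j)
        out.append(
            Restraint(
                "base_pair",
                i,
                j,
                lower=PAIR_C1C1_TARGET[0],
                upper=PAIR_C1C1_TARGET[1],
                weight=1.0,
            )
        )
    return out


def dca_restraint_count(sequence_length: int) -> int:
    """How many top coevolution contacts to keep: floor(0.2 * length)."""
    if sequence_length < 0:
        raise ValueError("length must be >= 0")
    return int(math.floor(0.2 * sequence_length))


def read_restraints(path) -> list[Restraint]:
    """Line-oriented restraint file.

    ``PAIR i j [weight]`` declares a base-pair restraint and
    ``DIST i j lower upper [weight]`` a distance restraint (C1'-C1');
    residue numbers are 1-based, '#' starts a comment.
    """
    out = []
    with open(path) as fh:
        for ln_no, raw in enumerate(fh, start=1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            try:
                tag = parts[0].upper()
                if tag == "PAIR":
                    i, j = int(parts[1]) - 1, int(parts[2]) - 1
                    w = float(parts[3]) if len(parts) > 3 else 1.0
                    out.extend(
                        replace(r, weight=w)
                        for r in restraints_from_pseudoknot([(i, j)])
                    )
                elif tag == "DIST":
                    i, j = int(parts[1]) - 1, int(parts[2]) - 1
                    lo, hi = float(parts[3]), float(parts[4])
                    w = float(parts[5]) if len(parts) > 5 else 1.0
                    out.append(
                        Restraint("distance", min(i, j), max(i, j), lo, hi, weight=w)
                    )
                else:
                    raise ValueError(f"unknown tag {tag!r}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{ln_no}: bad restraint line: {exc}") from exc
    return out


def write_restraints(restraints: list[Restraint], path) -> None:
    with open(path, "w") as fh:
        for r in restraints:
            if r.kind == "base_pair":
                fh.write(f"PAIR {r.i + 1} {r.j + 1} {r.weight:g}\n")
            else:
                fh.write(
                    f"DIST {r.i + 1} {r.j + 1} {r.lower:g} {r.upper:g} {r.weight:g}\n"
                )


# ---------------------------------------------------------------------------
# energy


def _flat_bottom(d: float, lo: float, hi: float) -> float:
    if d < lo:
        return lo - d
    if d > hi:
        return d - hi
    return 0.0


def restraint_violation(conf: Conformation, r: Restraint) -> float:
    """Largest bound violation of one restraint, in Å (0 = satisfied)."""
    viol = 0.0
    if r.kind == "distance":
        if conf.has_atom(r.i, r.atom) and conf.has_atom(r.j, r.atom):
            d = float(np.linalg.norm(conf.atom(r.i, r.atom) - conf.atom(r.j, r.atom)))
            viol = _flat_bottom(d, r.lower, r.upper)
        return viol
    # base_pair: C1'-C1' window plus N1-N3 when a purine-pyrimidine pair
    if conf.has_atom(r.i, "C1'") and conf.has_atom(r.j, "C1'"):
        d = float(np.linalg.norm(conf.atom(r.i, "C1'") - conf.atom(r.j, "C1'")))
        viol = max(viol, _flat_bottom(d, r.lower, r.upper))
    bi, bj = conf.sequence[r.i], conf.sequence[r.j]
    pur, pyr = (r.i, r.j) if bi in "AG" else (r.j, r.i)
    if not (bi in "AG" and bj in "AG") and not (bi in "CU" and bj in "CU"):
        if conf.has_atom(pur, "N1") and conf.has_atom(pyr, "N3"):
            d = float(np.linalg.norm(conf.atom(pur, "N1") - conf.atom(pyr, "N3")))
            viol = max(viol, _flat_bottom(d, *PAIR_N1N3_TARGET))
    return viol


def _connectivity_term(conf: Conformation) -> float:
    e = 0.0
    for _, d in conf.backbone_gaps():
        e += _flat_bottom(d, *CONN_BOUNDS) ** 2
    return e


def _clash_term(conf: Conformation) -> float:
    tree = cKDTree(conf.xyz)
    e = 0.0
    for i, j in tree.query_pairs(CLASH_DIST):
        ri, ni = conf.labels[i]
        rj, nj = conf.labels[j]
        if ri == rj:
            continue
        if abs(ri - rj) == 1 and {ni, nj} & {
            "P", "OP1", "OP2", "O5'", "O3'", "C3'", "C5'", "C2'",
        }:
            continue
        d = float(np.linalg.norm(conf.xyz[i] - conf.xyz[j]))
        e += (CLASH_DIST - d) ** 2
    return e


def _ss_term(conf: Conformation, pairs) -> float:
    e = 0.0
    for i, j in pairs:
        if conf.has_atom(i, "C1'") and conf.has_atom(j, "C1'"):
            d = float(np.linalg.norm(conf.atom(i, "C1'") - conf.atom(j, "C1'")))
            e += _flat_bottom(d, *WC_C1C1) ** 2
        bi, bj = conf.sequence[i], conf.sequence[j]
        if (bi in "AG") != (bj in "AG"):
            pur, pyr = (i, j) if bi in "AG" else (j, i)
            if conf.has_atom(pur, "N1") and conf.has_atom(pyr, "N3"):
                d = float(
                    np.linalg.norm(conf.atom(pur, "N1") - conf.atom(pyr, "N3"))
                )
                e += _flat_bottom(d, *WC_N1N3) ** 2
    return e


def energy(
    conf: Conformation,
    terms: OptimizerEnergy,
    restraints: list[Restraint] = (),
    ss: SecondaryStructure | None = None,
) -> float:
    """Weighted refinement energy; deterministic in its inputs."""
    e = 0.0
    if terms.w_conn:
        e += terms.w_conn * _connectivity_term(conf)
    if terms.w_clash:
        e += terms.w_clash * _clash_term(conf)
    if terms.w_ss and ss is not None:
        e += terms.w_ss * _ss_term(conf, ss.pairs)
    if terms.w_restraint and restraints:
        for r in restraints:
            e += terms.w_restraint * r.weight * restraint_violation(conf, r) ** 2
    if terms.w_stat and terms.potential is not None:
        e += terms.w_stat * terms.potential.score(conf)
    return e


# ---------------------------------------------------------------------------
# SAMC


# move magnitudes at T_high, scaled by sqrt(T / T_high)
MOVE_SIGMA_TRANS = 2.0  # Å
MOVE_SIGMA_ROT = math.radians(15.0)


def _element_anchors(conf: Conformation, el: MovableElement):
    """Backbone attachment points of a movable element."""
    p5 = conf.atom(el.start, "P") if conf.has_atom(el.start, "P") else conf.atom(el.start, "C1'")
    last = el.stop - 1
    p3 = conf.atom(last, "O3'") if conf.has_atom(last, "O3'") else conf.atom(last, "C1'")
    return np.asarray(p5), np.asarray(p3)


def _apply_random_move(
    conf: Conformation, el: MovableElement, rng: np.random.Generator, scale: float
) -> Conformation:
    residues = list(el.residues)
    cs = conf.coords()
    kind = int(rng.integers(3))
    if kind == 0:
        v = rng.normal(0.0, MOVE_SIGMA_TRANS * scale, 3)
        moved = translate_span(cs, residues, v)
    elif kind == 1:
        sel = cs.xyz[[lab[0] in set(residues) for lab in cs.labels]]
        point = sel.mean(axis=0)
        axis = rng.normal(size=3)
        theta = rng.normal(0.0, MOVE_SIGMA_ROT * scale)
        moved = rotate_span_about_point(cs, residues, point, axis, theta)
    else:
        a5, a3 = _element_anchors(conf, el)
        if np.linalg.norm(a3 - a5) < 1e-6:
            sel = cs.xyz[[lab[0] in set(residues) for lab in cs.labels]]
            a3 = sel.mean(axis=0)
        if np.linalg.norm(a3 - a5) < 1e-6:
            return conf
        theta = rng.normal(0.0, MOVE_SIGMA_ROT * scale)
        moved = rotate_span_about_axis(cs, residues, a5, a3, theta)
    return conf.with_coords(moved)


@dataclass
class SamcResult:
    trajectory: list[Conformation]
    best: Conformation
    best_energy: float
    acceptance_ratio: float
    energies: list[float]


def samc_optimize(
    c0: Conformation,
    elements: list[MovableElement],
    restraints: list[Restraint],
    schedule: AnnealSchedule,
    terms: OptimizerEnergy,
    seed: int = 0,
    ss: SecondaryStructure | None = None,
    max_kept: int = 1000,
) -> SamcResult:
    """Heat-then-cool Metropolis refinement of a conformation.

    At each step one uniformly random movable element gets one uniformly
    random move (translation / rotation about its centroid / rotation
    about its anchor axis) with temperature-scaled magnitude, accepted
    with probability min(1, exp(-dE/T)).  One conformation per
    temperature rung sweep is recorded (capped at ``max_kept``); the
    best-energy conformation seen is tracked separately.  Fixed seed
    gives a bit-reproducible trajectory.
    """
    if not elements:
        raise ValueError("nothing to move: empty movable-element list")
    rng = np.random.default_rng(seed)
    conf = c0.copy()
    e = energy(conf, terms, restraints, ss)
    best, best_e = conf.copy(), e
    temps = schedule.temperatures()
    stride = max(1, (schedule.total_steps // max_kept))
    trajectory = [conf.copy()]
    energies = [e]
    accepted = 0
    total = 0
    step = 0
    for t in temps:
        scale = math.sqrt(t / schedule.t_high)
        for _ in range(schedule.sweeps):
            el = elements[int(rng.integers(len(elements)))]
            cand = _apply_random_move(conf, el, rng, scale)
            e_new = energy(cand, terms, restraints, ss)
            total += 1
            de = e_new - e
            if de <= 0 or rng.random() < math.exp(-de / max(t, 1e-12)):
                conf, e = cand, e_new
                accepted += 1
                if e < best_e:
                    best, best_e = conf.copy(), e
            step += 1
            if step % stride == 0:
                trajectory.append(conf.copy())
                energies.append(e)
    if total and (len(trajectory) == 1 or energies[-1] != e):
        trajectory.append(conf.copy())
        energies.append(e)
    ratio = accepted / total if total else 1.0
    log.info(
        "samc: %d steps, acceptance %.3f, best energy %.4f", total, ratio, best_e
    )
    return SamcResult(trajectory, best, best_e, ratio, energies)


def best_of(
    trajectory: list[Conformation],
    terms: OptimizerEnergy,
    restraints: list[Restraint] = (),
    ss: SecondaryStructure | None = None,
) -> Conformation:
    """Minimum-energy member of a trajectory (ties: earliest)."""
    if not trajectory:
        raise ValueError("empty trajectory")
    best = None
    best_e = math.inf
    for c in trajectory:
        e = energy(c, terms, restraints, ss)
        if e < best_e:
            best, best_e = c, e
    return best.copy()
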