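"""Idealized ribonucleotide geometry and A-form helical parameters.

``NUCLEOTIDES`` holds heavy-atom coordinates of each base type in a
standard Watson-Crick pair frame.  The frame follows the usual base
reference-frame convention (C1' near (-2.5, 5.4), glycosidic nitrogen
near (-1.3, 4.5), both bases of a pair sharing the frame), except that
an 18.8-degree base-pair inclination is folded into the coordinates so
that helical propagation is a pure screw about z.  The paired partner of
a base is the proper 180-degree flip about x, ``PAIR_FLIP``;
complementary bases placed that way form canonical hydrogen-bond
geometry (N1-N3 ~ 2.8 A, C1'-C1' ~ 10.8 A; G.U wobbles are placed with
the same geometry, an accepted idealization).

The shared sugar-phosphate backbone was refined by least squares so that
propagating residues with the helical step (``TWIST_DEG`` = 32.7,
``RISE`` = 2.81 A, pair center displaced ``DISPLACEMENT`` from the
axis) keeps both strands covalently continuous (O3'-P = 1.60 A) with
preserved sugar chirality and no heavy-atom contacts below 2.9 A:
an idealized eleven-residues-per-turn A-form duplex.
"""

from __future__ import annotations

import numpy as np

from .geometry import RigidTransform, rotation_about_axis

__all__ = [
    "NUCLEOTIDES",
    "TWIST_DEG",
    "RISE",
    "DISPLACEMENT",
    "PAIR_FLIP",
    "GLYCOSIDIC_N",
    "BASE_RING",
    "ANCHOR_ATOMS",
    "BACKBONE_ATOMS",
    "WC_COMPLEMENT",
    "is_complementary",
    "complement",
    "pair_frame",
    "strand_frames",
    "place_nucleotide",
    "fit_base_frame",
]

TWIST_DEG = 32.7
RISE = 2.81
DISPLACEMENT = np.array([-3.1359, 0.0, 0.0])
PAIR_FLIP = np.diag([1.0, -1.0, -1.0])

GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}
BASE_RING = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}
# pseudo-matched anchors used to transfer a frame between unlike bases
# (purine N9/C4/C8 correspond spatially to pyrimidine N1/C2/C6)
ANCHOR_ATOMS = {
    "A": ("C1'", "N9", "C4", "C8"),
    "G": ("C1'", "N9", "C4", "C8"),
    "C": ("C1'", "N1", "C2", "C6"),
    "U": ("C1'", "N1", "C2", "C6"),
}
BACKBONE_ATOMS = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
)

WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_PAIRABLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def complement(base: str) -> str:
    return WC_COMPLEMENT[base]


def is_complementary(a: str, b: str) -> bool:
    """Watson-Crick or G.U wobble."""
    return (a, b) in _PAIRABLE


def pair_frame(i: int) -> RigidTransform:
    """Rigid transform placing pair-frame coordinates of helix step ``i``.

    Local point p maps to Rz(i*twist) @ (p + DISPLACEMENT) + i*RISE*z.
    """
    rot = rotation_about_axis([0.0, 0.0, 1.0], np.deg2rad(TWIST_DEG) * i)
    trans = rot @ DISPLACEMENT + np.array([0.0, 0.0, RISE * i])
    return RigidTransform(rot, trans)


def strand_frames(i: int) -> tuple[RigidTransform, RigidTransform]:
    """Residue frames for the two strands of pair ``i`` (A: 5'->3' with
    increasing i; B: antiparallel partner)."""
    t = pair_frame(i)
    flip = RigidTransform(PAIR_FLIP, np.zeros(3))
    return t, t.compose(flip)


def place_nucleotide(base: str, frame: RigidTransform) -> dict[str, np.ndarray]:
    """Standard nucleotide of ``base`` mapped through ``frame``."""
    out = {}
    for name, pos in NUCLEOTIDES[base].items():
        out[name] = frame.apply(np.asarray(pos, dtype=float)[None, :])[0]
    return out


def fit_base_frame(atoms: dict[str, np.ndarray], base: str) -> RigidTransform:
    """Transform mapping the standard nucleotide onto placed ``atoms``.

    Fits on the four anchor atoms (C1', glycosidic N and its two ring
    neighbours), which have near-identical standard positions for all
    bases, so the frame can be transferred between unlike bases when a
    template residue is remodelled to the target sequence.
    """
    from .geometry import CoordSet, kabsch

    names = ANCHOR_ATOMS[base]
    missing = [nm for nm in names if nm not in atoms]
    if missing:
        raise ValueError(f"cannot fit base frame, missing atoms {missing}")
    std = np.array([NUCLEOTIDES[base][nm] for nm in names])
    plc = np.array([atoms[nm] for nm in names])
    labels = [(0, nm) for nm in names]
    tf, _ = kabsch(CoordSet(labels, std), CoordSet(labels, plc))
    return tf


# ---------------------------------------------------------------------------
# Frozen standard nucleotide coordinates (pair frame, Å).  Derived from
# chemical-component ideal residue geometry fitted into the standard pair
# frame, with the shared backbone least-squares-refined for helical
# continuity as described in the module docstring.

NUCLEOTIDES: dict[str, dict[str, tuple[float, float, float]]] = {}


def _load_constants() -> None:
    from ._nucdata import NUCLEOTIDE_COORDS

    for base, atoms in NUCLEOTIDE_COORDS.items():
        NUCLEOTIDES[base] = {nm: np.array(p) for nm, p in atoms.items()}


_load_constants()
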