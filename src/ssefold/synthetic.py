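"""Synthetic RNA structures: loop templates and full ground-truth models.

These generators stand in for experimentally derived fragments so the
whole pipeline runs self-contained: loops are built by interpolating
nucleotide frames along the screw motion between their anchor helices
(then geometrically relaxed for covalent closure), stems are ideal
A-form helices, and complete molecules are produced by running the
regular tree assembly on those pieces.  A dedicated constructor builds
coaxially stacked hairpin-type (H-type) pseudoknots used as ground truth
in restraint-refinement experiments.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm, logm

from .conformation import Conformation
from .geometry import CoordSet, RigidTransform
from . import nucgeom
from .refine import DistanceRestraint, rigid_body_refine
from .secstruct import SecondaryStructure, parse_dotbracket, decompose_sse
from .templates import Template, build_ideal_helix

__all__ = [
    "interpolate_frames",
    "build_loop_template",
    "build_structure",
    "build_h_pseudoknot",
]

# covalent O3'-P junction target and acceptance window (Å)
BOND_LENGTH = 1.60
BOND_BOUNDS = (1.2, 2.0)


def interpolate_frames(
    start: RigidTransform, end: RigidTransform, count: int
) -> list[RigidTransform]:
    """``count`` frames along the screw motion from ``start`` to ``end``.

    Frame k sits at fraction (k+1)/(count+1) of the relative screw, so
    consecutive nucleotides placed on these frames advance uniformly.
    """
    rel = start.inverse().compose(end)
    log_rel = logm(rel.as_matrix())
    out = []
    # when the anchors point against each other (hairpin-type turn) the
    # screw geodesic can cut through the preceding helix; arch the path
    # outward along the start frame's helix axis instead
    z_start = start.rotation @ np.array([0.0, 0.0, 1.0])
    z_end = end.rotation @ np.array([0.0, 0.0, 1.0])
    turning = float(np.dot(z_start, z_end)) < -0.2
    arch = min(1.2 * count, 5.0) if turning else 0.0
    for k in range(count):
        frac = (k + 1) / (count + 1)
        step = np.real(expm(frac * log_rel))
        # re-orthogonalize the rotation block against logm round-off
        u, _, vt = np.linalg.svd(step[:3, :3])
        rot = u @ vt
        if np.linalg.det(rot) < 0:
            u[:, -1] *= -1
            rot = u @ vt
        frame = start.compose(RigidTransform(rot, step[:3, 3]))
        if arch:
            lifted = frame.translation + arch * np.sin(np.pi * frac) * z_start
            frame = RigidTransform(frame.rotation, lifted)
        out.append(frame)
    return out


def _stub_frames(base: RigidTransform, n_pairs: int = 2):
    """Pair frames of a closing-stub helix rooted at ``base``."""
    return [base.compose(nucgeom.pair_frame(i)) for i in range(n_pairs)]


def _random_complementary(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGU")) for _ in range(n))


def build_loop_template(
    kind: str,
    loop_seqs: list[str],
    rng: np.random.Generator | None = None,
    closing_seqs: list[tuple[str, str]] | None = None,
    relax: bool = True,
) -> Template:
    """Build a loop template with two closing base pairs per helix end.

    ``loop_seqs`` gives the unpaired residues of each strand segment
    5'->3' (one entry for hairpins, two for bulges/internal loops, one
    per segment for junctions; bulge strands may be empty strings).
    ``closing_seqs`` optionally fixes the closing-pair sequences of each
    helix end as (strand1_2mer, strand2_2mer) read 5'->3'; otherwise
    random complementary stubs are generated.

    Geometry: the parent stub is an ideal 2-bp helix; child stubs are
    placed coaxially (internal/bulge) or splayed at fixed tilt/azimuth
    (junctions); loop residues are interpolated along the connecting
    screw motion and the whole element is relaxed for covalent closure.
    """
    rng = rng or np.random.default_rng(0)
    n_ends = {"hairpin": 1, "bulge": 2, "internal": 2}.get(kind, len(loop_seqs))
    if kind == "junction" and len(loop_seqs) < 3:
        raise ValueError("junction needs at least three strand segments")
    if kind in ("bulge", "internal") and len(loop_seqs) != 2:
        raise ValueError(f"{kind} loop needs exactly two strand segments")
    if kind == "hairpin" and len(loop_seqs) != 1:
        raise ValueError("hairpin needs exactly one strand segment")

    if closing_seqs is None:
        closing_seqs = []
        for _ in range(n_ends):
            s1 = _random_complementary(rng, 2)
            s2 = "".join(nucgeom.complement(b) for b in reversed(s1))
            closing_seqs.append((s1, s2))

    counts = tuple(len(s) for s in loop_seqs)

    # ---- child stub base frames -------------------------------------
    parent_base = RigidTransform.identity()
    n_children = n_ends - 1
    child_bases: list[RigidTransform] = []
    if n_children == 1:
        gap = 1 if min(counts) == 0 else 2
        child_bases.append(nucgeom.pair_frame(1 + gap))
    elif n_children > 1:
        tilt = np.deg2rad(55.0)
        for c in range(n_children):
            az = 2.0 * np.pi * (c + 1) / (n_children + 1)
            rz = RigidTransform(
                np.array(
                    [
                        [np.cos(az), -np.sin(az), 0.0],
                        [np.sin(az), np.cos(az), 0.0],
                        [0.0, 0.0, 1.0],
                    ]
                ),
                np.zeros(3),
            )
            ry = RigidTransform(
                np.array(
                    [
                        [np.cos(tilt), 0.0, np.sin(tilt)],
                        [0.0, 1.0, 0.0],
                        [-np.sin(tilt), 0.0, np.cos(tilt)],
                    ]
                ),
                np.zeros(3),
            )
            lift = RigidTransform(np.eye(3), np.array([0.0, 0.0, 2.0 * nucgeom.RISE]))
            push = RigidTransform(np.eye(3), np.array([0.0, 0.0, 2.5 * nucgeom.RISE]))
            child_bases.append(
                nucgeom.pair_frame(1).compose(lift).compose(rz).compose(ry).compose(push)
            )

    # ---- local residue layout ---------------------------------------
    # pattern 5'->3': parent closing residues (outermost first), segment 0,
    # child0 near strand (loop-adjacent pair first), child0 far strand
    # (5'->3', i.e. deepest pair first), segment 1, ..., parent far strand
    p1, p2 = closing_seqs[0]
    np_parent = len(p1)
    parent_frames = _stub_frames(parent_base, np_parent)
    layout = []  # (base, frame, strand_b)
    for k in range(np_parent):
        layout.append((p1[k], parent_frames[k], False))
    for s, seg in enumerate(loop_seqs):
        for b in seg:
            layout.append((b, None, False))
        if s < n_children:
            c1, c2 = closing_seqs[s + 1]
            npc = len(c1)
            cf = _stub_frames(child_bases[s], npc)
            for k in range(npc):
                layout.append((c1[k], cf[k], False))
            for k in range(npc):
                layout.append((c2[k], cf[npc - 1 - k], True))
    for k in range(np_parent):
        layout.append((p2[k], parent_frames[np_parent - 1 - k], True))

    # resolve frames: loop residues interpolate between neighbours
    frames: list[RigidTransform | None] = []
    for base, fr, sb in layout:
        if fr is None:
            frames.append(None)
        else:
            f = fr
            if sb:
                f = f.compose(RigidTransform(nucgeom.PAIR_FLIP, np.zeros(3)))
            frames.append(f)
    i = 0
    while i < len(frames):
        if frames[i] is None:
            j = i
            while frames[j] is None:
                j += 1
            fill = interpolate_frames(frames[i - 1], frames[j], j - i)
            frames[i:j] = fill
            i = j
        i += 1

    seq = "".join(b for b, _, _ in layout)
    atom_sets = [nucgeom.place_nucleotide(b, f) for (b, _, _), f in zip(layout, frames)]

    # ---- strand / end-pair metadata ---------------------------------
    m = len(layout)
    end_pairs = [[(k, m - 1 - k) for k in range(np_parent)]]
    strands = []
    pos = np_parent
    for s, seg in enumerate(loop_seqs):
        strand = [pos - 1] + list(range(pos, pos + len(seg)))
        pos += len(seg)
        strand.append(pos)
        strands.append(strand)
        if s < n_children:
            npc = len(closing_seqs[s + 1][0])
            end_pairs.append(
                [(pos + k, pos + 2 * npc - 1 - k) for k in range(npc - 1, -1, -1)]
            )
            pos += 2 * npc

    conf = Conformation.from_residues(seq, atom_sets)
    if relax:
        conf = _relax_loop(conf, strands, end_pairs)

    labels = []
    coords = []
    for r in range(m):
        for nm, p in conf.residue_atoms(r).items():
            labels.append((r, nm))
            coords.append(p)
    return Template(
        sse_kind=kind,
        strand_lengths=counts,
        sequence=seq,
        coords=CoordSet(labels, np.array(coords)),
        source_id="synthetic",
        strands=strands,
        end_pairs=end_pairs,
    )


def build_exterior_template(
    loop_seqs: list[str],
    closing_seqs: list[tuple[str, str]],
    relax: bool = True,
) -> Template:
    """Template for the exterior region: dangling ends and the closing
    stubs of every top-level helix, laid out side by side.

    ``loop_seqs`` has one entry per chain segment (n_helices + 1 of
    them, outermost first; leading/trailing entries may be empty);
    ``closing_seqs`` one (strand1, strand2) stub per top-level helix.
    """
    nc = len(closing_seqs)
    if len(loop_seqs) != nc + 1:
        raise ValueError("exterior needs one more segment than helix ends")
    if nc == 0:
        raise ValueError("exterior template needs at least one helix end")
    spacing = 16.0
    child_bases = [
        RigidTransform(np.eye(3), np.array([c * spacing, 0.0, 0.0]))
        for c in range(nc)
    ]
    flip = RigidTransform(nucgeom.PAIR_FLIP, np.zeros(3))

    layout: list[tuple[str, RigidTransform | None]] = []
    strands: list[list[int]] = []
    end_pairs: list[list[tuple[int, int]]] = []
    pos = 0
    for s, seg in enumerate(loop_seqs):
        seg_idx = []
        if s == 0:
            for k, b in enumerate(seg):
                fr = child_bases[0].compose(nucgeom.pair_frame(-(len(seg) - k)))
                layout.append((b, fr))
                seg_idx.append(pos)
                pos += 1
        elif s == nc:
            for k, b in enumerate(seg):
                fr = child_bases[-1].compose(nucgeom.pair_frame(-(k + 1))).compose(flip)
                layout.append((b, fr))
                seg_idx.append(pos)
                pos += 1
        else:
            for b in seg:
                layout.append((b, None))
                seg_idx.append(pos)
                pos += 1
        if s < nc:
            c1, c2 = closing_seqs[s]
            npc = len(c1)
            cf = _stub_frames(child_bases[s], npc)
            near0 = pos
            for k in range(npc):
                layout.append((c1[k], cf[k]))
                pos += 1
            for k in range(npc):
                layout.append((c2[k], cf[npc - 1 - k].compose(flip)))
                pos += 1
            end_pairs.append(
                [(near0 + k, near0 + 2 * npc - 1 - k) for k in range(npc - 1, -1, -1)]
            )
            # strand bookkeeping: previous segment attaches to near outer
            if s == 0:
                strands.append(seg_idx + [near0])
            else:
                strands.append([prev_far_outer] + seg_idx + [near0])
            prev_far_outer = near0 + 2 * npc - 1
        else:
            strands.append([prev_far_outer] + seg_idx)

    frames: list[RigidTransform | None] = [fr for _, fr in layout]
    i = 0
    while i < len(frames):
        if frames[i] is None:
            j = i
            while frames[j] is None:
                j += 1
            frames[i:j] = interpolate_frames(frames[i - 1], frames[j], j - i)
            i = j
        i += 1
    seq = "".join(b for b, _ in layout)
    atom_sets = [nucgeom.place_nucleotide(b, f) for (b, _), f in zip(layout, frames)]
    conf = Conformation.from_residues(seq, atom_sets)
    if relax:
        conf = _relax_loop(conf, strands, end_pairs, fix_first_end=True)

    labels, coords = [], []
    for r in range(len(layout)):
        for nm, p in conf.residue_atoms(r).items():
            labels.append((r, nm))
            coords.append(p)
    return Template(
        sse_kind="exterior",
        strand_lengths=tuple(len(s) for s in loop_seqs),
        sequence=seq,
        coords=CoordSet(labels, np.array(coords)),
        source_id="synthetic",
        strands=strands,
        end_pairs=end_pairs,
    )


def _relax_loop(conf: Conformation, strands, end_pairs, fix_first_end: bool = True) -> Conformation:
    """Close the covalent junctions of a freshly laid-out loop."""
    closing_res = {r for end in end_pairs for p in end for r in p}
    atom_idx = {lab: k for k, lab in enumerate(conf.labels)}
    # bodies: one per closing-pair *end* (stub moves rigidly), one per loop residue
    bodies = []
    fixed = set()
    body_of_res = {}
    for e, end in enumerate(end_pairs):
        idx = [
            k
            for k, (r, _) in enumerate(conf.labels)
            if any(r in p for p in end)
        ]
        bodies.append(np.array(idx))
        for p in end:
            for r in p:
                body_of_res[r] = len(bodies) - 1
        if e == 0 and fix_first_end:
            fixed.add(len(bodies) - 1)
    for r in range(conf.n_residues):
        if r in body_of_res:
            continue
        idx = [k for k, (rr, _) in enumerate(conf.labels) if rr == r]
        bodies.append(np.array(idx))
        body_of_res[r] = len(bodies) - 1

    restraints = []
    exempt = set()
    for strand in strands:
        for a, b in zip(strand, strand[1:]):
            if (a, "O3'") in atom_idx and (b, "P") in atom_idx:
                i, j = atom_idx[(a, "O3'")], atom_idx[(b, "P")]
                restraints.append(DistanceRestraint(i, j, BOND_LENGTH, BOND_LENGTH, 8.0))
                exempt.add(frozenset((i, j)))
                for extra, lo, hi in (("O5'", 2.2, 2.8), ("OP1", 2.2, 3.2), ("OP2", 2.2, 3.2)):
                    if (b, extra) in atom_idx:
                        exempt.add(frozenset((i, atom_idx[(b, extra)])))
                if (a, "C3'") in atom_idx:
                    k2 = atom_idx[(a, "C3'")]
                    restraints.append(DistanceRestraint(k2, j, 2.4, 2.7, 3.0))
                    exempt.add(frozenset((k2, j)))
    new_xyz = rigid_body_refine(
        conf.xyz, bodies, restraints, fixed=fixed, clash_exempt=exempt
    )
    out = conf.copy()
    out.xyz = new_xyz
    return out


# ---------------------------------------------------------------------------
# full molecules


def random_sequence_for(dotbracket: str, seed: int = 0) -> str:
    """Random sequence consistent with a dot-bracket: paired positions
    are Watson-Crick complementary, unpaired positions uniform."""
    from .secstruct import _match_brackets

    rng = np.random.default_rng(seed)
    pairs = _match_brackets(dotbracket)
    seq = [""] * len(dotbracket)
    paired = {i for p in pairs for i in p}
    for i, j in sorted(pairs):
        b = str(rng.choice(list("ACGU")))
        seq[i] = b
        seq[j] = nucgeom.complement(b)
    for i in range(len(seq)):
        if i not in paired:
            seq[i] = str(rng.choice(list("ACGU")))
    return "".join(seq)


def build_structure(
    sequence: str, dotbracket: str, seed: int = 0
) -> tuple[Conformation, SecondaryStructure]:
    """Deterministic synthetic 3D structure for a nested secondary structure.

    Stems are ideal A-form helices; loops are frame-interpolated with the
    correct closing-pair sequences; the pieces are assembled by the
    regular tree assembler.  Pseudoknot pairs in the input are accepted
    but not realized in 3D (they remain in the returned secondary
    structure as pk_pairs).
    """
    from .assembler import assemble
    from .templates import template_from_node

    from .assembler import assemble, relax as _relax_full

    ss = parse_dotbracket(dotbracket, sequence)
    tree = decompose_sse(ss)
    rng = np.random.default_rng(seed)
    choices = {}
    for node in tree.walk():
        choices[id(node)] = _node_template(node, ss, rng)
    conf = assemble(tree, choices, ss)
    conf = _relax_full(conf, ss=ss)
    return conf, ss


def _node_template_layout(node, ss: SecondaryStructure) -> Template:
    """Deterministic unrelaxed base template for a node (ideal closing
    stubs + frame-interpolated loop residues); the starting point for
    the de novo loop generators."""
    return _node_template(node, ss, np.random.default_rng(0), relax=False)


def _node_template(node, ss: SecondaryStructure, rng, relax: bool = True) -> Template:
    from .templates import build_ideal_helix

    if node.kind == "stem":
        seq5 = "".join(ss.sequence[r] for r in node.strands[0])
        seq3 = "".join(ss.sequence[r] for r in node.strands[1])
        return build_ideal_helix(seq5, seq3)
    if node.kind == "exterior" and not node.closing_pairs:
        raise ValueError("cannot build a template for an unpaired chain")
    # loop node: closing sequences from the actual structure
    closing = []
    for end in node.end_pairs:
        # strand 1 and strand 2 of the stub, both read 5'->3'
        s1 = "".join(ss.sequence[p[0]] for p in sorted(end, key=lambda p: p[0]))
        s2 = "".join(ss.sequence[p[1]] for p in sorted(end, key=lambda p: p[1]))
        closing.append((s1, s2))
    if node.kind == "exterior":
        loop_seqs = []
        for strand in node.strands:
            inner = [r for r in strand if not any(r in p for p in node.closing_pairs)]
            loop_seqs.append("".join(ss.sequence[r] for r in inner))
        return build_exterior_template(loop_seqs, closing, relax=relax)
    loop_seqs = []
    for strand in node.strands:
        inner = [r for r in strand if not any(r in p for p in node.closing_pairs)]
        loop_seqs.append("".join(ss.sequence[r] for r in inner))
    t = build_loop_template(
        node.kind,
        loop_seqs,
        rng=rng,
        closing_seqs=closing,
        relax=relax,
    )
    return t


def build_h_pseudoknot(
    stem1: int = 5,
    stem2: int = 4,
    loop1: int = 2,
    loop2: int = 8,
    seed: int = 0,
) -> tuple[Conformation, SecondaryStructure]:
    """Coaxially stacked H-type pseudoknot as a synthetic ground truth.

    Layout 5'->3': stem1-5' / loop1 / stem2-5' / stem1-3' / loop2 /
    stem2-3'.  Stem2 stacks on top of stem1 so the two helices share one
    quasi-continuous axis, the classic fold of hairpin-type mRNA
    pseudoknots.  Returns the relaxed conformation and the secondary
    structure whose ``pk_pairs`` are the stem2 pairs.
    """
    rng = np.random.default_rng(seed)
    L1, L2, l1, l2 = stem1, stem2, loop1, loop2
    n = 2 * L1 + 2 * L2 + l1 + l2

    s1a = _random_complementary(rng, L1)
    s2a = _random_complementary(rng, L2)
    j1 = _random_complementary(rng, l1)
    j2 = _random_complementary(rng, l2)
    s1b = "".join(nucgeom.complement(b) for b in reversed(s1a))
    s2b = "".join(nucgeom.complement(b) for b in reversed(s2a))
    seq = s1a + j1 + s2a + s1b + j2 + s2b

    idx_s2a = L1 + l1
    idx_s1b = L1 + l1 + L2
    idx_j2 = idx_s1b + L1
    idx_s2b = idx_j2 + l2
    pairs1 = {(k, idx_j2 - 1 - k) for k in range(L1)}
    pairs2 = {(idx_s2a + m, n - 1 - m) for m in range(L2)}

    frames: dict[int, RigidTransform] = {}
    flip = RigidTransform(nucgeom.PAIR_FLIP, np.zeros(3))
    for k in range(L1):  # stem1
        fa = nucgeom.pair_frame(k)
        frames[k] = fa
        frames[idx_j2 - 1 - k] = fa.compose(flip)
    for m in range(L2):  # stem2 stacked above stem1
        fa = nucgeom.pair_frame(L1 + (L2 - 1 - m))
        frames[idx_s2a + m] = fa.compose(flip)
        frames[n - 1 - m] = fa
    # loops by interpolation
    for start, stop in (
        (L1 - 1, idx_s2a),  # loop1 bridges stem1 top (A) to stem2 far side
        (idx_j2 - 1, idx_s2b),  # loop2 bridges stem1 bottom (B) to stem2 near strand
    ):
        count = stop - start - 1
        fill = interpolate_frames(frames[start], frames[stop], count)
        for k, f in enumerate(fill):
            frames[start + 1 + k] = f

    atoms = [nucgeom.place_nucleotide(seq[i], frames[i]) for i in range(n)]
    conf = Conformation.from_residues(seq, atoms)

    # relax: stems rigid, loop residues free
    stem_res = {r for p in pairs1 | pairs2 for r in p}
    atom_idx = {lab: k for k, lab in enumerate(conf.labels)}
    bodies = []
    fixed = set()
    body1 = [k for k, (r, _) in enumerate(conf.labels) if any(r in p for p in pairs1)]
    body2 = [k for k, (r, _) in enumerate(conf.labels) if any(r in p for p in pairs2)]
    bodies.append(np.array(body1))
    fixed.add(0)
    bodies.append(np.array(body2))
    for r in range(n):
        if r in stem_res:
            continue
        bodies.append(
            np.array([k for k, (rr, _) in enumerate(conf.labels) if rr == r])
        )
    restraints = []
    exempt = set()
    for a in range(n - 1):
        b = a + 1
        if (a, "O3'") in atom_idx and (b, "P") in atom_idx:
            i, j = atom_idx[(a, "O3'")], atom_idx[(b, "P")]
            restraints.append(DistanceRestraint(i, j, BOND_LENGTH, BOND_LENGTH, 8.0))
            exempt.add(frozenset((i, j)))
            for extra in ("O5'", "OP1", "OP2"):
                if (b, extra) in atom_idx:
                    exempt.add(frozenset((i, atom_idx[(b, extra)])))
    conf.xyz = rigid_body_refine(
        conf.xyz, bodies, restraints, fixed=fixed, clash_exempt=exempt
    )
    ss = SecondaryStructure(seq, pairs1, pairs2)
    conf.provenance["generator"] = "h_pseudoknot"
    return conf, ss
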