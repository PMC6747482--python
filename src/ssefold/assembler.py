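"""Tree assembly of SSE templates into full conformations.

Templates are placed by pre-order traversal of the SSE tree: each child
template is rigid-body superposed onto its parent through the atoms of
their shared closing base pairs, duplicated residues keep the parent's
copy, and template residues whose base differs from the target sequence
are remodelled (backbone kept, standard base atoms re-placed through the
fitted glycosidic frame).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .conformation import Conformation
from .geometry import CoordSet, kabsch
from . import nucgeom
from .refine import DistanceRestraint, rigid_body_refine
from .secstruct import SecondaryStructure, SSENode
from .templates import Template, TemplateLibrary, query_templates
from .synthetic import BOND_LENGTH, BOND_BOUNDS

__all__ = [
    "PredictionConfig",
    "AssemblyError",
    "assemble",
    "assemble_top",
    "sample_templates",
    "relax",
]

log = logging.getLogger(__name__)


class AssemblyError(RuntimeError):
    pass


@dataclass
class PredictionConfig:
    """Knobs of a prediction run.

    ``n_predictions`` is the number of final models (default 5) and
    doubles as the cluster count; ``sampling_steps`` is the number of
    template-swap steps in sampling mode (default 500).
    """

    n_predictions: int = 5
    sampling_steps: int = 500
    seed: int = 0
    exclude_ids: set[str] = field(default_factory=set)
    refine: bool = True

    def __post_init__(self) -> None:
        if self.n_predictions < 1:
            raise ValueError("n_predictions must be >= 1")
        if self.sampling_steps < 0:
            raise ValueError("sampling_steps must be >= 0")


def _remodel_residue(
    atoms: dict[str, np.ndarray], template_base: str, target_base: str
) -> dict[str, np.ndarray]:
    """Mutate a placed residue to the target base, keeping its backbone."""
    if template_base == target_base:
        return dict(atoms)
    frame = nucgeom.fit_base_frame(atoms, template_base)
    std = nucgeom.place_nucleotide(target_base, frame)
    out = {}
    backbone = set(nucgeom.BACKBONE_ATOMS)
    for nm, p in atoms.items():
        if nm in backbone:
            out[nm] = p
    for nm, p in std.items():
        if nm not in backbone:
            out[nm] = p
    return out


def _fit_template(
    t: Template, node: SSENode, ss: SecondaryStructure
) -> dict[int, dict[str, np.ndarray]]:
    """Template residues keyed by global residue index, remodelled to ss."""
    globals_sorted = sorted(set(node.residues))
    if len(globals_sorted) != t.n_residues:
        raise AssemblyError(
            f"template of {t.n_residues} residues does not fit node "
            f"with {len(globals_sorted)} residues ({node.kind})"
        )
    out = {}
    for local, g in enumerate(globals_sorted):
        atoms = t.residue_atoms(local)
        out[g] = _remodel_residue(atoms, t.sequence[local], ss.sequence[g])
    return out


def assemble(
    tree: SSENode,
    choices: dict[int, Template],
    ss: SecondaryStructure,
) -> Conformation:
    """Assemble a conformation from one template per tree node.

    ``choices`` maps ``id(node)`` to the chosen template.  Children are
    superposed onto the already-placed parent through all atoms of their
    shared residues (the closing base pairs); on conflict the parent's
    coordinates win.
    """
    placed: dict[int, dict[str, np.ndarray]] = {}
    provenance = {}
    overlaps: list[float] = []

    def visit(node: SSENode, parent: SSENode | None) -> None:
        t = choices.get(id(node))
        if t is None:
            raise AssemblyError(f"no template for node {node.kind} {node.residues[:4]}...")
        provenance[str(sorted(set(node.residues))[0])] = {
            "kind": node.kind,
            "source_id": t.source_id,
            "template_index": t.meta.get("insertion_index"),
        }
        fitted = _fit_template(t, node, ss)
        if parent is None:
            for g, atoms in fitted.items():
                placed.setdefault(g, atoms)
        else:
            shared = sorted(set(node.residues) & set(placed.keys()))
            if not shared:
                raise AssemblyError("child node shares no residues with placed parent")
            mob_labels, mob_xyz, tgt_xyz = [], [], []
            for g in shared:
                for nm, p in fitted[g].items():
                    if nm in placed[g]:
                        mob_labels.append((g, nm))
                        mob_xyz.append(p)
                        tgt_xyz.append(placed[g][nm])
            if len(mob_labels) < 3:
                raise AssemblyError(
                    f"too few shared atoms ({len(mob_labels)}) to superpose node"
                )
            tf, overlap_rmsd = kabsch(
                CoordSet(mob_labels, np.array(mob_xyz)),
                CoordSet(mob_labels, np.array(tgt_xyz)),
            )
            log.debug("overlap rmsd %.3f on %d atoms", overlap_rmsd, len(mob_labels))
            overlaps.append(float(overlap_rmsd))
            for g, atoms in fitted.items():
                if g in placed:
                    continue  # keep parent's copy
                placed[g] = {nm: tf.apply(p[None, :])[0] for nm, p in atoms.items()}
        for ch in node.children:
            visit(ch, node)

    visit(tree, None)
    missing = set(range(ss.n)) - set(placed.keys())
    if missing:
        raise AssemblyError(f"assembly left residues unplaced: {sorted(missing)[:5]}")
    conf = Conformation.from_residues(
        ss.sequence,
        [placed[i] for i in range(ss.n)],
        provenance={"nodes": provenance, "overlaps": overlaps},
    )
    return conf


def _resolve_templates(
    tree: SSENode,
    lib: TemplateLibrary,
    ss: SecondaryStructure,
    cfg: PredictionConfig,
) -> dict[int, list[Template]]:
    """Ranked candidate templates per node, with de novo fallback."""
    from .loopgen import default_fragment_set, biresidue_build

    candidates: dict[int, list[Template]] = {}
    frags = None
    for node in tree.walk():
        hits = query_templates(lib, node, ss, exclude_ids=cfg.exclude_ids)
        if not hits:
            if node.kind == "stem":
                from .templates import build_ideal_helix

                seq5 = "".join(ss.sequence[r] for r in node.strands[0])
                seq3 = "".join(ss.sequence[r] for r in node.strands[1])
                hits = [build_ideal_helix(seq5, seq3)]
            else:
                if frags is None:
                    frags = default_fragment_set()
                log.info("no template for %s node; generating de novo", node.kind)
                hits = [
                    biresidue_build(
                        node, ss, frags, steps=200, seed=cfg.seed + 17
                    )
                ]
        candidates[id(node)] = hits
    return candidates


def assemble_top(
    tree: SSENode,
    lib: TemplateLibrary,
    ss: SecondaryStructure,
    cfg: PredictionConfig,
) -> list[Conformation]:
    """N assembled structures: rank-1 templates first, then random picks.

    The first conformation uses the top-homology template of every SSE;
    the other N-1 use seeded random choices among the candidates, as in
    fast-assembly mode.
    """
    candidates = _resolve_templates(tree, lib, ss, cfg)
    rng = np.random.default_rng(cfg.seed)
    out = []
    for k in range(cfg.n_predictions):
        choices = {}
        for node in tree.walk():
            cands = candidates[id(node)]
            if k == 0:
                choices[id(node)] = cands[0]
            else:
                choices[id(node)] = cands[int(rng.integers(len(cands)))]
        conf = assemble(tree, choices, ss)
        conf.provenance["prediction_index"] = k
        if cfg.refine:
            conf = relax(conf, ss=ss)
        out.append(conf)
    return out


def sample_templates(
    tree: SSENode,
    lib: TemplateLibrary,
    ss: SecondaryStructure,
    cfg: PredictionConfig,
    steps: int | None = None,
) -> list[Conformation]:
    """Template-swap sampling for ensemble diversity.

    Starts from the top-ranked assembly; at each step one random node's
    template is replaced by a random candidate and the molecule is
    re-assembled.  Every sampled conformation (including the start) is
    returned for clustering.
    """
    steps = cfg.sampling_steps if steps is None else steps
    candidates = _resolve_templates(tree, lib, ss, cfg)
    nodes = list(tree.walk())
    rng = np.random.default_rng(cfg.seed)
    current = {id(n): candidates[id(n)][0] for n in nodes}
    out = [assemble(tree, dict(current), ss)]
    for _ in range(steps):
        node = nodes[int(rng.integers(len(nodes)))]
        cands = candidates[id(node)]
        current[id(node)] = cands[int(rng.integers(len(cands)))]
        out.append(assemble(tree, dict(current), ss))
    return out


def relax(
    conf: Conformation,
    ss: SecondaryStructure | None = None,
    rounds: int = 2,
    restraints: list = (),
) -> Conformation:
    """Geometric relaxation: restore covalent junctions, relieve clashes.

    Residues move as rigid bodies against flat-bottom bond restraints at
    every expected O3'-P junction plus Watson-Crick maintenance
    restraints for the nested pairs of ``ss`` (C1'-C1' and N1-N3 held in
    their canonical windows).  An update that would increase the clash
    count is discarded, so relaxation never makes packing worse.
    """
    atom_idx = {lab: k for k, lab in enumerate(conf.labels)}
    # helices move as single rigid bodies so canonical pair geometry is
    # preserved exactly; all other residues move individually
    helix_of: dict[int, int] = {}
    if ss is not None:
        from .secstruct import _helices

        for h_id, helix in enumerate(_helices(ss.pairs)):
            for p in helix:
                for r in p:
                    helix_of[r] = h_id
    bodies = []
    atoms_of_res: dict[int, list[int]] = {}
    for k, (rr, _) in enumerate(conf.labels):
        atoms_of_res.setdefault(rr, []).append(k)
    helix_atoms: dict[int, list[int]] = {}
    for r in range(conf.n_residues):
        if r in helix_of:
            helix_atoms.setdefault(helix_of[r], []).extend(atoms_of_res[r])
        else:
            bodies.append(np.array(atoms_of_res[r]))
    for h_id in sorted(helix_atoms):
        bodies.append(np.array(helix_atoms[h_id]))
    body_restraints = []
    exempt = set()
    for a in range(conf.n_residues - 1):
        if a in conf.chain_breaks:
            continue
        b = a + 1
        if (a, "O3'") in atom_idx and (b, "P") in atom_idx:
            i, j = atom_idx[(a, "O3'")], atom_idx[(b, "P")]
            body_restraints.append(
                DistanceRestraint(i, j, BOND_BOUNDS[0], BOND_BOUNDS[1] * 0.9, 8.0)
            )
            exempt.add(frozenset((i, j)))
            for extra in ("O5'", "OP1", "OP2", "C5'"):
                if (b, extra) in atom_idx:
                    exempt.add(frozenset((i, atom_idx[(b, extra)])))
            if (a, "C3'") in atom_idx:
                exempt.add(frozenset((atom_idx[(a, "C3'")], j)))
    if ss is not None:
        for i, j in ss.pairs:
            for nm_i, nm_j, lo, hi in _pair_windows(conf.sequence[i], conf.sequence[j]):
                if (i, nm_i) in atom_idx and (j, nm_j) in atom_idx:
                    a_, b_ = atom_idx[(i, nm_i)], atom_idx[(j, nm_j)]
                    body_restraints.append(DistanceRestraint(a_, b_, lo, hi, 4.0))
                    exempt.add(frozenset((a_, b_)))
    for r in restraints:
        # user/pseudoknot restraints: same atom realization as the optimizer
        from .optimizer import PAIR_N1N3_TARGET

        pairs_to_add = []
        if r.kind == "distance":
            pairs_to_add.append((r.atom, r.atom, r.lower, r.upper))
        else:
            pairs_to_add.append(("C1'", "C1'", r.lower, r.upper))
            bi, bj = conf.sequence[r.i], conf.sequence[r.j]
            if (bi in "AG") != (bj in "AG"):
                pur, pyr = (r.i, r.j) if bi in "AG" else (r.j, r.i)
                if (pur, "N1") in atom_idx and (pyr, "N3") in atom_idx:
                    body_restraints.append(
                        DistanceRestraint(
                            atom_idx[(pur, "N1")],
                            atom_idx[(pyr, "N3")],
                            *PAIR_N1N3_TARGET,
                            4.0 * r.weight,
                        )
                    )
                    exempt.add(frozenset((atom_idx[(pur, "N1")], atom_idx[(pyr, "N3")])))
        for nm_i, nm_j, lo, hi in pairs_to_add:
            if (r.i, nm_i) in atom_idx and (r.j, nm_j) in atom_idx:
                a_, b_ = atom_idx[(r.i, nm_i)], atom_idx[(r.j, nm_j)]
                body_restraints.append(DistanceRestraint(a_, b_, lo, hi, 4.0 * r.weight))
                exempt.add(frozenset((a_, b_)))

    before = _clash_count(conf)
    new_xyz = rigid_body_refine(
        conf.xyz, bodies, body_restraints, clash_exempt=exempt, rounds=rounds
    )
    out = conf.copy()
    out.xyz = new_xyz
    if _clash_count(out) > before:
        return conf.copy()
    return out


# canonical pair distance windows (measured on the ideal helix fixture)
WC_C1C1_BOUNDS = (9.8, 11.6)
WC_N1N3_BOUNDS = (2.3, 3.5)


def _pair_windows(base_i: str, base_j: str):
    out = [("C1'", "C1'", *WC_C1C1_BOUNDS)]
    if base_i in "AG" and base_j in "CU":
        out.append(("N1", "N3", *WC_N1N3_BOUNDS))
    elif base_j in "AG" and base_i in "CU":
        out.append(("N3", "N1", *WC_N1N3_BOUNDS))
    return out


def _clash_count(conf: Conformation, cutoff: float = 2.5) -> int:
    from scipy.spatial import cKDTree

    tree = cKDTree(conf.xyz)
    count = 0
    for i, j in tree.query_pairs(cutoff):
        ri, ni = conf.labels[i]
        rj, nj = conf.labels[j]
        if ri == rj:
            continue
        if abs(ri - rj) == 1 and {ni, nj} & {"P", "OP1", "OP2", "O5'", "O3'", "C3'", "C5'"}:
            continue
        count += 1
    return count
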