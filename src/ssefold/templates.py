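"""SSE template library: harvesting, indexing, querying, fixture generation.

A template is an all-atom coordinate fragment shaped like one SSE (stem
or loop, loops carrying up to two closing base pairs per helix end so
successive templates can be assembled by overlapping them).  Templates
are indexed by an exact shape key: helix length for stems, per-strand
unpaired counts for loops.  Queries rank shape-compatible templates by
sequence identity to the query SSE.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conformation import Conformation
from .geometry import CoordSet
from . import nucgeom
from .secstruct import SecondaryStructure, SSENode, decompose_sse, split_pseudoknots

__all__ = [
    "Template",
    "TemplateLibrary",
    "shape_key",
    "harvest_templates",
    "query_templates",
    "build_ideal_helix",
    "build_fixture_library",
]

log = logging.getLogger(__name__)


@dataclass
class Template:
    """An SSE-shaped coordinate fragment with sequence metadata.

    Local residues are numbered 0..m-1 in the 5'->3' order of the source
    residues.  ``end_pairs`` lists closing base pairs (local indices)
    grouped per helix end, the pair farther from the loop first; for
    stems it is [[outermost], [innermost]].
    """

    sse_kind: str
    strand_lengths: tuple[int, ...]
    sequence: str
    coords: CoordSet
    source_id: str
    strands: list[list[int]]
    end_pairs: list[list[tuple[int, int]]]
    meta: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple:
        return (self.sse_kind, self.strand_lengths)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def residue_atoms(self, local_idx: int) -> dict[str, np.ndarray]:
        return {
            nm: self.coords.xyz[k]
            for k, (r, nm) in enumerate(self.coords.labels)
            if r == local_idx
        }


def shape_key(node: SSENode) -> tuple:
    """Exact shape key of an SSE node.

    Stems: ('stem', (helix_length,)).  Loops: (kind, per-strand unpaired
    counts 5'->3').  Exact-match keying is deliberate; misses fall back
    to de novo loop generation.
    """
    if node.kind == "stem":
        return ("stem", (len(node.strands[0]),))
    counts = tuple(
        sum(1 for r in s if not _is_closing(node, r)) for s in node.strands
    )
    return (node.kind, counts)


def _is_closing(node: SSENode, r: int) -> bool:
    return any(r in p for p in node.closing_pairs)


def node_sequence(node: SSENode, ss: SecondaryStructure) -> str:
    return "".join(ss.sequence[r] for r in sorted(set(node.residues)))


class TemplateLibrary:
    """Indexed template collection split into helix and loop sub-libraries."""

    def __init__(self) -> None:
        self._index: dict[tuple, list[Template]] = {}
        self._count = 0

    def add(self, t: Template) -> None:
        self._index.setdefault(t.key, []).append(t)
        t.meta.setdefault("insertion_index", self._count)
        self._count += 1

    def get(self, key: tuple) -> list[Template]:
        return list(self._index.get(key, []))

    def __len__(self) -> int:
        return sum(len(v) for v in self._index.values())

    @property
    def n_helices(self) -> int:
        return sum(len(v) for k, v in self._index.items() if k[0] == "stem")

    @property
    def n_loops(self) -> int:
        return len(self) - self.n_helices

    def merge(self, other: "TemplateLibrary") -> None:
        for ts in other._index.values():
            for t in ts:
                self.add(t)

    # -- persistence ---------------------------------------------------

    def save(self, directory) -> None:
        """One PDB + JSON sidecar per template, grouped by SSE kind."""
        from .pdbio import write_pdb

        root = Path(directory)
        for key, ts in self._index.items():
            for t in ts:
                kdir = root / t.sse_kind
                kdir.mkdir(parents=True, exist_ok=True)
                stem = f"{t.source_id}_{t.meta['insertion_index']:06d}"
                conf = _template_as_conformation(t)
                write_pdb(conf, kdir / f"{stem}.pdb")
                side = {
                    "sse_kind": t.sse_kind,
                    "strand_lengths": list(t.strand_lengths),
                    "sequence": t.sequence,
                    "source_id": t.source_id,
                    "strands": t.strands,
                    "end_pairs": [[list(p) for p in end] for end in t.end_pairs],
                }
                (kdir / f"{stem}.json").write_text(json.dumps(side, indent=1))

    @classmethod
    def load(cls, directory) -> "TemplateLibrary":
        from .pdbio import read_pdb

        lib = cls()
        root = Path(directory)
        for sidecar in sorted(root.glob("*/*.json")):
            meta = json.loads(sidecar.read_text())
            conf = read_pdb(sidecar.with_suffix(".pdb"))
            t = Template(
                sse_kind=meta["sse_kind"],
                strand_lengths=tuple(meta["strand_lengths"]),
                sequence=meta["sequence"],
                coords=conf.coords(),
                source_id=meta["source_id"],
                strands=[list(s) for s in meta["strands"]],
                end_pairs=[[tuple(p) for p in end] for end in meta["end_pairs"]],
            )
            lib.add(t)
        return lib


def _template_as_conformation(t: Template) -> Conformation:
    residues = [t.residue_atoms(i) for i in range(t.n_residues)]
    return Conformation.from_residues(t.sequence, residues)


# ---------------------------------------------------------------------------
# harvesting


def template_from_node(
    node: SSENode, ss: SecondaryStructure, conf: Conformation, source_id: str
) -> Template:
    """Cut one SSE out of an annotated structure as a template."""
    globals_sorted = sorted(set(node.residues))
    local_of = {g: l for l, g in enumerate(globals_sorted)}
    labels = []
    coords = []
    for g in globals_sorted:
        for nm, pos in conf.residue_atoms(g).items():
            labels.append((local_of[g], nm))
            coords.append(pos)
    seq = "".join(ss.sequence[g] for g in globals_sorted)
    if node.kind == "stem":
        strand_lengths = (len(node.strands[0]),)
        strands = [[local_of[g] for g in s] for s in node.strands]
        end_pairs = [
            [tuple(sorted((local_of[i], local_of[j]))) for (i, j) in [node.closing_pairs[0]]],
            [tuple(sorted((local_of[i], local_of[j]))) for (i, j) in [node.closing_pairs[-1]]],
        ]
    else:
        strands = [[local_of[g] for g in s] for s in node.strands]
        counts = tuple(
            sum(1 for r in s if not _is_closing(node, r)) for s in node.strands
        )
        strand_lengths = counts
        end_pairs = [
            [tuple(sorted((local_of[i], local_of[j]))) for (i, j) in end]
            for end in node.end_pairs
        ]
    return Template(
        sse_kind=node.kind,
        strand_lengths=strand_lengths,
        sequence=seq,
        coords=CoordSet(labels, np.array(coords)),
        source_id=source_id,
        strands=strands,
        end_pairs=end_pairs,
    )


def harvest_templates(
    structures: list[tuple[str, Conformation, set[tuple[int, int]] | None]],
) -> TemplateLibrary:
    """Decompose annotated structures into a template library.

    Each entry is ``(source_id, conformation, pairs)``; when ``pairs`` is
    None the base pairs are detected geometrically.  Structures that
    cannot be annotated are skipped with a warning.
    """
    lib = TemplateLibrary()
    for source_id, conf, pairs in structures:
        try:
            if pairs is None:
                from .analysis import annotate_interactions

                pairs = annotate_interactions(conf).wc_pairs
            nested, pk = split_pseudoknots(pairs)
            if pk:
                log.warning("%s: %d crossing pairs ignored during harvest", source_id, len(pk))
            ss = SecondaryStructure(conf.sequence, nested)
            tree = decompose_sse(ss)
        except Exception as exc:  # noqa: BLE001 - harvest is best-effort
            log.warning("skipping %s: %s", source_id, exc)
            continue
        for node in tree.walk():
            if node.kind == "exterior" and not node.closing_pairs:
                continue
            lib.add(template_from_node(node, ss, conf, source_id))
    return lib


# ---------------------------------------------------------------------------
# querying


def sequence_identity(a: str, b: str) -> float:
    if len(a) != len(b) or not a:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def query_templates(
    lib: TemplateLibrary,
    node: SSENode,
    ss: SecondaryStructure,
    exclude_ids: set[str] | None = None,
    n: int | None = None,
) -> list[Template]:
    """Shape-matching templates ranked by sequence identity to the node.

    Ties break on lexicographic source id, then insertion order, making
    the ranking a total order independent of library insertion order.
    An empty result signals the caller to generate the template de novo.
    """
    exclude_ids = exclude_ids or set()
    qseq = node_sequence(node, ss)
    hits = [t for t in lib.get(shape_key(node)) if t.source_id not in exclude_ids]
    hits.sort(
        key=lambda t: (
            -sequence_identity(qseq, t.sequence),
            t.source_id,
            t.meta.get("insertion_index", 0),
        )
    )
    return hits if n is None else hits[:n]


# ---------------------------------------------------------------------------
# fixture generators


def build_ideal_helix(sequence: str, pair_sequence: str | None = None) -> Template:
    """Ideal A-form double helix as a stem template.

    ``sequence`` is the 5'->3' first strand; ``pair_sequence`` (5'->3')
    defaults to the reverse complement.  Strands must be complementary
    (Watson-Crick or G.U wobble) at every position.
    """
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("empty helix sequence")
    L = len(sequence)
    if pair_sequence is None:
        pair_sequence = "".join(nucgeom.complement(b) for b in reversed(sequence))
    pair_sequence = pair_sequence.upper()
    if len(pair_sequence) != L:
        raise ValueError("strand length mismatch")
    for k, (a, b) in enumerate(zip(sequence, reversed(pair_sequence))):
        if not nucgeom.is_complementary(a, b):
            raise ValueError(f"non-complementary pair {a}-{b} at position {k + 1}")

    labels = []
    coords = []
    # local residues: 0..L-1 strand A (outer->inner), L..2L-1 strand B
    # (inner->outer); local pair k is (k, 2L-1-k)
    for k, base in enumerate(sequence):
        fa, fb = nucgeom.strand_frames(k)
        for nm, pos in nucgeom.place_nucleotide(base, fa).items():
            labels.append((k, nm))
            coords.append(pos)
        partner = pair_sequence[L - 1 - k]
        for nm, pos in nucgeom.place_nucleotide(partner, fb).items():
            labels.append((2 * L - 1 - k, nm))
            coords.append(pos)
    order = sorted(range(len(labels)), key=lambda i: labels[i][0])
    labels = [labels[i] for i in order]
    coords = [coords[i] for i in order]
    seq = sequence + pair_sequence
    return Template(
        sse_kind="stem",
        strand_lengths=(L,),
        sequence=seq,
        coords=CoordSet(labels, np.array(coords)),
        source_id="synthetic",
        strands=[list(range(L)), list(range(2 * L - 1, L - 1, -1))],
        end_pairs=[[(0, 2 * L - 1)], [(L - 1, L)]],
    )


def build_fixture_library(
    shapes: list[tuple],
    seed: int = 0,
    n_per_shape: int = 1,
    source_prefix: str = "synthetic",
) -> TemplateLibrary:
    """Deterministic library of ideal helices and generated loops.

    ``shapes`` entries are shape keys: ('stem', (L,)) or
    (loop_kind, per-strand unpaired counts).  Loop templates are built by
    the arc-interpolation generator with ideal-helix closing stubs; the
    seed fixes the sequences and loop jitter, so equal seeds give
    bit-identical libraries.
    """
    from .synthetic import build_loop_template

    rng = np.random.default_rng(seed)
    lib = TemplateLibrary()
    bases = "ACGU"
    for si, key in enumerate(shapes):
        kind, lengths = key
        for rep in range(n_per_shape):
            sid = f"{source_prefix}-{si}-{rep}"
            if kind == "stem":
                (L,) = lengths
                seq = "".join(rng.choice(list(bases)) for _ in range(L))
                t = build_ideal_helix(seq)
                t.source_id = sid
            else:
                loop_seqs = [
                    "".join(rng.choice(list(bases)) for _ in range(c)) for c in lengths
                ]
                t = build_loop_template(
                    kind,
                    loop_seqs,
                    rng=np.random.default_rng(rng.integers(2**31 - 1)),
                )
                t.source_id = sid
            lib.add(t)
    return lib
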