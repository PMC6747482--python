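"""RNA secondary structure: dot-bracket parsing, pseudoknot separation,
decomposition into the tree of smallest secondary elements (SSEs), and
enumeration of movable elements.

An SSE is a stem (helix) or one of the loop types closed by helices
(hairpin, bulge, internal, junction).  The tree of SSEs, with edges at
shared closing base pairs, is the unit of template lookup and assembly.
Base pairs that cross the nesting of the main structure (pseudoknots) are
carried separately and downstream become distance restraints rather than
templates.

Indexing is 0-based internally; user-facing formats (DBN files, PDB
output) are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "SecondaryStructure",
    "SSENode",
    "MovableElement",
    "ParseError",
    "parse_dotbracket",
    "split_pseudoknots",
    "decompose_sse",
    "movable_elements",
    "to_dotbracket",
    "read_dbn",
    "write_dbn",
]

# bracket alphabets in priority order; helix of alphabet k may be crossed by
# pairs of alphabet > k (pseudoknot annotation convention)
_OPENERS = "([{<" + "".join(chr(c) for c in range(ord("A"), ord("Z") + 1))
_CLOSERS = ")]}>" + "".join(chr(c) for c in range(ord("a"), ord("z") + 1))
_ALPHABETS = list(zip(_OPENERS, _CLOSERS))

VALID_BASES = set("ACGU")


class ParseError(ValueError):
    """Malformed dot-bracket or sequence input."""


@dataclass
class SecondaryStructure:
    """Sequence plus base pairs, split into nested and pseudoknot parts.

    ``pairs`` is crossing-free; ``pk_pairs`` holds every pair that crosses
    the nested set.  All pairs are ``(i, j)`` tuples with ``i < j``,
    0-based, and each index occurs in at most one pair overall.
    """

    sequence: str
    pairs: set[tuple[int, int]]
    pk_pairs: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ParseError(f"sequence contains non-RNA characters: {sorted(bad)}")
        seen: set[int] = set()
        for i, j in self.pairs | self.pk_pairs:
            if not (0 <= i < j < n):
                raise ParseError(f"pair ({i},{j}) out of range for length {n}")
            if i in seen or j in seen:
                raise ParseError(f"index appears in more than one pair near ({i},{j})")
            seen.add(i)
            seen.add(j)
        if _crossings(self.pairs):
            raise ParseError("nested pair set contains crossing pairs")

    @property
    def n(self) -> int:
        return len(self.sequence)

    def all_pairs(self) -> set[tuple[int, int]]:
        return self.pairs | self.pk_pairs


@dataclass
class SSENode:
    """One smallest secondary element in the decomposition tree.

    kind:
        ``stem`` | ``hairpin`` | ``bulge`` | ``internal`` | ``junction`` |
        ``exterior`` (degenerate: region outside any helix, including the
        free-chain case of a structure with no pairs).
    residues:
        ordered (5'->3') indices covered by the element, including
        closing-pair residues shared with neighbouring elements.
    closing_pairs:
        for stems: [outermost pair, innermost pair]; for loops: up to two
        stacked pairs per adjoining helix end, ordered parent end first
        then child ends 5'->3', outermost-first within each end.
    """

    kind: str
    residues: list[int]
    closing_pairs: list[tuple[int, int]]
    children: list["SSENode"] = field(default_factory=list)
    # for loops: residues grouped per helix end, used to build shape keys
    strands: list[list[int]] = field(default_factory=list)
    # pairs grouped per helix end (parent end first), outermost-first
    end_pairs: list[list[tuple[int, int]]] = field(default_factory=list)

    def walk(self) -> Iterator["SSENode"]:
        yield self
        for ch in self.children:
            yield from ch.walk()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SSENode({self.kind}, residues={self.residues}, children={len(self.children)})"


@dataclass(frozen=True)
class MovableElement:
    """Contiguous span [start, stop) whose rigid motion breaks no helix.

    ``anchor`` records how the span attaches to the rest of the chain:
    ``both`` (internal), ``5p``/``3p`` (chain end on the other side), or
    ``free`` (whole molecule).
    """

    start: int
    stop: int
    anchor: str

    @property
    def residues(self) -> range:
        return range(self.start, self.stop)


# ---------------------------------------------------------------------------
# parsing


def _match_brackets(db: str) -> set[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    used = [False] * len(db)
    for opener, closer in _ALPHABETS:
        if opener not in db and closer not in db:
            continue
        stack: list[int] = []
        for pos, ch in enumerate(db):
            if ch == opener:
                stack.append(pos)
            elif ch == closer:
                if not stack:
                    raise ParseError(f"unbalanced '{ch}' at position {pos + 1}")
                i = pos if False else stack.pop()
                pairs.add((i, pos))
                used[i] = used[pos] = True
        if stack:
            raise ParseError(f"unbalanced '{opener}' at position {stack[-1] + 1}")
    known = set(".") | set(_OPENERS) | set(_CLOSERS)
    for pos, ch in enumerate(db):
        if ch not in known:
            raise ParseError(f"unknown character '{ch}' at position {pos + 1}")
    return pairs


def parse_dotbracket(db: str, sequence: str) -> SecondaryStructure:
    """Parse a dot-bracket string into a :class:`SecondaryStructure`.

    All bracket alphabets of ``()[]{}<>`` and ``Aa..Zz`` are matched; the
    maximum crossing-free subset of the resulting pairing is kept as the
    nested structure and the remainder becomes ``pk_pairs``.
    """
    sequence = sequence.strip().upper().replace("T", "U")
    if len(db) != len(sequence):
        raise ParseError(
            f"structure length {len(db)} does not match sequence length {len(sequence)}"
        )
    all_pairs = _match_brackets(db)
    nested, pk = split_pseudoknots(all_pairs)
    return SecondaryStructure(sequence, nested, pk)


def _crossings(pairs: Iterable[tuple[int, int]]) -> list[tuple]:
    ps = sorted(pairs)
    out = []
    for a in range(len(ps)):
        i, j = ps[a]
        for b in range(a + 1, len(ps)):
            k, l = ps[b]
            if i < k < j < l:
                out.append(((i, j), (k, l)))
    return out


def split_pseudoknots(
    all_pairs: Iterable[tuple[int, int]],
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """Split a pairing into a maximum crossing-free subset and the rest.

    The nested part has maximum cardinality among crossing-free subsets
    (interval dynamic program); ties are broken by preferring to keep the
    pair with the smaller (5'-most) opening index.
    """
    pairs = {(min(i, j), max(i, j)) for i, j in all_pairs}
    seen: set[int] = set()
    for i, j in pairs:
        if i == j:
            raise ParseError(f"self-pair at index {i}")
        if i in seen or j in seen:
            raise ParseError(f"index {i if i in seen else j} paired twice")
        seen.add(i)
        seen.add(j)
    if not pairs or not _crossings(pairs):
        return set(pairs), set()

    positions = sorted(seen)
    pos_of = {p: r for r, p in enumerate(positions)}
    partner = {}
    for i, j in pairs:
        partner[pos_of[i]] = pos_of[j]
        partner[pos_of[j]] = pos_of[i]
    m = len(positions)

    # M[i][j]: max pairs retainable using positions i..j (compressed indices)
    from functools import lru_cache
    import sys

    sys.setrecursionlimit(10000 + 4 * m)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if i > j:
            return 0
        k = partner[i]
        if not (i < k <= j):
            return best(i + 1, j)
        take = 1 + best(i + 1, k - 1) + best(k + 1, j)
        skip = best(i + 1, j)
        return take if take >= skip else skip

    kept: set[tuple[int, int]] = set()

    def trace(i: int, j: int) -> None:
        while i <= j:
            k = partner[i]
            if not (i < k <= j):
                i += 1
                continue
            take = 1 + best(i + 1, k - 1) + best(k + 1, j)
            if take >= best(i + 1, j):  # prefer keeping the 5'-most opening
                kept.add((positions[i], positions[k]))
                trace(i + 1, k - 1)
                i = k + 1
            else:
                i += 1

    trace(0, m - 1)
    best.cache_clear()
    pk = pairs - kept
    return kept, pk


def to_dotbracket(ss: SecondaryStructure) -> str:
    """Serialize to dot-bracket, assigning extra alphabets to pseudoknots."""
    db = ["."] * ss.n
    groups: list[list[tuple[int, int]]] = [sorted(ss.pairs)]
    # greedy colouring of pk pairs into mutually non-crossing groups
    for pair in sorted(ss.pk_pairs):
        placed = False
        for g in groups[1:]:
            if not any(_cross(pair, q) for q in g) and not any(
                _conflict(pair, q) for q in g
            ):
                g.append(pair)
                placed = True
                break
        if not placed:
            groups.append([pair])
    if len(groups) > len(_ALPHABETS):
        raise ParseError("structure needs more bracket alphabets than supported")
    for (opener, closer), g in zip(_ALPHABETS, groups):
        for i, j in g:
            db[i] = opener
            db[j] = closer
    return "".join(db)


def _cross(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (i, j), (k, l) = sorted((p, q))
    return i < k < j < l


def _conflict(p: tuple[int, int], q: tuple[int, int]) -> bool:
    return bool(set(p) & set(q))


# ---------------------------------------------------------------------------
# SSE decomposition


def _helices(pairs: set[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group a crossing-free pairing into maximal stacked runs (helices)."""
    ps = sorted(pairs)
    pairset = set(ps)
    helices = []
    seen = set()
    for p in ps:
        if p in seen:
            continue
        run = [p]
        seen.add(p)
        i, j = p
        while (i + 1, j - 1) in pairset:
            i, j = i + 1, j - 1
            run.append((i, j))
            seen.add((i, j))
        helices.append(run)
    # drop runs that are suffixes of longer runs (seen handles this already)
    return helices


def decompose_sse(ss: SecondaryStructure) -> SSENode:
    """Decompose the nested structure into a rooted tree of SSEs.

    Stems alternate with loops; each edge is the shared closing pair(s).
    The root is the SSE containing the 5'-terminal residue: the first stem
    when the whole chain is enclosed by it, otherwise an ``exterior``
    pseudo-node spanning the unenclosed regions (this also covers the
    degenerate case of a structure with no pairs at all).
    """
    n = ss.n
    if not ss.pairs:
        node = SSENode("exterior", list(range(n)), [])
        node.strands = [list(range(n))]
        return node

    helices = _helices(ss.pairs)
    # map: outermost pair -> helix, innermost pair -> helix
    by_outer = {h[0]: h for h in helices}

    def build_stem(helix: list[tuple[int, int]]) -> SSENode:
        res5 = [p[0] for p in helix]
        res3 = [p[1] for p in helix]
        node = SSENode(
            "stem",
            res5 + res3[::-1],
            [helix[0], helix[-1]],
            strands=[res5, list(reversed(res3))],
        )
        node.children = [build_loop(helix)]
        loop = node.children[0]
        if loop is None:
            node.children = []
        return node

    def closing_for_end(helix: list[tuple[int, int]], inner_side: bool) -> list[tuple[int, int]]:
        """Up to two stacked pairs at one helix end, outermost of the two first."""
        if inner_side:
            # pairs adjoining the loop inside the helix: innermost two
            return helix[-2:] if len(helix) >= 2 else helix[-1:]
        return list(reversed(helix[:2])) if len(helix) >= 2 else helix[:1]

    def build_loop(helix: list[tuple[int, int]]) -> SSENode | None:
        """The loop enclosed by ``helix`` (between its innermost pair)."""
        i0, j0 = helix[-1]
        # child helices: maximal helices whose outermost pair lies in (i0, j0)
        inner = [
            h for p, h in by_outer.items() if i0 < p[0] and p[1] < j0
        ]
        # keep only top-level ones (not nested inside another inner helix)
        top = []
        for h in sorted(inner, key=lambda h: h[0][0]):
            if not any(
                g is not h and g[0][0] < h[0][0] and h[0][1] < g[0][1] for g in inner
            ):
                top.append(h)
        if not top and j0 - i0 == 1:
            return None  # blunt: helix directly stacked on next (cannot happen within one maximal helix)
        # strand segments between consecutive helix ends, 5'->3'
        anchors5 = [i0] + [h[0][1] for h in top]
        anchors3 = [h[0][0] for h in top] + [j0]
        strands = []
        unpaired_counts = []
        for a, b in zip(anchors5, anchors3):
            strands.append(list(range(a, b + 1)))
            unpaired_counts.append(b - a - 1)
        nbranch = len(top)
        if nbranch == 0:
            kind = "hairpin"
        elif nbranch == 1:
            u1, u2 = unpaired_counts
            kind = "internal" if (u1 > 0 and u2 > 0) else "bulge"
        else:
            kind = "junction"
        end_pairs = [closing_for_end(helix, True)]
        for h in top:
            end_pairs.append(closing_for_end(h, False))
        closing = [p for end in end_pairs for p in end]
        residues = sorted(
            {r for s in strands for r in s}
            | {r for p in closing for r in p}
        )
        node = SSENode(kind, residues, closing, strands=strands, end_pairs=end_pairs)
        node.children = [build_stem(h) for h in top]
        return node

    top_helices = [
        h for h in helices
        if not any(g[0][0] < h[0][0] and h[0][1] < g[0][1] for g in helices if g is not h)
    ]
    top_helices.sort(key=lambda h: h[0][0])
    spans_all = (
        len(top_helices) == 1
        and top_helices[0][0][0] == 0
        and top_helices[0][0][1] == n - 1
    )
    if spans_all:
        return build_stem(top_helices[0])
    # exterior pseudo-node holding dangling ends and top-level helices
    strands = []
    anchors5 = [-1] + [h[0][1] for h in top_helices]
    anchors3 = [h[0][0] for h in top_helices] + [n]
    for a, b in zip(anchors5, anchors3):
        strands.append([r for r in range(max(a, 0), min(b + 1, n)) if True])
    end_pairs = [
        list(reversed(h[:2])) if len(h) >= 2 else h[:1] for h in top_helices
    ]
    closing = [p for end in end_pairs for p in end]
    residues = sorted(
        {r for s in strands for r in s} | {r for p in closing for r in p}
    )
    node = SSENode("exterior", residues, closing, strands=strands, end_pairs=end_pairs)
    node.children = [build_stem(h) for h in top_helices]
    return node


# ---------------------------------------------------------------------------
# movable elements


def _helix_residue_sets(pairs: set[tuple[int, int]]) -> list[set[int]]:
    return [{r for p in h for r in p} for h in _helices(pairs)]


def movable_elements(ss: SecondaryStructure) -> list[MovableElement]:
    """Enumerate every contiguous span whose boundaries break no helix.

    A span qualifies when each helix of the nested structure is either
    entirely inside or entirely outside it; rigid motion of such a span
    leaves the secondary structure intact.  Spans are returned largest
    first, whole molecule included.
    """
    n = ss.n
    hsets = _helix_residue_sets(ss.pairs)
    # precompute per-helix min/max for fast containment tests
    bounds = [(min(s), max(s), s) for s in hsets]
    out: list[MovableElement] = []
    for start in range(n):
        for stop in range(start + 1, n + 1):
            ok = True
            for lo, hi, s in bounds:
                inside_lo = start <= lo and hi < stop
                if inside_lo:
                    continue
                # any residue of the helix inside the span => split
                if lo >= stop or hi < start:
                    continue
                if any(start <= r < stop for r in s):
                    ok = False
                    break
            if ok:
                if start == 0 and stop == n:
                    anchor = "free"
                elif start == 0:
                    anchor = "5p"
                elif stop == n:
                    anchor = "3p"
                else:
                    anchor = "both"
                out.append(MovableElement(start, stop, anchor))
    out.sort(key=lambda e: (-(e.stop - e.start), e.start))
    return out


# ---------------------------------------------------------------------------
# DBN files


def read_dbn(path) -> list[tuple[str, str, str]]:
    """Read a DBN file: optional '>name' line, then sequence/structure lines.

    Returns a list of (name, sequence, dotbracket) records.  Batch layouts
    (one sequence + many structures, or equal-count alternating lists) are
    handled by :func:`ssefold.tasks.expand_batch`.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    records = []
    name = ""
    buf: list[str] = []

    def flush() -> None:
        nonlocal buf, name
        if not buf:
            return
        seq = buf[0]
        structs = buf[1:]
        if not structs:
            raise ParseError(f"sequence without structure in {path}")
        for k, st in enumerate(structs):
            nm = name or f"record{len(records) + 1}"
            records.append((nm if len(structs) == 1 else f"{nm}.{k + 1}", seq, st))
        buf = []
        name = ""

    for ln in lines:
        if ln.startswith(">"):
            flush()
            name = ln[1:].strip()
        else:
            buf.append(ln)
    flush()
    return records


def write_dbn(path, name: str, ss: SecondaryStructure) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n{ss.sequence}\n{to_dotbracket(ss)}\n")
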