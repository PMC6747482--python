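"""Dot-bracket parsing, pseudoknot separation, SSE trees, movable elements."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssefold.secstruct import (
    ParseError,
    SecondaryStructure,
    decompose_sse,
    movable_elements,
    parse_dotbracket,
    split_pseudoknots,
    to_dotbracket,
)
from conftest import random_nested_structure


@pytest.mark.parametrize(
    "db,pairs,pk",
    [
        ("((((....))))", {(0, 11), (1, 10), (2, 9), (3, 8)}, set()),
        ("....", set(), set()),
        ("((..[[..))..]]", {(0, 9), (1, 8)}, {(4, 13), (5, 12)}),
    ],
)
def test_parse_dotbracket(db, pairs, pk):
    ss = parse_dotbracket(db, "A" * len(db) if not pairs else None or _seq(db))
    assert ss.pairs == pairs
    assert ss.pk_pairs == pk


def _seq(db):
    from ssefold.synthetic import random_sequence_for

    return random_sequence_for(db, 0)


def test_parse_errors():
    with pytest.raises(ParseError, match="position"):
        parse_dotbracket("(((", "GGG")
    with pytest.raises(ParseError, match="length"):
        parse_dotbracket("()", "GGG")
    with pytest.raises(ParseError):
        parse_dotbracket("(?)", "GCG")


def test_split_pseudoknots_examples():
    nested, pk = split_pseudoknots({(0, 9), (1, 8)})
    assert nested == {(0, 9), (1, 8)} and pk == set()
    nested, pk = split_pseudoknots({(0, 9), (1, 8), (4, 13), (5, 12)})
    assert nested == {(0, 9), (1, 8)}
    assert pk == {(4, 13), (5, 12)}
    # tie: both crossing groups have size 1 -> keep the 5'-most opening
    nested, pk = split_pseudoknots({(0, 5), (2, 7)})
    assert nested == {(0, 5)} and pk == {(2, 7)}


def _crossing_free(pairs):
    ps = sorted(pairs)
    for a in range(len(ps)):
        for b in range(a + 1, len(ps)):
            (i, j), (k, l) = ps[a], ps[b]
            if i < k < j < l:
                return False
    return True


def _max_noncrossing_bruteforce(pairs):
    from itertools import combinations

    best = 0
    pairs = list(pairs)
    for r in range(len(pairs), 0, -1):
        for sub in combinations(pairs, r):
            if _crossing_free(sub):
                return r
    return best


@settings(max_examples=60, deadline=None)
@given(st.data())
def test_split_pseudoknots_properties(data):
    """Nested + pk partition the input; nested is a maximum crossing-free set."""
    n = data.draw(st.integers(8, 18))
    rng_seed = data.draw(st.integers(0, 10**6))
    rng = np.random.default_rng(rng_seed)
    idx = list(rng.permutation(n))
    pairs = set()
    while len(idx) >= 2 and rng.random() < 0.8:
        i, j = idx.pop(), idx.pop()
        pairs.add((min(i, j), max(i, j)))
    nested, pk = split_pseudoknots(pairs)
    assert nested | pk == pairs
    assert nested & pk == set()
    assert _crossing_free(nested)
    if len(pairs) <= 8:
        assert len(nested) == _max_noncrossing_bruteforce(pairs)


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 10**6), st.integers(10, 30))
def test_dotbracket_roundtrip(seed, n):
    rng = np.random.default_rng(seed)
    db = random_nested_structure(rng, n)
    ss = parse_dotbracket(db, "A" * n)
    again = parse_dotbracket(to_dotbracket(ss), "A" * n)
    assert again.pairs == ss.pairs
    assert again.pk_pairs == ss.pk_pairs


def test_decompose_hairpin():
    ss = parse_dotbracket("((((....))))", "GGGCGAAAGCCC")
    tree = decompose_sse(ss)
    kinds = [n.kind for n in tree.walk()]
    assert kinds == ["stem", "hairpin"]
    stem = tree
    assert len(stem.strands[0]) == 4
    hp = tree.children[0]
    unpaired = [r for r in hp.residues if not any(r in p for p in hp.closing_pairs)]
    assert unpaired == [4, 5, 6, 7]


def test_decompose_internal():
    db = "((..((....))..))"
    ss = parse_dotbracket(db, _seq(db))
    kinds = [n.kind for n in decompose_sse(ss).walk()]
    assert kinds == ["stem", "internal", "stem", "hairpin"]


def test_decompose_junction():
    db = "((.((...)).((...)).))"
    ss = parse_dotbracket(db, _seq(db))
    tree = decompose_sse(ss)
    kinds = [n.kind for n in tree.walk()]
    assert kinds == ["stem", "junction", "stem", "hairpin", "stem", "hairpin"]
    junction = tree.children[0]
    assert len(junction.children) == 2


def test_decompose_no_pairs_gives_free_chain():
    ss = parse_dotbracket("....", "ACGU")
    tree = decompose_sse(ss)
    assert tree.kind == "exterior"
    assert tree.residues == [0, 1, 2, 3]
    assert not tree.children


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 10**6), st.integers(8, 30))
def test_decompose_reconstructs_pairing(seed, n):
    """Stem pairs collected over the tree equal the input pairing."""
    rng = np.random.default_rng(seed)
    db = random_nested_structure(rng, n)
    ss = parse_dotbracket(db, "G" * n)
    tree = decompose_sse(ss)
    rebuilt = set()
    for node in tree.walk():
        if node.kind == "stem":
            s5, s3 = node.strands
            for a, b in zip(s5, s3[::-1]):
                rebuilt.add((min(a, b), max(a, b)))
    assert rebuilt == ss.pairs
    covered = set()
    for node in tree.walk():
        covered.update(node.residues)
    assert covered == set(range(n))


def _movable_oracle(ss):
    """Brute force over all spans: no helix may be split by the span."""
    from ssefold.secstruct import _helices

    hres = [{r for p in h for r in p} for h in _helices(ss.pairs)]
    out = set()
    n = ss.n
    for a in range(n):
        for b in range(a + 1, n + 1):
            span = set(range(a, b))
            if all(h <= span or not (h & span) for h in hres):
                out.add((a, b))
    return out


@pytest.mark.parametrize(
    "db",
    ["((((....))))", "(((())))", "....", "((..((....))..))", "((.((...)).((...)).))"],
)
def test_movable_elements_match_oracle(db):
    ss = parse_dotbracket(db, "G" * len(db))
    got = {(e.start, e.stop) for e in movable_elements(ss)}
    assert got == _movable_oracle(ss)


def test_movable_elements_examples():
    ss = parse_dotbracket("((((....))))", "GGGCGAAAGCCC")
    spans = {(e.start, e.stop) for e in movable_elements(ss)}
    assert (4, 8) in spans  # the hairpin loop
    assert (5, 7) in spans  # any sub-span of it
    assert (0, 12) in spans  # whole molecule
    assert (0, 8) not in spans  # would cut the helix strands apart
    # fully paired duplex: only the whole molecule qualifies
    ss2 = parse_dotbracket("(((())))", "GGGGCCCC")
    assert {(e.start, e.stop) for e in movable_elements(ss2)} == {(0, 8)}
    # no pairs: every contiguous span qualifies
    ss3 = parse_dotbracket("....", "ACGU")
    assert len(movable_elements(ss3)) == 4 * 5 // 2


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10**6), st.integers(6, 30))
def test_movable_elements_property(seed, n):
    rng = np.random.default_rng(seed)
    db = random_nested_structure(rng, n)
    ss = parse_dotbracket(db, "G" * n)
    got = {(e.start, e.stop) for e in movable_elements(ss)}
    assert got == _movable_oracle(ss)


def test_secondary_structure_validation():
    with pytest.raises(ParseError):
        SecondaryStructure("GGGG", {(0, 1), (1, 2)})  # index used twice
    with pytest.raises(ParseError):
        SecondaryStructure("GG", {(0, 5)})  # out of range
    with pytest.raises(ParseError):
        SecondaryStructure("GGGGGGGG", {(0, 4), (2, 6)})  # crossing in nested
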