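"""Shared fixtures: all inputs are generated programmatically."""

import numpy as np
import pytest

from ssefold.loopgen import collect_distance_stats, default_fragment_set
from ssefold.secstruct import SecondaryStructure, decompose_sse, parse_dotbracket, to_dotbracket
from ssefold.synthetic import build_h_pseudoknot, build_structure, random_sequence_for
from ssefold.templates import build_ideal_helix, _template_as_conformation


@pytest.fixture(scope="session")
def hairpin_case():
    """Synthetic hairpin structure with its secondary structure."""
    conf, ss = build_structure("GGGCGAAAGCCC", "((((....))))", seed=0)
    return conf, ss


@pytest.fixture(scope="session")
def internal_case():
    db = "((..((....))..))"
    seq = random_sequence_for(db, seed=1)
    conf, ss = build_structure(seq, db, seed=0)
    return conf, ss


@pytest.fixture(scope="session")
def junction_case():
    db = "((.((...)).((...)).))"
    seq = random_sequence_for(db, seed=1)
    conf, ss = build_structure(seq, db, seed=0)
    return conf, ss


@pytest.fixture(scope="session")
def helix4():
    return build_ideal_helix("GGCA")


@pytest.fixture(scope="session")
def helix4_conf(helix4):
    return _template_as_conformation(helix4)


@pytest.fixture(scope="session")
def fragment_pool():
    return default_fragment_set()


@pytest.fixture(scope="session")
def fixture_bounds(hairpin_case):
    return collect_distance_stats([hairpin_case[0]])


@pytest.fixture(scope="session")
def hairpin_node(hairpin_case):
    _, ss = hairpin_case
    return decompose_sse(ss).children[0]


@pytest.fixture(scope="session")
def pk_system():
    """H-type pseudoknot ground truth + nested-only assembled start."""
    native, ss = build_h_pseudoknot(seed=2)
    nested = SecondaryStructure(ss.sequence, ss.pairs)
    start, _ = build_structure(ss.sequence, to_dotbracket(nested), seed=4)
    return native, ss, nested, start


def random_nested_structure(rng, n):
    """Random crossing-free pairing as a dot-bracket string of length n."""
    db = ["."] * n
    # stack-based random nesting
    open_stack = []
    for i in range(n):
        if open_stack and rng.random() < 0.35 and i - open_stack[-1] >= 4:
            j = open_stack.pop()
            db[j] = "("
            db[i] = ")"
        elif rng.random() < 0.4:
            open_stack.append(i)
    return "".join(db)
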