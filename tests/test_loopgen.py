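"""De novo loop generation: bi-residue fragments and distance geometry."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ssefold.conformation import Conformation
from ssefold.geometry import CoordSet, rmsd
from ssefold.loopgen import (
    biresidue_build,
    build_fragment_set,
    collect_distance_stats,
    dg_build,
    embed_distance_matrix,
    fix_chirality,
    smooth_bounds,
)
from ssefold import nucgeom
from ssefold.secstruct import decompose_sse, parse_dotbracket
from ssefold.templates import shape_key, _template_as_conformation


class TestFragmentSet:
    def test_count_is_n_minus_one(self, hairpin_case):
        conf, _ = hairpin_case
        assert len(build_fragment_set(conf)) == conf.n_residues - 1

    def test_chain_break_skipped(self, hairpin_case):
        conf, _ = hairpin_case
        broken = conf.copy()
        broken.chain_breaks = {5}
        assert len(build_fragment_set(broken)) == conf.n_residues - 2

    def test_single_residue_empty(self):
        atoms = nucgeom.place_nucleotide("A", nucgeom.pair_frame(0))
        conf = Conformation.from_residues("A", [atoms])
        assert build_fragment_set(conf) == []


class TestBiResidue:
    def test_zero_steps_valid_chain(self, hairpin_node, hairpin_case, fragment_pool):
        _, ss = hairpin_case
        t = biresidue_build(hairpin_node, ss, fragment_pool, steps=0, seed=1)
        assert t.n_residues == 8
        conf = _template_as_conformation(t)
        for _, d in conf.backbone_gaps():
            if d < 5.0:  # strand-boundary rows excluded by size
                assert 1.2 <= d <= 2.0

    def test_negative_steps_error(self, hairpin_node, hairpin_case, fragment_pool):
        with pytest.raises(ValueError):
            biresidue_build(hairpin_node, hairpin_case[1], fragment_pool, steps=-1)

    def test_infinite_temperature_accepts_everything(
        self, hairpin_node, hairpin_case, fragment_pool
    ):
        _, ss = hairpin_case
        t = biresidue_build(
            hairpin_node, ss, fragment_pool, steps=60, seed=2, t_high=1e9, t_low=1e9
        )
        assert t.meta["acceptance_ratio"] > 0.9

    def test_metropolis_reduces_closure_energy(
        self, hairpin_node, hairpin_case, fragment_pool
    ):
        _, ss = hairpin_case
        t = biresidue_build(hairpin_node, ss, fragment_pool, steps=500, seed=3)
        assert t.meta["closure_energy"] <= t.meta["initial_closure_energy"]

    @pytest.mark.parametrize("seed", range(0, 50, 1))
    def test_covalent_continuity_any_seed(
        self, hairpin_node, hairpin_case, fragment_pool, seed
    ):
        """Grown chains are covalently continuous regardless of seed."""
        _, ss = hairpin_case
        t = biresidue_build(
            hairpin_node, ss, fragment_pool, steps=0, seed=seed, relax=False
        )
        atoms = {r: t.residue_atoms(r) for r in range(t.n_residues)}
        strand = t.strands[0]
        # internal junctions of the grown chain (closure handled by relax)
        for a, b in zip(strand[:-1], strand[1:-1]):
            d = float(np.linalg.norm(atoms[a]["O3'"] - atoms[b]["P"]))
            assert 1.2 <= d <= 2.2

    def test_template_fits_library_shape(self, hairpin_node, hairpin_case, fragment_pool):
        _, ss = hairpin_case
        t = biresidue_build(hairpin_node, ss, fragment_pool, steps=0, seed=1)
        assert t.key == shape_key(hairpin_node)


class TestDistanceStats:
    def test_paired_bounds_bracket_ideal_helix(self, fixture_bounds):
        lo, hi = fixture_bounds.get("paired", "G.C1'", "C.C1'")
        assert lo <= 10.78 <= hi

    def test_idempotent_on_duplicates(self, hairpin_case):
        conf, _ = hairpin_case
        one = collect_distance_stats([conf])
        two = collect_distance_stats([conf, conf])
        assert one.entries == two.entries

    def test_empty_input_defaults_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            b = collect_distance_stats([])
        assert not b.entries
        assert any("default" in r.message for r in caplog.records)
        assert b.get("intra", "A.C1'", "A.P") == b.class_defaults["intra"]

    def test_percentile_mode_narrower(self, hairpin_case):
        conf, _ = hairpin_case
        full = collect_distance_stats([conf])
        trimmed = collect_distance_stats([conf], percentile=5.0)
        key = ("adjacent", "G.C1'", "G.C1'")
        if key in full.entries and key in trimmed.entries:
            flo, fhi = full.entries[key]
            tlo, thi = trimmed.entries[key]
            assert tlo >= flo - 1e-9 and thi <= fhi + 1e-9


class TestEmbedding:
    def test_known_fragment_reproduced_exactly(self):
        """Zero-width bounds on a rigid 5-atom fragment embed exactly."""
        names = ("C1'", "C2'", "C3'", "C4'", "O4'")
        pts = np.array([nucgeom.NUCLEOTIDES["A"][a] for a in names])
        d = cdist(pts, pts)
        emb = embed_distance_matrix(d)
        labels = [(0, nm) for nm in names]
        # chirality fix via the sugar improper, then superpose
        imp = [(0, 1, 2, 3)]
        ref = np.dot(np.cross(pts[1] - pts[0], pts[2] - pts[0]), pts[3] - pts[0])
        emb = fix_chirality(emb, imp, [ref])
        assert rmsd(CoordSet(labels, emb), CoordSet(labels, pts)) < 1e-6

    def test_345_triangle(self):
        d = np.array([[0.0, 3, 5], [3, 0, 4], [5, 4, 0]])
        emb = embed_distance_matrix(d)
        got = cdist(emb, emb)
        assert np.abs(got - d).max() < 1e-9

    def test_rank_deficient_bounds_error(self):
        d = np.zeros((4, 4))  # all atoms coincident
        with pytest.raises(ValueError, match="rank"):
            embed_distance_matrix(d)

    def test_smoothing_consistency_check(self):
        lower = np.array([[0.0, 1, 9], [1, 0, 1], [9, 1, 0]])
        upper = np.array([[0.0, 1, 9], [1, 0, 1], [9, 1, 0]])
        with pytest.raises(ValueError, match="inconsistent"):
            smooth_bounds(lower, upper)  # 9 > 1 + 1 path


class TestDGBuild:
    def test_hairpin_violations_below_tolerance(
        self, hairpin_node, hairpin_case, fixture_bounds
    ):
        _, ss = hairpin_case
        t = dg_build(hairpin_node, ss, fixture_bounds, seed=4)
        assert t.meta["max_bound_violation"] < 0.5

    def test_deterministic_and_shape_compatible(
        self, hairpin_node, hairpin_case, fixture_bounds
    ):
        _, ss = hairpin_case
        a = dg_build(hairpin_node, ss, fixture_bounds, seed=4)
        b = dg_build(hairpin_node, ss, fixture_bounds, seed=4)
        assert np.array_equal(a.coords.xyz, b.coords.xyz)
        assert a.key == shape_key(hairpin_node)

    def test_sugar_chirality_correct(self, hairpin_node, hairpin_case, fixture_bounds):
        _, ss = hairpin_case
        t = dg_build(hairpin_node, ss, fixture_bounds, seed=6)
        for r in range(t.n_residues):
            atoms = t.residue_atoms(r)
            ngly = nucgeom.GLYCOSIDIC_N[t.sequence[r]]
            v = np.dot(
                np.cross(atoms[ngly] - atoms["C1'"], atoms["O4'"] - atoms["C1'"]),
                atoms["C2'"] - atoms["C1'"],
            )
            std = nucgeom.NUCLEOTIDES[t.sequence[r]]
            ref = np.dot(
                np.cross(std[ngly] - std["C1'"], std["O4'"] - std["C1'"]),
                std["C2'"] - std["C1'"],
            )
            assert np.sign(v) == np.sign(ref)
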