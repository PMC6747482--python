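"""Clustering, scoring, annotation, and evaluation metrics."""

import itertools

import numpy as np
import pytest

from ssefold.analysis import (
    InteractionSet,
    ScoringTables,
    annotate_interactions,
    inf,
    kmeans_rmsd,
    pairwise_rmsd_matrix,
    rank_centroids,
    score_structure,
)
from ssefold.geometry import rmsd, rotation_about_axis



def _perturbed_family(conf, sigmas, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for s in sigmas:
        c = conf.copy()
        c.xyz = c.xyz + rng.normal(0, s, c.xyz.shape)
        out.append(c)
    return out


class TestRmsdMatrix:
    def test_identical_pair_zero(self, hairpin_case):
        conf, _ = hairpin_case
        m = pairwise_rmsd_matrix([conf, conf.copy()])
        assert np.abs(m).max() < 1e-9

    def test_symmetry_and_diagonal(self, hairpin_case):
        conf, _ = hairpin_case
        confs = _perturbed_family(conf, [0.2, 0.5, 1.0])
        m = pairwise_rmsd_matrix(confs)
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)

    def test_elements_match_direct_rmsd(self, hairpin_case):
        conf, _ = hairpin_case
        confs = _perturbed_family(conf, [0.3, 0.6, 1.2])
        m = pairwise_rmsd_matrix(confs)
        for i in range(3):
            for j in range(3):
                expected = rmsd(confs[i].coords(), confs[j].coords())
                assert m[i, j] == pytest.approx(expected, abs=1e-9)

    def test_sequence_mismatch_error(self, hairpin_case, helix4_conf):
        with pytest.raises(ValueError, match="sequence"):
            pairwise_rmsd_matrix([hairpin_case[0], helix4_conf])


def _brute_force_medoid(dmat, members):
    best, best_sum = None, np.inf
    for k in members:
        s = sum(dmat[k, j] for j in members if j != k)
        if s < best_sum - 1e-12:
            best, best_sum = k, s
    return best


class TestKmeans:
    def test_k_equals_n(self, hairpin_case):
        conf, _ = hairpin_case
        confs = _perturbed_family(conf, [0.2, 0.6, 1.4])
        cs = kmeans_rmsd(confs, k=3, seed=0)
        assert sorted(cs.centroids) == [0, 1, 2]

    def test_identical_conformations_k1(self, hairpin_case):
        conf, _ = hairpin_case
        cs = kmeans_rmsd([conf.copy() for _ in range(4)], k=1, seed=0)
        assert cs.centroids == [0]  # tie-break: smallest index
        assert cs.sizes == [4]

    def test_k_too_large_error(self, hairpin_case):
        conf, _ = hairpin_case
        with pytest.raises(ValueError):
            kmeans_rmsd([conf], k=2, seed=0)

    def test_centroids_satisfy_argmin_identity(self):
        """Converged centroids equal the exhaustive argmin-sum medoid."""
        rng = np.random.default_rng(42)
        for trial in range(20):
            n = int(rng.integers(6, 25))
            k = int(rng.integers(1, min(5, n) + 1))
            pts = rng.normal(size=(n, 4))
            dmat = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            cs = kmeans_rmsd(None, k=k, seed=trial, dmat=dmat)
            for ci, m in enumerate(cs.centroids):
                members = np.where(cs.assignment == ci)[0]
                assert m == _brute_force_medoid(dmat, members)


class TestScoring:
    def test_rigid_motion_invariance(self, hairpin_case):
        conf, _ = hairpin_case
        rot = rotation_about_axis([0.2, 1.0, -0.4], 1.1)
        moved = conf.copy()
        moved.xyz = conf.xyz @ rot.T + np.array([5.0, -3.0, 8.0])
        assert score_structure(moved) == pytest.approx(score_structure(conf), abs=1e-9)

    def test_native_beats_randomized_loop(self, hairpin_case):
        """The native hairpin outscores loop-randomized decoys, 20/20."""
        conf, ss = hairpin_case
        native_score = score_structure(conf)
        loop_res = {4, 5, 6, 7}
        mask = np.array([lab[0] in loop_res for lab in conf.labels])
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            decoy = conf.copy()
            decoy.xyz[mask] += rng.normal(0, 2.5, (mask.sum(), 3))
            if score_structure(decoy) > native_score:
                wins += 1
        assert wins == 20

    def test_empty_tables_score_zero(self, hairpin_case):
        conf, _ = hairpin_case
        assert ScoringTables().score(conf) == 0.0


class TestRanking:
    def test_orders_by_score(self, hairpin_case):
        conf, _ = hairpin_case
        confs = [conf] + _perturbed_family(conf, [1.5, 3.0], seed=1)
        cs = kmeans_rmsd(confs, k=3, seed=0)
        ranked = rank_centroids(cs, confs)
        scores = [c.provenance["cluster"]["score"] for c in ranked]
        assert scores == sorted(scores)
        # independent sort oracle
        direct = sorted(score_structure(confs[m]) for m in cs.centroids)
        assert scores == pytest.approx(direct)

    def test_single_cluster(self, hairpin_case):
        conf, _ = hairpin_case
        cs = kmeans_rmsd([conf], k=1, seed=0)
        ranked = rank_centroids(cs, [conf])
        assert len(ranked) == 1


class TestAnnotation:
    def test_ideal_helix(self, helix4_conf):
        ia = annotate_interactions(helix4_conf)
        assert ia.wc_pairs == {(0, 7), (1, 6), (2, 5), (3, 4)}
        assert ia.stacks == {(0, 1), (1, 2), (2, 3)}

    def test_extended_chain_empty(self):
        from ssefold import nucgeom
        from ssefold.conformation import Conformation
        from ssefold.geometry import RigidTransform

        residues = []
        for i in range(6):
            frame = RigidTransform(np.eye(3), np.array([12.0 * i, 0.0, 0.0]))
            residues.append(nucgeom.place_nucleotide("ACGUAC"[i], frame))
        conf = Conformation.from_residues("ACGUAC", residues)
        ia = annotate_interactions(conf)
        assert ia.wc_pairs == set() and ia.stacks == set()

    def test_loosened_thresholds_superset(self, hairpin_case):
        conf, _ = hairpin_case
        tight = annotate_interactions(conf)
        loose = annotate_interactions(
            conf,
            n1n3_range=(0.0, 1e9),
            c1c1_range=(0.0, 1e9),
            plane_angle_max=180.0,
            stack_centroid_max=1e9,
            stack_angle_max=180.0,
        )
        assert tight.wc_pairs <= loose.wc_pairs
        assert tight.stacks <= loose.stacks


class TestInf:
    def test_identical_sets(self):
        s = {(0, 5), (1, 4)}
        assert inf(s, s) == 1.0

    def test_disjoint_sets(self):
        assert inf({(0, 5)}, {(1, 4)}) == 0.0

    def test_overlap_two_of_four(self):
        pred = {(0, 9), (1, 8), (2, 7), (3, 6)}
        native = {(0, 9), (1, 8), (10, 19), (11, 18)}
        assert inf(pred, native) == pytest.approx(0.5)

    def test_empty_conventions(self):
        assert inf(set(), set()) == 1.0
        assert inf({(0, 1)}, set()) == 0.0
        assert inf(set(), {(0, 1)}) == 0.0

    def test_bounded_and_formula(self):
        rng = np.random.default_rng(0)
        universe = list(itertools.combinations(range(8), 2))
        for _ in range(25):
            pred = {universe[i] for i in rng.choice(len(universe), 5, replace=False)}
            native = {universe[i] for i in rng.choice(len(universe), 7, replace=False)}
            v = inf(pred, native)
            assert 0.0 <= v <= 1.0
            tp = len(pred & native)
            expected = np.sqrt((tp / len(pred)) * (tp / len(native))) if tp else 0.0
            assert v == pytest.approx(expected)

    def test_interaction_set_dispatch(self, helix4_conf):
        ia = annotate_interactions(helix4_conf)
        assert inf(ia, ia, "wc") == 1.0
        assert inf(ia, ia, "stack") == 1.0
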