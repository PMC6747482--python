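"""Restraints, refinement energy, and the annealing Monte Carlo sampler."""

import math

import numpy as np
import pytest

from ssefold.optimizer import (
    AnnealSchedule,
    OptimizerEnergy,
    Restraint,
    best_of,
    dca_restraint_count,
    energy,
    read_restraints,
    restraint_violation,
    restraints_from_pseudoknot,
    samc_optimize,
    write_restraints,
    PAIR_C1C1_TARGET,
    PAIR_N1N3_TARGET,
)
from ssefold.secstruct import movable_elements, parse_dotbracket
from ssefold.synthetic import build_structure


class TestRestraints:
    def test_empty(self):
        assert restraints_from_pseudoknot(set()) == []

    def test_one_per_pair(self):
        rs = restraints_from_pseudoknot({(4, 13), (5, 12)})
        assert [(r.i, r.j) for r in rs] == [(4, 13), (5, 12)]
        assert all(r.kind == "base_pair" for r in rs)

    def test_bounds_bracket_ideal_helix_geometry(self, helix4_conf):
        d = float(
            np.linalg.norm(helix4_conf.atom(0, "C1'") - helix4_conf.atom(7, "C1'"))
        )
        assert PAIR_C1C1_TARGET[0] <= d <= PAIR_C1C1_TARGET[1]
        dh = float(np.linalg.norm(helix4_conf.atom(0, "N1") - helix4_conf.atom(7, "N3")))
        assert PAIR_N1N3_TARGET[0] <= dh <= PAIR_N1N3_TARGET[1]

    def test_satisfied_on_ideal_helix(self, helix4_conf):
        for r in restraints_from_pseudoknot({(0, 7), (1, 6)}):
            assert restraint_violation(helix4_conf, r) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            Restraint("base_pair", 3, 3)
        with pytest.raises(ValueError):
            Restraint("distance", 0, 1, lower=5.0, upper=2.0)
        with pytest.raises(ValueError):
            Restraint("distance", 0, 1, lower=1, upper=2, weight=0.0)


@pytest.mark.parametrize("length,expected", [(75, 15), (0, 0), (78, 15), (80, 16)])
def test_dca_restraint_count(length, expected):
    assert dca_restraint_count(length) == expected


class TestRestraintFile:
    def test_roundtrip(self, tmp_path):
        rs = restraints_from_pseudoknot({(4, 13)}) + [
            Restraint("distance", 2, 9, 8.0, 12.0, weight=2.0)
        ]
        path = tmp_path / "r.rst"
        write_restraints(rs, path)
        back = read_restraints(path)
        assert [(r.kind, r.i, r.j) for r in back] == [(r.kind, r.i, r.j) for r in rs]

    def test_comments_and_errors(self, tmp_path):
        p = tmp_path / "ok.rst"
        p.write_text("# comment\nPAIR 5 14\n\nDIST 3 10 8 12 2.0\n")
        rs = read_restraints(p)
        assert len(rs) == 2 and rs[0].i == 4
        bad = tmp_path / "bad.rst"
        bad.write_text("PAIR 5\n")
        with pytest.raises(ValueError, match="bad.rst:1"):
            read_restraints(bad)


class TestEnergy:
    def test_clean_fixture_near_zero(self, hairpin_case):
        conf, ss = hairpin_case
        terms = OptimizerEnergy(w_stat=0.0)
        assert energy(conf, terms, [], ss) == pytest.approx(0.0, abs=1e-6)

    def test_satisfied_restraint_zero(self, hairpin_case):
        conf, ss = hairpin_case
        d = float(np.linalg.norm(conf.atom(0, "C1'") - conf.atom(5, "C1'")))
        r = Restraint("distance", 0, 5, d - 1.0, d + 1.0)
        terms = OptimizerEnergy()
        assert energy(conf, terms, [r], ss) == pytest.approx(0.0, abs=1e-9)

    def test_violated_restraint_quadratic(self, hairpin_case):
        conf, ss = hairpin_case
        d = float(np.linalg.norm(conf.atom(0, "C1'") - conf.atom(5, "C1'")))
        delta = 2.5
        r = Restraint("distance", 0, 5, d + delta, d + delta + 1.0, weight=1.5)
        terms = OptimizerEnergy(w_conn=0, w_clash=0, w_ss=0, w_restraint=2.0)
        assert energy(conf, terms, [r], ss) == pytest.approx(
            2.0 * 1.5 * delta**2, rel=1e-9
        )


def _flat_terms():
    return OptimizerEnergy(w_conn=0, w_clash=0, w_ss=0, w_restraint=0, w_stat=0)


class TestSamc:
    def test_zero_steps_trajectory_is_start(self, hairpin_case):
        conf, ss = hairpin_case
        els = movable_elements(ss)
        sched = AnnealSchedule(sweeps=0)
        res = samc_optimize(conf, els, [], sched, _flat_terms(), seed=0, ss=ss)
        assert len(res.trajectory) == 1
        assert np.array_equal(res.trajectory[0].xyz, conf.xyz)

    def test_empty_elements_error(self, hairpin_case):
        conf, ss = hairpin_case
        with pytest.raises(ValueError, match="nothing to move"):
            samc_optimize(conf, [], [], AnnealSchedule(), _flat_terms(), seed=0)

    def test_low_temperature_rejects_uphill(self, hairpin_case):
        """Any move that breaks a zero-width restraint is rejected as T -> 0."""
        conf, ss = hairpin_case
        els = [e for e in movable_elements(ss) if (e.start, e.stop) == (4, 5)]
        d = float(np.linalg.norm(conf.atom(4, "C1'") - conf.atom(9, "C1'")))
        r = Restraint("distance", 4, 9, d, d)  # zero width: any motion violates
        terms = OptimizerEnergy(w_conn=0, w_clash=0, w_ss=0, w_restraint=5.0)
        sched = AnnealSchedule(t_low=1e-9, t_high=1e-8, rungs=2, sweeps=50)
        res = samc_optimize(conf, els, [r], sched, terms, seed=3, ss=ss)
        assert res.acceptance_ratio < 0.05
        assert np.abs(res.best.xyz - conf.xyz).max() < 1e-9

    def test_fixed_seed_bit_reproducible(self, hairpin_case):
        conf, ss = hairpin_case
        els = movable_elements(ss)
        sched = AnnealSchedule(rungs=3, sweeps=5)
        terms = OptimizerEnergy()
        a = samc_optimize(conf, els, [], sched, terms, seed=7, ss=ss)
        b = samc_optimize(conf, els, [], sched, terms, seed=7, ss=ss)
        assert len(a.trajectory) == len(b.trajectory)
        for x, y in zip(a.trajectory, b.trajectory):
            assert np.array_equal(x.xyz, y.xyz)

    def test_secondary_structure_preserved(self, hairpin_case):
        """Nested pairs stay within WC windows in every trajectory sample."""
        conf, ss = hairpin_case
        els = movable_elements(ss)
        sched = AnnealSchedule(rungs=5, sweeps=20)
        res = samc_optimize(conf, els, [], sched, OptimizerEnergy(), seed=1, ss=ss)
        for sample in res.trajectory:
            for i, j in ss.pairs:
                d = float(np.linalg.norm(sample.atom(i, "C1'") - sample.atom(j, "C1'")))
                assert 9.0 <= d <= 11.6


class TestBestOf:
    def test_singleton(self, hairpin_case):
        conf, _ = hairpin_case
        assert np.array_equal(best_of([conf], _flat_terms()).xyz, conf.xyz)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            best_of([], _flat_terms())

    def test_matches_exhaustive_scan(self, hairpin_case):
        conf, ss = hairpin_case
        rng = np.random.default_rng(5)
        traj = []
        for _ in range(6):
            c = conf.copy()
            c.xyz = c.xyz + rng.normal(0, 0.8, c.xyz.shape)
            traj.append(c)
        terms = OptimizerEnergy(w_stat=0)
        energies = [energy(c, terms, [], ss) for c in traj]
        chosen = best_of(traj, terms, [], ss)
        assert np.array_equal(chosen.xyz, traj[int(np.argmin(energies))].xyz)

    def test_injected_minimum_found(self, hairpin_case):
        conf, ss = hairpin_case
        worse = conf.copy()
        worse.xyz = worse.xyz + np.random.default_rng(0).normal(0, 1.0, worse.xyz.shape)
        chosen = best_of([worse, conf, worse], OptimizerEnergy(), [], ss)
        assert np.array_equal(chosen.xyz, conf.xyz)


class TestSchedule:
    def test_temperatures_heat_then_cool(self):
        s = AnnealSchedule(t_low=0.1, t_high=10.0, rungs=4, sweeps=2)
        ts = s.temperatures()
        assert len(ts) == 8
        assert ts[0] == pytest.approx(0.1) and ts[3] == pytest.approx(10.0)
        assert ts == sorted(ts[:4]) + sorted(ts[4:], reverse=True)

    def test_validation(self):
        with pytest.raises(ValueError):
            AnnealSchedule(t_low=2.0, t_high=1.0)
        with pytest.raises(ValueError):
            AnnealSchedule(rungs=0)
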