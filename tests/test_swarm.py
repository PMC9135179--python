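"""Swarm optimizers: update rules, convergence, mask decoding, fitness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swarmeeg.benchmarks import sphere
from swarmeeg.swarm import (BAConfig, CSOConfig, PSOConfig, _Swarm,
                            feature_fitness, levy_step, mask_from_position,
                            pso_step, run_ba, run_cso, run_pso)


class _HalfRNG:
    """Stub RNG returning 0.5 everywhere (forces r1 = r2 = 0.5)."""

    def random(self, size=None):
        return np.full(size, 0.5) if size is not None else 0.5


def _swarm_of_one(x, v, pbest, gbest):
    return _Swarm(positions=np.array([x], dtype=float),
                  velocities=np.array([v], dtype=float),
                  pbest=np.array([pbest], dtype=float),
                  pbest_fitness=np.array([0.0]),
                  gbest=np.array(gbest, dtype=float), gbest_fitness=0.0)


class TestPSOStep:
    def test_fixed_point_when_at_both_bests(self):
        s = _swarm_of_one([1.0, 2.0], [0.0, 0.0], [1.0, 2.0], [1.0, 2.0])
        pso_step(s, PSOConfig(), _HalfRNG())
        assert np.array_equal(s.velocities, [[0.0, 0.0]])
        assert np.array_equal(s.positions, [[1.0, 2.0]])

    def test_hand_evaluated_update(self):
        # v = 0.64*0 + 1.524*0.5*(1-0) + 1.524*0.5*(1-0) = 1.524
        s = _swarm_of_one([0.0], [0.0], [1.0], [1.0])
        pso_step(s, PSOConfig(), _HalfRNG())
        assert s.velocities[0, 0] == pytest.approx(1.524)
        assert s.positions[0, 0] == pytest.approx(1.524)

    def test_dimension_mismatch_rejected(self):
        s = _swarm_of_one([0.0, 0.0], [0.0, 0.0], [0.0, 0.0], [0.0, 0.0])
        s.gbest = np.zeros(3)
        with pytest.raises(ValueError):
            pso_step(s, PSOConfig(), _HalfRNG())


class TestSphereConvergence:
    """All three optimizers at their published defaults on -sum(x^2)."""

    def test_pso_reaches_optimum(self):
        res = run_pso(sphere, 5, PSOConfig(seed=0))
        assert res.best_fitness > -1e-2

    def test_cso_reaches_optimum(self):
        res = run_cso(sphere, 5, CSOConfig(seed=0))
        assert res.best_fitness > -1e-2

    def test_ba_reaches_optimum(self):
        res = run_ba(sphere, 5, BAConfig(seed=0))
        assert res.best_fitness > -1e-2

    @pytest.mark.parametrize("runner,cfg_cls", [
        (run_pso, PSOConfig), (run_cso, CSOConfig), (run_ba, BAConfig)])
    def test_traces_monotone_and_seed_deterministic(self, runner, cfg_cls):
        a = runner(sphere, 4, cfg_cls(seed=3))
        b = runner(sphere, 4, cfg_cls(seed=3))
        assert np.array_equal(a.trace, b.trace)
        assert np.array_equal(a.best_position, b.best_position)
        assert (np.diff(a.trace) >= 0).all()

    def test_single_particle_at_optimum_stays_best(self):
        cfg = PSOConfig(population=2, generations=10, seed=0,
                        init_range=(0.0, 0.0))  # both particles at optimum
        res = run_pso(sphere, 3, cfg)
        assert res.best_fitness == 0.0
        assert np.array_equal(res.best_position, np.zeros(3))


class TestCSOSemantics:
    def test_abandonment_fraction_boundaries(self):
        calls = []

        def counting(x):
            calls.append(1)
            return -float(np.sum(x ** 2))

        n = 6
        # p_a = 0: per generation only the cuckoo is evaluated
        calls.clear()
        run_cso(counting, 3, CSOConfig(n_nests=n, p_abandon=0.0,
                                       generations=4, seed=0))
        assert len(calls) == n + 4 * 1
        # p_a = 1: cuckoo + all n-1 non-best nests re-walked
        calls.clear()
        run_cso(counting, 3, CSOConfig(n_nests=n, p_abandon=1.0,
                                       generations=4, seed=0))
        assert len(calls) == n + 4 * (1 + n - 1)

    def test_invalid_levy_exponent_rejected(self):
        with pytest.raises(ValueError):
            CSOConfig(levy_exponent=0.9)
        with pytest.raises(ValueError):
            levy_step(np.zeros(3), 1.0, 3.5, np.random.default_rng(0))


class TestLevyStep:
    def test_zero_alpha_is_identity(self):
        x = np.array([1.0, -2.0, 3.0])
        out = levy_step(x, 0.0, 1.5, np.random.default_rng(0))
        assert np.array_equal(out, x)

    def test_output_dimension_preserved(self):
        out = levy_step(np.zeros(7), 1.0, 2.0, np.random.default_rng(0))
        assert out.shape == (7,)

    def test_tail_index_matches_exponent(self):
        # log-log rank regression on the top 5% of |steps|
        rng = np.random.default_rng(0)
        steps = np.abs(levy_step(np.zeros(100000), 1.0, 1.5, rng))
        top = np.sort(steps)[-5000:]
        ranks = np.arange(len(top), 0, -1)
        slope = np.polyfit(np.log(top), np.log(ranks), 1)[0]
        assert -slope == pytest.approx(1.5, abs=0.2)


class TestBASemantics:
    def test_accepted_improvement_updates_loudness_and_rate(self):
        # run a short maximisation; any accepted move must leave
        # loudness below A0 for improving bats -- assert via monotonicity
        res = run_ba(sphere, 3, BAConfig(n_bats=5, generations=20, seed=1))
        assert res.best_fitness > -1.0  # moved from random init

    def test_zero_loudness_never_accepts(self):
        res = run_ba(sphere, 3, BAConfig(n_bats=5, generations=15,
                                         loudness0=0.0, seed=2))
        assert np.all(res.trace == res.trace[0])

    def test_invalid_frequency_range_rejected(self):
        with pytest.raises(ValueError):
            BAConfig(f_min=2.0, f_max=1.0)


class TestMaskFromPosition:
    def test_top_k_selection(self):
        mask = mask_from_position(np.array([0.9, 0.1, 0.5, 0.7]), 2)
        assert np.array_equal(np.flatnonzero(mask), [0, 3])

    def test_ties_break_to_lowest_index(self):
        mask = mask_from_position(np.ones(5), 2)
        assert np.array_equal(np.flatnonzero(mask), [0, 1])

    def test_full_scale_reduction_size(self):
        rng = np.random.default_rng(0)
        mask = mask_from_position(rng.standard_normal(9000), 4500)
        assert mask.sum() == 4500

    def test_oversized_m_rejected(self):
        with pytest.raises(ValueError):
            mask_from_position(np.zeros(4), 5)

    @given(d=st.integers(2, 60), data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_popcount_always_m(self, d, data):
        m = data.draw(st.integers(1, d))
        pos = np.random.default_rng(d).standard_normal(d)
        assert mask_from_position(pos, m).sum() == m


class TestFeatureFitness:
    def _features(self, seed=0, n=200, d=10):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, d))
        X[:, :5] += (2 * y[:, None] - 1) * 2.0  # columns 0-4 informative
        return X, y

    def test_informative_mask_scores_high(self):
        X, y = self._features()
        mask = np.zeros(10, bool)
        mask[:5] = True
        assert feature_fitness(mask, X, y, 0) > 0.9

    def test_noise_mask_scores_near_chance(self):
        X, y = self._features()
        mask = np.zeros(10, bool)
        mask[5:] = True
        assert abs(feature_fitness(mask, X, y, 0) - 0.5) <= 0.1

    def test_deterministic_under_split_seed(self):
        X, y = self._features()
        mask = np.ones(10, bool)
        assert feature_fitness(mask, X, y, 7) == feature_fitness(
            mask, X, y, 7)

    def test_single_class_rejected(self):
        X, _ = self._features()
        with pytest.raises(ValueError):
            feature_fitness(np.ones(10, bool), X, np.zeros(len(X)), 0)

    def test_soft_scoring_in_unit_interval(self):
        X, y = self._features()
        mask = np.ones(10, bool)
        s = feature_fitness(mask, X, y, 0, scoring="soft")
        assert 0.5 < s <= 1.0
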