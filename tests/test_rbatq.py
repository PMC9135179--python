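"""RBATQ: recurrent state builders, Q-learning agent, decision episodes."""

import numpy as np
import pytest

from swarmeeg.rbatq import (A_CLASS0, A_CLASS1, A_COMMIT, A_DEFER,
                            KIND_INITIAL, KIND_TRANSITION, AttentionParams,
                            BiLSTMParams, QAgent, RBATQClassifier, TabularQ,
                            TreeLSTMParams, attention_state, bilstm_forward,
                            q_target, run_episode, tree_state)


def _zeroed(params: BiLSTMParams):
    for d in (params.fwd, params.bwd):
        for k in d.W:
            d.W[k].value[:] = 0
        for k in d.b:
            d.b[k].value[:] = 0
    return params


class TestBiLSTMForward:
    def test_zero_parameter_fixed_point(self):
        # sigma(0) = 0.5, tanh(0) = 0 => g = 0, c = 0, h = 0 at every step
        params = _zeroed(BiLSTMParams(3, 4, rng=np.random.default_rng(0)))
        h, hp, y = bilstm_forward(np.random.default_rng(1).standard_normal(
            (6, 3)), params)
        assert np.all(h == 0) and np.all(hp == 0)
        assert np.allclose(y, 0.5)  # softmax of zero logits, 2 classes

    def test_softmax_rows_sum_to_one(self):
        params = BiLSTMParams(3, 5, rng=np.random.default_rng(2))
        _, _, y = bilstm_forward(np.random.default_rng(3).standard_normal(
            (4, 3)), params)
        assert np.allclose(y.sum(axis=1), 1.0, atol=1e-6)

    def test_reversal_swaps_directions(self):
        # with tied direction parameters, the backward states on x equal
        # the forward states on reversed x, step for step
        rng = np.random.default_rng(4)
        params = BiLSTMParams(3, 4, rng=rng)
        for k in params.fwd.W:
            params.bwd.W[k].value[:] = params.fwd.W[k].value
        for k in params.fwd.b:
            params.bwd.b[k].value[:] = params.fwd.b[k].value
        x = rng.standard_normal((3, 3))
        h, hp, _ = bilstm_forward(x, params)
        h_rev, _, _ = bilstm_forward(x[::-1], params)
        assert np.allclose(hp, h_rev[::-1], atol=1e-12)

    def test_width_mismatch_rejected(self):
        params = BiLSTMParams(3, 4, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            bilstm_forward(np.zeros((5, 7)), params)


class TestAttention:
    def test_single_step_weight_is_one(self):
        rng = np.random.default_rng(5)
        params = AttentionParams(4, rng=rng)
        h = rng.standard_normal((1, 4))
        hp = rng.standard_normal((1, 4))
        s1, w = attention_state(h, hp, params)
        assert w == pytest.approx([1.0])
        assert np.allclose(s1, np.concatenate([h[0], hp[0]]))

    def test_equal_states_give_the_common_state(self):
        rng = np.random.default_rng(6)
        params = AttentionParams(3, rng=rng)
        h = np.tile(rng.standard_normal(3), (5, 1))
        hp = np.tile(rng.standard_normal(3), (5, 1))
        s1, w = attention_state(h, hp, params)
        assert np.allclose(s1, np.concatenate([h[0], hp[0]]), atol=1e-12)
        assert w.sum() == pytest.approx(1.0, abs=1e-6)

    def test_weights_normalised_on_random_input(self):
        rng = np.random.default_rng(7)
        params = AttentionParams(4, rng=rng)
        _, w = attention_state(rng.standard_normal((6, 4)),
                               rng.standard_normal((6, 4)), params)
        assert w.sum() == pytest.approx(1.0, abs=1e-6)
        assert (w >= 0).all()

    def test_empty_sequence_rejected(self):
        params = AttentionParams(4)
        with pytest.raises(ValueError):
            attention_state(np.empty((0, 4)), np.empty((0, 4)), params)


class TestTreeState:
    def test_head_is_probability_vector(self):
        rng = np.random.default_rng(8)
        params = TreeLSTMParams(3, 4, rng=rng)
        _, y_r = tree_state(rng.standard_normal((8, 3)), params, depth=2)
        assert y_r.sum() == pytest.approx(1.0, abs=1e-6)

    def test_depth_zero_single_leaf(self):
        rng = np.random.default_rng(9)
        params = TreeLSTMParams(3, 4, rng=rng)
        x = rng.standard_normal((4, 3))
        s2, _ = tree_state(x, params, depth=0)
        assert s2.shape == (4,)

    def test_leaf_locality(self):
        # mean-pooled leaves: permuting frames inside one leaf's chunk
        # leaves s2 unchanged; swapping frames across leaves changes it
        rng = np.random.default_rng(10)
        params = TreeLSTMParams(3, 4, rng=rng)
        x = rng.standard_normal((8, 3))
        s2, _ = tree_state(x, params, depth=1)  # leaves: frames 0-3, 4-7
        x_within = x.copy()
        x_within[[0, 1]] = x_within[[1, 0]]
        s2_within, _ = tree_state(x_within, params, depth=1)
        assert np.allclose(s2, s2_within, atol=1e-12)
        x_across = x.copy()
        x_across[[0, 7]] = x_across[[7, 0]]
        s2_across, _ = tree_state(x_across, params, depth=1)
        assert not np.allclose(s2, s2_across)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tree_state(np.empty((0, 3)), TreeLSTMParams(3, 4))


class TestQTarget:
    def test_first_visit_returns_reward(self):
        assert q_target(1.0, 1, 123.0) == 1.0

    def test_second_visit_running_average(self):
        assert q_target(1.0, 2, 0.5) == pytest.approx(0.75)

    def test_converges_to_constant_reward(self):
        q = 0.0
        for t in range(1, 2001):
            q = q_target(0.7, t, q)
        assert q == pytest.approx(0.7, abs=1e-3)

    def test_invalid_visit_count_rejected(self):
        with pytest.raises(ValueError):
            q_target(1.0, 0, 0.0)


class TestQAgent:
    def test_repeated_updates_converge_to_reward(self):
        rng = np.random.default_rng(11)
        agent = QAgent(n_state=3, hidden=16, lr=0.01, rng=rng)
        s = rng.standard_normal(6)
        for _ in range(100):
            agent.update(s, KIND_INITIAL, A_COMMIT, reward=0.8)
        # RMSprop oscillates with ~lr amplitude once converged; check at
        # the point the running-average target has stabilised
        assert agent.q_value(s, KIND_INITIAL, A_COMMIT) == pytest.approx(
            0.8, abs=1e-2)

    def test_tabular_updates_converge_exactly(self):
        agent = TabularQ()
        for _ in range(1000):
            agent.update("s", 0, reward=0.8)
        assert agent.q_value("s", 0) == pytest.approx(0.8, abs=1e-3)

    def test_zero_step_leaves_parameters_unchanged(self):
        agent = QAgent(n_state=3, hidden=8, lr=0.0,
                       rng=np.random.default_rng(12))
        before = [p.value.copy() for p in agent.opt.params]
        agent.update(np.ones(6), KIND_INITIAL, A_DEFER, reward=1.0)
        for b, p in zip(before, agent.opt.params):
            assert np.array_equal(b, p.value)

    def test_invalid_action_for_state_rejected(self):
        agent = QAgent(n_state=3, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            agent.update(np.ones(6), KIND_INITIAL, A_CLASS0, reward=1.0)


def value_iteration_two_stage(r_commit, r_defer, r_final):
    """Oracle for the 2-step decision MDP: exact state values."""
    v_s2 = max(r_final)               # best terminal action from s2
    q_s1 = [r_commit, r_defer + v_s2]
    return q_s1, v_s2


class TestTabularOracle:
    def test_policy_matches_value_iteration(self):
        # deferring then predicting class 1 beats committing
        r_commit, r_defer, r_final = -1.0, 0.1, (-1.0, 1.0)
        agent = TabularQ()
        rng = np.random.default_rng(13)
        for _ in range(300):
            # explore both branches uniformly, update backward
            a2 = int(rng.integers(2))
            agent.update(("s2",), a2, r_final[a2])
            a1 = int(rng.integers(2))
            if a1 == 0:
                agent.update(("s1",), 0, r_commit)
            else:
                nq = max(agent.q_value(("s2",), a) for a in (0, 1))
                agent.update(("s1",), 1, r_defer, next_q=nq)
        q_s1, v_s2 = value_iteration_two_stage(r_commit, r_defer, r_final)
        assert agent.policy(("s1",), (0, 1)) == int(np.argmax(q_s1))
        assert agent.policy(("s2",), (0, 1)) == int(np.argmax(r_final))
        assert max(agent.q_value(("s2",), a) for a in (0, 1)) == \
            pytest.approx(v_s2, abs=1e-6)


class TestRunEpisode:
    def _agent(self):
        return QAgent(n_state=2, hidden=4, rng=np.random.default_rng(14))

    def test_forced_commit_correct(self):
        transitions, reward, pred = run_episode(
            self._agent(), np.ones(4), np.ones(2), stage1_pred=1, label=1,
            forced_actions=[A_COMMIT])
        assert len(transitions) == 1
        assert transitions[0][1:4] == (KIND_INITIAL, A_COMMIT, 1.0)
        assert reward == 1.0 and pred == 1

    def test_forced_defer_then_class0(self):
        transitions, reward, pred = run_episode(
            self._agent(), np.ones(4), np.ones(2), stage1_pred=1, label=0,
            forced_actions=[A_DEFER, A_CLASS0], r_defer=0.1)
        assert len(transitions) == 2
        assert transitions[0][2] == A_DEFER
        assert transitions[1][1:4] == (KIND_TRANSITION, A_CLASS0, 1.0)
        assert reward == pytest.approx(1.1) and pred == 0

    def test_episode_length_never_exceeds_two(self):
        agent = self._agent()
        rng = np.random.default_rng(15)
        for _ in range(50):
            transitions, _, _ = run_episode(
                agent, rng.standard_normal(4), rng.standard_normal(2),
                stage1_pred=0, label=1, explore_eps=1.0, rng=rng)
            assert 1 <= len(transitions) <= 2
            assert transitions[-1][4] is True  # terminates in s_e

    def test_greedy_episode_deterministic(self):
        agent = self._agent()
        outs = [run_episode(agent, np.ones(4), np.ones(2), 1, 1,
                            explore_eps=0.0) for _ in range(2)]
        assert outs[0][1] == outs[1][1] and outs[0][2] == outs[1][2]
        acts_a = [t[1:4] for t in outs[0][0]]
        acts_b = [t[1:4] for t in outs[1][0]]
        assert acts_a == acts_b


class TestDeferralBehaviour:
    """The policy should defer on the class whose stage-1 prediction fails.

    States are constructed directly: s1/s2 are class-coded Gaussian
    clusters and the stage-1 prediction is systematically wrong on class
    B (it always says class A), so committing on B pays -1 while
    deferring and reading s2 pays ~+1.1.
    """

    @staticmethod
    def _trial(seed, epochs=40, n=200):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        s1 = rng.standard_normal((n, 4)) * 0.3 + y[:, None] * 2.0
        s2 = rng.standard_normal((n, 2)) * 0.3 + y[:, None] * 2.0
        agent = QAgent(n_state=2, hidden=16, lr=0.01, rng=rng)
        for ep in range(epochs):
            eps = 0.5 + (0.05 - 0.5) * ep / (epochs - 1)
            for i in rng.permutation(n):
                transitions, _, _ = run_episode(
                    agent, s1[i], s2[i], stage1_pred=0, label=int(y[i]),
                    explore_eps=eps, rng=rng)
                for s_vec, kind, a, r, terminal in transitions:
                    if terminal:
                        nq = None
                    else:
                        a_n = agent.policy(s2[i], KIND_TRANSITION)
                        nq = agent.q_value(s2[i], KIND_TRANSITION, a_n)
                    agent.update(s_vec, kind, a, r, nq)
        defer = np.array([agent.policy(s1[i], KIND_INITIAL) == A_DEFER
                          for i in range(n)])
        return defer[y == 0].mean(), defer[y == 1].mean()

    def test_defers_more_on_the_misjudged_class(self):
        gaps = []
        for seed in range(4):
            defer_a, defer_b = self._trial(seed)
            assert defer_b >= defer_a  # never the other way around
            gaps.append(defer_b - defer_a)
        assert np.mean(gaps) > 0.3


class TestRBATQClassifier:
    def test_learns_separable_segments(self, small_segments):
        X, y = small_segments.flat, small_segments.labels
        clf = RBATQClassifier(state_size=8, hidden=16, frame_width=11,
                              dropout=0.0, pretrain_epochs=10, q_epochs=5,
                              random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.9

    def test_permuted_labels_score_near_chance(self, small_segments):
        X = small_segments.flat
        rng = np.random.default_rng(1)
        yp = rng.permutation(small_segments.labels)
        clf = RBATQClassifier(state_size=8, hidden=16, frame_width=11,
                              dropout=0.0, pretrain_epochs=6, q_epochs=3,
                              random_state=0).fit(X[:150], yp[:150])
        acc = (clf.predict(X[150:]) == yp[150:]).mean()
        assert abs(acc - 0.5) <= 0.15

    def test_fixed_seed_reproduces_reward_trace(self, small_segments):
        X, y = small_segments.flat, small_segments.labels
        traces = []
        for _ in range(2):
            clf = RBATQClassifier(state_size=4, hidden=8, frame_width=11,
                                  dropout=0.1, pretrain_epochs=2, q_epochs=3,
                                  random_state=7).fit(X[:100], y[:100])
            traces.append(clf.reward_trace_)
        assert np.array_equal(traces[0], traces[1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            RBATQClassifier(pretrain_epochs=1, q_epochs=1).fit(
                np.zeros((10, 44)), np.zeros(10))

    def test_joint_updates_keep_training_builders(self, small_segments):
        X, y = small_segments.flat, small_segments.labels
        frozen = RBATQClassifier(state_size=4, hidden=8, frame_width=11,
                                 dropout=0.0, pretrain_epochs=2, q_epochs=3,
                                 random_state=7).fit(X[:100], y[:100])
        joint = RBATQClassifier(state_size=4, hidden=8, frame_width=11,
                                dropout=0.0, pretrain_epochs=2, q_epochs=3,
                                joint_updates=True,
                                random_state=7).fit(X[:100], y[:100])
        w_frozen = frozen.bilstm_.fwd.W["xi"].value
        w_joint = joint.bilstm_.fwd.W["xi"].value
        assert not np.array_equal(w_frozen, w_joint)


class TestDecisionMDP:
    def test_terminal_rewards(self):
        from swarmeeg.rbatq import DecisionMDP
        mdp = DecisionMDP()
        assert mdp.terminal_reward(1, 1) == 1.0
        assert mdp.terminal_reward(0, 1) == -1.0
        assert mdp.r_defer == pytest.approx(0.1)
        assert mdp.actions(KIND_INITIAL) == (A_COMMIT, A_DEFER)
        assert mdp.actions(KIND_TRANSITION) == (A_CLASS0, A_CLASS1)
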