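"""RBATQ: a Q-learning decision agent over recurrent EEG state builders.

A segment is framed into a short sequence of feature vectors and mapped to
two alternative state representations:

* the initial state ``s1 = Att(X; theta_1)``: an attention-weighted pooling
  of the hidden states of a peephole BiLSTM (gates per the printed forward
  pass, including the cell-to-gate peephole terms), with a softmax output
  head on the pooled forward/backward states;
* the transition state ``s2 = Tree(X; theta_2)``: the root hidden state of
  a child-sum Tree-LSTM over a balanced binary tree of contiguous
  sub-windows, with its own softmax head ``y_r``.

The decision process has states {s1, s2, s_e} and actions {a1..a4}: at s1
the agent either commits (a1: predict the class indicated by the BiLSTM
head; terminal, reward +1/-1) or defers (a2: build s2, small positive
reward); at s2 it predicts class 0 (a3) or class 1 (a4) (terminal, reward
+1/-1).  Episodes therefore terminate within two decisions.

State-action values are approximated by an MLP on [state ; state-kind ;
one-hot action]; the training target is the running average
``(1/t) r + ((t-1)/t) Q(s', a')`` with per-(state-kind, action) visit
counts t, and parameters are updated by RMSprop on the squared error
between estimate and target.  State builders are pre-trained with
supervised cross-entropy and frozen during Q-learning (configurable).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._autodiff import (Adam, RMSprop, Tensor, concat, constant, max_norm_,
                        parameter, softmax_cross_entropy)
from .synthetic import zscore_segments

__all__ = [
    "BiLSTMParams", "AttentionParams", "TreeLSTMParams", "QAgent",
    "TabularQ", "bilstm_forward", "attention_state", "tree_state",
    "q_target", "q_update", "run_episode", "DecisionMDP",
    "RBATQClassifier",
    "train_rbatq", "rbatq_predict",
    "A_COMMIT", "A_DEFER", "A_CLASS0", "A_CLASS1", "KIND_INITIAL",
    "KIND_TRANSITION",
]

# action indices a1..a4
A_COMMIT, A_DEFER, A_CLASS0, A_CLASS1 = 0, 1, 2, 3
KIND_INITIAL, KIND_TRANSITION = 0, 1
ACTIONS_AT = {KIND_INITIAL: (A_COMMIT, A_DEFER),
              KIND_TRANSITION: (A_CLASS0, A_CLASS1)}


class DecisionMDP:
    """The two-step classify-or-defer decision process.

    States {s1, s2, s_e}, actions {a1..a4}, and the reward values for
    correct/incorrect terminal predictions and for deferral.  Episodes
    always terminate in s_e within two decisions.
    """

    STATES = ("s1", "s2", "s_e")

    def __init__(self, r_correct=1.0, r_incorrect=-1.0, r_defer=0.1):
        self.r_correct = float(r_correct)
        self.r_incorrect = float(r_incorrect)
        self.r_defer = float(r_defer)

    def actions(self, kind: int) -> tuple[int, ...]:
        return ACTIONS_AT[kind]

    def terminal_reward(self, predicted: int, label: int) -> float:
        return self.r_correct if predicted == label else self.r_incorrect


def _init(rng, *shape):
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    return parameter(rng.standard_normal(shape) / np.sqrt(fan_in))


# ---------------------------------------------------------------------------
# BiLSTM with peephole connections


class _LSTMDirection:
    """One direction's gate parameters (full peephole matrices)."""

    GATES = ("xi", "hi", "ci", "xf", "hf", "cf", "xc", "hc", "cc",
             "xo", "ho", "co")

    def __init__(self, n_input, n_state, rng):
        self.n_input, self.n_state = n_input, n_state
        self.W = {}
        for name in self.GATES:
            fan = n_input if name[0] == "x" else n_state
            self.W[name] = _init(rng, fan, n_state)
        self.b = {g: parameter(np.zeros(n_state)) for g in "ifco"}

    @property
    def params(self):
        return list(self.W.values()) + list(self.b.values())

    def step(self, x_t: Tensor, h_prev: Tensor, c_prev: Tensor):
        W, b = self.W, self.b
        i = (x_t @ W["xi"] + h_prev @ W["hi"] + c_prev @ W["ci"]
             + b["i"]).sigmoid()
        f = (x_t @ W["xf"] + h_prev @ W["hf"] + c_prev @ W["cf"]
             + b["f"]).sigmoid()
        g = (x_t @ W["xc"] + h_prev @ W["hc"] + c_prev @ W["cc"]
             + b["c"]).tanh()
        c = i * g + f * c_prev
        o = (x_t @ W["xo"] + h_prev @ W["ho"] + c @ W["co"]
             + b["o"]).sigmoid()
        h = o * c.tanh()
        return h, c

    def run(self, xs: list[Tensor], reverse: bool = False) -> list[Tensor]:
        batch = xs[0].shape[0]
        h = constant(np.zeros((batch, self.n_state)))
        c = constant(np.zeros((batch, self.n_state)))
        order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
        out: dict[int, Tensor] = {}
        for t in order:
            h, c = self.step(xs[t], h, c)
            out[t] = h
        return [out[t] for t in range(len(xs))]


class BiLSTMParams:
    """Both directions plus the softmax output head y_t."""

    def __init__(self, n_input, n_state, n_classes=2, rng=None):
        rng = rng or np.random.default_rng(0)
        self.n_state = n_state
        self.fwd = _LSTMDirection(n_input, n_state, rng)
        self.bwd = _LSTMDirection(n_input, n_state, rng)
        self.W_hy = _init(rng, n_state, n_classes)
        self.W_hpy = _init(rng, n_state, n_classes)
        self.b_y = parameter(np.zeros(n_classes))

    @property
    def params(self):
        return (self.fwd.params + self.bwd.params
                + [self.W_hy, self.W_hpy, self.b_y])

    def states(self, xs: list[Tensor]):
        """Per-step forward and backward hidden states for a batch."""
        return self.fwd.run(xs), self.bwd.run(xs, reverse=True)

    def head(self, h: Tensor, hp: Tensor) -> Tensor:
        """Logits W_hy h + W_h'y h' + b_y (softmax applied by caller)."""
        return h @ self.W_hy + hp @ self.W_hpy + self.b_y


def bilstm_forward(x_seq: np.ndarray, params: BiLSTMParams):
    """Run one sequence (T, d) through the BiLSTM.

    Returns ``(h_seq, h_prime_seq, y_seq)`` as numpy arrays of shapes
    (T, n_state), (T, n_state) and (T, n_classes); each row of ``y_seq``
    is the per-timestep softmax output.
    """
    x_seq = np.atleast_2d(np.asarray(x_seq, dtype=np.float64))
    if x_seq.shape[0] < 1:
        raise ValueError("sequence must have length >= 1")
    if x_seq.shape[1] != params.fwd.n_input:
        raise ValueError("feature width mismatch")
    xs = [constant(x_seq[t:t + 1]) for t in range(x_seq.shape[0])]
    hs, hps = params.states(xs)
    y = [params.head(h, hp).softmax(axis=1) for h, hp in zip(hs, hps)]
    return (np.vstack([h.value for h in hs]),
            np.vstack([h.value for h in hps]),
            np.vstack([t.value for t in y]))


# ---------------------------------------------------------------------------
# attention pooling


class AttentionParams:
    """Additive attention: score_t = v . tanh(W [h_t ; h'_t] + b)."""

    def __init__(self, n_state, attn_dim=None, rng=None):
        rng = rng or np.random.default_rng(0)
        attn_dim = attn_dim or n_state
        self.W = _init(rng, 2 * n_state, attn_dim)
        self.b = parameter(np.zeros(attn_dim))
        self.v = _init(rng, attn_dim, 1)

    @property
    def params(self):
        return [self.W, self.b, self.v]


def _attention_pool(hs, hps, params: AttentionParams):
    """Batched attention over time.

    Returns (context (B, 2*n_state) Tensor, weights (B, T) Tensor).
    """
    states = [concat([h, hp], axis=1) for h, hp in zip(hs, hps)]
    scores = [((s @ params.W + params.b).tanh() @ params.v)
              for s in states]                      # each (B, 1)
    score_mat = concat(scores, axis=1)              # (B, T)
    weights = score_mat.softmax(axis=1)
    ctx = None
    for t, s in enumerate(states):
        term = s * weights[:, t:t + 1]
        ctx = term if ctx is None else ctx + term
    return ctx, weights


def attention_state(h_seq, h_prime_seq, params: AttentionParams):
    """s1 = sum_t a_t [h_t ; h'_t] for one sequence; returns (s1, a)."""
    h_seq = np.atleast_2d(np.asarray(h_seq, dtype=np.float64))
    h_prime_seq = np.atleast_2d(np.asarray(h_prime_seq, dtype=np.float64))
    if h_seq.shape[0] < 1:
        raise ValueError("empty sequence")
    hs = [constant(h_seq[t:t + 1]) for t in range(h_seq.shape[0])]
    hps = [constant(h_prime_seq[t:t + 1]) for t in range(h_seq.shape[0])]
    ctx, weights = _attention_pool(hs, hps, params)
    return ctx.value[0], weights.value[0]


# ---------------------------------------------------------------------------
# child-sum Tree-LSTM


class TreeLSTMParams:
    """Child-sum composition weights shared by leaf and internal nodes."""

    def __init__(self, n_input, n_state, n_classes=2, rng=None):
        rng = rng or np.random.default_rng(0)
        self.n_input, self.n_state = n_input, n_state
        self.Wx = {g: _init(rng, n_input, n_state) for g in "ifgo"}
        self.U = {g: _init(rng, n_state, n_state) for g in "ifgo"}
        self.b = {g: parameter(np.zeros(n_state)) for g in "ifgo"}
        self.W_sy = _init(rng, n_state, n_classes)
        self.b_sy = parameter(np.zeros(n_classes))

    @property
    def params(self):
        return (list(self.Wx.values()) + list(self.U.values())
                + list(self.b.values()) + [self.W_sy, self.b_sy])

    def compose(self, x: Tensor, children):
        """One node: input x (B, d) and children [(h, c), ...]."""
        if children:
            h_sum = children[0][0]
            for h_k, _ in children[1:]:
                h_sum = h_sum + h_k
        else:
            h_sum = constant(np.zeros((x.shape[0], self.n_state)))
        i = (x @ self.Wx["i"] + h_sum @ self.U["i"] + self.b["i"]).sigmoid()
        g = (x @ self.Wx["g"] + h_sum @ self.U["g"] + self.b["g"]).tanh()
        o = (x @ self.Wx["o"] + h_sum @ self.U["o"] + self.b["o"]).sigmoid()
        c = i * g
        for h_k, c_k in children:  # one forget gate per child
            f_k = (x @ self.Wx["f"] + h_k @ self.U["f"]
                   + self.b["f"]).sigmoid()
            c = c + f_k * c_k
        h = o * c.tanh()
        return h, c


def _tree_root(xs: list[Tensor], params: TreeLSTMParams, depth: int):
    """Build the balanced binary tree over contiguous chunks of frames."""
    n_leaves = 2 ** depth
    t_total = len(xs)
    bounds = np.linspace(0, t_total, n_leaves + 1).astype(int)
    bounds = np.maximum.accumulate(np.maximum(bounds, 0))

    def span_mean(lo, hi):
        if hi <= lo:  # short sequences: repeat the last frame
            lo, hi = max(0, min(lo, t_total - 1)), max(1, min(hi, t_total))
            if hi <= lo:
                lo, hi = t_total - 1, t_total
        acc = xs[lo]
        for t in range(lo + 1, hi):
            acc = acc + xs[t]
        return acc * (1.0 / (hi - lo))

    nodes = []
    for k in range(n_leaves):
        lo, hi = int(bounds[k]), int(bounds[k + 1])
        nodes.append((params.compose(span_mean(lo, hi), []), (lo, hi)))
    while len(nodes) > 1:
        merged = []
        for k in range(0, len(nodes), 2):
            (hc_l, span_l), (hc_r, span_r) = nodes[k], nodes[k + 1]
            lo, hi = span_l[0], span_r[1]
            hc = params.compose(span_mean(lo, hi), [hc_l, hc_r])
            merged.append((hc, (lo, hi)))
        nodes = merged
    return nodes[0][0][0]  # root hidden state


def tree_state(x_seq, params: TreeLSTMParams, depth: int = 2):
    """Root state s2 and head output y_r for one sequence (T, d)."""
    x_seq = np.atleast_2d(np.asarray(x_seq, dtype=np.float64))
    if x_seq.shape[0] < 1:
        raise ValueError("empty input")
    xs = [constant(x_seq[t:t + 1]) for t in range(x_seq.shape[0])]
    root = _tree_root(xs, params, depth)
    y_r = (root @ params.W_sy + params.b_sy).softmax(axis=1)
    return root.value[0], y_r.value[0]


# ---------------------------------------------------------------------------
# Q agent


def q_target(r: float, t: int, q_prev: float) -> float:
    """Running-average target (1/t) r + ((t-1)/t) q_prev; requires t >= 1."""
    if t < 1:
        raise ValueError("visit count t must be >= 1")
    return r / t + (t - 1) / t * q_prev


class QAgent:
    """MLP state-action value estimator with running-average targets.

    Input is [state (padded to 2*n_state) ; state-kind one-hot(2) ;
    action one-hot(4)]; one tanh hidden layer; scalar output.  Updates are
    RMSprop steps on the squared error against :func:`q_target`.
    """

    def __init__(self, n_state, hidden=100, lr=0.002, rng=None):
        rng = rng or np.random.default_rng(0)
        self.n_state = n_state
        self.in_dim = 2 * n_state + 2 + 4
        self.W1 = _init(rng, self.in_dim, hidden)
        self.b1 = parameter(np.zeros(hidden))
        self.W2 = _init(rng, hidden, 1)
        self.b2 = parameter(np.zeros(1))
        self.visits: dict[tuple[int, int], int] = {}
        self.opt = RMSprop([self.W1, self.b1, self.W2, self.b2], lr=lr)

    def _encode(self, s_vec, kind, action) -> np.ndarray:
        s_vec = np.asarray(s_vec, dtype=np.float64).ravel()
        x = np.zeros(self.in_dim)
        x[: s_vec.size] = s_vec
        x[2 * self.n_state + kind] = 1.0
        x[2 * self.n_state + 2 + action] = 1.0
        return x[None, :]

    def _q_tensor(self, s_vec, kind, action) -> Tensor:
        x = constant(self._encode(s_vec, kind, action))
        return ((x @ self.W1 + self.b1).tanh() @ self.W2 + self.b2)

    def q_value(self, s_vec, kind, action) -> float:
        return float(self._q_tensor(s_vec, kind, action).value.item())

    def policy(self, s_vec, kind) -> int:
        """Greedy action argmax_a Q(s, a) over the actions legal at s."""
        actions = ACTIONS_AT[kind]
        values = [self.q_value(s_vec, kind, a) for a in actions]
        return actions[int(np.argmax(values))]

    def update(self, s_vec, kind, action, reward, next_q=None,
               alpha=None) -> float:
        """One RMSprop step toward the running-average target.

        ``next_q`` is Q(s', a') for the successor state-action pair; for
        terminal transitions (``next_q=None``) the target averages the new
        reward with the current estimate Q(s, a), so repeated visits under
        a constant reward converge to that reward.  Returns the target.
        """
        if kind not in ACTIONS_AT or action not in ACTIONS_AT[kind]:
            raise ValueError(f"action {action} invalid in state kind {kind}")
        t = self.visits.get((kind, action), 0) + 1
        self.visits[(kind, action)] = t
        if next_q is None:
            next_q = self.q_value(s_vec, kind, action)
        target = q_target(reward, t, next_q)
        if alpha is not None:
            self.opt.lr = alpha
        if self.opt.lr == 0.0:
            return target
        self.opt.zero_grad()
        q = self._q_tensor(s_vec, kind, action)
        loss = (q - constant(np.array([[target]]))).square().sum()
        loss.backward()
        self.opt.step()
        return target


def q_update(agent: QAgent, s_vec, kind, action, reward, next_q=None,
             alpha=None) -> float:
    """Functional wrapper over :meth:`QAgent.update`."""
    return agent.update(s_vec, kind, action, reward, next_q, alpha)


class TabularQ:
    """Tabular specialization of the Q-learner (exact running averages).

    Useful for small finite MDPs and as an oracle check: with the
    running-average target and constant rewards, Q(s, a) converges to the
    mean observed return.
    """

    def __init__(self):
        self.q: dict[tuple, float] = {}
        self.visits: dict[tuple, int] = {}

    def q_value(self, s, a) -> float:
        return self.q.get((s, a), 0.0)

    def policy(self, s, actions) -> int:
        values = [self.q_value(s, a) for a in actions]
        return actions[int(np.argmax(values))]

    def update(self, s, a, reward, next_q=None) -> float:
        t = self.visits.get((s, a), 0) + 1
        self.visits[(s, a)] = t
        if next_q is None:
            next_q = self.q_value(s, a)
        target = q_target(reward, t, next_q)
        # exact least-squares solution of the tabular case
        self.q[(s, a)] = target
        return target


# ---------------------------------------------------------------------------
# episodes


def run_episode(agent: QAgent, s1_vec, s2_vec, stage1_pred: int, label: int,
                explore_eps: float = 0.0, rng=None, r_defer: float = 0.1,
                forced_actions=None, mdp: DecisionMDP | None = None):
    """Roll out one <=2-step decision episode.

    Returns ``(transitions, total_reward, predicted_label)`` where each
    transition is ``(state_vec, kind, action, reward, terminal)``.
    ``forced_actions`` overrides the policy (used for tests and analyses);
    ``mdp`` overrides the reward values (``r_defer`` is kept for
    convenience when only the deferral reward differs).
    """
    mdp = mdp or DecisionMDP(r_defer=r_defer)
    rng = rng or np.random.default_rng(0)
    forced = list(forced_actions) if forced_actions is not None else []

    def choose(s_vec, kind):
        if forced:
            return forced.pop(0)
        if explore_eps > 0 and rng.random() < explore_eps:
            return int(rng.choice(mdp.actions(kind)))
        return agent.policy(s_vec, kind)

    transitions = []
    a = choose(s1_vec, KIND_INITIAL)
    if a == A_COMMIT:
        r = mdp.terminal_reward(stage1_pred, label)
        transitions.append((s1_vec, KIND_INITIAL, a, r, True))
        return transitions, r, stage1_pred
    transitions.append((s1_vec, KIND_INITIAL, A_DEFER, mdp.r_defer, False))
    a2 = choose(s2_vec, KIND_TRANSITION)
    pred = 0 if a2 == A_CLASS0 else 1
    r2 = mdp.terminal_reward(pred, label)
    transitions.append((s2_vec, KIND_TRANSITION, a2, r2, True))
    return transitions, mdp.r_defer + r2, pred


# ---------------------------------------------------------------------------
# estimator


class RBATQClassifier(ClassifierMixin, BaseEstimator):
    """EEG segment classifier driven by a Q-learning decision agent.

    Parameters (defaults are the full-scale study configuration)
    ----------------------------------------------------------------
    state_size : LSTM state width (250 full scale).
    hidden : Q-network hidden width (100).
    frame_width : samples per BiLSTM input frame (segments are reshaped
        into T = L // frame_width frames).
    tree_depth : balanced-binary-tree depth for the Tree-LSTM (2).
    dropout : dropout rate on the pooled attention context during
        pre-training (0.75 full scale).
    learning_rate : pre-training Adam / Q-update RMSprop rate (0.002).
    batch_size : pre-training mini-batch size (25).
    max_norm : max-norm constraint on state-builder weights (3).
    pretrain_epochs, q_epochs : schedule of the two phases.
    eps_start, eps_end : epsilon-greedy exploration decay.
    r_defer : reward for the defer action a2.
    """

    def __init__(self, state_size=250, hidden=100, frame_width=10,
                 tree_depth=2, dropout=0.75, learning_rate=0.002,
                 batch_size=25, max_norm=3.0, pretrain_epochs=20,
                 q_epochs=20, eps_start=0.5, eps_end=0.05, r_defer=0.1,
                 joint_updates=False, normalize=True, random_state=0):
        self.state_size = state_size
        self.hidden = hidden
        self.frame_width = frame_width
        self.tree_depth = tree_depth
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_norm = max_norm
        self.pretrain_epochs = pretrain_epochs
        self.q_epochs = q_epochs
        self.eps_start = eps_start
        self.eps_end = eps_end
        self.r_defer = r_defer
        self.joint_updates = joint_updates
        self.normalize = normalize
        self.random_state = random_state

    # -- framing ---------------------------------------------------------
    def _frames(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self.normalize:
            X = zscore_segments(X)
        n, length = X.shape
        t_steps = length // self.frame_width
        if t_steps < 1:
            raise ValueError("segment shorter than one frame")
        return X[:, : t_steps * self.frame_width].reshape(
            n, t_steps, self.frame_width)

    def _batch_states(self, frames: np.ndarray, train_rng=None):
        """Tensors (s1 context, stage-1 logits, s2 root, y_r logits)."""
        xs = [constant(frames[:, t, :]) for t in range(frames.shape[1])]
        hs, hps = self.bilstm_.states(xs)
        ctx, _ = _attention_pool(hs, hps, self.attention_)
        if train_rng is not None and self.dropout > 0:
            keep = 1.0 - self.dropout
            mask = train_rng.random(ctx.shape) < keep
            ctx = ctx * constant(mask / keep)
        half = self.state_size
        logits1 = self.bilstm_.head(ctx[:, :half], ctx[:, half:])
        root = _tree_root(xs, self.tree_, self.tree_depth)
        logits2 = root @ self.tree_.W_sy + self.tree_.b_sy
        return ctx, logits1, root, logits2

    # -- training --------------------------------------------------------
    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("RBATQ is a two-class model; got "
                             f"{len(self.classes_)} class(es)")
        frames = self._frames(X)
        n, _, d = frames.shape
        rng = np.random.default_rng(self.random_state)
        self.bilstm_ = BiLSTMParams(d, self.state_size, 2, rng)
        self.attention_ = AttentionParams(self.state_size, rng=rng)
        self.tree_ = TreeLSTMParams(d, self.state_size, 2, rng)
        self.agent_ = QAgent(self.state_size, self.hidden,
                             lr=self.learning_rate, rng=rng)

        # phase 1: supervised pre-training of both state builders
        builder_params = (self.bilstm_.params + self.attention_.params
                          + self.tree_.params)
        opt = Adam(builder_params, lr=self.learning_rate)
        bs = min(self.batch_size, n)

        def supervised_epoch():
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                opt.zero_grad()
                _, logits1, _, logits2 = self._batch_states(
                    frames[idx], train_rng=rng)
                loss = (softmax_cross_entropy(logits1, y_idx[idx])
                        + softmax_cross_entropy(logits2, y_idx[idx]))
                loss.backward()
                opt.step()
                max_norm_(builder_params, self.max_norm)
                epoch_loss += float(loss.value) * len(idx)
            return epoch_loss / n

        def frozen_states():
            ctx, logits1, root, _ = self._batch_states(frames)
            return ctx.value, root.value, logits1.value.argmax(axis=1)

        self.pretrain_loss_trace_ = np.array(
            [supervised_epoch() for _ in range(self.pretrain_epochs)])

        s1, s2, stage1_pred = frozen_states()
        self.stage1_train_accuracy_ = float(np.mean(stage1_pred == y_idx))

        # phase 2: Q-learning over the two-step decision MDP; with
        # joint_updates the builders keep adapting (one supervised epoch
        # per Q epoch, states refreshed) instead of staying frozen
        mdp = DecisionMDP(r_defer=self.r_defer)
        reward_trace = []
        for epoch in range(self.q_epochs):
            frac = epoch / max(self.q_epochs - 1, 1)
            eps = self.eps_start + (self.eps_end - self.eps_start) * frac
            total = 0.0
            for i in rng.permutation(n):
                transitions, reward, _ = run_episode(
                    self.agent_, s1[i], s2[i], int(stage1_pred[i]),
                    int(y_idx[i]), explore_eps=eps, rng=rng, mdp=mdp)
                for (s_vec, kind, action, r, terminal) in transitions:
                    if terminal:
                        next_q = None
                    else:
                        a_next = self.agent_.policy(s2[i], KIND_TRANSITION)
                        next_q = self.agent_.q_value(s2[i], KIND_TRANSITION,
                                                     a_next)
                    self.agent_.update(s_vec, kind, action, r, next_q)
                total += reward
            reward_trace.append(total / n)
            if self.joint_updates and epoch < self.q_epochs - 1:
                supervised_epoch()
                s1, s2, stage1_pred = frozen_states()
        self.reward_trace_ = np.array(reward_trace)
        self.n_features_in_ = np.atleast_2d(np.asarray(X)).shape[1]
        return self

    # -- inference -------------------------------------------------------
    def _episode_states(self, X):
        frames = self._frames(X)
        ctx, logits1, root, _ = self._batch_states(frames)
        return ctx.value, root.value, logits1.value.argmax(axis=1)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "agent_")
        s1, s2, stage1_pred = self._episode_states(X)
        out = np.empty(len(s1), dtype=int)
        for i in range(len(s1)):
            _, _, pred = run_episode(self.agent_, s1[i], s2[i],
                                     int(stage1_pred[i]), label=-1,
                                     explore_eps=0.0)
            out[i] = pred
        return self.classes_[out]

    def defer_mask(self, X) -> np.ndarray:
        """Which segments the greedy policy defers (a2) on."""
        check_is_fitted(self, "agent_")
        s1, _, _ = self._episode_states(X)
        return np.array([self.agent_.policy(s, KIND_INITIAL) == A_DEFER
                         for s in s1])


def train_rbatq(data, labels=None, **kwargs) -> RBATQClassifier:
    """Functional wrapper: fit an :class:`RBATQClassifier`."""
    from .synthetic import EEGSegmentSet
    if isinstance(data, EEGSegmentSet):
        X, y = data.flat, data.labels
    else:
        X, y = data, labels
    return RBATQClassifier(**kwargs).fit(X, y)


def rbatq_predict(model: RBATQClassifier, X) -> np.ndarray:
    return model.predict(np.atleast_2d(X))
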