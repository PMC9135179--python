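"""Swarm metaheuristics for wrapper feature selection.

Three population optimizers maximise a feature-subset fitness over
continuous positions in R^d (d = bottleneck width):

* PSO — inertia w = 0.64, acceleration c1 = c2 = 1.524, 30 particles,
  30 generations;
* Cuckoo search — n = 20 nests, abandonment fraction p_a = 0.45, step
  size alpha = 1.5, Lévy exponent 1.5 (Mantegna construction);
* Bat algorithm — 40 bats, frequency range [0, 2], initial loudness 1,
  initial pulse rate 0.5.

A continuous position is decoded to a boolean feature mask by taking the
top-m coordinates (ties to the lowest index), guaranteeing the fixed
9000 -> 4500 reduction of the full-scale pipeline.  The fitness critic is
the validation accuracy of a budgeted downstream softmax DNN on an inner
stratified 80/20 split (wrapper selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .classifier import SoftmaxDNNClassifier

__all__ = [
    "PSOConfig", "CSOConfig", "BAConfig", "SwarmResult",
    "pso_step", "run_pso", "levy_step", "run_cso", "run_ba",
    "mask_from_position", "feature_fitness", "SwarmFeatureSelector",
]


# ---------------------------------------------------------------------------
# configs


@dataclass
class PSOConfig:
    inertia: float = 0.64
    c1: float = 1.524
    c2: float = 1.524
    population: int = 30
    generations: int = 30
    init_range: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.inertia < 0:
            raise ValueError("inertia must be non-negative")
        if self.population < 2:
            raise ValueError("population must be at least 2")


@dataclass
class CSOConfig:
    n_nests: int = 20
    p_abandon: float = 0.45
    alpha: float = 1.5
    levy_exponent: float = 1.5
    generations: int = 100
    init_range: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_abandon <= 1.0:
            raise ValueError("p_abandon must lie in [0, 1]")
        if not 1.0 < self.levy_exponent <= 3.0:
            raise ValueError("levy_exponent must lie in (1, 3]")


@dataclass
class BAConfig:
    n_bats: int = 40
    f_min: float = 0.0
    f_max: float = 2.0
    loudness0: float = 1.0
    loudness_min: float = 0.0     # A_min: floor of the loudness decay
    pulse_rate0: float = 0.5
    loudness_decay: float = 0.9   # alpha_A: A_i <- alpha_A * A_i on accept
    rate_growth: float = 0.9      # gamma: r_i <- r0 * (1 - exp(-gamma * t))
    local_step: float = 0.05      # local-walk sigma, relative to init span
    generations: int = 100
    init_range: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.f_min > self.f_max:
            raise ValueError("f_min must not exceed f_max")
        if self.loudness0 < 0:
            raise ValueError("loudness must be non-negative")
        if not 0.0 <= self.pulse_rate0 <= 1.0:
            raise ValueError("pulse_rate0 must lie in [0, 1]")


@dataclass
class SwarmResult:
    """Outcome of one optimizer run (best-ever position and trace)."""

    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# PSO


@dataclass
class _Swarm:
    positions: np.ndarray      # (pop, d)
    velocities: np.ndarray
    pbest: np.ndarray
    pbest_fitness: np.ndarray
    gbest: np.ndarray
    gbest_fitness: float


def pso_step(swarm: _Swarm, cfg: PSOConfig, rng: np.random.Generator,
             fitness=None) -> _Swarm:
    """One velocity/position update (fresh r1, r2 per particle per dim).

    v <- w v + c1 r1 (P_id - x) + c2 r2 (P_gd - x);  x <- x + v.
    Personal/global bests update only on strict improvement when a
    ``fitness`` callable is supplied.
    """
    pop, d = swarm.positions.shape
    if swarm.gbest.shape != (d,):
        raise ValueError("global best dimension mismatch")
    r1 = rng.random((pop, d))
    r2 = rng.random((pop, d))
    swarm.velocities = (cfg.inertia * swarm.velocities
                        + cfg.c1 * r1 * (swarm.pbest - swarm.positions)
                        + cfg.c2 * r2 * (swarm.gbest - swarm.positions))
    swarm.positions = swarm.positions + swarm.velocities
    if fitness is not None:
        for i in range(pop):
            f = fitness(swarm.positions[i])
            if f > swarm.pbest_fitness[i]:
                swarm.pbest_fitness[i] = f
                swarm.pbest[i] = swarm.positions[i]
                if f > swarm.gbest_fitness:
                    swarm.gbest_fitness = f
                    swarm.gbest = swarm.positions[i].copy()
    return swarm


def run_pso(fitness, d: int, cfg: PSOConfig | None = None) -> SwarmResult:
    """Maximise ``fitness`` over R^d with particle swarm optimization."""
    cfg = cfg or PSOConfig()
    if d < 1:
        raise ValueError("dimension must be positive")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.init_range
    positions = rng.uniform(lo, hi, size=(cfg.population, d))
    pbf = np.array([fitness(x) for x in positions])
    best = int(np.argmax(pbf))
    swarm = _Swarm(positions, np.zeros_like(positions), positions.copy(),
                   pbf, positions[best].copy(), float(pbf[best]))
    trace = [swarm.gbest_fitness]
    for _ in range(cfg.generations):
        pso_step(swarm, cfg, rng, fitness=fitness)
        trace.append(swarm.gbest_fitness)
    return SwarmResult(swarm.gbest, swarm.gbest_fitness, np.array(trace))


# ---------------------------------------------------------------------------
# Cuckoo search


def levy_step(x: np.ndarray, alpha: float, levy_exponent: float,
              rng: np.random.Generator) -> np.ndarray:
    """x + alpha (+) Levy(levy_exponent), Mantegna heavy-tailed steps."""
    if not 1.0 < levy_exponent <= 3.0:
        raise ValueError("levy_exponent must lie in (1, 3]")
    x = np.asarray(x, dtype=np.float64)
    return x + alpha * _levy_draw(x.shape, levy_exponent, rng)


def _levy_draw(shape, lam: float, rng: np.random.Generator) -> np.ndarray:
    """Mantegna construction: step = u / |v|^(1/lam), u ~ N(0, sigma^2)."""
    sigma = (_gamma(1 + lam) * np.sin(np.pi * lam / 2)
             / (_gamma((1 + lam) / 2) * lam * 2 ** ((lam - 1) / 2))
             ) ** (1.0 / lam)
    u = rng.normal(0.0, sigma, size=shape)
    v = rng.normal(0.0, 1.0, size=shape)
    return u / np.abs(v) ** (1.0 / lam)


def run_cso(fitness, d: int, cfg: CSOConfig | None = None) -> SwarmResult:
    """Maximise ``fitness`` with cuckoo search.

    Per generation: one Lévy-flight cuckoo (step scaled by the distance to
    the best nest, the canonical Mantegna/Yang scaling) replaces a random
    nest if fitter; the worst fraction p_a of non-best nests then move by
    a biased random walk; the best nest is always retained.
    """
    cfg = cfg or CSOConfig()
    if d < 1:
        raise ValueError("dimension must be positive")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.init_range
    nests = rng.uniform(lo, hi, size=(cfg.n_nests, d))
    fit = np.array([fitness(x) for x in nests])
    best = int(np.argmax(fit))
    best_pos, best_fit = nests[best].copy(), float(fit[best])
    trace = [best_fit]
    for _ in range(cfg.generations):
        # cuckoo via Lévy flight from a random nest toward/around the best
        i = rng.integers(cfg.n_nests)
        step = _levy_draw(d, cfg.levy_exponent, rng)
        direction = nests[i] - best_pos
        if not np.any(direction):
            direction = np.full(d, (hi - lo) * 0.01)
        cand = nests[i] + 0.01 * cfg.alpha * step * direction
        f_c = fitness(cand)
        j = rng.integers(cfg.n_nests)
        if f_c > fit[j]:
            nests[j], fit[j] = cand, f_c
        # abandon the worst fraction p_a (never the best nest)
        n_drop = min(int(np.ceil(cfg.p_abandon * cfg.n_nests)),
                     cfg.n_nests - 1)
        if n_drop > 0:
            order = np.argsort(fit)  # ascending: worst first
            worst = [k for k in order if k != int(np.argmax(fit))][:n_drop]
            p1 = rng.permutation(cfg.n_nests)
            p2 = rng.permutation(cfg.n_nests)
            for k in worst:
                walk = rng.random(d) * (nests[p1[k]] - nests[p2[k]])
                cand_k = nests[k] + walk
                f_k = fitness(cand_k)
                if f_k > fit[k]:  # keep only quality replacements
                    nests[k], fit[k] = cand_k, f_k
        b = int(np.argmax(fit))
        if fit[b] > best_fit:
            best_fit, best_pos = float(fit[b]), nests[b].copy()
        trace.append(best_fit)
    return SwarmResult(best_pos, best_fit, np.array(trace))


# ---------------------------------------------------------------------------
# Bat algorithm


def run_ba(fitness, d: int, cfg: BAConfig | None = None) -> SwarmResult:
    """Maximise ``fitness`` with the bat algorithm.

    Frequencies f_i ~ U(f_min, f_max) tune velocities toward the global
    best; when rand > r_i the candidate is a local walk around the best;
    candidates are accepted when rand < A_i and they improve the bat's own
    solution, upon which loudness decays (A_i *= 0.9) and the pulse rate
    grows toward its initial value (r_i = r0 (1 - exp(-0.9 t))).
    """
    cfg = cfg or BAConfig()
    if d < 1:
        raise ValueError("dimension must be positive")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.init_range
    x = rng.uniform(lo, hi, size=(cfg.n_bats, d))
    v = np.zeros_like(x)
    fit = np.array([fitness(p) for p in x])
    A = np.full(cfg.n_bats, float(cfg.loudness0))
    r = np.full(cfg.n_bats, float(cfg.pulse_rate0))
    best = int(np.argmax(fit))
    best_pos, best_fit = x[best].copy(), float(fit[best])
    trace = [best_fit]
    for t in range(1, cfg.generations + 1):
        for i in range(cfg.n_bats):
            f_i = cfg.f_min + (cfg.f_max - cfg.f_min) * rng.random()
            v[i] = v[i] + (x[i] - best_pos) * f_i
            cand = x[i] + v[i]
            if rng.random() > r[i]:
                # local random walk around the current best solution,
                # scaled by mean loudness and the initialisation span
                sigma = cfg.local_step * (hi - lo) * np.mean(A)
                cand = best_pos + sigma * rng.standard_normal(d)
            f_cand = fitness(cand)
            if rng.random() < A[i] and f_cand > fit[i]:
                x[i], fit[i] = cand, f_cand
                A[i] = max(cfg.loudness_decay * A[i], cfg.loudness_min)
                r[i] = cfg.pulse_rate0 * (1.0 - np.exp(-cfg.rate_growth * t))
                if f_cand > best_fit:
                    best_fit, best_pos = float(f_cand), cand.copy()
        trace.append(best_fit)
    return SwarmResult(best_pos, best_fit, np.array(trace))


# ---------------------------------------------------------------------------
# mask decoding and wrapper fitness


def mask_from_position(position: np.ndarray, m: int) -> np.ndarray:
    """Boolean mask of the ``m`` largest coordinates (ties: lowest index)."""
    position = np.asarray(position, dtype=np.float64)
    d = position.size
    if not 0 < m <= d:
        raise ValueError(f"m={m} must lie in [1, {d}]")
    order = np.argsort(-position, kind="stable")
    mask = np.zeros(d, dtype=bool)
    mask[order[:m]] = True
    return mask


def feature_fitness(mask: np.ndarray, features: np.ndarray,
                    labels: np.ndarray, split_seed: int = 0,
                    epochs: int = 5, hidden_sizes=(16,),
                    learning_rate: float = 0.01,
                    scoring: str = "accuracy") -> float:
    """Wrapper fitness: budgeted-DNN validation score on masked features.

    An inner stratified 80/20 split of the rows is scored with a
    :class:`SoftmaxDNNClassifier` trained for ``epochs`` epochs; returns a
    value in [0, 1], deterministic under ``split_seed``.  ``scoring``
    selects plain validation accuracy or its smooth surrogate ``"soft"``
    (mean predicted probability of the true class), which has much lower
    estimator variance on small validation splits and therefore gives the
    swarm a less noisy, less plateau-ridden objective.
    """
    mask = np.asarray(mask, dtype=bool)
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if features.shape[1] != mask.size:
        raise ValueError("mask dimension must equal feature count")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    if scoring not in ("accuracy", "soft"):
        raise ValueError("scoring must be 'accuracy' or 'soft'")
    x_tr, x_va, y_tr, y_va = train_test_split(
        features[:, mask], labels, test_size=0.2, stratify=labels,
        random_state=split_seed)
    clf = SoftmaxDNNClassifier(hidden_sizes=hidden_sizes, dropout=0.0,
                               weight_decay=0.0, epochs=epochs,
                               fine_tune_epochs=0, batch_size=32,
                               learning_rate=learning_rate,
                               random_state=split_seed)
    clf.fit(x_tr, y_tr)
    if scoring == "soft":
        proba = clf.predict_proba(x_va)
        classes = list(clf.classes_)
        idx = np.array([classes.index(v) for v in y_va])
        return float(proba[np.arange(len(y_va)), idx].mean())
    return float(np.mean(clf.predict(x_va) == y_va))


_RUNNERS = {"pso": (run_pso, PSOConfig), "cso": (run_cso, CSOConfig),
            "ba": (run_ba, BAConfig)}


class SwarmFeatureSelector(SelectorMixin, BaseEstimator):
    """Select a fixed-size feature subset with a swarm optimizer.

    Parameters
    ----------
    method : {"pso", "cso", "ba"}
    n_selected : int
        Number of features to keep (full-scale: 4500 of 9000).
    generations, population : int or None
        Override the optimizer's schedule (None keeps its default).
    fitness_epochs : int
        Training budget of the wrapper critic's DNN.
    """

    def __init__(self, method="pso", n_selected=4500, generations=None,
                 population=None, fitness_epochs=5, fitness_hidden=(16,),
                 fitness_learning_rate=0.01, fitness_scoring="accuracy",
                 optimizer_params=None, random_state=0):
        self.method = method
        self.n_selected = n_selected
        self.generations = generations
        self.population = population
        self.fitness_epochs = fitness_epochs
        self.fitness_hidden = fitness_hidden
        self.fitness_learning_rate = fitness_learning_rate
        self.fitness_scoring = fitness_scoring
        self.optimizer_params = optimizer_params
        self.random_state = random_state

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        y = np.asarray(y)
        if self.method not in _RUNNERS:
            raise ValueError(f"unknown method {self.method!r}; "
                             f"choose from {sorted(_RUNNERS)}")
        d = X.shape[1]
        m = int(self.n_selected)
        if not 0 < m <= d:
            raise ValueError(f"n_selected={m} must lie in [1, {d}]")
        runner, cfg_cls = _RUNNERS[self.method]
        kwargs = {"seed": self.random_state, "init_range": (0.0, 1.0)}
        if self.generations is not None:
            kwargs["generations"] = self.generations
        if self.population is not None:
            size_field = {"pso": "population", "cso": "n_nests",
                          "ba": "n_bats"}[self.method]
            kwargs[size_field] = self.population
        kwargs.update(self.optimizer_params or {})
        cfg = cfg_cls(**kwargs)

        def fitness(position):
            mask = mask_from_position(position, m)
            return feature_fitness(mask, X, y, split_seed=self.random_state,
                                   epochs=self.fitness_epochs,
                                   hidden_sizes=self.fitness_hidden,
                                   learning_rate=self.fitness_learning_rate,
                                   scoring=self.fitness_scoring)

        result = runner(fitness, d, cfg)
        self.best_position_ = result.best_position
        self.best_fitness_ = result.best_fitness
        self.trace_ = result.trace
        self.mask_ = mask_from_position(result.best_position, m)
        self.n_features_in_ = d
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "mask_")
        return self.mask_
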