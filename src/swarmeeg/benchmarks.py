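"""Frozen benchmark problems for the swarm optimizers.

Two standard checks used by both the test suite and the acceptance
script:

* the sphere function f(x) = -sum(x^2) (maximised; optimum 0 at the
  origin), run at the optimizers' published default parameters;
* a feature-recovery problem: d = 40 features of which 8 carry all the
  class signal (equal mean shifts of 0.6 sd per feature), the rest pure
  noise.  An optimizer "recovers" a feature when it appears in the final
  top-8 mask.

The recovery runs use the smooth wrapper critic (mean predicted
probability of the true class) and exploration-oriented optimizer
settings; both choices are documented in the methods note.
"""

from __future__ import annotations

import numpy as np

from .swarm import SwarmFeatureSelector

__all__ = ["sphere", "make_recovery_problem", "RECOVERY_SETTINGS",
           "recovery_trial"]


def sphere(x: np.ndarray) -> float:
    return -float(np.sum(np.asarray(x) ** 2))


def make_recovery_problem(seed: int, n: int = 500, d: int = 40,
                          n_informative: int = 8, effect: float = 0.6):
    """Two balanced classes; ``n_informative`` features shifted by
    ``±effect``; returns (X, y, informative_indices)."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, d))
    info = rng.choice(d, n_informative, replace=False)
    X[:, info] += (2 * y[:, None] - 1) * effect
    return X, y, np.sort(info)


# Exploration-oriented settings for subset search (the sphere defaults
# favour fast contraction; top-m mask search needs sustained diversity).
RECOVERY_SETTINGS: dict[str, dict] = {
    "pso": {"generations": 30, "population": 30,
            "optimizer_params": {"inertia": 0.9}},
    "cso": {"generations": 120, "population": 20},
    "ba": {"generations": 60, "population": 30,
           "optimizer_params": {"local_step": 0.2, "f_max": 0.5,
                                "loudness_decay": 0.97,
                                "loudness_min": 0.5}},
}


def recovery_trial(method: str, seed: int) -> int:
    """Run one seeded recovery trial; returns #informative recovered."""
    X, y, info = make_recovery_problem(seed)
    sel = SwarmFeatureSelector(
        method, n_selected=8, fitness_epochs=5, fitness_hidden=(8,),
        fitness_learning_rate=0.02, fitness_scoring="soft",
        random_state=seed, **RECOVERY_SETTINGS[method]).fit(X, y)
    return len(set(info.tolist()) & set(np.flatnonzero(sel.mask_).tolist()))
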