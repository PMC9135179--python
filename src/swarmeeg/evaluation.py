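"""Problem composition, stratified 10-fold cross-validation, and metrics.

Classification problems follow the study's naming: a string like "ACD-E"
pools sets A, C and D as the negative class against set E (ictal-like) as
the positive class; "schizophrenia" is healthy vs schizophrenia.  Metrics
per fold come from the confusion counts; the good detection rate (GDR) is
reported as sensitivity (the fraction of true events detected) and the
error rate as 100 - accuracy.  Aggregates are unweighted means over folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .pipeline import SASDLClassifier
from .rbatq import RBATQClassifier
from .synthetic import EEGSegmentSet

__all__ = ["ProblemSpec", "ConfusionCounts", "CVReport", "compose_problem",
           "kfold_split", "confusion_metrics", "run_cv", "PIPELINES"]

_VALID_NEGATIVE = set("ABCD")


@dataclass(frozen=True)
class ProblemSpec:
    """A binary problem: union of negative pools vs one positive pool."""

    negative_sets: tuple[str, ...]
    positive_set: str
    name: str

    @classmethod
    def parse(cls, name: str) -> "ProblemSpec":
        if name == "schizophrenia":
            return cls(("healthy",), "schizophrenia", name)
        try:
            neg, pos = name.split("-")
        except ValueError:
            raise ValueError(
                f"unknown problem {name!r}; expected e.g. 'A-E', 'ABCD-E' "
                "or 'schizophrenia'") from None
        if pos != "E" or not neg or not set(neg) <= _VALID_NEGATIVE \
                or len(set(neg)) != len(neg):
            raise ValueError(
                f"unknown problem {name!r}; negatives must be distinct "
                "letters from A-D and the positive set is E")
        return cls(tuple(neg), pos, name)


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(tp=int(np.sum((y_true == 1) & (y_pred == 1))),
                   tn=int(np.sum((y_true == 0) & (y_pred == 0))),
                   fp=int(np.sum((y_true == 0) & (y_pred == 1))),
                   fn=int(np.sum((y_true == 1) & (y_pred == 0))))

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, accuracy, GDR and error rate in percent.

    Degenerate denominators yield ``None`` for the affected metric rather
    than propagating NaN.
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    sens = 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn else None
    spec = 100.0 * c.tn / (c.tn + c.fp) if c.tn + c.fp else None
    acc = 100.0 * (c.tp + c.tn) / c.total
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc,
            "gdr": sens, "error_rate": 100.0 - acc}


def compose_problem(pools: dict[str, EEGSegmentSet],
                    spec: ProblemSpec | str) -> EEGSegmentSet:
    """Union the named pools into a labelled binary segment set."""
    if isinstance(spec, str):
        spec = ProblemSpec.parse(spec)
    names = [*spec.negative_sets, spec.positive_set]
    if len(set(names)) != len(names):
        raise ValueError(f"{spec.name}: pools must be disjoint")
    missing = [n for n in names if n not in pools]
    if missing:
        raise ValueError(f"{spec.name}: missing pools {missing}")
    segments, labels, provenance = [], [], []
    for name in names:
        pool = pools[name]
        segments.append(pool.segments)
        label = int(name == spec.positive_set)
        labels.append(np.full(len(pool), label))
        provenance.extend([name] * len(pool))
    return EEGSegmentSet(np.concatenate(segments), np.concatenate(labels),
                         pools[names[0]].channel_count,
                         meta={"problem": spec.name,
                               "source_sets": provenance})


def kfold_split(n: int, k: int, labels, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment: array of fold ids in [0, k)."""
    labels = np.asarray(labels)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    # stratification needs at least k members per class; below that
    # (e.g. singleton folds) fall back to a plain shuffled partition
    if k <= np.bincount(np.unique(labels, return_inverse=True)[1]).min():
        splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                   random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(n),
                                                        labels)):
        assignment[test_idx] = fold
    return assignment


@dataclass
class CVReport:
    """Cross-validation outcome: per-fold counts plus aggregate metrics."""

    pipeline: str
    problem: str
    k: int
    seed: int
    fold_counts: list[ConfusionCounts]
    config: dict = field(default_factory=dict)

    @property
    def fold_metrics(self) -> list[dict]:
        return [confusion_metrics(c) for c in self.fold_counts]

    def aggregate(self) -> dict:
        """Unweighted mean over folds (None-valued metrics excluded)."""
        out = {}
        for key in ("sensitivity", "specificity", "accuracy", "gdr",
                    "error_rate"):
            vals = [m[key] for m in self.fold_metrics if m[key] is not None]
            out[key] = float(np.mean(vals)) if vals else None
        return out

    def to_dict(self) -> dict:
        return {"pipeline": self.pipeline, "problem": self.problem,
                "k": self.k, "seed": self.seed,
                "fold_counts": [vars(c) for c in self.fold_counts],
                "fold_metrics": self.fold_metrics,
                "aggregate": self.aggregate(), "config": self.config}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _make_estimator(pipeline: str, seed: int, params: dict | None):
    params = dict(params or {})
    if pipeline == "sae_dnn":
        return SASDLClassifier(selection=None, random_state=seed, **params)
    if pipeline in ("sasdl_pso", "sasdl_cso", "sasdl_ba"):
        return SASDLClassifier(selection=pipeline.split("_")[1],
                               random_state=seed, **params)
    if pipeline == "rbatq":
        return RBATQClassifier(random_state=seed, **params)
    raise ValueError(f"unknown pipeline {pipeline!r}; choose from "
                     f"{sorted(PIPELINES)}")


PIPELINES = ("sae_dnn", "sasdl_pso", "sasdl_cso", "sasdl_ba", "rbatq")


def run_cv(pipeline: str, data: EEGSegmentSet, k: int = 10, seed: int = 0,
           estimator_params: dict | None = None,
           problem: str = "synthetic") -> CVReport:
    """Stratified k-fold evaluation of one pipeline on a segment set.

    Every fitted component (autoencoder, selector, classifier, state
    builders, agent) sees only the training folds; the held-out fold is
    used exclusively for the confusion counts.
    """
    y = data.labels
    if len(np.unique(y)) < 2:
        raise ValueError("data must contain both classes")
    X = data.flat
    assignment = kfold_split(len(y), k, y, seed)
    fold_counts = []
    for fold in range(k):
        test = assignment == fold
        est = _make_estimator(pipeline, seed, estimator_params)
        est.fit(X[~test], y[~test])
        pred = est.predict(X[test])
        fold_counts.append(ConfusionCounts.from_predictions(y[test], pred))
    return CVReport(pipeline, problem, k, seed, fold_counts,
                    config={"estimator_params": estimator_params or {},
                            "n_segments": int(len(y))})
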