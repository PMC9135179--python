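"""Softmax deep neural network classifier closing the SASDL pipeline.

Two ReLU hidden layers (full-scale sizes 2250 and 500) and a 2-unit
softmax output; cross-entropy plus weight decay minimised with Adam;
dropout between the fully connected layers.  The last ``fine_tune_epochs``
epochs update only the softmax head's parameters (hidden layers frozen),
the reading of "fine tuning on the last 20 iterations".
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._autodiff import Adam, constant, parameter, softmax_cross_entropy

__all__ = ["SoftmaxDNNClassifier", "train_dnn", "predict"]


class SoftmaxDNNClassifier(ClassifierMixin, BaseEstimator):
    """Feed-forward softmax classifier (sklearn estimator).

    Parameters
    ----------
    hidden_sizes : tuple of int
        Hidden layer widths; the full-scale configuration is (2250, 500).
    dropout : float in [0, 1)
        Dropout rate applied after each hidden layer during training.
    weight_decay : float
        L2 penalty on all weight matrices added to the cross-entropy.
    epochs, fine_tune_epochs, batch_size, learning_rate
        Adam schedule; during the final ``fine_tune_epochs`` only the
        softmax output layer is updated.
    """

    def __init__(self, hidden_sizes=(2250, 500), dropout=0.5,
                 weight_decay=1e-4, epochs=50, fine_tune_epochs=20,
                 batch_size=10, learning_rate=1e-3, random_state=0):
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.fine_tune_epochs = fine_tune_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _forward(self, X, rng=None):
        """Logits tensor; dropout applied only when ``rng`` is given."""
        h = constant(X)
        for i, (w, b) in enumerate(zip(self.weights_, self.biases_)):
            h = h @ w + b
            if i < len(self.weights_) - 1:
                h = h.relu()
                if rng is not None and self.dropout > 0:
                    keep = 1.0 - self.dropout
                    mask = rng.random(h.shape) < keep
                    h = h * constant(mask / keep)
        return h

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        counts = np.bincount(y_idx)
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per class")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.fine_tune_epochs > self.epochs:
            raise ValueError("fine_tune_epochs must not exceed epochs")
        rng = np.random.default_rng(self.random_state)
        sizes = [X.shape[1], *self.hidden_sizes, len(self.classes_)]
        self.weights_, self.biases_ = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            self.weights_.append(parameter(
                rng.standard_normal((fan_in, fan_out)) *
                np.sqrt(2.0 / fan_in)))
            self.biases_.append(parameter(np.zeros(fan_out)))
        all_params = self.weights_ + self.biases_
        head_params = [self.weights_[-1], self.biases_[-1]]
        opt = Adam(all_params, lr=self.learning_rate)
        opt_head = Adam(head_params, lr=self.learning_rate)
        n = X.shape[0]
        bs = min(self.batch_size, n)
        trace = []
        for epoch in range(self.epochs):
            fine_tuning = epoch >= self.epochs - self.fine_tune_epochs
            optimizer = opt_head if fine_tuning else opt
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                optimizer.zero_grad()
                logits = self._forward(X[idx], rng=rng)
                loss = softmax_cross_entropy(logits, y_idx[idx])
                if self.weight_decay > 0:
                    wd = None
                    for w in (head_params[:1] if fine_tuning
                              else self.weights_):
                        s = w.square().sum()
                        wd = s if wd is None else wd + s
                    loss = loss + wd * (self.weight_decay / 2.0)
                if not np.isfinite(loss.value):
                    raise RuntimeError(f"non-finite loss at epoch {epoch}")
                loss.backward()
                optimizer.step()
                epoch_loss += float(loss.value) * len(idx)
            trace.append(epoch_loss / n)
        self.loss_trace_ = np.array(trace)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature width mismatch")
        logits = self._forward(X).value
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        # np.argmax breaks ties toward the lower class index
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def train_dnn(features, labels, **kwargs) -> SoftmaxDNNClassifier:
    return SoftmaxDNNClassifier(**kwargs).fit(features, labels)


def predict(model: SoftmaxDNNClassifier, features):
    """Return (probabilities, labels) for a trained model."""
    proba = model.predict_proba(features)
    return proba, model.classes_[np.argmax(proba, axis=1)]
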