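"""SASDL: sparse autoencoder -> swarm feature selection -> softmax DNN.

The training flow fits the sparse autoencoder on the training segments,
encodes them to bottleneck features, selects a fixed-size subset of
bottleneck units with a swarm optimizer (wrapper fitness), and trains the
softmax DNN on the selected features.  Testing encodes with the trained
autoencoder, applies the same mask, and classifies.  Full-scale widths:
9000-unit bottleneck, 4500 selected features, hidden layers 2250 and 500.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .autoencoder import SparseAutoencoder
from .classifier import SoftmaxDNNClassifier
from .swarm import SwarmFeatureSelector
from .synthetic import zscore_segments

__all__ = ["SASDLClassifier"]


class SASDLClassifier(ClassifierMixin, BaseEstimator):
    """End-to-end SASDL classifier (sklearn estimator).

    Parameters
    ----------
    selection : {"pso", "cso", "ba", None}
        Swarm optimizer for feature selection; ``None`` skips selection
        (the plain SAE + DNN baseline).
    sae_params, selector_params, dnn_params : dict
        Keyword overrides forwarded to :class:`SparseAutoencoder`,
        :class:`SwarmFeatureSelector` and :class:`SoftmaxDNNClassifier`.
    normalize : bool
        Apply per-segment z-scoring before the autoencoder.
    """

    def __init__(self, selection="pso", sae_params=None, selector_params=None,
                 dnn_params=None, normalize=True, random_state=0):
        self.selection = selection
        self.sae_params = sae_params
        self.selector_params = selector_params
        self.dnn_params = dnn_params
        self.normalize = normalize
        self.random_state = random_state

    def _prep(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return zscore_segments(X) if self.normalize else X

    def fit(self, X, y):
        X = self._prep(X)
        y = np.asarray(y)
        self.sae_ = SparseAutoencoder(random_state=self.random_state,
                                      **(self.sae_params or {}))
        self.sae_.fit(X)
        features = self.sae_.transform(X)
        if self.selection is not None:
            self.selector_ = SwarmFeatureSelector(
                method=self.selection, random_state=self.random_state,
                **(self.selector_params or {}))
            self.selector_.fit(features, y)
            features = self.selector_.transform(features)
        else:
            self.selector_ = None
        self.dnn_ = SoftmaxDNNClassifier(random_state=self.random_state,
                                         **(self.dnn_params or {}))
        self.dnn_.fit(features, y)
        self.classes_ = self.dnn_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def _features(self, X) -> np.ndarray:
        check_is_fitted(self, "dnn_")
        features = self.sae_.transform(self._prep(X))
        if self.selector_ is not None:
            features = self.selector_.transform(features)
        return features

    def predict(self, X) -> np.ndarray:
        return self.dnn_.predict(self._features(X))

    def predict_proba(self, X) -> np.ndarray:
        return self.dnn_.predict_proba(self._features(X))
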