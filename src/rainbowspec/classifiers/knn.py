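"""k-nearest-neighbors classification with Euclidean distances."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from ..errors import InvalidParameterError
from .dummy import dummy_code


class KNNClassifier:
    """Majority vote over the k nearest training samples.

    Neighbor order is deterministic: ties in distance resolve by training
    index; ties in the vote resolve to the first class in sorted order.
    """

    def __init__(self, k: int = 1):
        if k < 1:
            raise InvalidParameterError(f"k must be >= 1, got {k}")
        self.k = k
        self.X_ = None
        self.y_ = None
        self.class_order_ = None

    def fit(self, X, y):
        self.X_ = np.atleast_2d(np.asarray(X, dtype=float))
        self.y_ = np.asarray(y)
        _, self.class_order_ = dummy_code(self.y_)
        if self.k > len(self.y_):
            raise InvalidParameterError(
                f"k={self.k} exceeds the number of training samples {len(self.y_)}"
            )
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        dist = cdist(X, self.X_)
        # stable sort => equal distances keep training-index order
        order = np.argsort(dist, axis=1, kind="stable")[:, : self.k]
        return np.array([self._vote(row) for row in order], dtype=object)

    def _vote(self, neighbor_idx):
        votes = self.y_[neighbor_idx]
        counts = [np.sum(votes == c) for c in self.class_order_]
        return self.class_order_[int(np.argmax(counts))]
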