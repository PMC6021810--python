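"""Soft-margin SVM with the Pearson VII universal kernel (binary only)."""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVC

from ..errors import InvalidParameterError, UnsupportedConfigurationError
from .dummy import dummy_code
from .kernels import puk_kernel


class SVMClassifier:
    """Binary kernel SVM; the Gram matrix is precomputed with the PUK kernel."""

    def __init__(self, C: float = 1.0, sigma: float = 1.0, omega: float = 1.0):
        if C <= 0:
            raise InvalidParameterError(f"C must be positive, got {C}")
        self.C = C
        self.sigma = sigma
        self.omega = omega
        self.X_ = None
        self.class_order_ = None
        self._svc = None

    def _gram(self, A, B):
        return puk_kernel(A, B, sigma=self.sigma, omega=self.omega)

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        _, class_order = dummy_code(y)
        if len(class_order) != 2:
            raise UnsupportedConfigurationError(
                f"SVM supports exactly two classes, got {len(class_order)}"
            )
        self.X_ = X
        self.class_order_ = class_order
        codes = np.array([class_order.index(lab) for lab in y])
        self._svc = SVC(C=self.C, kernel="precomputed")
        self._svc.fit(self._gram(X, X), codes)
        return self

    def decision_function(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._svc.decision_function(self._gram(X, self.X_))

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        codes = self._svc.predict(self._gram(X, self.X_))
        return np.array([self.class_order_[c] for c in codes], dtype=object)
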