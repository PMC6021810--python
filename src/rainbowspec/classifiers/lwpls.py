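"""Locally weighted PLS classification (just-in-time modelling).

For every query a fresh PLS-DA model is fitted with training samples
weighted by their similarity to the query: omega_n = exp(-d_n / (phi * s_d)),
where d_n are Euclidean query-to-sample distances and s_d their standard
deviation.  Small phi concentrates the model on close neighbors; as phi
grows the weights flatten and the prediction converges to global PLS-DA.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..errors import InvalidParameterError
from .dummy import decode, dummy_code
from .pls import nipals


def similarity_weights(distances, phi: float) -> np.ndarray:
    """Exponentially decaying sample weights from query distances."""
    if phi <= 0:
        raise InvalidParameterError(f"phi must be positive, got {phi}")
    d = np.asarray(distances, dtype=float)
    s = d.std()
    if s == 0:  # all samples equidistant: no locality information
        return np.ones_like(d)
    return np.exp(-d / (phi * s))


def _weighted_pls_score_path(X, Y, query, weights, n_lv):
    """Continuous predictions for the query at every LV count 1..n_lv.

    Weighted centering plus sqrt-weight row scaling turns the weighted
    covariance maximization into a standard NIPALS run.
    Returns an (n_lv_extracted, C) array.
    """
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0 or not np.all(np.isfinite(w)):
        warnings.warn("all sample weights vanished; falling back to uniform weights",
                      stacklevel=2)
        w = np.ones_like(w)
    wn = w / w.sum()
    x_mean = wn @ X
    y_mean = wn @ Y
    sw = np.sqrt(w)[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate local blocks are expected
        W, P, Q, T = nipals((X - x_mean) * sw, (Y - y_mean) * sw, n_lv)
    a_max = W.shape[1]
    qc = np.asarray(query, dtype=float) - x_mean
    if a_max == 0:
        # weighted X block is numerically zero (e.g. one dominant neighbor):
        # the local model collapses to the weighted class means
        return y_mean[None, :].copy()
    out = np.zeros((a_max, Y.shape[1]))
    for a in range(1, a_max + 1):
        Wa, Pa, Qa = W[:, :a], P[:, :a], Q[:, :a]
        B = Wa @ np.linalg.solve(Pa.T @ Wa, Qa.T)
        out[a - 1] = qc @ B + y_mean
    return out


def lwplsc_predict(X, Y, query, phi: float, n_lv: int, class_order=None):
    """Predict one query just-in-time; returns ``(scores, label)``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] < 2:
        raise InvalidParameterError("need at least two training samples")
    query = np.asarray(query, dtype=float).ravel()
    d = np.linalg.norm(X - query, axis=1)
    w = similarity_weights(d, phi)
    path = _weighted_pls_score_path(X, Y, query, w, n_lv)
    scores = path[-1]
    if class_order is None:
        class_order = [str(j) for j in range(Y.shape[1])]
    label = decode(scores[None, :], class_order)[0]
    return scores, label


class LWPLSClassifier:
    """fit/predict wrapper fitting one weighted PLS-DA model per query."""

    def __init__(self, n_lv: int = 2, phi: float = 1.0):
        if phi <= 0:
            raise InvalidParameterError(f"phi must be positive, got {phi}")
        self.n_lv = n_lv
        self.phi = phi
        self.X_ = None
        self.Y_ = None
        self.class_order_ = None

    def fit(self, X, y):
        self.X_ = np.atleast_2d(np.asarray(X, dtype=float))
        self.Y_, self.class_order_ = dummy_code(y)
        return self

    def predict_scores(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([
            lwplsc_predict(self.X_, self.Y_, q, self.phi, self.n_lv,
                           self.class_order_)[0]
            for q in X
        ])

    def predict(self, X):
        return decode(self.predict_scores(X), self.class_order_)
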