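"""Partial least squares discriminant analysis (NIPALS, PLS2).

Latent variables are extracted greedily: each weight vector maximizes the
covariance between the X-score and the Y-score, and both blocks are then
deflated by the rank-one approximation built from the X-score, which makes
successive score vectors mutually orthogonal.  Classification decodes the
continuous dummy-coded predictions by argmax.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidInputError, InvalidParameterError
from .dummy import decode, dummy_code

_EPS = np.finfo(float).eps


def nipals(Xc, Yc, n_lv: int, tol: float = 1e-12, max_iter: int = 500):
    """Extract up to ``n_lv`` components from centered blocks.

    Returns ``(W, P, Q, T)``: X-weights (p x A), X-loadings (p x A),
    Y-loadings (C x A) and X-scores (n x A).  Stops early, with a warning,
    if a block deflates to numerical zero before ``n_lv`` components.
    """
    X = np.array(Xc, dtype=float)
    Y = np.array(Yc, dtype=float)
    n, p = X.shape
    C = Y.shape[1]
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((C, n_lv))
    T = np.zeros((n, n_lv))
    x_scale = np.linalg.norm(Xc) + _EPS
    extracted = 0
    for a in range(n_lv):
        if np.linalg.norm(X) < 1e-10 * x_scale:
            warnings.warn(
                f"X block exhausted after {extracted} components (requested {n_lv})",
                stacklevel=2,
            )
            break
        u = Y[:, int(np.argmax(Y.var(axis=0)))]
        if np.linalg.norm(u) < _EPS:
            u = X @ X.sum(axis=0)
        t = np.zeros(n)
        for _ in range(max_iter):
            w = X.T @ u
            w_norm = np.linalg.norm(w)
            if w_norm < _EPS:
                break
            w /= w_norm
            t_new = X @ w
            q = Y.T @ t_new / max(t_new @ t_new, _EPS)
            u = Y @ q / max(q @ q, _EPS)
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), _EPS):
                t = t_new
                break
            t = t_new
        tt = t @ t
        if tt < 1e-20 * x_scale**2:
            warnings.warn(
                f"degenerate score vector at component {a + 1}; stopping early",
                stacklevel=2,
            )
            break
        p_load = X.T @ t / tt
        q_load = Y.T @ t / tt
        X = X - np.outer(t, p_load)
        Y = Y - np.outer(t, q_load)
        W[:, a] = w
        P[:, a] = p_load
        Q[:, a] = q_load
        T[:, a] = t
        extracted += 1
    A = extracted
    return W[:, :A], P[:, :A], Q[:, :A], T[:, :A]


@dataclass
class PLSModel:
    """A fitted PLS-DA model (all components retained)."""

    x_mean: np.ndarray
    y_mean: np.ndarray
    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    T: np.ndarray
    class_order: list
    n_lv: int = field(default=0)

    def __post_init__(self):
        if self.n_lv == 0:
            self.n_lv = self.W.shape[1]

    def coef(self, n_lv: int | None = None) -> np.ndarray:
        """Regression coefficients B (p x C) using the first ``n_lv`` LVs."""
        a = self.n_lv if n_lv is None else min(n_lv, self.n_lv)
        Wa, Pa, Qa = self.W[:, :a], self.P[:, :a], self.Q[:, :a]
        return Wa @ np.linalg.solve(Pa.T @ Wa, Qa.T)

    def predict_scores(self, X, n_lv: int | None = None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.shape[0]:
            raise InvalidInputError(
                f"query has {X.shape[1]} features, model expects {self.x_mean.shape[0]}"
            )
        return (X - self.x_mean) @ self.coef(n_lv) + self.y_mean

    def predict(self, X, n_lv: int | None = None) -> np.ndarray:
        return decode(self.predict_scores(X, n_lv), self.class_order)

    def to_json(self, path=None) -> str:
        payload = {
            "model": "plsda",
            "n_lv": int(self.n_lv),
            "class_order": list(self.class_order),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean.tolist(),
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "Q": self.Q.tolist(),
            "T": self.T.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PLSModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            x_mean=np.array(payload["x_mean"]),
            y_mean=np.array(payload["y_mean"]),
            W=np.array(payload["W"]),
            P=np.array(payload["P"]),
            Q=np.array(payload["Q"]),
            T=np.array(payload["T"]),
            class_order=payload["class_order"],
            n_lv=payload["n_lv"],
        )


def pls_fit(X, Y, n_lv: int, class_order=None) -> PLSModel:
    """Fit a PLS2 model on raw X and dummy-coded Y (centering is internal)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = X.shape
    if n < 2:
        raise InvalidInputError("need at least two training samples")
    max_lv = min(n - 1, p)
    if n_lv < 1:
        raise InvalidParameterError(f"n_lv must be >= 1, got {n_lv}")
    if n_lv > max_lv:
        warnings.warn(
            f"n_lv={n_lv} exceeds min(n-1, p)={max_lv}; reduced", stacklevel=2
        )
        n_lv = max_lv
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    W, P, Q, T = nipals(X - x_mean, Y - y_mean, n_lv)
    if class_order is None:
        class_order = [str(j) for j in range(Y.shape[1])]
    return PLSModel(x_mean, y_mean, W, P, Q, T, list(class_order))


class PLSDAClassifier:
    """fit/predict wrapper: labels -> dummy code -> PLS2 -> argmax."""

    def __init__(self, n_lv: int = 2):
        self.n_lv = n_lv
        self.model_: PLSModel | None = None

    def fit(self, X, y):
        Y, class_order = dummy_code(y)
        self.model_ = pls_fit(X, Y, self.n_lv, class_order)
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def predict_scores(self, X, n_lv: int | None = None):
        return self.model_.predict_scores(X, n_lv)
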