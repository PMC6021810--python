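"""Kernel PLS-DA in dual form.

The data are mapped into a kernel-induced feature space through the Gram
matrix, which is double-centered on the training samples; kernel NIPALS
then extracts score vectors, and prediction centers the test-versus-train
kernel rows consistently before applying the dual regression coefficients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidInputError, InvalidParameterError
from .dummy import decode, dummy_code
from .kernels import gaussian_kernel, linear_kernel

_EPS = np.finfo(float).eps

KERNELS = ("gaussian", "linear")


def _kernel(name, A, B, sigma):
    if name == "gaussian":
        return gaussian_kernel(A, B, sigma)
    if name == "linear":
        return linear_kernel(A, B)
    raise InvalidParameterError(f"unknown kernel {name!r}")


def kernel_nipals(Kc, Yc, n_lv: int, tol: float = 1e-12, max_iter: int = 500):
    """Dual NIPALS on a double-centered Gram matrix.

    Returns ``(T, U)`` with unit-norm X-scores; stops early with a warning
    when the residual blocks vanish.
    """
    K = np.array(Kc, dtype=float)
    Y = np.array(Yc, dtype=float)
    n = K.shape[0]
    T = np.zeros((n, n_lv))
    U = np.zeros((n, n_lv))
    k_scale = np.linalg.norm(Kc) + _EPS
    extracted = 0
    for a in range(n_lv):
        if np.linalg.norm(K) < 1e-12 * k_scale or np.linalg.norm(Y) < 1e-12:
            warnings.warn(
                f"kernel block exhausted after {extracted} components (requested {n_lv})",
                stacklevel=2,
            )
            break
        u = Y[:, int(np.argmax(Y.var(axis=0)))]
        if np.linalg.norm(u) < _EPS:
            u = K.sum(axis=1)
        t = np.zeros(n)
        for _ in range(max_iter):
            t_new = K @ u
            norm = np.linalg.norm(t_new)
            if norm < _EPS:
                break
            t_new /= norm
            c = Y.T @ t_new
            u = Y @ c
            u_norm = np.linalg.norm(u)
            if u_norm < _EPS:
                break
            u /= u_norm
            if np.linalg.norm(t_new - t) <= tol:
                t = t_new
                break
            t = t_new
        if np.linalg.norm(t) < _EPS:
            warnings.warn(
                f"degenerate dual score at component {a + 1}; stopping early",
                stacklevel=2,
            )
            break
        # rank-one double deflation: K <- (I - tt') K (I - tt')
        Kt = K @ t
        tKt = t @ Kt
        K = K - np.outer(t, Kt) - np.outer(Kt, t) + tKt * np.outer(t, t)
        Y = Y - np.outer(t, t @ Y)
        T[:, a] = t
        U[:, a] = u
        extracted += 1
    return T[:, :extracted], U[:, :extracted]


@dataclass
class KernelPLSModel:
    """A fitted kernel PLS-DA model in dual form."""

    X_train: np.ndarray
    K: np.ndarray  # uncentered training Gram
    y_mean: np.ndarray
    Yc: np.ndarray
    T: np.ndarray
    U: np.ndarray
    class_order: list
    kernel: str = "gaussian"
    sigma: float = 1.0
    n_lv: int = field(default=0)

    def __post_init__(self):
        if self.n_lv == 0:
            self.n_lv = self.T.shape[1]

    @property
    def Kc(self) -> np.ndarray:
        n = self.K.shape[0]
        H = np.eye(n) - np.full((n, n), 1.0 / n)
        return H @ self.K @ H

    def dual_coef(self, n_lv: int | None = None) -> np.ndarray:
        a = self.n_lv if n_lv is None else min(n_lv, self.n_lv)
        Ta, Ua = self.T[:, :a], self.U[:, :a]
        M = Ta.T @ self.Kc @ Ua
        return Ua @ np.linalg.solve(M, Ta.T @ self.Yc)

    def _test_gram(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.X_train.shape[1]:
            raise InvalidInputError(
                f"query has {X.shape[1]} features, model expects {self.X_train.shape[1]}"
            )
        Kt = _kernel(self.kernel, X, self.X_train, self.sigma)
        n = self.K.shape[0]
        ones = np.full((X.shape[0], n), 1.0 / n)
        H = np.eye(n) - np.full((n, n), 1.0 / n)
        return (Kt - ones @ self.K) @ H

    def predict_scores(self, X, n_lv: int | None = None) -> np.ndarray:
        return self._test_gram(X) @ self.dual_coef(n_lv) + self.y_mean

    def predict(self, X, n_lv: int | None = None) -> np.ndarray:
        return decode(self.predict_scores(X, n_lv), self.class_order)

    def to_json(self, path=None) -> str:
        payload = {
            "model": "kplsda",
            "kernel": self.kernel,
            "sigma": self.sigma,
            "n_lv": int(self.n_lv),
            "class_order": list(self.class_order),
            "X_train": self.X_train.tolist(),
            "K": self.K.tolist(),
            "y_mean": self.y_mean.tolist(),
            "Yc": self.Yc.tolist(),
            "T": self.T.tolist(),
            "U": self.U.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "KernelPLSModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            X_train=np.array(payload["X_train"]),
            K=np.array(payload["K"]),
            y_mean=np.array(payload["y_mean"]),
            Yc=np.array(payload["Yc"]),
            T=np.array(payload["T"]),
            U=np.array(payload["U"]),
            class_order=payload["class_order"],
            kernel=payload["kernel"],
            sigma=payload["sigma"],
            n_lv=payload["n_lv"],
        )


def kpls_fit(X, Y, n_lv: int, sigma: float = 1.0, kernel: str = "gaussian",
             class_order=None) -> KernelPLSModel:
    """Fit kernel PLS on raw X and dummy-coded Y."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise InvalidInputError("need at least two training samples")
    if n_lv < 1:
        raise InvalidParameterError(f"n_lv must be >= 1, got {n_lv}")
    if n_lv > n - 1:
        warnings.warn(f"n_lv={n_lv} exceeds n-1={n - 1}; reduced", stacklevel=2)
        n_lv = n - 1
    K = _kernel(kernel, X, X, sigma)
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    Kc = H @ K @ H
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    T, U = kernel_nipals(Kc, Yc, n_lv)
    if class_order is None:
        class_order = [str(j) for j in range(Y.shape[1])]
    return KernelPLSModel(X, K, y_mean, Yc, T, U, list(class_order), kernel, sigma)


class KPLSDAClassifier:
    """fit/predict wrapper around :func:`kpls_fit`."""

    def __init__(self, n_lv: int = 2, sigma: float = 1.0, kernel: str = "gaussian"):
        self.n_lv = n_lv
        self.sigma = sigma
        self.kernel = kernel
        self.model_: KernelPLSModel | None = None

    def fit(self, X, y):
        Y, class_order = dummy_code(y)
        self.model_ = kpls_fit(X, Y, self.n_lv, self.sigma, self.kernel, class_order)
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def predict_scores(self, X, n_lv: int | None = None):
        return self.model_.predict_scores(X, n_lv)
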