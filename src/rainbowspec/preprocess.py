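"""Row-wise pre-processing of feature matrices.

The default method is Savitzky-Golay smoothing (degree 2, 33-point
window); standard normal variate, min-max and area normalization, and
polynomial baseline correction are available as alternatives.  Every
transform is fitted and applied per row, so no statistics leak between
training and test sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateInputError, InvalidParameterError
from .features import FeatureMatrix

SAVGOL_WINDOW = 33
SAVGOL_DEGREE = 2

NORMALIZE_MODES = ("snv", "minmax", "area")
METHODS = ("none", "savgol", "snv", "minmax", "area", "baseline")


@dataclass(frozen=True)
class SmootherConfig:
    window: int = SAVGOL_WINDOW
    degree: int = SAVGOL_DEGREE

    def __post_init__(self):
        if self.window % 2 == 0 or self.window < 1:
            raise InvalidParameterError(f"window must be odd and >= 1, got {self.window}")
        if self.degree >= self.window:
            raise InvalidParameterError("polynomial degree must be smaller than the window")


def _apply(X, fn):
    """Run ``fn`` on the raw array, rewrapping a FeatureMatrix if given one."""
    if isinstance(X, FeatureMatrix):
        return X.with_X(fn(X.X))
    return fn(np.asarray(X, dtype=float))


def savgol_smooth(X, cfg: SmootherConfig | None = None):
    """Savitzky-Golay smoothing of each row.

    Edge points are served by evaluating the polynomial fitted to the
    nearest full window (scipy's ``mode='interp'``).
    """
    cfg = cfg or SmootherConfig()

    def fn(arr):
        arr = np.atleast_2d(arr)
        if cfg.window > arr.shape[1]:
            raise InvalidParameterError(
                f"window {cfg.window} exceeds vector length {arr.shape[1]}"
            )
        return savgol_filter(arr, cfg.window, cfg.degree, axis=1, mode="interp")

    return _apply(X, fn)


def normalize(X, mode: str = "snv"):
    """Per-row normalization.

    ``snv``: subtract the row mean and divide by the row standard
    deviation (ddof=1).  ``minmax``: rescale each row to [0, 1].
    ``area``: divide by the row sum so each row integrates to 1.
    """
    if mode not in NORMALIZE_MODES:
        raise InvalidParameterError(f"unknown normalization mode {mode!r}")

    def fn(arr):
        arr = np.atleast_2d(arr)
        if mode == "snv":
            sd = arr.std(axis=1, ddof=1, keepdims=True)
            if np.any(sd == 0):
                raise DegenerateInputError("zero-variance row cannot be SNV-normalized")
            return (arr - arr.mean(axis=1, keepdims=True)) / sd
        if mode == "minmax":
            lo = arr.min(axis=1, keepdims=True)
            rng = arr.max(axis=1, keepdims=True) - lo
            if np.any(rng == 0):
                raise DegenerateInputError("constant row cannot be min-max normalized")
            return (arr - lo) / rng
        total = arr.sum(axis=1, keepdims=True)
        if np.any(total == 0):
            raise DegenerateInputError("zero-sum row cannot be area-normalized")
        return arr / total

    return _apply(X, fn)


def baseline_correct(X, degree: int = 1):
    """Subtract a per-row least-squares polynomial baseline of given degree."""
    if degree < 0:
        raise InvalidParameterError(f"baseline degree must be >= 0, got {degree}")

    def fn(arr):
        arr = np.atleast_2d(arr)
        p = arr.shape[1]
        t = np.arange(p, dtype=float)
        # Vandermonde fit of all rows at once
        V = np.vander(t, degree + 1)
        coef, *_ = np.linalg.lstsq(V, arr.T, rcond=None)
        return arr - (V @ coef).T

    return _apply(X, fn)


def preprocess(X, method: str = "savgol", **kwargs):
    """Dispatch to one of the pre-processing methods by name."""
    if method not in METHODS:
        raise InvalidParameterError(f"unknown preprocessing method {method!r}")
    if method == "none":
        return _apply(X, lambda arr: np.array(arr, dtype=float, copy=True))
    if method == "savgol":
        cfg = SmootherConfig(
            window=kwargs.get("window", SAVGOL_WINDOW),
            degree=kwargs.get("degree", SAVGOL_DEGREE),
        )
        return savgol_smooth(X, cfg)
    if method == "baseline":
        return baseline_correct(X, degree=kwargs.get("degree", 1))
    return normalize(X, mode=method)
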