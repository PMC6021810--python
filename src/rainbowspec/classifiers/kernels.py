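"""Kernel functions: Gaussian (RBF) and Pearson VII universal kernel."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from ..errors import InvalidParameterError


def gaussian_kernel(A, B, sigma: float) -> np.ndarray:
    """K_ij = exp(-||a_i - b_j||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    sq = cdist(A, B, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * sigma**2))


def linear_kernel(A, B) -> np.ndarray:
    """Plain dot-product kernel, used to cross-check the dual PLS route."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    return A @ B.T


def puk_kernel(A, B, sigma: float = 1.0, omega: float = 1.0) -> np.ndarray:
    """Pearson VII universal kernel.

    k(x, y) = 1 / [1 + (2 sqrt(2^(1/omega) - 1) ||x - y|| / sigma)^2]^omega

    ``sigma`` controls the half-width and ``omega`` the Pearson tailing
    behaviour; k(x, x) = 1 for any parameters.
    """
    if sigma <= 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    if omega <= 0:
        raise InvalidParameterError(f"omega must be positive, got {omega}")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    dist = cdist(A, B, metric="euclidean")
    scale = 2.0 * np.sqrt(2.0 ** (1.0 / omega) - 1.0) / sigma
    return 1.0 / (1.0 + (scale * dist) ** 2) ** omega
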