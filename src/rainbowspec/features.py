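"""Pseudo-spectral feature extraction.

A 100x100 RGB rainbow patch is collapsed to a length-100 feature vector:
the three channels are combined per pixel as F = W1*R + W2*G + W3*B and
each row of the combined image is averaged.  Rows run along the
dispersion axis, so index position plays the role of wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError, LabelError
from .segmentation import RainbowPatch

#: Channel luminance ratios used for feature extraction (red, green, blue).
DEFAULT_CHANNEL_WEIGHTS = (0.2, 0.7, 0.1)

N_FEATURES = 100


@dataclass(frozen=True)
class ChannelWeights:
    """Luminance ratios of the red, green and blue channels."""

    w_red: float = DEFAULT_CHANNEL_WEIGHTS[0]
    w_green: float = DEFAULT_CHANNEL_WEIGHTS[1]
    w_blue: float = DEFAULT_CHANNEL_WEIGHTS[2]

    def __post_init__(self):
        w = (self.w_red, self.w_green, self.w_blue)
        if any(x < 0 for x in w) or sum(w) <= 0:
            raise InvalidParameterError(
                f"channel weights must be non-negative with positive sum, got {w}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.w_red, self.w_green, self.w_blue], dtype=float)


def _patch_pixels(patch) -> np.ndarray:
    pixels = patch.pixels if isinstance(patch, RainbowPatch) else np.asarray(patch)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise InvalidInputError(f"expected an NxNx3 patch, got shape {pixels.shape}")
    if pixels.shape[0] != pixels.shape[1]:
        raise InvalidInputError(f"patch must be square, got shape {pixels.shape}")
    return pixels.astype(float)


def combine_channels(patch, weights: ChannelWeights | tuple = DEFAULT_CHANNEL_WEIGHTS) -> np.ndarray:
    """Per-pixel weighted channel combination; no rounding is applied."""
    if not isinstance(weights, ChannelWeights):
        weights = ChannelWeights(*weights)
    pixels = _patch_pixels(patch)
    w = weights.as_array()
    return pixels[..., 0] * w[0] + pixels[..., 1] * w[1] + pixels[..., 2] * w[2]


def row_means(combined: np.ndarray) -> np.ndarray:
    """Mean of each row of the combined-intensity image."""
    combined = np.asarray(combined, dtype=float)
    if combined.ndim != 2 or combined.shape[0] != combined.shape[1]:
        raise InvalidInputError(f"expected a square 2-D matrix, got shape {combined.shape}")
    return combined.mean(axis=1)


def patch_to_vector(patch, weights=DEFAULT_CHANNEL_WEIGHTS) -> np.ndarray:
    """Full patch -> feature-vector conversion (combine then row-average)."""
    return row_means(combine_channels(patch, weights))


@dataclass
class FeatureMatrix:
    """n x p feature matrix with per-sample species and type labels.

    Serializes to CSV with columns ``sample_id, species, type, v1..vp``;
    the round trip is lossless to full float precision.
    """

    X: np.ndarray
    species: np.ndarray
    types: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.species = np.asarray(self.species, dtype=object)
        self.types = np.asarray(self.types, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n = self.X.shape[0]
        if self.X.ndim != 2:
            raise InvalidInputError("X must be 2-D")
        if not (len(self.species) == len(self.types) == len(self.sample_ids) == n):
            raise LabelError("label arrays must match the number of rows of X")
        if np.any(~np.isfinite(self.X)):
            raise InvalidInputError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def labels(self, task: str = "type") -> np.ndarray:
        if task == "type":
            return self.types
        if task == "species":
            return self.species
        raise LabelError(f"unknown label task {task!r}")

    def with_X(self, X: np.ndarray) -> "FeatureMatrix":
        """Copy with a replaced data block, labels unchanged."""
        return FeatureMatrix(X, self.species.copy(), self.types.copy(), self.sample_ids.copy())

    def subset(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.X[idx], self.species[idx], self.types[idx], self.sample_ids[idx]
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=[f"v{i + 1}" for i in range(self.n_features)])
        df.insert(0, "type", self.types)
        df.insert(0, "species", self.species)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta = ["sample_id", "species", "type"]
        missing = [c for c in meta if c not in df.columns]
        if missing:
            raise LabelError(f"feature CSV is missing columns {missing}")
        value_cols = [c for c in df.columns if c not in meta]
        return cls(
            df[value_cols].to_numpy(dtype=float),
            df["species"].to_numpy(),
            df["type"].to_numpy(),
            df["sample_id"].to_numpy(),
        )


def build_feature_matrix(
    patches,
    species,
    types,
    sample_ids=None,
    weights=DEFAULT_CHANNEL_WEIGHTS,
) -> FeatureMatrix:
    """Stack per-patch feature vectors into a labelled matrix, preserving order."""
    patches = list(patches)
    if not patches:
        raise InvalidInputError("need at least one patch")
    species = list(species)
    types = list(types)
    if len(species) != len(patches) or len(types) != len(patches):
        raise LabelError("every patch needs a species and a type label")
    if any(s is None for s in species) or any(t is None for t in types):
        raise LabelError("labels must not be None")
    if sample_ids is None:
        sample_ids = [f"sample_{i:04d}" for i in range(len(patches))]
    X = np.vstack([patch_to_vector(p, weights) for p in patches])
    return FeatureMatrix(X, np.array(species, dtype=object), np.array(types, dtype=object),
                         np.array(list(sample_ids), dtype=object))
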