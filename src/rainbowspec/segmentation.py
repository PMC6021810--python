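"""Rainbow-patch segmentation.

Extracts a single standardized 100x100 RGB patch from a photograph of a
diffraction rainbow on a dark background.  The pipeline is: grayscale
conversion, median-filter denoising, Otsu thresholding on the gray
histogram, an optional HSV saturation gate, morphological clean-up,
largest-connected-component selection, and bilinear resampling of the
RGB bounding-box crop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, transform
from skimage.color import rgb2hsv

from .errors import (
    DegenerateInputError,
    InvalidInputError,
    InvalidParameterError,
    SegmentationError,
)

#: Standard luminance weights used for the segmentation grayscale step.
#: The feature-extraction stage uses its own channel weights.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)

PATCH_SIZE = 100


@dataclass(frozen=True)
class SegmentationConfig:
    """Settings for :func:`extract_rainbow`."""

    gray_weights: tuple = LUMINANCE_WEIGHTS
    median_window: int = 3
    saturation_min: float | None = 0.15  # None disables the HSV gate
    morph_radius: int = 1
    patch_size: int = PATCH_SIZE


@dataclass(frozen=True)
class OtsuResult:
    """Threshold search result over all 256 candidate gray levels.

    ``criterion[T]`` is the between-class variance g(T); candidates with an
    empty class are recorded as 0.  Class statistics are reported at the
    optimum: ``omega1``/``omega2`` are the class probabilities,
    ``mu1``/``mu2`` the class mean gray levels and ``mu`` the global mean.
    """

    threshold: int
    criterion: np.ndarray
    omega1: float
    omega2: float
    mu1: float
    mu2: float
    mu: float


@dataclass(frozen=True)
class RainbowPatch:
    """A standardized crop of one extracted rainbow.

    ``pixels`` is always ``patch_size x patch_size x 3`` uint8; rows run
    along the dispersion (long) axis of the detected component.
    """

    pixels: np.ndarray
    source_bbox: tuple  # (min_row, min_col, max_row, max_col) in the input
    rotated: bool = field(default=False)


def _check_rgb(img) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError(f"expected HxWx3 RGB image, got shape {img.shape}")
    return img


def to_grayscale(img, weights=LUMINANCE_WEIGHTS) -> np.ndarray:
    """Weighted RGB -> gray conversion, rounded and clipped to [0, 255].

    ``weights`` must be non-negative and sum to a positive value; they are
    used as given (not renormalized), so weights summing to 1 keep the
    gray image inside the input range.
    """
    img = _check_rgb(img)
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or np.any(w < 0) or w.sum() <= 0:
        raise InvalidParameterError(
            "grayscale weights must be three non-negative values with positive sum"
        )
    gray = img[..., 0] * w[0] + img[..., 1] * w[1] + img[..., 2] * w[2]
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def median_filter(img, window: int = 3) -> np.ndarray:
    """Square-window median filter with reflect padding at the edges."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise InvalidInputError(f"expected a 2-D gray image, got shape {img.shape}")
    if window < 1 or window % 2 == 0:
        raise InvalidParameterError(f"median window must be odd and >= 1, got {window}")
    return ndimage.median_filter(img, size=window, mode="reflect")


def gray_histogram(img) -> np.ndarray:
    """Normalized 256-bin gray-level histogram p, with sum(p) == 1."""
    img = np.asarray(img)
    if img.size == 0:
        raise InvalidInputError("cannot build a histogram of an empty image")
    counts = np.bincount(img.ravel().astype(np.int64), minlength=256)[:256]
    return counts / counts.sum()


def otsu_criterion(hist, decomposed: bool = False) -> np.ndarray:
    """Between-class variance g(T) for every candidate threshold T in 0..255.

    Class 1 collects levels <= T, class 2 levels > T; thresholds leaving
    either class empty get g = 0.  ``decomposed=False`` evaluates the
    product form omega1*omega2*(mu2 - mu1)^2; ``decomposed=True`` evaluates
    the equivalent sum of the classes' squared deviations from the global
    mean, omega1*(mu1 - mu)^2 + omega2*(mu2 - mu)^2.
    """
    p = np.asarray(hist, dtype=float)
    if p.shape != (256,):
        raise InvalidInputError("histogram must have 256 bins")
    levels = np.arange(256, dtype=float)
    omega1 = np.cumsum(p)
    mass1 = np.cumsum(p * levels)
    mu_total = mass1[-1]
    omega2 = 1.0 - omega1
    valid = (omega1 > 0) & (omega2 > 0)
    g = np.zeros(256)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = mass1 / omega1
        mu2 = (mu_total - mass1) / omega2
    if decomposed:
        g[valid] = omega1[valid] * (mu1[valid] - mu_total) ** 2 + omega2[valid] * (
            mu2[valid] - mu_total
        ) ** 2
    else:
        g[valid] = omega1[valid] * omega2[valid] * (mu2[valid] - mu1[valid]) ** 2
    return g


def otsu_threshold(hist) -> OtsuResult:
    """Threshold maximizing the between-class variance.

    Requires at least two distinct nonzero histogram levels; ties in the
    criterion are broken toward the smallest threshold.
    """
    p = np.asarray(hist, dtype=float)
    if p.shape != (256,):
        raise InvalidInputError("histogram must have 256 bins")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise InvalidInputError("histogram must be a probability distribution")
    if np.count_nonzero(p) < 2:
        raise DegenerateInputError("histogram has fewer than two distinct levels")
    g = otsu_criterion(p)
    t = int(np.argmax(g))
    levels = np.arange(256, dtype=float)
    omega1 = float(p[: t + 1].sum())
    omega2 = 1.0 - omega1
    mu1 = float((p[: t + 1] * levels[: t + 1]).sum() / omega1)
    mu2 = float((p[t + 1 :] * levels[t + 1 :]).sum() / omega2)
    mu = float((p * levels).sum())
    return OtsuResult(t, g, omega1, omega2, mu1, mu2, mu)


def binarize(img, threshold: int) -> np.ndarray:
    """Object mask: pixels strictly greater than the threshold."""
    if not 0 <= threshold <= 255:
        raise InvalidParameterError(f"threshold must lie in [0, 255], got {threshold}")
    return np.asarray(img) > threshold


def morphological_clean(mask, radius: int = 1) -> np.ndarray:
    """Binary opening then closing with a disk element; radius 0 is identity."""
    mask = np.asarray(mask, dtype=bool)
    if radius < 0:
        raise InvalidParameterError(f"morphology radius must be >= 0, got {radius}")
    if radius == 0:
        return mask.copy()
    selem = morphology.disk(radius)
    return morphology.closing(morphology.opening(mask, selem), selem)


def saturation_mask(img, s_min: float) -> np.ndarray:
    """True where HSV saturation >= ``s_min`` (on the [0, 1] scale)."""
    img = _check_rgb(img)
    sat = rgb2hsv(img)[..., 1]
    return sat >= s_min


def extract_rainbow(img, cfg: SegmentationConfig | None = None) -> RainbowPatch:
    """Run the full segmentation pipeline and return one standardized patch.

    The largest connected component wins (ties broken by leftmost bounding
    box).  The RGB crop is rotated, if needed, so its long axis is vertical
    — rows then index the dispersion axis — and bilinearly resampled to
    ``cfg.patch_size`` squared.

    Raises :class:`SegmentationError` (with the diagnostic mask attached)
    when no component survives thresholding and clean-up.
    """
    cfg = cfg or SegmentationConfig()
    img = _check_rgb(img)
    gray = to_grayscale(img, cfg.gray_weights)
    denoised = median_filter(gray, cfg.median_window)
    try:
        otsu = otsu_threshold(gray_histogram(denoised))
    except DegenerateInputError as exc:
        raise SegmentationError(
            f"image has no gray-level contrast: {exc}", mask=np.zeros_like(denoised, bool)
        ) from exc
    mask = binarize(denoised, otsu.threshold)
    if cfg.saturation_min is not None:
        mask &= saturation_mask(img, cfg.saturation_min)
    mask = morphological_clean(mask, cfg.morph_radius)

    labels = measure.label(mask, connectivity=2)
    regions = measure.regionprops(labels)
    if not regions:
        raise SegmentationError("no connected component above threshold", mask=mask)
    # largest area first; ties toward the leftmost bounding box
    best = min(regions, key=lambda r: (-r.area, r.bbox[1]))
    minr, minc, maxr, maxc = best.bbox
    crop = img[minr:maxr, minc:maxc].astype(float)
    rotated = False
    if crop.shape[1] > crop.shape[0]:
        crop = np.rot90(crop)
        rotated = True
    size = cfg.patch_size
    resampled = transform.resize(
        crop, (size, size), order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )
    pixels = np.clip(np.rint(resampled), 0, 255).astype(np.uint8)
    return RainbowPatch(pixels, (minr, minc, maxr, maxc), rotated)
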