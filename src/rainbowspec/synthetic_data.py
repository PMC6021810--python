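"""Synthetic fixtures: rainbow photographs and structured feature matrices.

Two generators make the whole pipeline testable without external data:

* :func:`make_rainbow_image` renders a dark scene containing one or two
  smoothly color-graded elliptical patches (color dispersing along the
  vertical axis) plus optional Gaussian and salt-and-pepper noise, and
  returns pixel-level ground truth alongside.

* :func:`make_feature_population` draws an n x 100 feature matrix with
  three species groups separated by offsets in variables ~40-60 and a
  binary organic / non-organic labelling driven by a *radial* rule on two
  latent factors, so the type classes are interleaved rings that no
  linear classifier can separate.  A certificate (PLS-DA LOOCV accuracy
  below a stated ceiling) is asserted at generation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.color import hsv2rgb

from .errors import InvalidParameterError, NonlinearityCertificateError
from .features import FeatureMatrix, combine_channels, row_means

SPECIES = ("gala", "pink_lady", "braeburn")
TYPES = ("non-organic", "organic")


# ---------------------------------------------------------------------------
# rainbow scenes


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, spectral profile and noise model of one synthetic scene."""

    height: int = 240
    width: int = 320
    center: tuple = (120.0, 90.0)  # (row, col) of the primary patch
    axes: tuple = (80.0, 30.0)  # semi-axes (vertical, horizontal); long axis vertical
    bands: tuple = (  # (position in [0,1], width, amplitude above the floor)
        (0.25, 0.12, 55.0),
        (0.55, 0.18, 80.0),
        (0.8, 0.1, 45.0),
    )
    hue_range: tuple = (0.72, 0.0)  # violet at the top row -> red at the bottom
    saturation: float = 0.5  # patch color saturation (must clear the HSV gate)
    band_floor: float = 170.0  # baseline patch brightness so the full ellipse segments
    two_patches: bool = False
    noise_sd: float = 0.0
    salt_pepper: float = 0.0
    seed: int = 0

    def __post_init__(self):
        a, b = self.axes
        if a <= 0 or b <= 0:
            raise InvalidParameterError("patch semi-axes must be positive")
        if any(amp > 255 or amp < 0 for _, _, amp in self.bands):
            raise InvalidParameterError("band amplitudes must lie in [0, 255]")
        for cc in self._centers():
            r0, c0 = cc
            if r0 - a < 0 or r0 + a > self.height - 1 or c0 - b < 0 or c0 + b > self.width - 1:
                raise InvalidParameterError(
                    f"patch at {cc} with axes {self.axes} does not fit the "
                    f"{self.height}x{self.width} frame"
                )

    def _centers(self):
        centers = [self.center]
        if self.two_patches:
            centers.append((self.center[0], self.width - 1 - self.center[1]))
        return centers


@dataclass(frozen=True)
class GroundTruth:
    """Pixel-level truth for the primary (leftmost) patch."""

    mask: np.ndarray  # bool mask of the primary patch
    bbox: tuple  # (min_row, min_col, max_row, max_col), exclusive stops
    profile: np.ndarray  # expected 100-point combined-intensity row means


def _envelope(t, bands, floor=0.0):
    v = np.full_like(t, float(floor))
    for pos, width, amp in bands:
        v += amp * np.exp(-0.5 * ((t - pos) / width) ** 2)
    return np.clip(v, 0.0, 255.0)


def _render_patch(spec: SceneSpec, center) -> tuple[np.ndarray, np.ndarray]:
    """Clean float RGB image of one patch and its boolean mask."""
    rr, cc = np.mgrid[0 : spec.height, 0 : spec.width].astype(float)
    a, b = spec.axes
    r0, c0 = center
    inside = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
    t = np.clip((rr - (r0 - a)) / (2.0 * a), 0.0, 1.0)
    h0, h1 = spec.hue_range
    hsv = np.zeros((spec.height, spec.width, 3))
    hsv[..., 0] = h0 + (h1 - h0) * t
    hsv[..., 1] = spec.saturation
    hsv[..., 2] = _envelope(t, spec.bands, spec.band_floor) / 255.0
    rgb = hsv2rgb(hsv) * 255.0
    rgb[~inside] = 0.0
    return rgb, inside


def _bbox_of(mask) -> tuple:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)


def make_rainbow_image(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the scene; returns ``(uint8 image, ground truth)``.

    Noise is applied last; the ground truth (mask, bounding box and the
    expected 100-point spectral profile of the primary patch) is computed
    from the clean render.
    """
    rng = np.random.default_rng(spec.seed)
    clean = np.zeros((spec.height, spec.width, 3))
    patches = []
    for center in spec._centers():
        rgb, mask = _render_patch(spec, center)
        clean = np.maximum(clean, rgb)
        patches.append((center, mask))
    # primary = leftmost patch, matching the extractor's tie-break
    patches.sort(key=lambda item: item[0][1])
    primary_mask = patches[0][1]
    bbox = _bbox_of(primary_mask)
    minr, minc, maxr, maxc = bbox
    crop = clean[minr:maxr, minc:maxc]
    truth_rows = row_means_rect(combine_channels_rect(crop))
    profile = np.interp(
        np.linspace(0, len(truth_rows) - 1, 100),
        np.arange(len(truth_rows)),
        truth_rows,
    )

    noisy = clean.copy()
    if spec.noise_sd > 0:
        noisy += rng.normal(0.0, spec.noise_sd, noisy.shape)
    if spec.salt_pepper > 0:
        u = rng.random((spec.height, spec.width))
        noisy[u < spec.salt_pepper / 2.0] = 255.0
        noisy[(u >= spec.salt_pepper / 2.0) & (u < spec.salt_pepper)] = 0.0
    image = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    return image, GroundTruth(primary_mask, bbox, profile)


def combine_channels_rect(crop, weights=(0.2, 0.7, 0.1)) -> np.ndarray:
    """Channel combination for a non-square crop (ground-truth path only)."""
    crop = np.asarray(crop, dtype=float)
    w = np.asarray(weights, dtype=float)
    return crop[..., 0] * w[0] + crop[..., 1] * w[1] + crop[..., 2] * w[2]


def row_means_rect(combined) -> np.ndarray:
    return np.asarray(combined, dtype=float).mean(axis=1)


def random_scene_specs(n: int, seed: int = 0, noise_sd: float = 0.0,
                       salt_pepper: float = 0.0, two_patches: bool = False):
    """A reproducible batch of varied scene specs for segmentation tests."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        a = rng.uniform(55.0, 85.0)
        b = rng.uniform(18.0, 38.0)
        height, width = 240, 320
        r0 = rng.uniform(a + 2, height - 1 - a - 2)
        if two_patches:
            c0 = rng.uniform(b + 2, width / 2 - b - 4)
        else:
            c0 = rng.uniform(b + 2, width - 1 - b - 2)
        bands = tuple(
            (float(np.clip(pos + rng.uniform(-0.05, 0.05), 0.05, 0.95)),
             float(rng.uniform(0.1, 0.2)),
             float(rng.uniform(40.0, 85.0)))
            for pos in (0.25, 0.55, 0.8)
        )
        specs.append(
            SceneSpec(
                height=height, width=width, center=(float(r0), float(c0)),
                axes=(float(a), float(b)), bands=bands, two_patches=two_patches,
                noise_sd=noise_sd, salt_pepper=salt_pepper,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# feature populations


@dataclass(frozen=True)
class PopulationSpec:
    """Statistical design of a synthetic feature population.

    ``n_per_cell`` samples per species x type cell.  Species identity adds
    a Gaussian bump inside variables 40-60; the organic / non-organic
    label follows the sign of ``r - radius_threshold`` where r is the
    radius of two latent factors smoothly embedded at ``latent_centers``.
    """

    n_per_cell: int = 25
    species: tuple = SPECIES
    species_band_centers: tuple = (45.0, 50.0, 55.0)
    species_band_width: float = 4.0
    species_amplitude: float = 25.0
    latent_centers: tuple = (25.0, 75.0)
    latent_width: float = 6.0
    latent_amplitude: float = 12.0
    radius_threshold: float = 1.0
    radius_margin: float = 0.15
    radius_min: float = 0.2
    radius_max: float = 2.2
    noise_sd: float = 2.0
    seed: int = 42
    n_features: int = 100
    certify: bool = True
    linear_ceiling: float = 75.0  # max tolerated PLS-DA LOOCV accuracy (%)

    def __post_init__(self):
        if self.n_per_cell < 2:
            raise InvalidParameterError("need at least two samples per cell")
        if len(self.species) != len(self.species_band_centers):
            raise InvalidParameterError("one band center per species is required")
        if not (self.radius_min < self.radius_threshold < self.radius_max):
            raise InvalidParameterError("radius threshold must sit inside the radius range")


def _bump(v, center, width):
    return np.exp(-0.5 * ((v - center) / width) ** 2)


def make_feature_population(spec: PopulationSpec | None = None):
    """Draw the population; returns ``(FeatureMatrix, params dict)``.

    Row order is species-major (matching a samples-1..150 block layout),
    types alternating inside each species block.  Fully deterministic
    under ``spec.seed``.
    """
    spec = spec or PopulationSpec()
    rng = np.random.default_rng(spec.seed)
    v = np.arange(spec.n_features, dtype=float)
    base = 70.0 + 50.0 * _bump(v, 50.0, 28.0)
    g1 = spec.latent_amplitude * _bump(v, spec.latent_centers[0], spec.latent_width)
    g2 = spec.latent_amplitude * _bump(v, spec.latent_centers[1], spec.latent_width)

    rows, species_lab, type_lab, ids, latents = [], [], [], [], []
    for s_idx, species in enumerate(spec.species):
        s_bump = spec.species_amplitude * _bump(
            v, spec.species_band_centers[s_idx], spec.species_band_width
        )
        for type_name in TYPES:
            if type_name == "organic":
                r_lo, r_hi = spec.radius_threshold + spec.radius_margin, spec.radius_max
            else:
                r_lo, r_hi = spec.radius_min, spec.radius_threshold - spec.radius_margin
            for j in range(spec.n_per_cell):
                if spec.noise_sd > 0:
                    theta = rng.uniform(0.0, 2.0 * np.pi)
                    r = rng.uniform(r_lo, r_hi)
                else:
                    # degenerate noiseless fixture mode: latent draws count as
                    # noise, so each cell collapses to its centroid latent
                    theta, r = 0.0, 0.5 * (r_lo + r_hi)
                z1, z2 = r * np.cos(theta), r * np.sin(theta)
                x = base + s_bump + z1 * g1 + z2 * g2
                if spec.noise_sd > 0:
                    x = x + rng.normal(0.0, spec.noise_sd, spec.n_features)
                rows.append(np.clip(x, 0.0, 255.0))
                species_lab.append(species)
                type_lab.append(type_name)
                ids.append(f"{species}-{type_name}-{j:02d}")
                latents.append((z1, z2))

    fm = FeatureMatrix(np.vstack(rows), species_lab, type_lab, ids)
    params = {
        "spec": spec,
        "latents": np.array(latents),
        "base": base,
        "latent_profiles": (g1, g2),
    }
    # the certificate only makes sense for the stochastic design; the
    # noiseless mode collapses every cell to a single point
    if spec.certify and spec.noise_sd > 0:
        certify_nonlinear(fm, ceiling=spec.linear_ceiling)
    return fm, params


def certify_nonlinear(fm: FeatureMatrix, ceiling: float = 75.0, max_lv: int = 10) -> float:
    """Assert that no global PLS-DA model separates the type labels.

    Returns the best LOOCV accuracy over 1..max_lv latent variables and
    raises :class:`NonlinearityCertificateError` if it reaches the ceiling.
    """
    from .evaluation import _loocv_plsda_all_lv  # local import: avoid cycle at load

    acc = _loocv_plsda_all_lv(fm.X, fm.types, list(range(1, max_lv + 1)))
    best = max(acc.values())
    if best >= ceiling:
        raise NonlinearityCertificateError(
            f"linear PLS-DA reaches {best:.1f}% LOOCV accuracy "
            f"(ceiling {ceiling:.1f}%); the population is too linearly separable"
        )
    return best


def with_seed(spec: PopulationSpec, seed: int) -> PopulationSpec:
    """Convenience: same design, different random seed."""
    return replace(spec, seed=seed)
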