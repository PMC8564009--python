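"""Gray-level co-occurrence texture features, computed per spectral band.

The gray-level co-occurrence matrix (GLCM) ``g(i, j)`` is the probability
that a pixel with quantized gray level ``i`` has a neighbor at a fixed
spatial offset (distance, angle) with level ``j``.  Four Haralick-type
statistics summarize it:

    homogeneity = sum_ij g(i,j) / (1 + (i - j)^2)
    contrast    = sum_ij (i - j)^2 g(i,j)
    energy      = sum_ij g(i,j)^2                    (angular second moment)
    correlation = (sum_ij i*j*g(i,j) - mu_x mu_y) / (sigma_x sigma_y)

with ``mu``/``sigma`` the means and standard deviations of the marginal
level distributions.  Applied to each of the six bands this yields the
24-variable texture feature set (4 statistics x 6 bands).

Reflectance in [0, 1] is uniformly quantized to ``n_levels`` gray levels
before counting; pixels outside the region of interest are excluded from
every pair.  Level indices run 0..N-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .cube import MultispectralCube, RoiMask

__all__ = [
    "GlcmConfig",
    "GLCM",
    "GlcmStatistics",
    "IGNORE",
    "quantize",
    "compute_glcm",
    "glcm_statistics",
    "extract_texture",
    "texture_feature_names",
]

#: Sentinel level for pixels excluded from co-occurrence counting.
IGNORE = -1

_CANONICAL_ANGLES = (0, 45, 90, 135)

# Offsets (drow, dcol) for the canonical directions at unit distance.  Angles
# are measured counterclockwise from the positive column axis with the row
# axis pointing down, so 45 deg steps up-and-right.
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GlcmConfig:
    """Co-occurrence construction parameters.

    ``n_levels`` gray levels (uniform bins over [0, 1] reflectance),
    pair offset of ``distance`` pixels along each angle in ``angles_deg``,
    optional symmetrization (count each pair in both directions) and
    averaging of the per-angle normalized matrices into a single
    rotation-robust GLCM.
    """

    n_levels: int = 64
    distance: int = 1
    angles_deg: tuple[int, ...] = _CANONICAL_ANGLES
    symmetric: bool = True
    average_over_angles: bool = True

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError(f"n_levels must be >= 2, got {self.n_levels}")
        if self.distance < 1:
            raise ValueError(f"distance must be >= 1, got {self.distance}")
        angles = tuple(self.angles_deg)
        if not angles or any(a not in _CANONICAL_ANGLES for a in angles):
            raise ValueError(
                f"angles must be a non-empty subset of {_CANONICAL_ANGLES}, got {angles}"
            )
        object.__setattr__(self, "angles_deg", angles)


@dataclass(frozen=True)
class GLCM:
    """A normalized co-occurrence probability matrix with its construction config."""

    g: np.ndarray
    config: GlcmConfig

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=np.float64)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError(f"GLCM must be square, got shape {g.shape}")
        if g.min() < 0:
            raise ValueError("GLCM entries must be non-negative")
        if abs(g.sum() - 1.0) > 1e-12:
            raise ValueError(f"GLCM must sum to 1, got {g.sum()!r}")
        object.__setattr__(self, "g", g)


class GlcmStatistics(NamedTuple):
    homogeneity: float
    contrast: float
    energy: float
    correlation: float


def quantize(band_image: np.ndarray, roi: RoiMask, n_levels: int) -> np.ndarray:
    """Uniformly quantize reflectance in [0, 1] to integer levels 0..n_levels-1.

    ``levels = floor(clip(x, 0, 1 - eps) * n_levels)``; a reflectance of
    exactly 1.0 therefore maps to the top level, not ``n_levels``.  Pixels
    outside the ROI are set to the :data:`IGNORE` sentinel.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    img = np.asarray(band_image, dtype=np.float64)
    if img.shape != roi.mask.shape:
        raise ValueError(f"band shape {img.shape} != mask shape {roi.mask.shape}")
    if not roi.mask.any():
        raise ValueError("empty ROI: no pixels to quantize")
    eps = np.finfo(np.float64).eps
    clipped = np.clip(img, 0.0, 1.0 - eps)
    levels = np.floor(clipped * n_levels).astype(np.int64)
    levels[~roi.mask] = IGNORE
    return levels


def _offset_for(angle_deg: int, distance: int) -> tuple[int, int]:
    drow, dcol = _ANGLE_OFFSETS[angle_deg]
    return drow * distance, dcol * distance


def compute_glcm(levels: np.ndarray, config: GlcmConfig) -> GLCM:
    """Count co-occurring level pairs and normalize to a probability matrix.

    For each configured angle, every pixel is paired with the pixel at
    ``distance`` steps along that angle; pairs touching an :data:`IGNORE`
    pixel or leaving the image are skipped.  With ``symmetric`` each pair is
    counted in both orders.  Matrices are normalized per angle; with
    ``average_over_angles`` their mean is returned, otherwise matrices are
    computed per angle and the first angle's matrix is returned for a single
    angle (multiple angles require averaging).
    """
    levels = np.asarray(levels)
    n = config.n_levels
    if levels.max(initial=IGNORE) >= n:
        raise ValueError("level values exceed configured n_levels")
    if not config.average_over_angles and len(config.angles_deg) > 1:
        raise ValueError("multiple angles require average_over_angles=True")
    per_angle: list[np.ndarray] = []
    for angle in config.angles_deg:
        drow, dcol = _offset_for(angle, config.distance)
        h, w = levels.shape
        r0 = max(0, -drow)
        r1 = min(h, h - drow)
        c0 = max(0, -dcol)
        c1 = min(w, w - dcol)
        if r0 >= r1 or c0 >= c1:
            raise ValueError(
                f"image too small for offset (drow={drow}, dcol={dcol}); no valid pairs"
            )
        a = levels[r0:r1, c0:c1]
        b = levels[r0 + drow : r1 + drow, c0 + dcol : c1 + dcol]
        valid = (a != IGNORE) & (b != IGNORE)
        if not valid.any():
            raise ValueError(
                f"no valid pixel pairs at offset (drow={drow}, dcol={dcol}); ROI too small"
            )
        counts = np.bincount(
            (a[valid] * n + b[valid]).ravel(), minlength=n * n
        ).reshape(n, n).astype(np.float64)
        if config.symmetric:
            counts = counts + counts.T
        per_angle.append(counts / counts.sum())
    g = np.mean(per_angle, axis=0) if config.average_over_angles else per_angle[0]
    return GLCM(g=g, config=config)


def glcm_statistics(glcm: GLCM, zero_variance_correlation: float = 0.0) -> GlcmStatistics:
    """The four scalar texture statistics of a normalized GLCM.

    Correlation is undefined when either marginal has zero variance (e.g. a
    constant region); it is reported as ``zero_variance_correlation``
    (default 0, carrying no linear-dependence information).
    """
    g = glcm.g
    n = g.shape[0]
    i = np.arange(n, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff2 = (ii - jj) ** 2
    homogeneity = float(np.sum(g / (1.0 + diff2)))
    contrast = float(np.sum(diff2 * g))
    energy = float(np.sum(g**2))
    px = g.sum(axis=1)
    py = g.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    var_x = float(np.sum((i - mu_x) ** 2 * px))
    var_y = float(np.sum((i - mu_y) ** 2 * py))
    sigma = math.sqrt(var_x) * math.sqrt(var_y)
    if sigma <= 1e-15:
        correlation = float(zero_variance_correlation)
    else:
        correlation = float((np.sum(ii * jj * g) - mu_x * mu_y) / sigma)
    return GlcmStatistics(homogeneity, contrast, energy, correlation)


def texture_feature_names(band_centers_nm: tuple[float, ...]) -> list[str]:
    """Band-major names: tex_<band>nm_<statistic>, matching extract_texture order."""
    stats = GlcmStatistics._fields
    return [f"tex_{int(round(c))}nm_{s}" for c in band_centers_nm for s in stats]


def extract_texture(
    cube: MultispectralCube, roi: RoiMask, config: GlcmConfig | None = None
) -> np.ndarray:
    """Per-band texture statistics as a flat vector of length ``4 * n_bands``.

    Each band is quantized, its GLCM computed and summarized; the vector is
    ordered band-major, then (homogeneity, contrast, energy, correlation).
    """
    if not cube.is_calibrated:
        raise ValueError("extract_texture expects a calibrated cube")
    if config is None:
        config = GlcmConfig()
    out = np.empty(4 * cube.n_bands, dtype=np.float64)
    for b in range(cube.n_bands):
        levels = quantize(cube.band(b), roi, config.n_levels)
        stats = glcm_statistics(compute_glcm(levels, config))
        out[4 * b : 4 * b + 4] = stats
    return out
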