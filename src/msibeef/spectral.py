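"""Band-mean spectral features and CIELAB color features.

Two spectral feature sets are extracted from a calibrated cube:

* **MS** — the mean ROI reflectance of each band (6 values for the standard
  six-band cube).
* **CIELAB** — three bands are assigned to the R, G and B channels of a
  linear RGB triple, converted to CIEXYZ tristimulus values with the fixed
  3x3 matrix below, then to (L*, a*, b*) relative to a white point:

      L* = 116 f(Y/Yn) - 16
      a* = 500 [f(X/Xn) - f(Y/Yn)]
      b* = 200 [f(Y/Yn) - f(Z/Zn)]

  with the usual cube-root compression ``f(t) = t^(1/3)`` above the knee
  ``(24/116)^3`` and the linear segment ``(841/108) t + 16/116`` below it.

The inputs are calibrated physical reflectances, so the RGB triple enters
the XYZ matrix linearly — no display gamma/companding is applied.  The
default white point is the response of the XYZ matrix to the unit white
stimulus (its row sums), a D65-like point, so a perfectly white diffuse
surface maps to (100, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import MultispectralCube, RoiMask

__all__ = [
    "XYZ_FROM_RGB",
    "DEFAULT_WHITE_POINT",
    "RgbMapping",
    "ms_features",
    "ms_feature_names",
    "rgb_to_xyz",
    "xyz_to_lab",
    "cielab_features",
    "CIELAB_FEATURE_NAMES",
]

#: Linear RGB -> CIEXYZ conversion matrix (ITU-R BT.709 primaries, D65).
XYZ_FROM_RGB = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)

#: XYZ of the unit white stimulus under the matrix above (its row sums).
DEFAULT_WHITE_POINT = tuple(XYZ_FROM_RGB.sum(axis=1))

_LAB_KNEE = (24.0 / 116.0) ** 3
_LAB_SLOPE = 841.0 / 108.0
_LAB_OFFSET = 16.0 / 116.0

CIELAB_FEATURE_NAMES = ("lab_L", "lab_a", "lab_b")


@dataclass(frozen=True)
class RgbMapping:
    """Which cube bands feed the R, G and B channels of the XYZ conversion.

    Defaults pick the band centers closest to the red, green and blue
    primaries among the standard six: R <- 680 nm, G <- 570 nm, B <- 500 nm.
    """

    r_band_nm: float = 680.0
    g_band_nm: float = 570.0
    b_band_nm: float = 500.0

    def __post_init__(self) -> None:
        bands = (self.r_band_nm, self.g_band_nm, self.b_band_nm)
        if len(set(bands)) != 3:
            raise ValueError(f"RGB mapping bands must be distinct, got {bands}")

    def band_indices(self, cube: MultispectralCube) -> tuple[int, int, int]:
        return (
            cube.band_index(self.r_band_nm),
            cube.band_index(self.g_band_nm),
            cube.band_index(self.b_band_nm),
        )


def ms_features(cube: MultispectralCube, roi: RoiMask) -> np.ndarray:
    """Mean ROI reflectance per band, in cube band order."""
    if not cube.is_calibrated:
        raise ValueError("ms_features expects a calibrated cube")
    if roi.mask.shape != cube.spatial_shape:
        raise ValueError("ROI shape does not match cube")
    if not roi.mask.any():
        raise ValueError("empty ROI")
    return cube.pixels[roi.mask].mean(axis=0)


def ms_feature_names(band_centers_nm: tuple[float, ...]) -> list[str]:
    return [f"ms_{int(round(c))}nm" for c in band_centers_nm]


def rgb_to_xyz(rgb: np.ndarray) -> np.ndarray:
    """Map a linear RGB triple in [0, 1] to CIEXYZ tristimulus values."""
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.shape[-1] != 3:
        raise ValueError(f"expected RGB triple(s), got shape {rgb.shape}")
    if rgb.min() < 0 or rgb.max() > 1:
        raise ValueError("RGB components must lie in [0, 1]")
    return rgb @ XYZ_FROM_RGB.T


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=np.float64)
    return np.where(t > _LAB_KNEE, np.cbrt(t), _LAB_SLOPE * t + _LAB_OFFSET)


def xyz_to_lab(
    xyz: np.ndarray, white_point: tuple[float, float, float] = DEFAULT_WHITE_POINT
) -> np.ndarray:
    """Convert CIEXYZ to CIELAB (L*, a*, b*) relative to ``white_point``."""
    xyz = np.asarray(xyz, dtype=np.float64)
    wp = np.asarray(white_point, dtype=np.float64)
    if wp.shape != (3,) or np.any(wp <= 0):
        raise ValueError(f"white point must be three positive values, got {white_point}")
    fx, fy, fz = np.moveaxis(_lab_f(xyz / wp), -1, 0)
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return np.stack([L, a, b], axis=-1)


def cielab_features(
    cube: MultispectralCube,
    roi: RoiMask,
    mapping: RgbMapping | None = None,
    white_point: tuple[float, float, float] = DEFAULT_WHITE_POINT,
    per_pixel: bool = False,
) -> np.ndarray:
    """(L*, a*, b*) of the ROI under the configured band-to-RGB mapping.

    By default the ROI-mean reflectance of the three mapped bands forms one
    RGB triple (three features).  With ``per_pixel`` the conversion is done
    pixelwise and the Lab values are averaged over the ROI instead.
    """
    if mapping is None:
        mapping = RgbMapping()
    idx = mapping.band_indices(cube)
    if per_pixel:
        rgb = cube.pixels[roi.mask][:, idx]
        return xyz_to_lab(rgb_to_xyz(rgb), white_point).mean(axis=0)
    means = ms_features(cube, roi)
    rgb = means[list(idx)]
    return xyz_to_lab(rgb_to_xyz(rgb), white_point)
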