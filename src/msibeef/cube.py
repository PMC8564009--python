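"""Multispectral cube data model, file I/O, reflectance calibration and ROI selection.

A multispectral cube is an ``H x W x B`` intensity array acquired through a
small number of bandpass filters (here six, centered at 500, 530, 570, 680,
760 and 808 nm on the reference instrument).  Raw cubes hold sensor counts on
a 16-bit scale; calibrated cubes hold relative reflectance in ``[0, 1]``
obtained by ratioing against dark-response and diffuse-reference frames:

    R = (I_raw - I_dark) / (I_ref - I_dark) * rho_ref

where ``rho_ref`` is the nominal reflectance of the diffuse standard
(0.20 for the 20 % Spectralon-type target).  The pointwise ratio cancels the
illumination field and the per-pixel sensor gain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MultispectralCube",
    "CalibrationFrames",
    "RoiMask",
    "CalibrationError",
    "CubeFormatError",
    "DEFAULT_BAND_CENTERS_NM",
    "load_cube",
    "save_cube",
    "calibrate",
    "segment_roi",
]

DEFAULT_BAND_CENTERS_NM: tuple[float, ...] = (500.0, 530.0, 570.0, 680.0, 760.0, 808.0)


class CubeFormatError(ValueError):
    """Raised when a stored cube is inconsistent with its declared metadata."""


class CalibrationError(ValueError):
    """Raised when reflectance calibration cannot be performed."""


@dataclass
class MultispectralCube:
    """An ``H x W x B`` multispectral image with band-center metadata.

    Parameters
    ----------
    pixels
        Intensity array of shape ``(height, width, n_bands)``.  Raw cubes are
        integer counts in ``[0, 2**bit_depth - 1]``; calibrated cubes are
        finite reflectances clipped to ``[0, 1]``.
    band_centers_nm
        Strictly increasing center wavelengths, one per band.
    bit_depth
        ADC bit depth of the raw data (16 for the reference camera).
    is_calibrated
        Whether ``pixels`` holds reflectance rather than counts.
    """

    pixels: np.ndarray
    band_centers_nm: tuple[float, ...] = DEFAULT_BAND_CENTERS_NM
    bit_depth: int = 16
    is_calibrated: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError(
                f"pixels must be (height, width, n_bands), got shape {self.pixels.shape}"
            )
        self.band_centers_nm = tuple(float(c) for c in self.band_centers_nm)
        if self.pixels.shape[2] != len(self.band_centers_nm):
            raise CubeFormatError(
                f"cube has {self.pixels.shape[2]} bands but "
                f"{len(self.band_centers_nm)} band centers were declared"
            )
        if any(b <= a for a, b in zip(self.band_centers_nm, self.band_centers_nm[1:])):
            raise ValueError(f"band centers must be strictly increasing: {self.band_centers_nm}")
        if self.is_calibrated:
            if not np.all(np.isfinite(self.pixels)):
                raise ValueError("calibrated cube contains non-finite values")
            if self.pixels.min() < 0 or self.pixels.max() > 1:
                raise ValueError("calibrated reflectance must lie in [0, 1]")
        else:
            full_scale = 2**self.bit_depth - 1
            if self.pixels.min() < 0 or self.pixels.max() > full_scale:
                raise ValueError(
                    f"raw counts must lie in [0, {full_scale}] for bit depth {self.bit_depth}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    @property
    def n_bands(self) -> int:
        return self.pixels.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def band(self, index: int) -> np.ndarray:
        """Return the 2-D image of one band."""
        return self.pixels[:, :, index]

    def band_index(self, center_nm: float, tol_nm: float = 1.0) -> int:
        """Index of the band whose center is within ``tol_nm`` of ``center_nm``."""
        diffs = np.abs(np.asarray(self.band_centers_nm) - center_nm)
        idx = int(np.argmin(diffs))
        if diffs[idx] > tol_nm:
            raise KeyError(
                f"no band within {tol_nm} nm of {center_nm} nm "
                f"(centers: {self.band_centers_nm})"
            )
        return idx


@dataclass
class CalibrationFrames:
    """Dark-response and diffuse-reference frames for reflectance calibration.

    ``dark`` and ``reference`` may be 2-D (shared across bands, broadcast) or
    3-D (per-band).  ``reference_reflectance`` is the nominal reflectance of
    the diffuse standard (default 0.20 for a 20 % target).
    """

    dark: np.ndarray
    reference: np.ndarray
    reference_reflectance: float = 0.20

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=np.float64)
        self.reference = np.asarray(self.reference, dtype=np.float64)
        if not 0.0 < self.reference_reflectance <= 1.0:
            raise ValueError(
                f"reference_reflectance must lie in (0, 1], got {self.reference_reflectance}"
            )


@dataclass
class RoiMask:
    """Boolean foreground mask over the cube's spatial grid."""

    mask: np.ndarray
    min_fraction: float = 0.01

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        frac = self.mask.mean() if self.mask.size else 0.0
        if frac < self.min_fraction:
            raise ValueError(
                f"only {frac:.3%} of pixels are foreground "
                f"(minimum {self.min_fraction:.3%})"
            )

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def save_cube(cube: MultispectralCube, path: str | Path, dialect: str = "tiff_multipage") -> Path:
    """Write a cube to disk; bit-exact round trip for integer rasters.

    ``tiff_multipage``: one 2-D page per band (uint16 for raw cubes, float32
    for calibrated ones) plus a JSON sidecar ``<name>.json`` holding
    ``band_centers_nm``, ``bit_depth`` and ``is_calibrated``.
    ``npz_archive``: a single ``.npz`` with the same keys.
    """
    path = Path(path)
    meta = {
        "band_centers_nm": list(cube.band_centers_nm),
        "bit_depth": cube.bit_depth,
        "is_calibrated": cube.is_calibrated,
        "n_bands": cube.n_bands,
    }
    if dialect == "tiff_multipage":
        import tifffile

        if cube.is_calibrated:
            pages = cube.pixels.astype(np.float32)
        else:
            pages = np.round(cube.pixels).astype(np.uint16)
        tifffile.imwrite(path, np.moveaxis(pages, 2, 0))
        _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    elif dialect == "npz_archive":
        np.savez(
            path,
            pixels=cube.pixels,
            band_centers_nm=np.asarray(cube.band_centers_nm),
            bit_depth=np.asarray(cube.bit_depth),
            is_calibrated=np.asarray(cube.is_calibrated),
        )
    else:
        raise ValueError(f"unknown cube dialect {dialect!r}")
    return path


def load_cube(path: str | Path, dialect: str = "tiff_multipage") -> MultispectralCube:
    """Read a cube written by :func:`save_cube`.

    Raises
    ------
    FileNotFoundError
        If the cube file (or its TIFF sidecar) is missing.
    CubeFormatError
        If the stored page/array count disagrees with the declared band count
        or the header cannot be parsed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cube file not found: {path}")
    if dialect == "tiff_multipage":
        import tifffile

        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(f"cube sidecar header not found: {sidecar}")
        try:
            meta = json.loads(sidecar.read_text())
            band_centers = meta["band_centers_nm"]
            bit_depth = int(meta["bit_depth"])
            is_calibrated = bool(meta["is_calibrated"])
            declared = int(meta.get("n_bands", len(band_centers)))
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            raise CubeFormatError(f"corrupt cube header {sidecar}: {exc}") from exc
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[np.newaxis]
        if pages.shape[0] != declared or declared != len(band_centers):
            raise CubeFormatError(
                f"{path}: file has {pages.shape[0]} pages but header declares "
                f"{declared} bands ({len(band_centers)} centers)"
            )
        pixels = np.moveaxis(pages, 0, 2)
        if is_calibrated:
            pixels = pixels.astype(np.float64)
    elif dialect == "npz_archive":
        with np.load(path) as npz:
            try:
                pixels = npz["pixels"]
                band_centers = npz["band_centers_nm"].tolist()
                bit_depth = int(npz["bit_depth"])
                is_calibrated = bool(npz["is_calibrated"])
            except KeyError as exc:
                raise CubeFormatError(f"corrupt cube archive {path}: missing {exc}") from exc
        if pixels.ndim != 3 or pixels.shape[2] != len(band_centers):
            raise CubeFormatError(
                f"{path}: array has {pixels.shape[2] if pixels.ndim == 3 else '?'} bands "
                f"but header declares {len(band_centers)}"
            )
    else:
        raise ValueError(f"unknown cube dialect {dialect!r}")
    return MultispectralCube(
        pixels=pixels,
        band_centers_nm=tuple(band_centers),
        bit_depth=bit_depth,
        is_calibrated=is_calibrated,
    )


def calibrate(raw: MultispectralCube, frames: CalibrationFrames) -> MultispectralCube:
    """Convert raw counts to relative reflectance.

    Per pixel and band::

        R = (I_raw - I_dark) / (I_ref - I_dark) * rho_ref

    clipped to ``[0, 1]``.  Pixels where the reference does not exceed the
    dark response carry no calibration information; they are set to 0 and a
    warning is emitted.

    Raises
    ------
    CalibrationError
        If the cube is already calibrated, shapes are incompatible, or the
        reference frame is everywhere invalid.
    """
    if raw.is_calibrated:
        raise CalibrationError("cube is already calibrated; refusing to calibrate twice")
    pixels = raw.pixels.astype(np.float64)
    dark = frames.dark
    ref = frames.reference
    if dark.ndim == 2:
        dark = dark[:, :, np.newaxis]
    if ref.ndim == 2:
        ref = ref[:, :, np.newaxis]
    try:
        np.broadcast_shapes(pixels.shape, dark.shape, ref.shape)
    except ValueError as exc:
        raise CalibrationError(
            f"shape mismatch: cube {pixels.shape}, dark {frames.dark.shape}, "
            f"reference {frames.reference.shape}"
        ) from exc
    denom = ref - dark
    valid = denom > 0
    valid = np.broadcast_to(valid, pixels.shape)
    if not valid.any():
        raise CalibrationError("reference frame never exceeds dark frame; cannot calibrate")
    if not valid.all():
        warnings.warn(
            f"{(~valid).sum()} pixel(s) with reference <= dark set to 0 reflectance",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (pixels - dark) / denom * frames.reference_reflectance
    refl = np.where(valid, refl, 0.0)
    refl = np.clip(refl, 0.0, 1.0)
    return MultispectralCube(
        pixels=refl,
        band_centers_nm=raw.band_centers_nm,
        bit_depth=raw.bit_depth,
        is_calibrated=True,
    )


def segment_roi(
    cube: MultispectralCube,
    method: str = "full_frame",
    band_index: int | None = None,
    min_fraction: float = 0.01,
) -> RoiMask:
    """Select the foreground (tissue) region of a calibrated cube.

    ``full_frame`` keeps every pixel.  ``otsu_threshold`` applies Otsu's
    threshold to one band (default: the band nearest 680 nm, which shows the
    strongest tissue/background contrast) and keeps the largest connected
    above-threshold component.  A constant band cannot be thresholded; the
    method then falls back to the full frame with a warning.
    """
    if not cube.is_calibrated:
        raise ValueError("segment_roi expects a calibrated cube")
    if method == "full_frame":
        return RoiMask(np.ones(cube.spatial_shape, dtype=bool), min_fraction=min_fraction)
    if method != "otsu_threshold":
        raise ValueError(f"unknown ROI method {method!r}")

    from skimage.filters import threshold_otsu
    from skimage.measure import label

    if band_index is None:
        band_index = cube.band_index(680.0, tol_nm=np.inf)
    img = cube.band(band_index)
    if np.ptp(img) == 0:
        warnings.warn(
            "band is constant; Otsu thresholding degenerate, falling back to full frame",
            stacklevel=2,
        )
        return RoiMask(np.ones(cube.spatial_shape, dtype=bool), min_fraction=min_fraction)
    thresh = threshold_otsu(img)
    fg = img > thresh
    labels = label(fg, connectivity=2)
    if labels.max() == 0:
        warnings.warn("no foreground component found; falling back to full frame", stacklevel=2)
        return RoiMask(np.ones(cube.spatial_shape, dtype=bool), min_fraction=min_fraction)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == int(np.argmax(sizes))
    return RoiMask(mask, min_fraction=min_fraction)
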