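"""Seeded generator of labeled multispectral cubes with class structure.

The generator emulates six-band (500/530/570/680/760/808 nm) reflectance
images of three beef cuts, reproducing the qualitative contrasts the
analysis relies on:

* **spectral** — shank is brightest overall (more white tendon and lipid);
  sirloin shows a relative reflectance dip at the 760 nm band (water /
  deoxymyoglobin absorption) and is otherwise spectrally close to flank;
* **textural** — shank carries oriented white stripes (fascia and muscle
  fiber direction), sirloin faint blob-like marbling, flank only weak
  noise-like texture.

The two modalities are deliberately complementary: overall-brightness
variability between animals makes flank and shank overlap spectrally
(texture tells them apart), while sirloin's faint marbling overlaps flank's
weak texture (the 760 nm dip tells them apart).  Neither modality alone
separates all three classes; their fusion does.

Each sample is produced through a forward measurement model matching the
calibration equation's quantities: a smooth polynomial illumination gain
field, counts proportional to reflectance on a 16-bit scale, a dark level
of 5 % of full scale, additive Gaussian sensor noise, and matching dark and
20 %-reference frames.  Calibrating the raw cube against its frames
recovers the underlying reflectance field, so the whole pipeline is
testable end-to-end without any measured data.

Per-sample biological variability is simulated by jittering the class
template (overall brightness, band-wise reflectance, texture amplitude and
orientation) with seeded randomness; the drawn parameters are recorded in a
manifest so every sample's ground truth is recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .cube import (
    DEFAULT_BAND_CENTERS_NM,
    CalibrationFrames,
    MultispectralCube,
    RoiMask,
    calibrate,
)

__all__ = [
    "ClassTemplate",
    "GeneratorConfig",
    "Sample",
    "LabeledDataset",
    "default_templates",
    "generate_sample",
    "iter_dataset",
    "generate_dataset",
]

TEXTURE_KINDS = ("marbling_blobs", "oriented_stripes", "weak_noise")

#: Texture amplitude multiplier per band; heterogeneity is most visible in
#: the short-wavelength bands where muscle pigments absorb strongly.
BAND_TEXTURE_FACTORS = np.array([1.2, 1.1, 1.0, 0.9, 0.85, 0.8])


@dataclass(frozen=True)
class ClassTemplate:
    """Mean spectral profile and texture model of one beef-cut class."""

    name: str
    reflectance_profile: tuple[float, ...]
    texture_kind: str
    texture_contrast: float
    stripe_angle_deg: float = 90.0
    blob_density: float = 0.003  # blobs per pixel (marbling only)

    def __post_init__(self) -> None:
        if self.texture_kind not in TEXTURE_KINDS:
            raise ValueError(f"texture_kind must be one of {TEXTURE_KINDS}")
        profile = tuple(float(p) for p in self.reflectance_profile)
        if any(not 0.0 < p < 1.0 for p in profile):
            raise ValueError(f"reflectance profile must lie in (0, 1), got {profile}")
        if not 0.0 <= self.texture_contrast < 1.0:
            raise ValueError("texture_contrast must lie in [0, 1)")
        object.__setattr__(self, "reflectance_profile", profile)


def default_templates() -> tuple[ClassTemplate, ClassTemplate, ClassTemplate]:
    """The three default cut templates (sirloin, flank, shank)."""
    return (
        ClassTemplate(
            name="sirloin",
            reflectance_profile=(0.26, 0.30, 0.34, 0.48, 0.40, 0.51),
            texture_kind="marbling_blobs",
            texture_contrast=0.06,
            blob_density=0.005,
        ),
        ClassTemplate(
            name="flank",
            reflectance_profile=(0.26, 0.30, 0.34, 0.48, 0.45, 0.51),
            texture_kind="weak_noise",
            texture_contrast=0.05,
        ),
        ClassTemplate(
            name="shank",
            reflectance_profile=(0.28, 0.32, 0.36, 0.50, 0.48, 0.53),
            texture_kind="oriented_stripes",
            texture_contrast=0.20,
            stripe_angle_deg=90.0,
        ),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic dataset.

    Defaults mirror the reference experiment's sampling design: 555 samples
    (200 sirloin, 160 flank, 195 shank) of six-band cubes.  Frames default
    to 128 x 128 pixels — texture statistics stabilize well below the
    instrument's native 1290 x 960, which is supported but unnecessary for
    method validation.  ``noise_sd`` is additive Gaussian sensor noise in
    raw counts on the 16-bit scale; the dark level is 5 % of full scale and
    unit reflectance maps to 85 % of full scale at nominal gain.
    ``separation_scale`` scales every class profile's deviation from the
    across-class mean profile (0 makes the classes spectrally identical).
    """

    image_size: tuple[int, int] = (128, 128)
    n_per_class: dict | None = None
    noise_sd: float = 600.0
    n_calibration_frames: int = 100
    illumination_order: int = 2
    illumination_amplitude: float = 0.08
    bit_depth: int = 16
    seed: int = 0
    class_templates: tuple[ClassTemplate, ...] = field(default_factory=default_templates)
    separation_scale: float = 1.0
    band_centers_nm: tuple[float, ...] = DEFAULT_BAND_CENTERS_NM
    jitter_brightness_sd: float = 0.12
    jitter_band_sd: float = 0.03
    jitter_contrast_range: tuple[float, float] = (0.3, 1.7)
    jitter_band_amplitude: float = 0.4
    jitter_angle_sd_deg: float = 20.0

    def __post_init__(self) -> None:
        if self.n_per_class is None:
            object.__setattr__(
                self, "n_per_class", {"sirloin": 200, "flank": 160, "shank": 195}
            )
        if min(self.image_size) < 8:
            raise ValueError("image_size must be at least 8 x 8")
        if self.separation_scale < 0:
            raise ValueError("separation_scale must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_total(self) -> int:
        return sum(self.n_per_class.values())

    def scaled_templates(self) -> tuple[ClassTemplate, ...]:
        """Templates with profile deviations scaled by ``separation_scale``."""
        profiles = np.array([t.reflectance_profile for t in self.class_templates])
        mean = profiles.mean(axis=0)
        scaled = mean + self.separation_scale * (profiles - mean)
        scaled = np.clip(scaled, 1e-3, 1 - 1e-3)
        return tuple(
            replace(t, reflectance_profile=tuple(row))
            for t, row in zip(self.class_templates, scaled)
        )


# -- texture fields ----------------------------------------------------------
# Each field is a zero-mean pattern normalized to max |value| = 1; the band
# amplitude then sets the relative reflectance modulation.


def _normalize_field(f: np.ndarray) -> np.ndarray:
    f = f - f.mean()
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _stripe_field(shape: tuple[int, int], angle_deg: float, rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    theta = np.deg2rad(angle_deg)
    # stripes run along `theta`; intensity varies along the perpendicular
    u = -np.sin(theta) * cols + np.cos(theta) * rows
    period = rng.uniform(8.0, 16.0)
    phase = rng.uniform(0, 2 * np.pi)
    base = np.sin(2 * np.pi * u / period + phase)
    stripes = np.tanh(3.0 * base) / np.tanh(3.0)  # soft-thresholded sinusoid
    rough = gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    rough = 0.25 * rough / max(rough.std(), 1e-12)
    return _normalize_field(stripes + rough)


def _blob_field(
    shape: tuple[int, int], density: float, rng: np.random.Generator
) -> np.ndarray:
    h, w = shape
    n_blobs = max(1, int(rng.poisson(density * h * w)))
    canvas = np.zeros(shape)
    rows, cols = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        cr, cc = rng.uniform(0, h), rng.uniform(0, w)
        radius = rng.uniform(2.0, 6.0)
        canvas[(rows - cr) ** 2 + (cols - cc) ** 2 <= radius**2] = 1.0
    # marbling graininess varies between cuts; randomize the smoothing scale
    return _normalize_field(gaussian_filter(canvas, sigma=rng.uniform(1.5, 3.5)))


def _noise_field(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    # correlation length of the weak background texture varies per sample
    return _normalize_field(
        gaussian_filter(rng.standard_normal(shape), sigma=rng.uniform(2.0, 4.0))
    )


def _texture_field(template: ClassTemplate, shape, rng) -> np.ndarray:
    if template.texture_kind == "oriented_stripes":
        return _stripe_field(shape, template.stripe_angle_deg, rng)
    if template.texture_kind == "marbling_blobs":
        return _blob_field(shape, template.blob_density, rng)
    return _noise_field(shape, rng)


def _gain_field(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = config.image_size
    if config.illumination_order == 0 or config.illumination_amplitude == 0:
        return np.ones((h, w))
    y, x = np.mgrid[0:h, 0:w]
    y = 2.0 * y / max(h - 1, 1) - 1.0
    x = 2.0 * x / max(w - 1, 1) - 1.0
    field = np.zeros((h, w))
    terms = [
        x**i * y**j
        for i in range(config.illumination_order + 1)
        for j in range(config.illumination_order + 1 - i)
        if i + j > 0
    ]
    coeffs = rng.uniform(-1, 1, size=len(terms))
    for c, t in zip(coeffs, terms):
        field += c * t
    peak = max(np.abs(field).max(), 1e-12)
    return 1.0 + config.illumination_amplitude * field / peak


def generate_sample(
    template: ClassTemplate, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[MultispectralCube, CalibrationFrames, RoiMask]:
    """One raw cube with matching calibration frames and ground-truth mask.

    The true reflectance field of band ``b`` is
    ``profile[b] * (1 + amplitude_b * texture)`` with a single texture field
    shared across bands and a band-dependent amplitude.  Raw counts follow
    ``gain * reflectance * K + dark + noise`` (K = counts per unit
    reflectance), the reference frame images the 20 % standard under the
    same gain, and the dark frame holds the dark level plus noise; all
    frames are quantized to the configured bit depth.
    """
    h, w = config.image_size
    n_bands = len(config.band_centers_nm)
    profile = np.asarray(template.reflectance_profile, dtype=np.float64)
    if len(profile) != n_bands:
        raise ValueError("template profile length must match band count")
    full_scale = 2**config.bit_depth - 1
    dark_level = round(0.05 * full_scale)
    counts_per_reflectance = 0.85 * full_scale

    factors = (
        BAND_TEXTURE_FACTORS[:n_bands]
        if n_bands <= len(BAND_TEXTURE_FACTORS)
        else np.ones(n_bands)
    )
    # texture contrast varies chromatically: each band's modulation depth
    # gets its own multiplicative jitter, independent of the band means
    if config.jitter_band_amplitude > 0:
        factors = factors * rng.uniform(
            1 - config.jitter_band_amplitude, 1 + config.jitter_band_amplitude, n_bands
        )
    amplitudes = template.texture_contrast * factors
    if np.any(profile * (1 + amplitudes) >= 1.0) or np.any(profile * (1 - amplitudes) <= 0.0):
        raise ValueError(
            f"texture contrast {template.texture_contrast} pushes reflectance "
            f"outside (0, 1) for profile {tuple(profile)}"
        )
    texture = _texture_field(template, (h, w), rng)
    reflectance = profile[np.newaxis, np.newaxis, :] * (
        1.0 + amplitudes[np.newaxis, np.newaxis, :] * texture[:, :, np.newaxis]
    )

    gain = _gain_field(config, rng)[:, :, np.newaxis]
    signal = gain * reflectance * counts_per_reflectance + dark_level
    ref_signal = gain[:, :, 0] * 0.2 * counts_per_reflectance + dark_level
    dark_signal = np.full((h, w), float(dark_level))
    if config.noise_sd > 0:
        signal = signal + rng.normal(0, config.noise_sd, signal.shape)
        # dark/reference frames are acquired as an average of many exposures
        # (standard practice), so their noise is reduced by sqrt(n_frames)
        frame_sd = config.noise_sd / np.sqrt(config.n_calibration_frames)
        ref_signal = ref_signal + rng.normal(0, frame_sd, ref_signal.shape)
        dark_signal = dark_signal + rng.normal(0, frame_sd, dark_signal.shape)
    raw = np.clip(np.round(signal), 0, full_scale).astype(np.uint16)
    ref = np.clip(np.round(ref_signal), 0, full_scale)
    dark = np.clip(np.round(dark_signal), 0, full_scale)

    cube = MultispectralCube(
        pixels=raw,
        band_centers_nm=config.band_centers_nm,
        bit_depth=config.bit_depth,
        is_calibrated=False,
    )
    frames = CalibrationFrames(dark=dark, reference=ref, reference_reflectance=0.20)
    mask = RoiMask(np.ones((h, w), dtype=bool))
    return cube, frames, mask


@dataclass(frozen=True)
class Sample:
    """One generated, calibrated sample with its drawn ground truth."""

    sample_id: str
    label: str
    cube: MultispectralCube
    mask: RoiMask
    truth: dict


@dataclass
class LabeledDataset:
    """Materialized collection of samples plus a ground-truth manifest."""

    samples: list
    manifest: pd.DataFrame

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])

    def __len__(self) -> int:
        return len(self.samples)


def _jitter_template(
    template: ClassTemplate, config: GeneratorConfig, rng: np.random.Generator
) -> ClassTemplate:
    profile = np.asarray(template.reflectance_profile)
    brightness = np.exp(rng.normal(0, config.jitter_brightness_sd))
    band_jitter = np.exp(rng.normal(0, config.jitter_band_sd, size=len(profile)))
    profile = np.clip(profile * brightness * band_jitter, 0.02, 0.95)
    lo, hi = config.jitter_contrast_range
    contrast = template.texture_contrast * rng.uniform(lo, hi)
    # keep reflectance inside (0, 1) under the worst-case band amplitude
    fmax = max(BAND_TEXTURE_FACTORS) * (1 + config.jitter_band_amplitude)
    contrast = min(contrast, 0.95 / fmax * min(1 / profile.max() - 1, 1))
    angle = template.stripe_angle_deg + rng.normal(0, config.jitter_angle_sd_deg)
    density = template.blob_density * rng.uniform(0.7, 1.3)
    return replace(
        template,
        reflectance_profile=tuple(profile),
        texture_contrast=float(max(contrast, 0.0)),
        stripe_angle_deg=float(angle),
        blob_density=float(density),
    )


def iter_dataset(config: GeneratorConfig, calibrated: bool = True) -> Iterator[Sample]:
    """Yield samples one at a time (constant memory); seeded and ordered.

    Sample order interleaves classes deterministically; each sample draws
    from its own child random stream, so results do not depend on how many
    samples are consumed.
    """
    templates = {t.name: t for t in config.scaled_templates()}
    for name in config.n_per_class:
        if name not in templates:
            raise ValueError(f"no template for class {name!r}")
    schedule = [
        (name, i) for name, count in config.n_per_class.items() for i in range(count)
    ]
    streams = np.random.SeedSequence(config.seed).spawn(len(schedule))
    for (name, i), seed_seq in zip(schedule, streams):
        rng = np.random.default_rng(seed_seq)
        jittered = _jitter_template(templates[name], config, rng)
        raw, frames, mask = generate_sample(jittered, config, rng)
        cube = calibrate(raw, frames) if calibrated else raw
        truth = {
            "texture_kind": jittered.texture_kind,
            "texture_contrast": jittered.texture_contrast,
            "stripe_angle_deg": jittered.stripe_angle_deg,
            "blob_density": jittered.blob_density,
            **{
                f"profile_{int(round(c))}nm": p
                for c, p in zip(config.band_centers_nm, jittered.reflectance_profile)
            },
        }
        if not calibrated:
            truth["frames"] = frames
        yield Sample(f"{name}_{i:04d}", name, cube, mask, truth)


def generate_dataset(config: GeneratorConfig, calibrated: bool = True) -> LabeledDataset:
    """Materialize the full dataset with its ground-truth manifest."""
    samples = list(iter_dataset(config, calibrated=calibrated))
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id, "class": s.label, "seed": config.seed}
        row.update({k: v for k, v in s.truth.items() if not isinstance(v, CalibrationFrames)})
        rows.append(row)
    return LabeledDataset(samples=samples, manifest=pd.DataFrame(rows))
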