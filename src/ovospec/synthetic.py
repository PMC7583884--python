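"""Synthetic egg cohorts, grade-dependent spectra, and renderable scenes.

The real study images 280 eggs (10/day for 28 days) under nine acquisition
geometries: dome-illuminated reflection, fibre transmission, and a fibre
source at incident angles 0° (pure scattering) through 60° (scattering mixed
with increasing surface reflection).  Those cubes were never deposited, so
this module generates cohorts with the statistical structure the downstream
analysis assumes:

* Haugh units decline linearly at −1.75 units/day from 85.70, with Gaussian
  egg-to-egg noise; grades AA/A/B1/B2 are the storage weeks 1–4.
* An egg's spectrum is a three-endmember mixture
  ``α·S_int + (1−α−β)·S_shell + β·S_src`` where only the interior endmember
  ``S_int`` carries freshness information (Gaussian absorption peaks whose
  amplitudes are affine in HU).  The scattered-light fraction α is largest at
  0° incidence and decays linearly with angle; under dome reflection almost
  all collected light is shell reflectance, and transmission additionally
  bleeds through a fraction of the raw source.  The shell endmember carries
  per-spectrum random shell-colour variation — informative of nothing — so
  modes dominated by shell light are noisy as well as uninformative.
* Spectra are then distorted multiplicatively and additively (work for
  MSC/SNV/detrend) plus per-band channel noise.
* Scenes are small cubes with elliptical egg regions, Lambertian shading,
  a few glare pixels, plus matching white and dark reference frames for
  black/white correction.

All randomness flows through explicit seeds; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .freshness import grade_of_day, haugh_unit, protein_height

logger = logging.getLogger(__name__)

SCATTER_ANGLES = (0, 10, 20, 30, 40, 50, 60)


@dataclass(frozen=True)
class AcquisitionMode:
    """One of the nine acquisition geometries.

    ``kind`` is ``reflection`` (dome source), ``transmission`` (fibre under
    the egg) or ``scatter`` (fibre at ``angle_deg``; 0° = pure scattering,
    10–60° = scattering/reflection mixtures).  ``angle_deg`` is defined iff
    ``kind == 'scatter'``.
    """

    kind: str
    angle_deg: Optional[int] = None

    def __post_init__(self):
        if self.kind not in ("reflection", "transmission", "scatter"):
            raise ValueError(f"unknown acquisition kind {self.kind!r}")
        if self.kind == "scatter":
            if self.angle_deg not in SCATTER_ANGLES:
                raise ValueError(
                    f"scatter angle must be one of {SCATTER_ANGLES}, "
                    f"got {self.angle_deg}")
        elif self.angle_deg is not None:
            raise ValueError(f"angle_deg is only defined for scatter modes")

    @property
    def label(self) -> str:
        return self.kind if self.kind != "scatter" else f"scatter_{self.angle_deg}"

    @classmethod
    def from_label(cls, label: str) -> "AcquisitionMode":
        if label in ("reflection", "transmission"):
            return cls(label)
        if label.startswith("scatter_"):
            return cls("scatter", int(label.split("_", 1)[1]))
        raise ValueError(f"unknown mode label {label!r}")


def all_modes() -> list[AcquisitionMode]:
    """The nine study modes: reflection, transmission, scatter 0°–60°."""
    return [AcquisitionMode("reflection"), AcquisitionMode("transmission")] + [
        AcquisitionMode("scatter", a) for a in SCATTER_ANGLES]


@dataclass(frozen=True)
class Spectrum:
    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "wavelengths_nm",
                           np.asarray(self.wavelengths_nm, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.wavelengths_nm.shape != self.values.shape:
            raise ValueError("wavelengths and values must have equal length")
        if self.wavelengths_nm.ndim != 1:
            raise ValueError("spectrum must be 1-D")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")


@dataclass(frozen=True)
class EggRecord:
    """One egg on one storage day, with one spectrum per acquisition mode."""

    egg_id: str
    day: int
    weight_g: float
    protein_height_mm: float
    haugh: float
    grade: str
    spectra: dict  # mode label -> Spectrum


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic cohort generator.

    Defaults encode the study: 256 bands over 400–1000 nm (VNIR camera at
    desk scale), HU = 85.70 − 1.75·day + N(0, 4²) (weekly HU sds of the real
    cohort span 3.6–5.5), weights uniform on the purchased mass range
    31.5–46.6 g, informative absorption centres in the visible/NIR regions
    where real grade differences concentrate, and a scattered-light fraction
    falling linearly from 0.9 at 0° incidence to 0.3 at 60°.
    """

    n_bands: int = 256
    wavelength_min_nm: float = 400.0
    wavelength_max_nm: float = 1000.0
    slope_per_day: float = -1.75
    intercept: float = 85.70
    haugh_noise_sd: float = 4.0
    weight_range_g: tuple[float, float] = (31.5, 46.6)
    informative_centers_nm: tuple[float, ...] = (450.0, 550.0, 680.0, 980.0)
    scatter_fraction_at_0: float = 0.9
    scatter_fraction_slope: float = 0.01   # per degree; 0.9 - 60*0.01 = 0.3
    reflection_scatter_fraction: float = 0.05
    transmission_scatter_fraction: float = 0.45
    transmission_bleed_fraction: float = 0.35
    multiplicative_sd: float = 0.10
    additive_sd: float = 0.05
    channel_noise_sd: float = 0.01
    shell_color_sd: float = 0.12
    seed: int = 0

    def __post_init__(self):
        if self.n_bands < 8:
            raise ValueError("n_bands must be >= 8")
        if not self.wavelength_min_nm < self.wavelength_max_nm:
            raise ValueError("wavelength_min must be < wavelength_max")
        for name in ("scatter_fraction_at_0", "reflection_scatter_fraction",
                     "transmission_scatter_fraction",
                     "transmission_bleed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.transmission_scatter_fraction + self.transmission_bleed_fraction > 1.0:
            raise ValueError("transmission fractions must sum to <= 1")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return np.linspace(self.wavelength_min_nm, self.wavelength_max_nm,
                           self.n_bands)


# ---------------------------------------------------------------------------
# Endmember spectra
# ---------------------------------------------------------------------------
# Peak widths (nm) and amplitude coefficients for the interior endmember.
# Amplitude of peak c is  a0_c + a1_c * (HU - 60)/30 : affine in normalised
# HU, with alternating signs so freshness moves peaks in both directions.
# The a1 magnitudes (~0.02 reflectance units per 30 HU) set the freshness
# signal against the 0.01 channel noise so that the signal-to-noise of HU
# readout degrades materially as the scattered fraction α falls.
_PEAK_WIDTHS = (22.0, 28.0, 30.0, 18.0)
_PEAK_A0 = (0.10, 0.14, 0.12, 0.08)
_PEAK_A1 = (0.024, -0.020, 0.022, -0.018)
# Shell-colour variation basis: a broad tilt and a pigment-like band.
_SHELL_PIGMENT_CENTER = 560.0
_SHELL_PIGMENT_WIDTH = 80.0


def _cycle(seq: Sequence[float], n: int) -> np.ndarray:
    return np.array([seq[i % len(seq)] for i in range(n)])


def interior_spectrum(haugh: float, wl: np.ndarray,
                      config: GeneratorConfig) -> np.ndarray:
    """Noise-free interior endmember S_int(λ; HU)."""
    z = (haugh - 60.0) / 30.0
    centers = np.asarray(config.informative_centers_nm, dtype=float)
    widths = _cycle(_PEAK_WIDTHS, centers.size)
    a0 = _cycle(_PEAK_A0, centers.size)
    a1 = _cycle(_PEAK_A1, centers.size)
    s = 0.40 + 0.25 * np.exp(-(((wl - 750.0) / 200.0) ** 2))
    for c, wdt, p0, p1 in zip(centers, widths, a0, a1):
        s = s + (p0 + p1 * z) * np.exp(-(((wl - c) / wdt) ** 2))
    return s


def shell_spectrum(wl: np.ndarray) -> np.ndarray:
    """Mean shell endmember S_shell(λ): smooth, brighter toward the NIR."""
    return 0.45 + 0.35 * (wl - 400.0) / 600.0 \
        - 0.06 * np.exp(-(((wl - _SHELL_PIGMENT_CENTER) / _SHELL_PIGMENT_WIDTH) ** 2))


def source_spectrum(wl: np.ndarray) -> np.ndarray:
    """Raw source endmember S_src(λ): flat (normalised halogen output)."""
    return np.ones_like(wl)


def mode_fractions(mode: AcquisitionMode,
                   config: GeneratorConfig) -> tuple[float, float]:
    """(α, β): scattered-light and source-bleed fractions of a mode."""
    if mode.kind == "reflection":
        return config.reflection_scatter_fraction, 0.0
    if mode.kind == "transmission":
        return (config.transmission_scatter_fraction,
                config.transmission_bleed_fraction)
    alpha = config.scatter_fraction_at_0 \
        - config.scatter_fraction_slope * mode.angle_deg
    return float(np.clip(alpha, 0.0, 1.0)), 0.0


def egg_spectrum(haugh: float, mode: AcquisitionMode, config: GeneratorConfig,
                 rng: np.random.Generator) -> Spectrum:
    """One distorted spectrum of an egg with the given Haugh unit.

    The random stream is consumed identically whatever the sd values, so a
    zero-noise config with the same seed reproduces the same draw positions.
    """
    if not np.isfinite(haugh):
        raise ValueError("haugh must be finite")
    wl = config.wavelengths_nm
    alpha, beta = mode_fractions(mode, config)

    shell = shell_spectrum(wl)
    c_tilt, c_pig = rng.standard_normal(2) * config.shell_color_sd
    shell = shell + c_tilt * (wl - 700.0) / 300.0 \
        + c_pig * np.exp(-(((wl - _SHELL_PIGMENT_CENTER)
                            / _SHELL_PIGMENT_WIDTH) ** 2))

    clean = (alpha * interior_spectrum(haugh, wl, config)
             + (1.0 - alpha - beta) * shell
             + beta * source_spectrum(wl))

    b = 1.0 + rng.standard_normal() * config.multiplicative_sd
    a = rng.standard_normal() * config.additive_sd
    noise = rng.standard_normal(wl.size) * config.channel_noise_sd
    values = b * clean + a + noise
    n_clip = int(np.sum(values < 0.0))
    if n_clip:
        logger.debug("clipped %d negative reflectances to 0", n_clip)
        values = np.clip(values, 0.0, None)
    return Spectrum(wl, values)


def undistorted_spectrum(haugh: float, mode: AcquisitionMode,
                         config: GeneratorConfig) -> Spectrum:
    """The noise-free mixture (distortion sds treated as zero)."""
    wl = config.wavelengths_nm
    alpha, beta = mode_fractions(mode, config)
    clean = (alpha * interior_spectrum(haugh, wl, config)
             + (1.0 - alpha - beta) * shell_spectrum(wl)
             + beta * source_spectrum(wl))
    return Spectrum(wl, clean)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(n_days: int, eggs_per_day: int,
                    modes: Sequence[AcquisitionMode],
                    config: GeneratorConfig) -> list[EggRecord]:
    """Simulate ``n_days × eggs_per_day`` graded eggs with per-mode spectra.

    HU = intercept + slope·day + N(0, haugh_noise_sd²); weight uniform on the
    configured range; protein height back-solved from the Haugh formula so
    the (h, w) → HU round trip is exact; grade from the storage week.
    """
    if n_days < 1 or eggs_per_day < 1:
        raise ValueError("n_days and eggs_per_day must be >= 1")
    if n_days > 28:
        raise ValueError("grading is defined for days 1..28 only")
    rng = np.random.default_rng(config.seed)
    records: list[EggRecord] = []
    for day in range(1, n_days + 1):
        for j in range(eggs_per_day):
            hu = (config.intercept + config.slope_per_day * day
                  + rng.standard_normal() * config.haugh_noise_sd)
            w = rng.uniform(*config.weight_range_g)
            h = protein_height(hu, w)
            spectra = {m.label: egg_spectrum(hu, m, config, rng)
                       for m in modes}
            records.append(EggRecord(
                egg_id=f"d{day:02d}e{j:02d}", day=day, weight_g=float(w),
                protein_height_mm=float(h), haugh=float(hu),
                grade=grade_of_day(day), spectra=spectra))
    return records


def cohort_to_frame(records: Sequence[EggRecord]):
    """Cohort as a long table: one row per egg × mode, band values as columns."""
    import pandas as pd

    rows = []
    for rec in records:
        for label, spec in rec.spectra.items():
            row = {"egg_id": rec.egg_id, "day": rec.day,
                   "weight_g": rec.weight_g, "haugh": rec.haugh,
                   "grade": rec.grade, "mode": label}
            row.update({f"{w:.3f}": v for w, v in
                        zip(spec.wavelengths_nm, spec.values)})
            rows.append(row)
    return pd.DataFrame(rows)


def cohort_matrix(records: Sequence[EggRecord], mode: AcquisitionMode):
    """(SpectraMatrix, grade labels) of one mode across a cohort."""
    from .preprocess import SpectraMatrix

    label = mode.label if isinstance(mode, AcquisitionMode) else str(mode)
    X = np.vstack([rec.spectra[label].values for rec in records])
    wl = records[0].spectra[label].wavelengths_nm
    ids = [rec.egg_id for rec in records]
    y = np.array([rec.grade for rec in records])
    return SpectraMatrix(X, wl, ids), y


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

#: Flat-field background reflectance of the sample stage.
_BACKGROUND_LEVEL = 0.15
_DARK_LEVEL = 0.05
#: Calibration frames are averages of many acquisitions; their per-pixel
#: noise is this fraction of the raw channel noise.
_CALIBRATION_NOISE_FACTOR = 0.1
_GLARE_PIXELS = 3


def _gain(wl: np.ndarray) -> np.ndarray:
    """Detector × source gain curve (≥ 1 so corrected noise never inflates)."""
    return 1.0 + 0.4 * np.exp(-(((wl - 650.0) / 260.0) ** 2))


def _ellipse_mask(rows: int, cols: int, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[0:rows, 0:cols]
    return (((rr - center[0]) / axes[0]) ** 2
            + ((cc - center[1]) / axes[1]) ** 2) <= 1.0


def render_scene(spectra: Sequence[Spectrum], layout: Sequence[tuple],
                 image_size: tuple[int, int], config: GeneratorConfig,
                 rng: np.random.Generator):
    """Render (raw, white, dark) cubes of eggs on a dark stage.

    ``layout`` holds one ``(center_rc, semi_axes_rc)`` ellipse per spectrum;
    ellipses must be disjoint and inside the image.  Egg pixels carry their
    spectrum scaled by Lambertian shading in [0.6, 1]; a few glare pixels per
    egg carry the flat source spectrum.  Black/white correction of the raw
    cube recovers shading × spectrum up to noise.
    """
    from .hsi_io import Hypercube

    if len(spectra) != len(layout):
        raise ValueError("need exactly one ellipse per spectrum")
    rows, cols = image_size
    if not spectra:
        wl = config.wavelengths_nm
    else:
        wl = spectra[0].wavelengths_nm
    bands = wl.size

    masks = []
    for center, axes in layout:
        if (center[0] - axes[0] < 0 or center[0] + axes[0] >= rows
                or center[1] - axes[1] < 0 or center[1] + axes[1] >= cols):
            raise ValueError(f"ellipse {center}, {axes} exceeds image bounds")
        masks.append(_ellipse_mask(rows, cols, center, axes))
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if np.any(masks[i] & masks[j]):
                raise ValueError(f"ellipses {i} and {j} overlap")

    gain = _gain(wl)
    ideal = np.broadcast_to(_BACKGROUND_LEVEL, (rows, cols, bands)).copy()
    for (center, axes), mask, spec in zip(layout, masks, spectra):
        rr, cc = np.nonzero(mask)
        r2 = (((rr - center[0]) / axes[0]) ** 2
              + ((cc - center[1]) / axes[1]) ** 2)
        shading = 0.6 + 0.4 * np.sqrt(np.clip(1.0 - r2, 0.0, 1.0))
        ideal[rr, cc, :] = shading[:, None] * spec.values[None, :]
        n_glare = min(_GLARE_PIXELS, rr.size)
        glare_idx = rng.choice(rr.size, size=n_glare, replace=False)
        ideal[rr[glare_idx], cc[glare_idx], :] = source_spectrum(wl)[None, :]

    noise = config.channel_noise_sd
    raw = (_DARK_LEVEL + gain[None, None, :] * ideal
           + rng.standard_normal((rows, cols, bands)) * noise)
    white = (_DARK_LEVEL + gain[None, None, :]
             + rng.standard_normal((rows, cols, bands))
             * noise * _CALIBRATION_NOISE_FACTOR)
    dark = (_DARK_LEVEL
            + rng.standard_normal((rows, cols, bands))
            * noise * _CALIBRATION_NOISE_FACTOR)
    return (Hypercube(raw, wl), Hypercube(white, wl), Hypercube(dark, wl))
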