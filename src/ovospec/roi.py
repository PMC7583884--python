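"""Automatic egg ROI extraction from corrected cubes.

Two-step procedure mirroring a conveyor-line workflow: (1) build a
pseudo-RGB view (650/550/450 nm), binarise, close small defects
(dilation then erosion), label connected components and fit one expanded
ellipse per component; (2) average each ellipse's pixel spectra into one
spectrum per egg.  Fitting an ellipse — rather than using the raw threshold
mask — keeps interior glare pixels inside the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .hsi_io import Hypercube
from .preprocess import SpectraMatrix


@dataclass(frozen=True)
class MaskParams:
    """Threshold/morphology/ellipse parameters of the mask step.

    ``threshold`` is ``"otsu"`` or a fixed float on the grayscale image;
    ``expand_factor`` inflates the fitted semi-axes (1.0–1.5).
    """

    threshold: Union[str, float] = "otsu"
    morph_radius_px: int = 2
    expand_factor: float = 1.05
    min_area_px: int = 20

    def __post_init__(self):
        if isinstance(self.threshold, str) and self.threshold != "otsu":
            raise ValueError("threshold must be 'otsu' or a number")
        if self.morph_radius_px < 0:
            raise ValueError("morph_radius_px must be >= 0")
        if not 1.0 <= self.expand_factor <= 1.5:
            raise ValueError("expand_factor must lie in [1, 1.5]")


@dataclass
class RoiMask:
    """Labelled elliptical egg masks: 0 = background, k >= 1 = egg k."""

    labels: np.ndarray
    ellipses: dict  # label -> (center_rc, semi_axes_rc)
    params: MaskParams

    @property
    def n_rois(self) -> int:
        return len(self.ellipses)


def pseudo_rgb(cube: Hypercube, r_nm: float = 650.0, g_nm: float = 550.0,
               b_nm: float = 450.0) -> np.ndarray:
    """(lines, samples, 3) image from the bands nearest 650/550/450 nm.

    Ties between equidistant bands resolve to the lower wavelength; a request
    outside the cube's wavelength range raises.
    """
    wl = cube.wavelengths_nm
    channels = []
    for target in (r_nm, g_nm, b_nm):
        if not wl.min() <= target <= wl.max():
            raise ValueError(
                f"requested wavelength {target} nm outside cube range "
                f"[{wl.min()}, {wl.max()}]")
        idx = int(np.argmin(np.abs(wl - target)))  # argmin takes first = lower
        channels.append(cube.data[:, :, idx])
    return np.stack(channels, axis=-1)


def egg_mask(image: np.ndarray, params: MaskParams = MaskParams()) -> RoiMask:
    """Threshold + closing + connected components + expanded ellipse fit.

    Components are numbered in raster order of their centroids (top-most,
    then left-most, gets label 1).  Per component the ellipse is centred at
    the centroid with semi-axes half the maximum vertical/horizontal extents,
    inflated by ``expand_factor``.  An image with no surviving component
    returns an empty mask (all zeros) rather than raising.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    gray = image.mean(axis=-1) if image.ndim == 3 else image
    if image.ndim not in (2, 3):
        raise ValueError("image must be 2-D grayscale or 3-D RGB")

    if params.threshold == "otsu":
        thr = threshold_otsu(gray)
    else:
        thr = float(params.threshold)
    binary = gray > thr
    if params.morph_radius_px > 0:
        selem = morphology.disk(params.morph_radius_px)
        binary = morphology.erosion(morphology.dilation(binary, selem), selem)

    components = measure.label(binary, connectivity=2)
    props = [p for p in measure.regionprops(components)
             if p.area >= params.min_area_px]
    props.sort(key=lambda p: (p.centroid[0], p.centroid[1]))  # raster order

    labels = np.zeros(gray.shape, dtype=int)
    ellipses: dict[int, tuple] = {}
    rr, cc = np.mgrid[0:gray.shape[0], 0:gray.shape[1]]
    for k, p in enumerate(props, start=1):
        center = p.centroid
        rows = p.bbox[2] - p.bbox[0]      # max vertical extent
        cols = p.bbox[3] - p.bbox[1]      # max horizontal extent
        axes = (rows / 2.0 * params.expand_factor,
                cols / 2.0 * params.expand_factor)
        inside = (((rr - center[0]) / axes[0]) ** 2
                  + ((cc - center[1]) / axes[1]) ** 2) <= 1.0
        labels[inside] = k
        ellipses[k] = (center, axes)
    return RoiMask(labels, ellipses, params)


def roi_mean_spectra(cube: Hypercube, mask: RoiMask) -> SpectraMatrix:
    """Per-ROI unweighted mean spectrum, one row per label in label order."""
    if mask.labels.shape != cube.data.shape[:2]:
        raise ValueError(
            f"mask shape {mask.labels.shape} != cube spatial shape "
            f"{cube.data.shape[:2]}")
    rows = []
    ids = []
    for k in sorted(mask.ellipses):
        sel = mask.labels == k
        if not sel.any():
            raise ValueError(f"ROI label {k} has no pixels")
        rows.append(cube.data[sel].mean(axis=0))
        ids.append(f"roi{k}")
    X = np.vstack(rows) if rows else np.empty((0, cube.bands))
    return SpectraMatrix(X, cube.wavelengths_nm, ids)
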