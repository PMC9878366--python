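"""Calibrated digital surface analysis of tattoo photographs.

Mirrors a manual image-analysis protocol: calibrate the pixel scale from a
known physical distance in the photograph, convert to 8-bit grayscale,
select ink pixels by thresholding (ink is darker than skin), and average the
measured area over three thresholds to damp sensitivity to the exact cutoff.
Color-resolved areas come from deterministic nearest-prototype
classification in CIELAB, with skin/background classes discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from skimage import color as skcolor


class CalibrationError(ValueError):
    """Non-positive calibration distances or scale."""


class ThresholdError(ValueError):
    """Threshold outside the image intensity range, or constant image."""


#: RGB prototypes (0-255) per canonical color class used for classification.
COLOR_PROTOTYPES_RGB: dict[str, tuple[int, int, int]] = {
    "black_gray": (40, 40, 40),
    "red": (200, 30, 30),
    "orange_yellow": (240, 170, 40),
    "green": (30, 140, 60),
    "blue": (40, 70, 200),
    "violet_pink": (190, 80, 170),
    "brown": (120, 70, 40),
    "white": (235, 235, 240),
    "skin": (224, 182, 150),
    "background": (255, 255, 255),
}

#: Classes treated as non-tattoo and discarded from area measurements.
BACKGROUND_CLASSES: tuple[str, ...] = ("skin", "background")


def calibrate_scale(pixel_distance: float, physical_distance_cm: float) -> float:
    """Pixels per cm from a known in-image distance."""
    if pixel_distance <= 0 or physical_distance_cm <= 0:
        raise CalibrationError(
            f"calibration distances must be positive, got {pixel_distance} px / "
            f"{physical_distance_cm} cm"
        )
    return pixel_distance / physical_distance_cm


@dataclass(frozen=True)
class CalibratedImage:
    """Raster (grayscale or RGB, 0-255) with a pixels-per-cm scale."""

    pixels: np.ndarray
    scale_px_per_cm: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.scale_px_per_cm <= 0:
            raise CalibrationError(f"scale must be positive, got {self.scale_px_per_cm}")
        if self.pixels.size == 0:
            raise ValueError("image raster is empty")
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"expected 2-D grayscale or 3-D RGB raster, got ndim={self.pixels.ndim}")

    @classmethod
    def from_file(cls, path, scale_px_per_cm: float) -> "CalibratedImage":
        import imageio.v3 as iio

        return cls(np.asarray(iio.imread(path)), scale_px_per_cm, provenance=str(path))

    def to_gray_u8(self) -> np.ndarray:
        """8-bit grayscale view of the raster."""
        px = self.pixels
        if px.ndim == 3:
            gray = skcolor.rgb2gray(px[..., :3])  # float in [0, 1]
            return np.clip(np.round(gray * 255.0), 0, 255).astype(np.uint8)
        if px.dtype == np.uint8:
            return px
        arr = np.asarray(px, dtype=float)
        if arr.max() <= 1.0:
            arr = arr * 255.0
        return np.clip(np.round(arr), 0, 255).astype(np.uint8)

    def px2_to_cm2(self, pixel_count: float) -> float:
        return pixel_count / self.scale_px_per_cm**2


@dataclass(frozen=True)
class SurfaceMeasurement:
    """Thresholded surface areas; total is the mean of the three thresholds."""

    total_area_cm2: float
    per_threshold_areas_cm2: tuple[float, float, float]
    per_color_area_cm2: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        mean = sum(self.per_threshold_areas_cm2) / 3.0
        if abs(mean - self.total_area_cm2) > 1e-9 * max(1.0, mean):
            raise ValueError("total_area_cm2 must equal the mean of per-threshold areas")
        if any(a < 0 for a in self.per_threshold_areas_cm2):
            raise ValueError("areas must be non-negative")


def auto_threshold(image: CalibratedImage) -> int:
    """Between-class-variance-maximizing (Otsu) cutoff on the 8-bit grayscale.

    When several cutoffs maximize the criterion (the plateau between two
    clean modes), the plateau midpoint is returned, so the three-threshold
    set {cutoff − δ, cutoff, cutoff + δ} stays clear of both modes.
    """
    gray = image.to_gray_u8()
    if int(gray.min()) == int(gray.max()):
        raise ThresholdError("constant image has no separable threshold")
    hist = np.bincount(gray.ravel(), minlength=256).astype(float)
    total = hist.sum()
    w0 = np.cumsum(hist)  # weight of class "<= t"
    m0 = np.cumsum(hist * np.arange(256))
    w1 = total - w0
    mean_total = m0[-1] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (m0[-1] - m0) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.nan_to_num(var_between, nan=-1.0)
    best = var_between.max()
    plateau = np.flatnonzero(var_between >= best * (1 - 1e-12))
    return int(round((plateau[0] + plateau[-1]) / 2))


def threshold_set(image: CalibratedImage, delta: int = 10) -> tuple[int, int, int]:
    """Three thresholds {auto − δ, auto, auto + δ}, clipped to the 8-bit range."""
    t = auto_threshold(image)
    return (
        int(np.clip(t - delta, 0, 255)),
        t,
        int(np.clip(t + delta, 0, 255)),
    )


def binary_area(
    image: CalibratedImage,
    thresholds: Sequence[int],
    invert: bool = False,
) -> SurfaceMeasurement:
    """Ink area at three cutoffs, averaged.

    At each threshold the foreground is pixels at or below the cutoff (ink is
    darker than skin; ``invert=True`` selects pixels above it for atypical
    images). Areas are pixel counts divided by scale².
    """
    if len(thresholds) != 3:
        raise ValueError(f"exactly three thresholds required, got {len(thresholds)}")
    gray = image.to_gray_u8()
    lo, hi = int(gray.min()), int(gray.max())
    areas = []
    for t in thresholds:
        if not 0 <= t <= 255:
            raise ThresholdError(f"threshold {t} outside the 8-bit intensity range")
        mask = gray > t if invert else gray <= t
        areas.append(image.px2_to_cm2(int(mask.sum())))
    return SurfaceMeasurement(
        total_area_cm2=sum(areas) / 3.0,
        per_threshold_areas_cm2=(areas[0], areas[1], areas[2]),
    )


def color_class_area(
    image: CalibratedImage,
    classes: Sequence[str],
    prototypes_rgb: Optional[Mapping[str, tuple[int, int, int]]] = None,
) -> dict[str, float]:
    """Per-color ink area (cm²) by nearest-prototype classification in CIELAB.

    Every pixel is assigned to the perceptually nearest prototype among the
    requested classes plus the skin/background classes; the latter are
    discarded, and each remaining class's area is its pixel count / scale².
    """
    if not classes:
        raise ValueError("at least one color class is required")
    if image.pixels.ndim != 3:
        raise ValueError("color classification requires an RGB image")
    protos = dict(COLOR_PROTOTYPES_RGB if prototypes_rgb is None else prototypes_rgb)
    labels = list(dict.fromkeys([*classes, *BACKGROUND_CLASSES]))
    missing = [c for c in labels if c not in protos]
    if missing:
        raise KeyError(f"no prototype for classes {missing}")
    proto_rgb = np.asarray([protos[c] for c in labels], dtype=float) / 255.0
    proto_lab = skcolor.rgb2lab(proto_rgb.reshape(1, -1, 3)).reshape(-1, 3)
    rgb = np.asarray(image.pixels[..., :3], dtype=float)
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    lab = skcolor.rgb2lab(rgb).reshape(-1, 3)
    dists = ((lab[:, None, :] - proto_lab[None, :, :]) ** 2).sum(axis=2)
    assignment = dists.argmin(axis=1)
    out: dict[str, float] = {}
    for idx, label in enumerate(labels):
        if label in BACKGROUND_CLASSES:
            continue
        out[label] = image.px2_to_cm2(int((assignment == idx).sum()))
    return out
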