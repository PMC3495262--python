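"""Constituent area fractions of the arterial wall.

Three stain families are quantified, each as positive pixels ÷ wall pixels:

* **immunofluorescence** (αSMA, CD34, MAC387) — an intensity threshold is
  calibrated per acquisition batch against a matched negative control
  (primary antibody omitted) and then applied to every sample in the batch;
* **VVG elastin** — dark pixels in the brightfield image, after removing
  small compact connected components (nuclei) below a blob-size threshold;
* **PSR collagen** — red-dominant pixels in the brightfield image define
  the region of interest; within it, any pixel of the co-registered
  polarized image brighter than a black threshold counts as birefringent
  collagen.

Threshold calibration subtracts the negative control's intensity histogram
from the sample's (both normalized to unit mass, because sample and control
walls differ in pixel count) and places the cut-off at the minimum intensity
of the highest-intensity contiguous run of positive difference — the
intensity band occupied by specific signal and absent from the control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops

from .errors import CalibrationLookupError, DegenerateInputError
from .masks import ArteryImageSet

__all__ = [
    "ThresholdCalibration",
    "StainFractionRecord",
    "NOTHING_POSITIVE",
    "calibrate_threshold",
    "area_fraction",
    "elastin_fraction_vvg",
    "collagen_fraction_psr",
    "batch_quantify",
]

#: Sentinel threshold meaning "sample indistinguishable from control".
NOTHING_POSITIVE = 256


@dataclass
class ThresholdCalibration:
    channel: str
    threshold: int  # 0..255, or NOTHING_POSITIVE
    batch_key: tuple[str, str]
    control_histogram: np.ndarray  # 256-bin counts
    sample_histogram: np.ndarray

    @property
    def nothing_positive(self) -> bool:
        return self.threshold >= NOTHING_POSITIVE


@dataclass
class StainFractionRecord:
    stain: str
    fraction: float
    positive_pixels: int
    wall_pixels: int
    threshold: int
    min_blob_size: int | None = None
    black_threshold: int | None = None

    def __post_init__(self) -> None:
        if self.wall_pixels <= 0:
            raise DegenerateInputError("wall mask is empty")
        assert self.fraction == self.positive_pixels / self.wall_pixels


def _masked_histogram(channel: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = np.asarray(channel)[mask]
    return np.bincount(vals.astype(np.int64).ravel(), minlength=256)[:256]


def calibrate_threshold(
    sample_channel: np.ndarray,
    sample_wall: np.ndarray,
    control_channel: np.ndarray,
    control_wall: np.ndarray,
    *,
    channel: str = "gray",
    batch_key: tuple[str, str] = ("default", "default"),
    min_run_mass: float = 1e-3,
) -> ThresholdCalibration:
    """Calibrate a positive-stain threshold against a negative control.

    Runs of the positive difference histogram carrying less than
    ``min_run_mass`` of the sample's mass are ignored so a handful of
    outlier pixels cannot masquerade as the signal band.  If no qualifying
    run exists the sentinel ``NOTHING_POSITIVE`` (256) is returned, meaning
    every fraction computed with it is zero.
    """
    if not sample_wall.any() or not control_wall.any():
        raise DegenerateInputError("sample and control wall masks must be non-empty")
    sample_hist = _masked_histogram(sample_channel, sample_wall)
    control_hist = _masked_histogram(control_channel, control_wall)
    sample_p = sample_hist / sample_hist.sum()
    control_p = control_hist / control_hist.sum()
    diff = sample_p - control_p
    positive = diff > 0

    threshold = NOTHING_POSITIVE
    run_start = None
    best = None
    for i in range(256):
        if positive[i] and run_start is None:
            run_start = i
        if run_start is not None and (not positive[i] or i == 255):
            run_end = i + 1 if positive[i] else i
            if sample_p[run_start:run_end].sum() >= min_run_mass:
                best = run_start  # later (higher-intensity) runs overwrite
            run_start = None
    if best is not None:
        threshold = int(np.clip(best, 0, 255))
    else:
        warnings.warn(
            "sample indistinguishable from negative control; "
            "returning sentinel threshold 256",
            stacklevel=2,
        )
    return ThresholdCalibration(
        channel=channel,
        threshold=threshold,
        batch_key=batch_key,
        control_histogram=control_hist,
        sample_histogram=sample_hist,
    )


def area_fraction(
    channel: np.ndarray,
    wall: np.ndarray,
    threshold: int,
    stain: str = "stain",
) -> StainFractionRecord:
    """Positive-pixel fraction of the wall at a fixed threshold."""
    if not 0 <= threshold <= NOTHING_POSITIVE:
        raise ValueError("threshold must lie in [0, 256]")
    n_wall = int(wall.sum())
    if n_wall == 0:
        raise DegenerateInputError("wall mask is empty")
    positive = int(np.count_nonzero(np.asarray(channel, dtype=np.int64)[wall] >= threshold))
    return StainFractionRecord(
        stain=stain,
        fraction=positive / n_wall,
        positive_pixels=positive,
        wall_pixels=n_wall,
        threshold=threshold,
    )


def elastin_fraction_vvg(
    vvg: np.ndarray,
    wall: np.ndarray,
    elastin_threshold: int = 100,
    min_blob_size: int = 0,
    min_circularity: float = 0.5,
) -> StainFractionRecord:
    """Elastin fraction from a VVG brightfield image.

    Elastin stains dark, so pixels at or below ``elastin_threshold`` inside
    the wall are candidates.  Connected components smaller than
    ``min_blob_size`` pixels that are also compact (circularity
    4πA/P² ≥ ``min_circularity``) are classified as nuclei and removed;
    thin elastic fragments fail the compactness test and survive.
    """
    n_wall = int(wall.sum())
    if n_wall == 0:
        raise DegenerateInputError("wall mask is empty")
    dark = (np.asarray(vvg, dtype=np.int64) <= elastin_threshold) & wall
    if min_blob_size > 0 and dark.any():
        labels = label(dark, connectivity=2)
        remove = np.zeros(labels.max() + 1, dtype=bool)
        for region in regionprops(labels):
            if region.area < min_blob_size:
                perim = region.perimeter
                circ = (
                    4.0 * np.pi * region.area / perim**2 if perim > 0 else 1.0
                )
                if circ >= min_circularity:
                    remove[region.label] = True
        dark = dark & ~remove[labels]
    positive = int(dark.sum())
    return StainFractionRecord(
        stain="elastin",
        fraction=positive / n_wall,
        positive_pixels=positive,
        wall_pixels=n_wall,
        threshold=elastin_threshold,
        min_blob_size=min_blob_size,
    )


def collagen_fraction_psr(
    brightfield: np.ndarray,
    polarized: np.ndarray,
    wall: np.ndarray,
    red_margin: int = 20,
    black_threshold: int = 30,
) -> StainFractionRecord:
    """Collagen fraction from a picrosirius-red brightfield/polarized pair.

    The red-stained region of interest is taken as pixels whose red channel
    exceeds both green and blue by ``red_margin``; within ROI ∩ wall, a
    polarized-light pixel brighter than ``black_threshold`` ("not black")
    is birefringent collagen.  Fraction is positives over all wall pixels.
    """
    if brightfield.shape[:2] != polarized.shape[:2]:
        raise ValueError("brightfield and polarized images are not registered")
    if brightfield.ndim != 3 or brightfield.shape[2] < 3:
        raise ValueError("brightfield must be an RGB image")
    n_wall = int(wall.sum())
    if n_wall == 0:
        raise DegenerateInputError("wall mask is empty")
    bf = brightfield.astype(np.int64)
    red_roi = (bf[..., 0] >= bf[..., 1] + red_margin) & (
        bf[..., 0] >= bf[..., 2] + red_margin
    )
    positive_mask = red_roi & wall & (np.asarray(polarized, dtype=np.int64) > black_threshold)
    positive = int(positive_mask.sum())
    return StainFractionRecord(
        stain="collagen",
        fraction=positive / n_wall,
        positive_pixels=positive,
        wall_pixels=n_wall,
        threshold=red_margin,
        black_threshold=black_threshold,
    )


def batch_quantify(
    samples: list[tuple[str, ArteryImageSet, np.ndarray]],
    calibrations: dict[tuple[str, str], ThresholdCalibration],
    stains: tuple[str, ...] = ("sma", "cd34", "mac387"),
) -> pd.DataFrame:
    """Apply per-batch calibrations across a set of fluorescence images.

    ``samples`` is a list of (image_id, image set, wall mask); each stain of
    each image is thresholded with the calibration registered for
    ``(objective, stain)``.  Output has one row per (image, stain), sorted.
    """
    rows = []
    for image_id, images, wall in samples:
        objective = images.batch_key[0]
        for stain in stains:
            key = (objective, stain)
            if key not in calibrations:
                raise CalibrationLookupError(
                    f"no calibration for batch key {key!r}"
                )
            cal = calibrations[key]
            rec = area_fraction(images.channels[stain], wall, cal.threshold, stain)
            rows.append(
                {
                    "image_id": image_id,
                    "stain": stain,
                    "fraction": rec.fraction,
                    "positive_pixels": rec.positive_pixels,
                    "wall_pixels": rec.wall_pixels,
                    "threshold": rec.threshold,
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["image_id", "stain"], kind="mergesort")
        .reset_index(drop=True)
    )
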