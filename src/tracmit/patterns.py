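"""Micropattern detection and single-cell occupancy filtering.

The micropatterns are the only static structures in the field, so a
per-pixel minimum-intensity projection over time isolates them; the
projection is median-smoothed, thresholded with Huang's fuzzy-entropy
method, and connected components are kept if their physical area matches
the expected micropattern area.  Each surviving L contributes one
analysis box anchored at the L's lower-left corner.

Occupancy is scored per box with fStDev — the temporal standard
deviation divided by the temporal mean, averaged over the box.
Normalising by the mean makes the score invariant to the overall
brightness of the chromatin transgene, so one bandpass separates empty
boxes (low score) from crowded ones (high score) across cells of very
different expression levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import disk

from .config import PipelineConfig
from .errors import MaskCoverageError, ZeroMeanError
from .stack import TimeLapseStack
from .thresholds import huang_threshold

__all__ = [
    "PatternROI",
    "min_intensity_projection",
    "detect_pattern_rois",
    "temporal_projections",
    "fstdev_score",
    "filter_by_occupancy",
]


@dataclass
class PatternROI:
    """One detected micropattern and its analysis box.

    ``anchor`` is the (row, col) of the L's lower-left corner — the
    maximum-row, minimum-col corner of the thresholded component.  The
    box is ``(row0, col0, height, width)`` in pixels, fully inside the
    image.  ``status`` is refined as the pipeline progresses:
    ``analyzable_candidate`` -> ``analyzable`` or ``no_division``.
    """

    pattern_id: int
    anchor: tuple[int, int]
    box: tuple[int, int, int, int]
    fstdev: float = float("nan")
    status: str = "analyzable_candidate"

    def box_slices(self) -> tuple[slice, slice]:
        r0, c0, h, w = self.box
        return slice(r0, r0 + h), slice(c0, c0 + w)


def min_intensity_projection(stack: TimeLapseStack) -> np.ndarray:
    """Per-pixel minimum over valid frames.

    Static structures (micropatterns) survive; anything transient (a
    moving cell) is suppressed to background.  Raises
    :class:`MaskCoverageError` if some pixel is valid in zero frames.
    """
    pixels = stack.pixels.astype(np.float64)
    if stack.mask is None:
        return pixels.min(axis=0)
    mask = stack.mask
    counts = mask.sum(axis=0)
    if np.any(counts == 0):
        raise MaskCoverageError("some pixels are valid in zero frames")
    masked = np.where(mask, pixels, np.inf)
    return masked.min(axis=0)


def temporal_projections(stack: TimeLapseStack) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel temporal standard deviation (population) and mean over
    valid frames."""
    pixels = stack.pixels.astype(np.float64)
    if stack.mask is None:
        return pixels.std(axis=0, ddof=0), pixels.mean(axis=0)
    mask = stack.mask
    counts = mask.sum(axis=0)
    if np.any(counts == 0):
        raise MaskCoverageError("some pixels are valid in zero frames")
    vals = np.where(mask, pixels, 0.0)
    mean = vals.sum(axis=0) / counts
    var = np.where(mask, (pixels - mean) ** 2, 0.0).sum(axis=0) / counts
    return np.sqrt(var), mean


def detect_pattern_rois(
    minint_image: np.ndarray,
    config: PipelineConfig,
    pixel_size_um: float,
) -> list[PatternROI]:
    """Find L-shaped micropatterns on the MinInt image and set their boxes.

    Median filter -> Huang threshold -> connected components -> physical
    area bandpass -> lower-left anchor -> box at ``anchor +
    anchor_offset_px``.  Components whose box would leave the image are
    dropped.  IDs are ordered by (anchor row, anchor col).
    """
    smoothed = ndi.median_filter(
        np.asarray(minint_image, dtype=np.float64),
        footprint=disk(config.median_radius_px),
    )
    thr = huang_threshold(smoothed)
    mask = smoothed > thr
    labels, n_comp = ndi.label(mask)
    if n_comp == 0:
        return []
    lo_um2, hi_um2 = config.pattern_area_um2_band
    px_area_um2 = pixel_size_um**2
    box_h, box_w = config.roi_box_px(pixel_size_um)
    dy, dx = config.anchor_offset_px
    H, W = minint_image.shape
    found: list[tuple[tuple[int, int], tuple[int, int, int, int]]] = []
    objects = ndi.find_objects(labels)
    for idx, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        comp = labels[slc] == idx
        area_um2 = comp.sum() * px_area_um2
        if not (lo_um2 <= area_um2 <= hi_um2):
            continue
        rows, cols = np.nonzero(comp)
        anchor = (slc[0].start + int(rows.max()), slc[1].start + int(cols.min()))
        r0 = anchor[0] + dy
        c0 = anchor[1] + dx
        if r0 < 0 or c0 < 0 or r0 + box_h > H or c0 + box_w > W:
            continue
        found.append((anchor, (r0, c0, box_h, box_w)))
    found.sort(key=lambda item: item[0])
    return [
        PatternROI(pattern_id=i, anchor=anchor, box=box)
        for i, (anchor, box) in enumerate(found)
    ]


def fstdev_score(
    roi: PatternROI,
    stdev_image: np.ndarray,
    mean_image: np.ndarray,
    mode: str = "mean_of_ratio",
) -> float:
    """Occupancy score of one box.

    ``mean_of_ratio`` (default) averages the per-pixel stdev/mean ratio
    image inside the box, excluding zero-mean pixels; ``ratio_of_means``
    divides the box-mean stdev by the box-mean intensity.  Either way the
    score is invariant to a global intensity scaling of the stack.
    """
    rs, cs = roi.box_slices()
    s = np.asarray(stdev_image, dtype=np.float64)[rs, cs]
    m = np.asarray(mean_image, dtype=np.float64)[rs, cs]
    nz = m > 0
    if not np.any(nz):
        raise ZeroMeanError(f"pattern {roi.pattern_id}: all box pixels have zero mean")
    if mode == "ratio_of_means":
        return float(s[nz].mean() / m[nz].mean())
    return float((s[nz] / m[nz]).mean())


def filter_by_occupancy(
    rois: list[PatternROI],
    scores: list[float],
    config: PipelineConfig,
) -> list[PatternROI]:
    """Set each ROI's status from its fStDev score.

    The band is closed on both ends: a score inside ``fstdev_band`` keeps
    the ROI as ``analyzable_candidate``; below it the box is ``empty``,
    above it ``crowded``.  Only candidates proceed downstream.
    """
    if len(rois) != len(scores):
        raise ValueError("need exactly one score per ROI")
    lo, hi = config.fstdev_band
    out = []
    for roi, score in zip(rois, scores):
        roi.fstdev = float(score)
        if score < lo:
            roi.status = "empty"
        elif score > hi:
            roi.status = "crowded"
        else:
            roi.status = "analyzable_candidate"
        out.append(roi)
    return out
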