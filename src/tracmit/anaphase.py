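"""Anaphase-figure detection inside candidate boxes.

Condensed chromatin is enhanced with a scale-normalised, negated
Laplacian of Gaussian (bright blobs give positive response; the thin
pattern arms and broad interphase nuclei are suppressed at the chromatin
scale), hard-thresholded relative to the box's peak response, and closed
morphologically to heal fragmented figures.  An anaphase figure is then a
pair of segmented chromatin masses at a plausible separation, with
similar orientations and similar areas.  Repeated sightings of the same
figure at later time points are dropped, and a local intensity threshold
on the raw box flags crowded patterns that slipped through the fStDev
bandpass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import disk

from .config import PipelineConfig
from .errors import BimodalityError, ConstantImageError
from .patterns import PatternROI
from .thresholds import intermeans_threshold, intermodes_threshold

__all__ = [
    "ChromatinBlob",
    "AnaphaseEvent",
    "log_filter",
    "binarize_and_close",
    "extract_blobs",
    "detect_anaphase_pairs",
    "deduplicate_events",
    "crowding_filter",
    "fold_angle_difference_deg",
]

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ChromatinBlob:
    """A segmented condensed-chromatin component in one frame.

    ``orientation_deg`` is the major axis direction of the fitted
    second-moment ellipse, measured from the +x (column) axis,
    counter-clockwise in a y-up frame, in [0, 180).  Centroid coordinates
    are in full-frame pixels.
    """

    frame: int
    centroid: tuple[float, float]
    area_px: int
    orientation_deg: float
    major_px: float
    minor_px: float

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValueError("blob area must be >= 1 px")
        if not (self.major_px >= self.minor_px > 0):
            raise ValueError("need major >= minor > 0")
        if not (0.0 <= self.orientation_deg < 180.0):
            raise ValueError("orientation must lie in [0, 180)")

    @property
    def axis_ratio(self) -> float:
        return self.major_px / self.minor_px


@dataclass(frozen=True)
class AnaphaseEvent:
    """A validated pair of chromatin masses in one frame of one pattern."""

    pattern_id: int
    frame: int
    blob_a: ChromatinBlob
    blob_b: ChromatinBlob
    midpoint: tuple[float, float]
    separation_px: float
    axis_deg: float  # inter-centroid segment direction, [0, 180)


def fold_angle_difference_deg(a: float, b: float) -> float:
    """Orientation difference modulo 180, folded to [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def log_filter(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Scale-normalised, negated Laplacian of Gaussian.

    Bright compact features of scale ~``sigma_px`` yield strongly positive
    responses; constant regions yield zero.  The sigma^2 normalisation
    makes responses comparable across scales.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    img = np.asarray(image, dtype=np.float64)
    # remove the DC level first: the truncated discrete kernel does not sum
    # exactly to zero, so a constant offset would otherwise leak through
    img = img - img.mean()
    return -(sigma_px**2) * ndi.gaussian_laplace(img, sigma=sigma_px)


def binarize_and_close(
    response: np.ndarray,
    config: PipelineConfig,
    threshold: float | None = None,
) -> np.ndarray:
    """Hard-threshold a LoG response and morphologically close the mask.

    In the default relative mode the threshold is ``log_threshold_frac``
    times the maximum response of ``response`` (pass ``threshold`` to
    reuse a precomputed per-box value, e.g. the maximum over the box's
    whole time-lapse); in absolute mode ``log_threshold_abs`` is used.
    Threshold comparison is ``>=`` so a fraction of 1.0 keeps exactly the
    maximal pixel(s).  Closing uses a disk of ``closing_radius_px``.
    """
    resp = np.asarray(response, dtype=np.float64)
    if threshold is None:
        if config.log_threshold_mode == "absolute":
            threshold = config.log_threshold_abs
        else:
            threshold = config.log_threshold_frac * float(resp.max())
    if threshold <= 0:  # no blob-positive signal anywhere
        return np.zeros(resp.shape, dtype=bool)
    mask = resp >= threshold
    if not mask.any():
        return mask
    structure = disk(config.closing_radius_px).astype(bool)
    return ndi.binary_closing(mask, structure=structure)


def _ellipse_fit(comp_mask: np.ndarray) -> tuple[tuple[float, float], float, float, float]:
    """Centroid, orientation (deg, y-up from +x, [0,180)), major and minor
    axis lengths (px) of a binary component from its pixel covariance.

    A 1/12 px^2 term on the diagonal accounts for the finite extent of a
    pixel, so even a one-pixel-wide component has a positive minor axis.
    """
    coords = np.argwhere(comp_mask).astype(np.float64)
    centroid = coords.mean(axis=0)
    d = coords - centroid
    cov = d.T @ d / coords.shape[0] + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)  # ascending
    major = 4.0 * math.sqrt(max(evals[1], 0.0))
    minor = 4.0 * math.sqrt(max(evals[0], 0.0))
    vr, vc = evecs[:, 1]
    angle = math.degrees(math.atan2(-vr, vc)) % 180.0
    return (float(centroid[0]), float(centroid[1])), angle, major, minor


def extract_blobs(
    mask: np.ndarray,
    frame_index: int,
    roi: PatternROI,
    min_area_px: int = 1,
) -> list[ChromatinBlob]:
    """Connected components (8-connectivity) of a box-restricted mask as
    :class:`ChromatinBlob` records with full-frame centroids.

    ``min_area_px`` drops speckle components below the size of any real
    chromatin figure (the pipeline passes ``config.min_blob_area_px``)."""
    labels, n_comp = ndi.label(np.asarray(mask, dtype=bool), structure=_EIGHT_CONN)
    if n_comp == 0:
        return []
    r0, c0 = roi.box[0], roi.box[1]
    blobs = []
    for slc_idx, slc in enumerate(ndi.find_objects(labels), start=1):
        if slc is None:
            continue
        comp = labels[slc] == slc_idx
        if int(comp.sum()) < min_area_px:
            continue
        (cr, cc), angle, major, minor = _ellipse_fit(comp)
        blobs.append(
            ChromatinBlob(
                frame=frame_index,
                centroid=(r0 + slc[0].start + cr, c0 + slc[1].start + cc),
                area_px=int(comp.sum()),
                orientation_deg=angle,
                major_px=major,
                minor_px=minor,
            )
        )
    return blobs


def _pair_event(pattern_id: int, a: ChromatinBlob, b: ChromatinBlob) -> AnaphaseEvent:
    dr = b.centroid[0] - a.centroid[0]
    dc = b.centroid[1] - a.centroid[1]
    sep = math.hypot(dr, dc)
    axis = math.degrees(math.atan2(-dr, dc)) % 180.0
    mid = ((a.centroid[0] + b.centroid[0]) / 2.0, (a.centroid[1] + b.centroid[1]) / 2.0)
    return AnaphaseEvent(
        pattern_id=pattern_id,
        frame=a.frame,
        blob_a=a,
        blob_b=b,
        midpoint=mid,
        separation_px=sep,
        axis_deg=axis,
    )


def pair_is_valid(a: ChromatinBlob, b: ChromatinBlob, config: PipelineConfig) -> bool:
    """The three anaphase-pair constraints: separation band, orientation
    tolerance, area-ratio bound (all closed intervals)."""
    sep = math.hypot(b.centroid[0] - a.centroid[0], b.centroid[1] - a.centroid[1])
    lo, hi = config.pair_distance_band_px
    if not (lo <= sep <= hi):
        return False
    if config.pair_angle_mode == "axis":
        axis = math.degrees(
            math.atan2(-(b.centroid[0] - a.centroid[0]), b.centroid[1] - a.centroid[1])
        ) % 180.0
        d = max(
            fold_angle_difference_deg(a.orientation_deg, axis),
            fold_angle_difference_deg(b.orientation_deg, axis),
        )
    else:
        d = fold_angle_difference_deg(a.orientation_deg, b.orientation_deg)
    if d > config.pair_angle_tol_deg:
        return False
    ratio = max(a.area_px, b.area_px) / min(a.area_px, b.area_px)
    return ratio <= config.pair_area_ratio_max


def detect_anaphase_pairs(
    blobs: list[ChromatinBlob],
    pattern_id: int,
    config: PipelineConfig,
) -> list[AnaphaseEvent]:
    """All valid unordered pairs among one frame's blobs of one pattern.

    When several valid pairs share a blob, the pair with the smallest
    area ratio wins (ties broken by smallest separation), and the loser
    is dropped — one figure cannot belong to two anaphases.
    """
    candidates = []
    for i in range(len(blobs)):
        for j in range(i + 1, len(blobs)):
            a, b = blobs[i], blobs[j]
            if a.frame != b.frame:
                raise ValueError("pair detection runs per frame")
            if pair_is_valid(a, b, config):
                ratio = max(a.area_px, b.area_px) / min(a.area_px, b.area_px)
                sep = math.hypot(
                    b.centroid[0] - a.centroid[0], b.centroid[1] - a.centroid[1]
                )
                candidates.append((ratio, sep, i, j))
    candidates.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    used: set[int] = set()
    events = []
    for _, _, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        events.append(_pair_event(pattern_id, blobs[i], blobs[j]))
    return events


def deduplicate_events(
    events: list[AnaphaseEvent], dedupe_radius_px: float
) -> list[AnaphaseEvent]:
    """Drop re-sightings: an event is discarded when an earlier retained
    event of the same pattern has its midpoint within the dedupe radius
    (any later frame, not only the next).  Earliest frame wins."""
    kept: list[AnaphaseEvent] = []
    for ev in sorted(events, key=lambda e: (e.pattern_id, e.frame)):
        dup = False
        for prev in kept:
            if prev.pattern_id != ev.pattern_id or prev.frame > ev.frame:
                continue
            d = math.hypot(
                prev.midpoint[0] - ev.midpoint[0], prev.midpoint[1] - ev.midpoint[1]
            )
            if d <= dedupe_radius_px:
                dup = True
                break
        if not dup:
            kept.append(ev)
    return kept


def crowding_filter(
    frame_image: np.ndarray,
    minint_image: np.ndarray,
    roi: PatternROI,
    event: AnaphaseEvent,
    config: PipelineConfig,
) -> tuple[bool, int, str | None]:
    """Reject events whose box holds chromatin beyond the two anaphase
    masses.

    The static component (background + micropattern, i.e. the MinInt
    projection) is subtracted from the raw box crop so only cell signal
    remains; the residual is thresholded locally (intermodes by default —
    the more sensitive choice; intermeans optional), components below the
    nucleus-size floor are ignored, and any component not matching
    ``blob_a``/``blob_b`` counts as an extra cell.  If the local
    threshold cannot be computed the event is *kept* and flagged
    ``crowding_uncheckable`` — sensitivity over specificity.

    Returns ``(accepted, component count, flag)``.
    """
    rs, cs = roi.box_slices()
    residual = (
        np.asarray(frame_image, dtype=np.float64)[rs, cs]
        - np.asarray(minint_image, dtype=np.float64)[rs, cs]
    )
    np.clip(residual, 0.0, None, out=residual)
    try:
        if config.crowding_method == "intermeans":
            thr = intermeans_threshold(residual)
        else:
            thr = intermodes_threshold(residual)
    except (BimodalityError, ConstantImageError):
        return True, 2, "crowding_uncheckable"
    labels, n_comp = ndi.label(residual > thr, structure=_EIGHT_CONN)
    if n_comp == 0:
        return True, 0, "crowding_uncheckable"
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
    big = {i + 1 for i, a in enumerate(areas) if a >= config.min_nucleus_area_px}
    r0, c0 = roi.box[0], roi.box[1]
    matched = set()
    for blob in (event.blob_a, event.blob_b):
        br = int(round(blob.centroid[0] - r0))
        bc = int(round(blob.centroid[1] - c0))
        if 0 <= br < labels.shape[0] and 0 <= bc < labels.shape[1]:
            lab = labels[br, bc]
            if lab in big:
                matched.add(lab)
    extras = big - matched
    count = len(big)
    if extras:
        return False, count, "crowded_rejected"
    return True, count, None
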