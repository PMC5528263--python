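"""Backward tracking from anaphase to prometaphase.

An accepted anaphase event is walked back in time in two stages.  First,
*reunion*: scanning backwards, the intensity profile along the segment
joining the two anaphase masses on the (blob-positive) LoG image is
inspected; while the masses are separate the profile has two end peaks
with a low gap between them, and the first frame in which that gap
disappears is the last metaphase frame — the two chromosome sets were
still one plate, which also certifies that segregation succeeded.  The
component under the profile midpoint seeds the second stage.

Second, the plate is linked frame by frame backwards with a
nearest-neighbour (Brownian-motion) tracker: the closest shape-conformant
blob within a maximum displacement continues the track, up to
``max_gap_frames`` consecutive detection-free frames may be bridged, and
the track ends when the gap allowance is exhausted — by then the
chromatin no longer looks like a plate, i.e. prometaphase.  The earliest
linked frame is reported as metaphase start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .anaphase import AnaphaseEvent, ChromatinBlob
from .config import PipelineConfig
from .errors import ProfileError, SeedShapeError
from .patterns import PatternROI

__all__ = ["PlateTrack", "line_profile", "detect_reunion", "backtrack_plate", "plate_shape_ok"]


@dataclass
class PlateTrack:
    """The metaphase plate linked backwards from reunion to its first
    appearance.  ``plate_blobs`` is ordered from ``metaphase_start_frame``
    to ``reunion_frame``; bridged gap frames have no entry."""

    pattern_id: int
    anaphase_frame: int
    reunion_frame: int
    plate_blobs: list[ChromatinBlob] = field(default_factory=list)
    metaphase_start_frame: int = -1
    gaps_closed: int = 0
    truncated: bool = False  # track ran into frame 0 while still linking

    def __post_init__(self) -> None:
        if self.metaphase_start_frame < 0 and self.plate_blobs:
            self.metaphase_start_frame = self.plate_blobs[0].frame
        if self.plate_blobs and not (
            self.metaphase_start_frame <= self.reunion_frame < self.anaphase_frame
        ):
            raise ValueError("need metaphase_start <= reunion < anaphase")


def line_profile(
    image: np.ndarray,
    p1: tuple[float, float],
    p2: tuple[float, float],
    n_samples: int,
) -> np.ndarray:
    """``n_samples`` bilinear samples along the segment p1->p2, endpoints
    included.  Points are (row, col); both must lie inside the image."""
    image = np.asarray(image, dtype=np.float64)
    if n_samples < 2:
        raise ProfileError("need at least two samples")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.allclose(p1, p2):
        raise ProfileError("profile endpoints coincide")
    for p in (p1, p2):
        if not (0 <= p[0] <= image.shape[0] - 1 and 0 <= p[1] <= image.shape[1] - 1):
            raise ProfileError(f"point {tuple(p)} outside image {image.shape}")
    frac = np.linspace(0.0, 1.0, n_samples)
    coords = np.outer(1 - frac, p1) + np.outer(frac, p2)
    return ndi.map_coordinates(image, coords.T, order=1, mode="nearest")


def _profile_is_merged(profile: np.ndarray, frac: float) -> bool:
    """True when the profile shows no low-response gap between its two
    half-maxima — the signature of a single central mass."""
    n = profile.size
    half = n // 2
    i1 = int(np.argmax(profile[:half]))
    i2 = half + int(np.argmax(profile[half:]))
    peak = 0.5 * (profile[i1] + profile[i2])
    if peak <= 0:
        return False
    gap_min = float(profile[i1 : i2 + 1].min())
    return gap_min >= frac * peak


def plate_shape_ok(blob: ChromatinBlob, config: PipelineConfig) -> bool:
    """Metaphase-plate shape bands: fitted-ellipse axis lengths and ratio."""
    lo_M, hi_M = config.plate_major_px_band
    lo_m, hi_m = config.plate_minor_px_band
    return (
        lo_M <= blob.major_px <= hi_M
        and lo_m <= blob.minor_px <= hi_m
        and blob.axis_ratio >= config.plate_axis_ratio_min
    )


def detect_reunion(
    log_stack: np.ndarray,
    blobs_by_frame: list[list[ChromatinBlob]],
    event: AnaphaseEvent,
    roi: PatternROI,
    config: PipelineConfig,
) -> tuple[int, ChromatinBlob] | None:
    """Find the last metaphase frame before ``event`` and its seed blob.

    ``log_stack`` is the box-restricted (T, h, w) blob-positive LoG
    response; ``blobs_by_frame`` the box's segmented blobs per frame.
    Scans backwards from ``event.frame - 1`` over at most
    ``reunion_search_frames`` frames; at each frame the inter-centroid
    profile is tested for the disappearance of the anaphase gap, and the
    blob nearest the profile midpoint becomes the seed.  Returns ``None``
    when no reunion is found — failed segregation, two unrelated nuclei,
    or a detection error.
    """
    r0, c0 = roi.box[0], roi.box[1]
    a = (event.blob_a.centroid[0] - r0, event.blob_a.centroid[1] - c0)
    b = (event.blob_b.centroid[0] - r0, event.blob_b.centroid[1] - c0)
    h, w = log_stack.shape[1:]
    a = (min(max(a[0], 0.0), h - 1.0), min(max(a[1], 0.0), w - 1.0))
    b = (min(max(b[0], 0.0), h - 1.0), min(max(b[1], 0.0), w - 1.0))
    n_samples = max(8, int(round(2 * event.separation_px)))
    mid = event.midpoint
    first = event.frame - 1
    last = max(0, event.frame - config.reunion_search_frames)
    for t in range(first, last - 1, -1):
        profile = line_profile(log_stack[t], a, b, n_samples)
        if not _profile_is_merged(profile, config.reunion_profile_frac):
            continue
        best = None
        best_d = config.max_link_px
        for blob in blobs_by_frame[t]:
            d = math.hypot(blob.centroid[0] - mid[0], blob.centroid[1] - mid[1])
            if d <= best_d:
                best_d = d
                best = blob
        if best is not None:
            return t, best
    return None


def backtrack_plate(
    blobs_by_frame: list[list[ChromatinBlob]],
    seed: ChromatinBlob,
    config: PipelineConfig,
    pattern_id: int,
    anaphase_frame: int,
) -> PlateTrack:
    """Link the plate backwards from ``seed`` with gap closing.

    Per earlier frame, the closest blob within ``max_link_px`` of the last
    tracked position that passes the plate shape bands continues the
    track; up to ``max_gap_frames`` consecutive frames without a link are
    bridged, one more ends the track.  A seed failing the shape bands
    raises :class:`SeedShapeError`.
    """
    if not plate_shape_ok(seed, config):
        raise SeedShapeError(
            f"seed blob at frame {seed.frame} fails the plate shape bands"
        )
    track_blobs = [seed]
    pos = seed.centroid
    gaps_closed = 0
    gap_run = 0
    truncated = False
    t = seed.frame - 1
    while t >= 0:
        best = None
        best_d = config.max_link_px
        for blob in blobs_by_frame[t]:
            if not plate_shape_ok(blob, config):
                continue
            d = math.hypot(blob.centroid[0] - pos[0], blob.centroid[1] - pos[1])
            if d <= best_d:
                best_d = d
                best = blob
        if best is None:
            gap_run += 1
            if gap_run > config.max_gap_frames:
                break
        else:
            gaps_closed += gap_run
            gap_run = 0
            track_blobs.append(best)
            pos = best.centroid
        t -= 1
    else:
        # walked off the start of the recording while still linking
        truncated = gap_run == 0
    track_blobs.reverse()
    return PlateTrack(
        pattern_id=pattern_id,
        anaphase_frame=anaphase_frame,
        reunion_frame=seed.frame,
        plate_blobs=track_blobs,
        metaphase_start_frame=track_blobs[0].frame,
        gaps_closed=gaps_closed,
        truncated=truncated,
    )
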