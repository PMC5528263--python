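"""Exported measurements: plate angle, metaphase duration, mispositioning.

The metaphase plate angle is reported against the direction of the L's
horizontal arm (+x, counter-clockwise positive in a y-up frame), modulo
180° — a plate has no polarity.  In control cells the plate sits near
45° to the arms, so the exported deviation is the folded angular distance
from 45°, in [0°, 90°]; a deviation beyond 40° (strict) calls the
spindle mispositioned.  Review montages replace interactive validation:
four box crops per event (metaphase start, mid-metaphase, reunion,
anaphase) with the plate axis and L anchor overlaid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .anaphase import fold_angle_difference_deg
from .config import PipelineConfig
from .patterns import PatternROI
from .stack import TimeLapseStack
from .tracking import PlateTrack

__all__ = [
    "AngleMeasurement",
    "MitosisResult",
    "plate_angle",
    "metaphase_duration",
    "classify_spindle_position",
    "assemble_results",
    "render_review_montage",
    "circular_median_deg",
]


@dataclass(frozen=True)
class AngleMeasurement:
    """Plate angle in [0, 180) from the horizontal arm, and its folded
    deviation from the expected angle, in [0, 90]."""

    plate_angle_deg: float
    deviation_deg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.plate_angle_deg < 180.0):
            raise ValueError("plate angle must lie in [0, 180)")
        if not (0.0 <= self.deviation_deg <= 90.0):
            raise ValueError("deviation must lie in [0, 90]")


@dataclass
class MitosisResult:
    """One analyzable division: where, when, at what angle, for how long."""

    pattern_id: int
    anaphase_frame: int
    metaphase_start_frame: int
    plate_angle_deg: float
    deviation_deg: float
    metaphase_duration_min: float
    mispositioned: bool
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.metaphase_start_frame < self.anaphase_frame:
            raise ValueError("metaphase must start before anaphase")
        if not (0.0 <= self.plate_angle_deg < 180.0):
            raise ValueError("plate angle must lie in [0, 180)")
        if not (0.0 <= self.deviation_deg <= 90.0):
            raise ValueError("deviation must lie in [0, 90]")


def circular_median_deg(angles: list[float]) -> float:
    """Median of orientations (mod 180), robust to the 0/180 wrap.

    Angles are doubled onto the circle, the circular mean locates the
    cluster, and the median of the folded residuals about it is taken.
    """
    if not angles:
        raise ValueError("no angles")
    doubled = np.radians(np.asarray(angles, dtype=float) * 2.0)
    mean = math.degrees(math.atan2(np.sin(doubled).mean(), np.cos(doubled).mean())) / 2.0
    resid = [((a - mean + 90.0) % 180.0) - 90.0 for a in angles]
    return (mean + float(np.median(resid))) % 180.0


def plate_angle(
    track: PlateTrack,
    roi: PatternROI,
    config: PipelineConfig,
) -> AngleMeasurement:
    """Plate angle of a track: median blob orientation over the last
    ``angle_median_frames`` metaphase frames (reunion inclusive), folded
    deviation from ``expected_angle_deg``.

    Blob orientations are already measured counter-clockwise (y-up) from
    the +column axis, which is the direction of the horizontal arm for
    the standard L orientation (arms up and right)."""
    if not track.plate_blobs:
        raise ValueError("empty track")
    n = min(config.angle_median_frames, len(track.plate_blobs))
    last = track.plate_blobs[-n:]
    theta = circular_median_deg([b.orientation_deg for b in last])
    dev = fold_angle_difference_deg(theta, config.expected_angle_deg)
    return AngleMeasurement(plate_angle_deg=theta, deviation_deg=dev)


def metaphase_duration(track: PlateTrack, frame_interval_min: float) -> float:
    """(anaphase frame - metaphase start frame) x frame interval, minutes.

    For a truncated track this is a lower bound (the plate may predate
    the recording)."""
    return (track.anaphase_frame - track.metaphase_start_frame) * frame_interval_min


def classify_spindle_position(
    measurement: AngleMeasurement, config: PipelineConfig
) -> bool:
    """True iff the plate deviates more than ``mispositioned_offset_deg``
    (strict inequality) from the expected 45° position."""
    return measurement.deviation_deg > config.mispositioned_offset_deg


def assemble_results(
    tracks: list[PlateTrack],
    measurements: list[AngleMeasurement],
    frame_interval_min: float,
    config: PipelineConfig,
    extra_flags: list[set[str]] | None = None,
) -> tuple[list[MitosisResult], dict]:
    """Build one :class:`MitosisResult` per surviving track plus the
    per-field summary (n analyzable, n mispositioned, percent)."""
    if len(tracks) != len(measurements):
        raise ValueError("need one measurement per track")
    results = []
    for i, (track, meas) in enumerate(zip(tracks, measurements)):
        flags = set(extra_flags[i]) if extra_flags else set()
        if track.gaps_closed > 0:
            flags.add("gap_closed")
        if track.truncated:
            flags.add("track_truncated")
        results.append(
            MitosisResult(
                pattern_id=track.pattern_id,
                anaphase_frame=track.anaphase_frame,
                metaphase_start_frame=track.metaphase_start_frame,
                plate_angle_deg=meas.plate_angle_deg,
                deviation_deg=meas.deviation_deg,
                metaphase_duration_min=metaphase_duration(track, frame_interval_min),
                mispositioned=classify_spindle_position(meas, config),
                qc_flags=flags,
            )
        )
    n = len(results)
    n_mis = sum(r.mispositioned for r in results)
    summary = {
        "n_analyzable": n,
        "n_mispositioned": n_mis,
        "percent_mispositioned": (100.0 * n_mis / n) if n else None,
    }
    return results, summary


def render_review_montage(
    stack: TimeLapseStack,
    result: MitosisResult,
    roi: PatternROI,
    track: PlateTrack,
    out_dir: str | Path,
) -> tuple[Path, dict]:
    """Write a 4-panel PNG montage for one event and return its path plus
    the overlay annotation values (for cross-checking against the CSV).

    Panels: metaphase start, mid-metaphase, reunion, anaphase, clamped to
    available frames; the plate axis through the seed centroid and the L
    anchor are overlaid on each panel.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = result.metaphase_start_frame
    t_reunion = track.reunion_frame
    t_mid = (t_start + t_reunion) // 2
    t_ana = result.anaphase_frame
    frames = [
        min(max(t, 0), stack.n_frames - 1) for t in (t_start, t_mid, t_reunion, t_ana)
    ]
    titles = ["metaphase start", "mid metaphase", "reunion", "anaphase"]
    rs, cs = roi.box_slices()
    seed = track.plate_blobs[-1]
    angle_txt = f"{result.plate_angle_deg:.2f}"
    th = math.radians(result.plate_angle_deg)
    dr, dc = -math.sin(th), math.cos(th)
    cr = seed.centroid[0] - roi.box[0]
    cc = seed.centroid[1] - roi.box[1]
    L = 12.0
    fig, axes = plt.subplots(1, 4, figsize=(10, 3))
    for ax, t, title in zip(axes, frames, titles):
        crop = stack.pixels[t][rs, cs]
        ax.imshow(crop, cmap="gray", interpolation="nearest")
        ax.plot(
            [cc - L * dc, cc + L * dc], [cr - L * dr, cr + L * dr], "c-", lw=1.2
        )
        ar = roi.anchor[0] - roi.box[0]
        ac = roi.anchor[1] - roi.box[1]
        if 0 <= ar < crop.shape[0] and 0 <= ac < crop.shape[1]:
            ax.plot(ac, ar, "y+", ms=10)
        ax.set_title(f"{title} (t={t})", fontsize=8)
        ax.axis("off")
    fig.suptitle(
        f"pattern {result.pattern_id}: angle {angle_txt} deg, "
        f"duration {result.metaphase_duration_min:.0f} min",
        fontsize=9,
    )
    path = out_dir / f"{result.pattern_id}_{result.anaphase_frame}.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    annotation = {"plate_angle_deg": angle_txt, "frames": frames}
    return path, annotation
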