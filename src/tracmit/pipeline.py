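"""End-to-end pipeline: registration -> pattern detection -> occupancy
filter -> anaphase detection -> backtracking -> measurement -> export.

Each stage is individually callable from its own module; ``run_pipeline``
composes them in order and is deterministic given (stack, config).  Stage
failures are re-raised as :class:`PipelineStageError` with the stage name
attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anaphase as ana
from . import measure as meas
from . import patterns as pat
from . import registration as reg
from . import tracking as trk
from .config import PipelineConfig
from .errors import PipelineStageError
from .measure import MitosisResult
from .stack import TimeLapseStack

__all__ = ["run_pipeline", "write_results", "PipelineOutput", "process_candidate_roi"]


@dataclass
class PipelineOutput:
    """Everything ``run_pipeline`` produces, plus intermediates useful
    for review (drift trace, MinInt projection, per-event records)."""

    results: list[MitosisResult]
    rois: list[pat.PatternROI]
    summary: dict
    tracks: list[trk.PlateTrack] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    drift: reg.DriftTrace | None = None
    minint: np.ndarray | None = None
    registered: TimeLapseStack | None = None


def _roi_log_stack(
    stack: TimeLapseStack, roi: pat.PatternROI, config: PipelineConfig
) -> np.ndarray:
    """Blob-positive LoG response of the box crop for every frame.

    The crop is padded by 4 sigma before filtering so box-edge responses
    are computed on real context, then cut back to the box.
    """
    pad = int(math.ceil(4 * config.log_sigma_px))
    r0, c0, h, w = roi.box
    T, H, W = stack.pixels.shape
    pr0, pc0 = max(0, r0 - pad), max(0, c0 - pad)
    pr1, pc1 = min(H, r0 + h + pad), min(W, c0 + w + pad)
    out = np.empty((T, h, w), dtype=np.float64)
    sr = slice(r0 - pr0, r0 - pr0 + h)
    sc = slice(c0 - pc0, c0 - pc0 + w)
    for t in range(T):
        resp = ana.log_filter(stack.pixels[t, pr0:pr1, pc0:pc1], config.log_sigma_px)
        out[t] = resp[sr, sc]
    return out


def process_candidate_roi(
    stack: TimeLapseStack,
    minint: np.ndarray,
    roi: pat.PatternROI,
    config: PipelineConfig,
) -> tuple[list[dict], list[trk.PlateTrack], list[set[str]]]:
    """Run anaphase detection and backtracking inside one candidate box.

    Returns per-event records (for events.csv), the surviving plate
    tracks, and per-track extra QC flags.  One segmentation (the
    binarized LoG) serves both pair detection and backtracking.
    """
    log_stack = _roi_log_stack(stack, roi, config)
    if config.log_threshold_mode == "absolute":
        threshold = config.log_threshold_abs
    else:
        threshold = config.log_threshold_frac * float(log_stack.max())
    blobs_by_frame: list[list[ana.ChromatinBlob]] = []
    raw_events: list[ana.AnaphaseEvent] = []
    for t in range(stack.n_frames):
        mask = ana.binarize_and_close(log_stack[t], config, threshold=threshold)
        blobs = ana.extract_blobs(mask, t, roi, min_area_px=config.min_blob_area_px)
        blobs_by_frame.append(blobs)
        raw_events.extend(ana.detect_anaphase_pairs(blobs, roi.pattern_id, config))
    events = ana.deduplicate_events(raw_events, config.dedupe_radius_px)

    records: list[dict] = []
    tracks: list[trk.PlateTrack] = []
    flags_per_track: list[set[str]] = []
    for ev in events:
        record = {
            "pattern_id": ev.pattern_id,
            "frame": ev.frame,
            "row_a": ev.blob_a.centroid[0],
            "col_a": ev.blob_a.centroid[1],
            "row_b": ev.blob_b.centroid[0],
            "col_b": ev.blob_b.centroid[1],
            "separation_px": ev.separation_px,
            "accepted": False,
            "reject_reason": "",
        }
        accepted, _count, flag = ana.crowding_filter(
            stack.pixels[ev.frame], minint, roi, ev, config
        )
        if not accepted:
            record["reject_reason"] = flag or "crowded_rejected"
            records.append(record)
            continue
        extra = {flag} if flag else set()
        if ev.frame == 0:
            record["reject_reason"] = "no_frames_before_event"
            records.append(record)
            continue
        reunion = trk.detect_reunion(log_stack, blobs_by_frame, ev, roi, config)
        if reunion is None:
            record["reject_reason"] = "no_reunion"
            records.append(record)
            continue
        _t_reunion, seed = reunion
        try:
            track = trk.backtrack_plate(
                blobs_by_frame, seed, config, roi.pattern_id, ev.frame
            )
        except trk.SeedShapeError:
            record["reject_reason"] = "seed_shape"
            records.append(record)
            continue
        record["accepted"] = True
        records.append(record)
        tracks.append(track)
        flags_per_track.append(extra)
    return records, tracks, flags_per_track


def run_pipeline(
    stack: TimeLapseStack, config: PipelineConfig | None = None
) -> PipelineOutput:
    """Execute the full pipeline on one field of view."""
    config = config or PipelineConfig()
    out = PipelineOutput(results=[], rois=[], summary={})

    stage = "registration"
    try:
        if config.register:
            out.drift = reg.estimate_drift(stack)
            registered = reg.apply_shifts(stack, out.drift)
        else:
            registered = stack
        out.registered = registered
    except Exception as exc:  # noqa: BLE001 - wrapped with stage context
        raise PipelineStageError(stage, exc) from exc

    stage = "pattern_detection"
    try:
        minint = pat.min_intensity_projection(registered)
        out.minint = minint
        rois = pat.detect_pattern_rois(minint, config, stack.pixel_size_um)
        stdev_img, mean_img = pat.temporal_projections(registered)
        scores = [
            pat.fstdev_score(roi, stdev_img, mean_img, mode=config.fstdev_mode)
            for roi in rois
        ]
        rois = pat.filter_by_occupancy(rois, scores, config)
        out.rois = rois
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    stage = "anaphase_detection_and_backtracking"
    all_tracks: list[trk.PlateTrack] = []
    all_flags: list[set[str]] = []
    try:
        for roi in rois:
            if roi.status != "analyzable_candidate":
                continue
            records, tracks, flags = process_candidate_roi(
                registered, minint, roi, config
            )
            out.events.extend(records)
            all_tracks.extend(tracks)
            all_flags.extend(flags)
            roi.status = "analyzable" if tracks else "no_division"
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    stage = "measurement"
    try:
        measurements = []
        for track in all_tracks:
            roi = next(r for r in rois if r.pattern_id == track.pattern_id)
            measurements.append(meas.plate_angle(track, roi, config))
        results, summary = meas.assemble_results(
            all_tracks,
            measurements,
            stack.frame_interval_min,
            config,
            extra_flags=all_flags,
        )
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    out.results = results
    out.summary = summary
    out.tracks = all_tracks
    return out


RESULT_COLUMNS = [
    "pattern_id",
    "anchor_row",
    "anchor_col",
    "anaphase_frame",
    "metaphase_start_frame",
    "plate_angle_deg",
    "deviation_deg",
    "metaphase_duration_min",
    "mispositioned",
    "qc_flags",
]

ROI_COLUMNS = [
    "pattern_id",
    "anchor_row",
    "anchor_col",
    "box_height",
    "box_width",
    "fstdev",
    "status",
]


def write_results(
    results: list[MitosisResult],
    rois: list[pat.PatternROI],
    out_dir: str | Path,
    summary: dict | None = None,
) -> dict[str, Path]:
    """Write results.csv, rois.csv (and summary.csv when a summary is
    given) with stable column order; angles carry 2 decimals."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    anchor = {r.pattern_id: r.anchor for r in rois}
    rows = []
    for res in results:
        a = anchor.get(res.pattern_id, (-1, -1))
        rows.append(
            {
                "pattern_id": res.pattern_id,
                "anchor_row": a[0],
                "anchor_col": a[1],
                "anaphase_frame": res.anaphase_frame,
                "metaphase_start_frame": res.metaphase_start_frame,
                "plate_angle_deg": f"{res.plate_angle_deg:.2f}",
                "deviation_deg": f"{res.deviation_deg:.2f}",
                "metaphase_duration_min": res.metaphase_duration_min,
                "mispositioned": res.mispositioned,
                "qc_flags": ";".join(sorted(res.qc_flags)),
            }
        )
    results_df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    results_path = out_dir / "results.csv"
    results_df.to_csv(results_path, index=False)

    roi_rows = []
    status_map = {"analyzable_candidate": "no_division"}
    for roi in rois:
        roi_rows.append(
            {
                "pattern_id": roi.pattern_id,
                "anchor_row": roi.anchor[0],
                "anchor_col": roi.anchor[1],
                "box_height": roi.box[2],
                "box_width": roi.box[3],
                "fstdev": f"{roi.fstdev:.4f}",
                "status": status_map.get(roi.status, roi.status),
            }
        )
    rois_df = pd.DataFrame(roi_rows, columns=ROI_COLUMNS)
    rois_path = out_dir / "rois.csv"
    rois_df.to_csv(rois_path, index=False)

    paths = {"results": results_path, "rois": rois_path}
    if summary is not None:
        summary_df = pd.DataFrame([summary])
        summary_path = out_dir / "summary.csv"
        summary_df.to_csv(summary_path, index=False)
        paths["summary"] = summary_path
    return paths
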