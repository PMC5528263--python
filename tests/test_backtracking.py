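"""Line profiles, reunion detection and backward plate linking."""

import numpy as np
import pytest

from tracmit.anaphase import AnaphaseEvent, ChromatinBlob
from tracmit.config import PipelineConfig
from tracmit.errors import ProfileError, SeedShapeError
from tracmit.patterns import PatternROI
from tracmit.tracking import (
    backtrack_plate,
    detect_reunion,
    line_profile,
    plate_shape_ok,
)


def plate_blob(frame, r=30.0, c=30.0, major=14.0, minor=5.0, angle=45.0):
    return ChromatinBlob(
        frame=frame, centroid=(r, c), area_px=60,
        orientation_deg=angle, major_px=major, minor_px=minor,
    )


def round_blob(frame, r=30.0, c=30.0):
    return ChromatinBlob(
        frame=frame, centroid=(r, c), area_px=300,
        orientation_deg=0.0, major_px=20.0, minor_px=19.0,
    )


class TestLineProfile:
    def test_constant_image_constant_profile(self):
        img = np.full((40, 40), 7.5)
        prof = line_profile(img, (5, 5), (30, 35), 16)
        np.testing.assert_allclose(prof, 7.5)

    def test_column_ramp_gives_arithmetic_progression(self):
        img = np.tile(np.arange(50, dtype=float), (50, 1))
        prof = line_profile(img, (10, 4), (10, 44), 21)
        np.testing.assert_allclose(prof, np.linspace(4, 44, 21), atol=1e-9)

    def test_agrees_with_dense_supersampling_oracle(self):
        import scipy.ndimage as ndi

        rng = np.random.default_rng(0)
        img = ndi.gaussian_filter(rng.normal(size=(60, 60)), 2.0)
        p1, p2, n = (7.3, 11.1), (48.2, 51.7), 25
        prof = line_profile(img, p1, p2, n)
        # oracle: sample each point individually with bilinear interpolation
        for k in range(n):
            f = k / (n - 1)
            r = p1[0] * (1 - f) + p2[0] * f
            c = p1[1] * (1 - f) + p2[1] * f
            r0, c0 = int(r), int(c)
            fr, fc = r - r0, c - c0
            val = (
                img[r0, c0] * (1 - fr) * (1 - fc)
                + img[r0 + 1, c0] * fr * (1 - fc)
                + img[r0, c0 + 1] * (1 - fr) * fc
                + img[r0 + 1, c0 + 1] * fr * fc
            )
            assert prof[k] == pytest.approx(val, abs=1e-6)

    def test_coincident_or_outside_points_raise(self):
        img = np.zeros((20, 20))
        with pytest.raises(ProfileError):
            line_profile(img, (5, 5), (5, 5), 10)
        with pytest.raises(ProfileError):
            line_profile(img, (5, 5), (25, 5), 10)


def synthetic_log_stack(T=20, anaphase_frame=10, merge_before=True):
    """(T, 62, 62) blob-positive response: two spots after
    ``anaphase_frame``, one central spot before it (if ``merge_before``)."""
    yy, xx = np.mgrid[0:62, 0:62].astype(float)

    def spot(r, c, s=2.5, amp=100.0):
        return amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * s**2))

    stack = np.zeros((T, 62, 62))
    for t in range(T):
        if t >= anaphase_frame:
            stack[t] = spot(24, 30) + spot(38, 30)
        elif merge_before:
            stack[t] = spot(31, 30)
        else:
            stack[t] = spot(24, 30) + spot(38, 30)
    return stack


def blobs_for(log_stack, anaphase_frame, merge_before=True):
    T = log_stack.shape[0]
    out = []
    for t in range(T):
        if t >= anaphase_frame or not merge_before:
            out.append([plate_blob(t, 24.0, 30.0), plate_blob(t, 38.0, 30.0)])
        else:
            out.append([plate_blob(t, 31.0, 30.0)])
    return out


def event_at(frame):
    a = plate_blob(frame, 24.0, 30.0)
    b = plate_blob(frame, 38.0, 30.0)
    return AnaphaseEvent(0, frame, a, b, (31.0, 30.0), 14.0, 90.0)


ROI = PatternROI(pattern_id=0, anchor=(61, 0), box=(0, 0, 62, 62))


class TestDetectReunion:
    def test_reunion_found_one_frame_before_anaphase(self, pipeline_config):
        log = synthetic_log_stack()
        blobs = blobs_for(log, 10)
        got = detect_reunion(log, blobs, event_at(10), ROI, pipeline_config)
        assert got is not None
        t, seed = got
        assert t == 9
        assert seed.centroid == (31.0, 30.0)

    def test_event_at_frame_zero_is_discarded(self, pipeline_config):
        log = synthetic_log_stack()
        blobs = blobs_for(log, 0)
        assert detect_reunion(log, blobs, event_at(0), ROI, pipeline_config) is None

    def test_never_merging_masses_yield_no_reunion(self, pipeline_config):
        log = synthetic_log_stack(merge_before=False)
        blobs = blobs_for(log, 10, merge_before=False)
        assert detect_reunion(log, blobs, event_at(10), ROI, pipeline_config) is None

    def test_monotone_in_profile_fraction(self, pipeline_config):
        log = synthetic_log_stack()
        blobs = blobs_for(log, 10)
        frames = {}
        for frac in (0.3, 0.5, 0.8):
            got = detect_reunion(
                log, blobs, event_at(10), ROI,
                pipeline_config.with_overrides(reunion_profile_frac=frac),
            )
            frames[frac] = None if got is None else got[0]
        vals = [frames[f] for f in (0.3, 0.5, 0.8) if frames[f] is not None]
        assert all(b <= a for a, b in zip(vals, vals[1:]))


class TestBacktrackPlate:
    def make_frames(self, present):
        """blobs_by_frame with a plate at the listed frames only."""
        T = max(present) + 2
        return [
            [plate_blob(t)] if t in present else [] for t in range(T)
        ]

    def test_continuous_plate_tracked_to_first_frame(self, pipeline_config):
        frames = self.make_frames(set(range(10, 16)))
        track = backtrack_plate(frames, plate_blob(15), pipeline_config, 0, 16)
        assert track.metaphase_start_frame == 10
        assert track.gaps_closed == 0
        assert not track.truncated

    def test_three_frame_gap_is_bridged(self, pipeline_config):
        present = {10, 11, 15}  # frames 12-14 missing: exactly 3
        frames = self.make_frames(present)
        track = backtrack_plate(frames, plate_blob(15), pipeline_config, 0, 16)
        assert track.metaphase_start_frame == 10
        assert track.gaps_closed == 3

    def test_four_frame_gap_terminates_track(self, pipeline_config):
        present = {10, 15}  # frames 11-14 missing: 4 > max_gap_frames
        frames = self.make_frames(present)
        track = backtrack_plate(frames, plate_blob(15), pipeline_config, 0, 16)
        assert track.metaphase_start_frame == 15
        assert not track.truncated

    def test_track_reaching_frame_zero_is_truncated(self, pipeline_config):
        frames = self.make_frames(set(range(0, 6)))
        track = backtrack_plate(frames, plate_blob(5), pipeline_config, 0, 6)
        assert track.metaphase_start_frame == 0
        assert track.truncated

    def test_non_plate_shapes_are_not_linkable(self, pipeline_config):
        frames = [
            [round_blob(t)] if t < 13 else [plate_blob(t)] for t in range(16)
        ]
        track = backtrack_plate(frames, plate_blob(15), pipeline_config, 0, 16)
        assert track.metaphase_start_frame == 13

    def test_seed_failing_shape_bands_raises(self, pipeline_config):
        frames = self.make_frames({10})
        with pytest.raises(SeedShapeError):
            backtrack_plate(frames, round_blob(11), pipeline_config, 0, 12)

    def test_track_invariants_hold(self, pipeline_config):
        frames = self.make_frames(set(range(8, 16)))
        track = backtrack_plate(frames, plate_blob(15), pipeline_config, 0, 16)
        assert track.metaphase_start_frame <= track.reunion_frame < track.anaphase_frame
        for b in track.plate_blobs:
            assert plate_shape_ok(b, pipeline_config)
        frames_seq = [b.frame for b in track.plate_blobs]
        assert frames_seq == sorted(frames_seq)
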