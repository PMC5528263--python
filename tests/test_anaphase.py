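"""LoG enhancement, blob segmentation, pair detection, dedupe, crowding."""

import math

import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings, strategies as st

from tracmit.anaphase import (
    AnaphaseEvent,
    ChromatinBlob,
    binarize_and_close,
    crowding_filter,
    deduplicate_events,
    detect_anaphase_pairs,
    extract_blobs,
    fold_angle_difference_deg,
    log_filter,
)
from tracmit.config import PipelineConfig
from tracmit.patterns import PatternROI
from tracmit.synth import Ellipse, render_ellipse


def blob(frame=0, r=10.0, c=10.0, area=40, angle=0.0, major=10.0, minor=4.0):
    return ChromatinBlob(
        frame=frame,
        centroid=(r, c),
        area_px=area,
        orientation_deg=angle,
        major_px=major,
        minor_px=minor,
    )


def make_event(pid, frame, mid=(30.0, 30.0), sep=16.0):
    a = blob(frame, mid[0], mid[1] - sep / 2)
    b = blob(frame, mid[0], mid[1] + sep / 2)
    return AnaphaseEvent(
        pattern_id=pid,
        frame=frame,
        blob_a=a,
        blob_b=b,
        midpoint=mid,
        separation_px=sep,
        axis_deg=0.0,
    )


class TestLogFilter:
    def test_constant_image_zero_response(self):
        resp = log_filter(np.full((40, 40), 123.0), 2.5)
        np.testing.assert_allclose(resp, 0.0, atol=1e-6)

    def test_gaussian_spot_peak_at_center_and_scale_selectivity(self):
        s = 3.0
        yy, xx = np.mgrid[0:61, 0:61] - 30.0
        img = 1000.0 * np.exp(-(yy**2 + xx**2) / (2 * s**2))
        resp = log_filter(img, s)
        assert np.unravel_index(resp.argmax(), resp.shape) == (30, 30)
        peaks = {sig: log_filter(img, sig)[30, 30] for sig in (1.0, 2.0, 3.0, 4.0, 6.0)}
        assert max(peaks, key=peaks.get) == 3.0

    def test_thin_line_suppressed_relative_to_plate_sized_disk(self):
        img_line = np.full((60, 60), 0.0)
        img_line[30, :] = 1000.0
        img_disk = np.zeros((60, 60))
        yy, xx = np.mgrid[0:60, 0:60]
        img_disk[(yy - 30) ** 2 + (xx - 30) ** 2 <= 3.0**2] = 1000.0
        assert log_filter(img_line, 2.5).max() < log_filter(img_disk, 2.5).max()

    def test_nonpositive_sigma_raises(self):
        with pytest.raises(ValueError):
            log_filter(np.zeros((10, 10)), 0.0)


class TestBinarizeAndClose:
    def test_all_zero_response_gives_empty_mask(self, pipeline_config):
        assert not binarize_and_close(np.zeros((30, 30)), pipeline_config).any()

    def test_fragments_within_closing_radius_become_one_component(
        self, pipeline_config
    ):
        resp = np.zeros((30, 30))
        resp[10:14, 5:12] = 10.0
        resp[10:14, 14:21] = 10.0  # 2 px gap, closing radius 2
        mask = binarize_and_close(resp, pipeline_config, threshold=5.0)
        _, n = ndi.label(mask)
        assert n == 1

    def test_threshold_fraction_one_keeps_only_maximal_pixels(self):
        cfg = PipelineConfig(log_threshold_frac=1.0, closing_radius_px=1)
        resp = np.zeros((20, 20))
        resp[5, 5] = 7.0
        resp[9, 9] = 3.0
        mask = resp >= 1.0 * resp.max()  # pre-closing semantics
        assert mask.sum() == 1 and mask[5, 5]


class TestExtractBlobs:
    def roi(self):
        return PatternROI(pattern_id=0, anchor=(61, 0), box=(100, 200, 62, 62))

    def test_empty_mask_gives_no_blobs(self):
        assert extract_blobs(np.zeros((62, 62), bool), 0, self.roi()) == []

    def test_axis_aligned_rectangle_orientation_zero(self):
        mask = np.zeros((62, 62), bool)
        mask[20:24, 10:20] = True  # 4 rows x 10 cols: elongated along +x
        (b,) = extract_blobs(mask, 3, self.roi())
        assert b.frame == 3
        assert b.orientation_deg == pytest.approx(0.0, abs=1e-6)
        assert b.major_px > b.minor_px
        assert b.area_px == 40
        # centroid reported in full-frame coordinates
        assert b.centroid[0] == pytest.approx(100 + 21.5)
        assert b.centroid[1] == pytest.approx(200 + 14.5)

    @pytest.mark.parametrize("angle", [10.0, 30.0, 45.0, 120.0, 170.0])
    def test_rotated_ellipse_orientation_recovered(self, angle):
        canvas = np.zeros((62, 62))
        render_ellipse(canvas, Ellipse((31.0, 31.0), 10.0, 3.5, angle, 100.0))
        (b,) = extract_blobs(canvas > 50.0, 0, self.roi())
        assert fold_angle_difference_deg(b.orientation_deg, angle) <= 2.0

    def test_min_area_floor_drops_specks(self):
        mask = np.zeros((62, 62), bool)
        mask[5, 5] = True
        mask[20:26, 20:26] = True
        blobs = extract_blobs(mask, 0, self.roi(), min_area_px=4)
        assert len(blobs) == 1 and blobs[0].area_px == 36


def brute_force_pairs(blobs, config):
    """Naive reference: constraint filter then greedy shared-blob
    resolution by (area ratio, separation)."""
    cands = []
    for i in range(len(blobs)):
        for j in range(i + 1, len(blobs)):
            a, b = blobs[i], blobs[j]
            sep = math.hypot(
                b.centroid[0] - a.centroid[0], b.centroid[1] - a.centroid[1]
            )
            lo, hi = config.pair_distance_band_px
            if sep < lo or sep > hi:
                continue
            d = abs(a.orientation_deg - b.orientation_deg) % 180.0
            d = min(d, 180.0 - d)
            if d > config.pair_angle_tol_deg:
                continue
            ratio = max(a.area_px, b.area_px) / min(a.area_px, b.area_px)
            if ratio > config.pair_area_ratio_max:
                continue
            cands.append((ratio, sep, i, j))
    cands.sort()
    used, kept = set(), []
    for _, _, i, j in cands:
        if i in used or j in used:
            continue
        used |= {i, j}
        kept.append(frozenset((i, j)))
    return kept


def random_blobs(rng, n, frame=0):
    out = []
    for _ in range(n):
        out.append(
            blob(
                frame=frame,
                r=float(rng.uniform(0, 60)),
                c=float(rng.uniform(0, 60)),
                area=int(rng.integers(10, 120)),
                angle=float(rng.uniform(0, 180)),
                major=float(rng.uniform(6, 20)),
                minor=float(rng.uniform(2, 6)),
            )
        )
    return out


class TestPairDetection:
    def test_constructed_pass_and_fail_cases(self, pipeline_config):
        a = blob(r=30, c=20)
        b = blob(r=30, c=40)  # 20 px apart, parallel, equal area
        assert len(detect_anaphase_pairs([a, b], 0, pipeline_config)) == 1
        c = blob(r=30, c=24)  # 4 px apart: below the distance band
        assert detect_anaphase_pairs([a, c], 0, pipeline_config) == []

    def test_matches_brute_force_on_random_blob_sets(self, pipeline_config):
        rng = np.random.default_rng(12)
        for _ in range(100):
            blobs = random_blobs(rng, int(rng.integers(2, 8)))
            got = detect_anaphase_pairs(blobs, 0, pipeline_config)
            got_sets = [
                frozenset((blobs.index(e.blob_a), blobs.index(e.blob_b))) for e in got
            ]
            assert sorted(got_sets, key=sorted) == sorted(
                brute_force_pairs(blobs, pipeline_config), key=sorted
            )

    def test_shared_blob_resolved_by_smallest_area_ratio(self, pipeline_config):
        a = blob(r=30, c=20, area=40)
        b = blob(r=30, c=40, area=42)  # ratio 1.05
        c = blob(r=10, c=20, area=70)  # with a: ratio 1.75
        events = detect_anaphase_pairs([a, b, c], 0, pipeline_config)
        assert len(events) == 1
        assert {events[0].blob_a, events[0].blob_b} == {a, b}

    def test_event_geometry_fields(self, pipeline_config):
        a = blob(frame=7, r=30, c=20)
        b = blob(frame=7, r=30, c=40)
        (e,) = detect_anaphase_pairs([a, b], 3, pipeline_config)
        assert e.pattern_id == 3
        assert e.separation_px == pytest.approx(20.0)
        assert e.midpoint == (30.0, 30.0)
        assert e.axis_deg == pytest.approx(0.0)
        assert e.frame == 7


class TestDeduplicate:
    def test_same_location_later_frame_dropped(self):
        e16 = make_event(0, 16)
        e17 = make_event(0, 17)
        assert deduplicate_events([e17, e16], 10.0) == [e16]

    def test_distant_events_both_kept(self):
        e1 = make_event(0, 16, mid=(10.0, 10.0))
        e2 = make_event(0, 20, mid=(50.0, 55.0))
        assert len(deduplicate_events([e1, e2], 10.0)) == 2

    def test_different_patterns_never_interfere(self):
        e1 = make_event(0, 16)
        e2 = make_event(1, 17)
        assert len(deduplicate_events([e1, e2], 10.0)) == 2

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 2),
                st.integers(0, 30),
                st.floats(0, 60, allow_nan=False),
                st.floats(0, 60, allow_nan=False),
            ),
            max_size=12,
        )
    )
    def test_idempotence(self, raw):
        events = [make_event(pid, f, mid=(r, c)) for pid, f, r, c in raw]
        once = deduplicate_events(events, 10.0)
        assert deduplicate_events(once, 10.0) == once


class TestCrowdingFilter:
    def scene(self, extra_nucleus=False):
        """Box with two anaphase masses, optionally an extra nucleus."""
        minint = np.full((200, 200), 250.0)
        frame = minint.copy()
        roi = PatternROI(pattern_id=0, anchor=(100, 40), box=(40, 40, 62, 62))
        for sign in (-1, 1):
            render_ellipse(
                frame, Ellipse((70.0 + sign * 7, 70.0), 4.5, 2.8, 0.0, 3000.0)
            )
        if extra_nucleus:
            render_ellipse(frame, Ellipse((88.0, 88.0), 8.0, 8.0, 0.0, 1600.0))
        # a 2 px speck, below any nucleus-size floor
        frame[44, 44] = 3000.0
        frame[44, 45] = 3000.0
        a = blob(5, 63.0, 70.0)
        b = blob(5, 77.0, 70.0)
        event = AnaphaseEvent(0, 5, a, b, (70.0, 70.0), 14.0, 90.0)
        return frame, minint, roi, event

    def test_two_masses_only_accepted(self, pipeline_config):
        frame, minint, roi, event = self.scene()
        ok, count, flag = crowding_filter(frame, minint, roi, event, pipeline_config)
        assert ok
        assert count == 2
        assert flag is None

    def test_extra_nucleus_rejected_with_count(self, pipeline_config):
        frame, minint, roi, event = self.scene(extra_nucleus=True)
        ok, count, flag = crowding_filter(frame, minint, roi, event, pipeline_config)
        assert not ok
        assert count == 3
        assert flag == "crowded_rejected"

    def test_unthresholdable_box_kept_with_flag(self, pipeline_config):
        minint = np.full((200, 200), 250.0)
        frame = minint.copy()  # residual identically zero
        roi = PatternROI(pattern_id=0, anchor=(100, 40), box=(40, 40, 62, 62))
        event = make_event(0, 5, mid=(70.0, 70.0))
        ok, _count, flag = crowding_filter(frame, minint, roi, event, pipeline_config)
        assert ok
        assert flag == "crowding_uncheckable"


class TestEventCountMonotonicity:
    def test_dedupe_never_increases_events(self):
        rng = np.random.default_rng(5)
        events = [
            make_event(int(rng.integers(0, 2)), int(rng.integers(0, 20)),
                       mid=(float(rng.uniform(0, 60)), float(rng.uniform(0, 60))))
            for _ in range(30)
        ]
        assert len(deduplicate_events(events, 10.0)) <= len(events)
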