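"""Shared fixtures: seeded synthetic fields and their pipeline outputs.

Field generation and the full pipeline are the expensive parts of the
suite, so one default field and its analysis are session-scoped and
shared by every module's tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from tracmit.config import PipelineConfig
from tracmit.pipeline import run_pipeline
from tracmit.synth import SyntheticConfig, generate_field


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_field():
    """One seeded 4x5 field, 64 frames, default acquisition conditions."""
    cfg = SyntheticConfig(n_frames=64, random_seed=1)
    stack, truth = generate_field(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def default_output(default_field, pipeline_config):
    """Full pipeline run on the default field."""
    _cfg, stack, _truth = default_field
    return run_pipeline(stack, pipeline_config)


def match_rois_to_truth(rois, truth) -> dict[int, int]:
    """Map each detected ROI's pattern_id to the nearest ground-truth
    pattern index (anchors agree to a couple of pixels on these fields)."""
    out = {}
    for roi in rois:
        d = [
            abs(roi.anchor[0] - a[0]) + abs(roi.anchor[1] - a[1])
            for a in truth.anchors
        ]
        out[roi.pattern_id] = int(np.argmin(d))
    return out


@pytest.fixture(scope="session")
def roi_truth_map(default_field, default_output):
    _cfg, _stack, truth = default_field
    return match_rois_to_truth(default_output.rois, truth)
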