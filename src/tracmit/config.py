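"""Pipeline configuration.

Every tunable of the pipeline lives in one flat, validated record with
documented defaults, loadable from a flat YAML file.  Defaults target HeLa
cells on 700 µm² L-patterns imaged at 0.65 µm/px every 8 min and were
calibrated on the synthetic suite (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .errors import ConfigKeyError, ConfigValueError

__all__ = ["PipelineConfig", "load_config", "default_config"]

Band = tuple[float, float]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline tunables.

    Bands are closed ``(low, high)`` intervals.  Pixel quantities assume
    the calibration carried by the input stack; micrometre quantities are
    converted using the stack's ``pixel_size_um``.
    """

    # -- pattern detection ------------------------------------------------
    pattern_area_um2_band: Band = (420.0, 980.0)  # 700 um^2 x (0.6, 1.4)
    median_radius_px: int = 2
    roi_box_um: Band = (40.0, 40.0)  # (height, width) of the per-pattern box
    anchor_offset_px: tuple[int, int] = (-46, -15)  # box origin - L corner, (row, col)
    # -- occupancy filter --------------------------------------------------
    fstdev_band: Band = (0.12, 0.32)
    fstdev_mode: str = "mean_of_ratio"  # or "ratio_of_means"
    # -- anaphase detection ------------------------------------------------
    log_sigma_px: float = 2.5
    log_threshold_frac: float = 0.30
    log_threshold_mode: str = "relative"  # or "absolute"
    log_threshold_abs: float = 0.0  # used only in absolute mode
    closing_radius_px: int = 2
    min_blob_area_px: int = 20
    pair_distance_band_px: Band = (6.0, 30.0)
    pair_angle_tol_deg: float = 30.0
    pair_angle_mode: str = "mass"  # or "axis": compare each mass to the pair axis
    pair_area_ratio_max: float = 2.0
    dedupe_radius_px: float = 10.0
    crowding_method: str = "intermodes"  # or "intermeans"
    min_nucleus_area_px: int = 30
    # -- backtracking ------------------------------------------------------
    reunion_profile_frac: float = 0.5
    reunion_search_frames: int = 6
    max_gap_frames: int = 3
    max_link_px: float = 10.0
    plate_major_px_band: Band = (8.0, 30.0)
    plate_minor_px_band: Band = (2.0, 10.0)
    plate_axis_ratio_min: float = 1.8
    # -- measurement -------------------------------------------------------
    expected_angle_deg: float = 45.0
    mispositioned_offset_deg: float = 40.0
    angle_median_frames: int = 3
    # -- misc --------------------------------------------------------------
    register: bool = True
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pattern_area_um2_band",
            "roi_box_um",
            "fstdev_band",
            "pair_distance_band_px",
            "plate_major_px_band",
            "plate_minor_px_band",
        ):
            band = getattr(self, name)
            if len(band) != 2:
                raise ConfigValueError(f"{name} must be a (low, high) pair")
            if band[0] > band[1]:
                raise ConfigValueError(f"{name}: low {band[0]} > high {band[1]}")
        for name in (
            "median_radius_px",
            "log_sigma_px",
            "closing_radius_px",
            "dedupe_radius_px",
            "max_link_px",
            "plate_axis_ratio_min",
            "pair_area_ratio_max",
            "min_nucleus_area_px",
            "min_blob_area_px",
        ):
            if getattr(self, name) <= 0:
                raise ConfigValueError(f"{name} must be positive")
        for name in ("log_threshold_frac", "reunion_profile_frac"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ConfigValueError(f"{name} must lie in (0, 1], got {value}")
        if self.max_gap_frames < 0:
            raise ConfigValueError("max_gap_frames must be >= 0")
        if self.angle_median_frames < 1:
            raise ConfigValueError("angle_median_frames must be >= 1")
        if self.fstdev_mode not in ("mean_of_ratio", "ratio_of_means"):
            raise ConfigValueError(f"unknown fstdev_mode {self.fstdev_mode!r}")
        if self.log_threshold_mode not in ("relative", "absolute"):
            raise ConfigValueError(f"unknown log_threshold_mode {self.log_threshold_mode!r}")
        if self.pair_angle_mode not in ("mass", "axis"):
            raise ConfigValueError(f"unknown pair_angle_mode {self.pair_angle_mode!r}")
        if self.crowding_method not in ("intermodes", "intermeans"):
            raise ConfigValueError(f"unknown crowding_method {self.crowding_method!r}")

    def roi_box_px(self, pixel_size_um: float) -> tuple[int, int]:
        """ROI box (height, width) in pixels at the given calibration."""
        return (
            int(round(self.roi_box_um[0] / pixel_size_um)),
            int(round(self.roi_box_um[1] / pixel_size_um)),
        )

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


_TUPLE_FIELDS = {
    "pattern_area_um2_band",
    "roi_box_um",
    "anchor_offset_px",
    "fstdev_band",
    "pair_distance_band_px",
    "plate_major_px_band",
    "plate_minor_px_band",
}


def default_config() -> PipelineConfig:
    """The documented defaults."""
    return PipelineConfig()


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a flat YAML key:value config file; missing keys take defaults.

    An empty or absent file yields the full default configuration.
    Unknown keys raise :class:`ConfigKeyError`; invalid values raise
    :class:`ConfigValueError`.
    """
    if path is None:
        return PipelineConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if data is None:
        return PipelineConfig()
    if not isinstance(data, dict):
        raise ConfigValueError(f"config file {path} must hold a flat mapping")
    known = {f.name for f in fields(PipelineConfig)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigKeyError(f"unknown config key {key!r}")
        if key in _TUPLE_FIELDS:
            if not isinstance(value, (list, tuple)) or len(value) != 2:
                raise ConfigValueError(f"{key} must be a 2-element list")
            value = tuple(value)
        kwargs[key] = value
    return PipelineConfig(**kwargs)
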