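"""Time-lapse stack container and TIFF I/O.

A field of view is a single-channel, 16-bit multi-page TIFF: one page per
time point, both the static micropattern fluorescence and the dynamic
chromatin fluorescence recorded in the same channel.  Physical calibration
(pixel pitch in micrometres, frame interval in minutes) is not trusted to
be present in the file and is supplied by the caller; consistent TIFF
resolution metadata, when present, overrides the argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import MultiChannelError, TooFewFramesError, UnreadableImageError

__all__ = ["TimeLapseStack", "read_stack", "write_stack"]


@dataclass
class TimeLapseStack:
    """A (frame, row, col) uint16 intensity cube with physical calibration.

    ``mask`` (optional, same shape, bool) marks pixels actually imaged in
    each frame; registration sets it False on border pixels filled with 0
    after shifting.  ``mask=None`` means every pixel of every frame is
    valid.
    """

    pixels: np.ndarray
    pixel_size_um: float
    frame_interval_min: float
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise MultiChannelError(
                f"expected a (frame, row, col) cube, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint16:
            if not np.issubdtype(self.pixels.dtype, np.integer):
                raise TypeError("stack pixels must be unsigned 16-bit integers")
            if self.pixels.min() < 0 or self.pixels.max() > 0xFFFF:
                raise ValueError("intensities outside the unsigned 16-bit range")
            self.pixels = self.pixels.astype(np.uint16)
        if self.n_frames < 2:
            raise TooFewFramesError(f"need >= 2 frames, got {self.n_frames}")
        if self.height < 32 or self.width < 32:
            raise ValueError("frames must be at least 32x32 pixels")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        if self.mask is not None and self.mask.shape != self.pixels.shape:
            raise ValueError("mask shape must match pixel shape")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def height(self) -> int:
        return self.pixels.shape[1]

    @property
    def width(self) -> int:
        return self.pixels.shape[2]

    def frame(self, t: int) -> np.ndarray:
        return self.pixels[t]

    def valid_mask(self) -> np.ndarray:
        """Boolean validity cube; materialises the all-valid default."""
        if self.mask is None:
            return np.ones(self.pixels.shape, dtype=bool)
        return self.mask

    def with_pixels(self, pixels: np.ndarray, mask: np.ndarray | None = None) -> "TimeLapseStack":
        """New stack sharing this stack's calibration."""
        return TimeLapseStack(
            pixels=pixels,
            pixel_size_um=self.pixel_size_um,
            frame_interval_min=self.frame_interval_min,
            mask=mask,
        )


def read_stack(
    path: str | Path,
    pixel_size_um: float = 0.65,
    frame_interval_min: float = 8.0,
) -> TimeLapseStack:
    """Read a single-channel multi-page TIFF as a :class:`TimeLapseStack`.

    Frames are returned in page (acquisition) order.  Raises
    :class:`UnreadableImageError` for files that are not TIFFs,
    :class:`MultiChannelError` for RGB or multi-channel input and
    :class:`TooFewFramesError` for fewer than two pages.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise UnreadableImageError(f"cannot read {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        raise TooFewFramesError(f"{path} holds a single frame; need a time-lapse")
    # RGB pages read as a trailing length-3/4 axis; a channel axis reads as
    # 4-D (T, C, H, W).  Valid greyscale frames are at least 32 px wide, so a
    # last axis of <= 4 can only be a colour axis.
    if arr.ndim != 3 or arr.shape[-1] <= 4:
        raise MultiChannelError(
            f"{path} is not a single-channel greyscale stack (shape {arr.shape})"
        )
    return TimeLapseStack(
        pixels=arr,
        pixel_size_um=pixel_size_um,
        frame_interval_min=frame_interval_min,
    )


def write_stack(stack: TimeLapseStack, path: str | Path) -> Path:
    """Write the stack as an uncompressed multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.pixels, photometric="minisblack")
    return path
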