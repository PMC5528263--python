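"""Translation-only drift correction.

Stage drift and positioning hysteresis between time points are, by
nature, translations, so alignment is translation-only: windowed phase
correlation of every frame against frame 0 initialises the shift, and a
Gauss-Newton least-squares fit restricted to static pixels (those no
moving cell ever visits) refines it to sub-pixel precision.  Frame 0 is
the fixed reference; running pairwise registration is avoided because
linking errors would accumulate over long recordings.  Corrections are
applied by linear-interpolation resampling.

Pixels shifted in from outside the field are zero-filled and flagged
invalid in the output stack's mask so temporal projections can ignore
them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.registration import phase_cross_correlation

from .errors import ConstantImageError
from .stack import TimeLapseStack

__all__ = ["DriftTrace", "estimate_drift", "apply_shifts"]


@dataclass
class DriftTrace:
    """Per-frame (dy, dx) shift of each frame relative to frame 0, plus
    the normalised correlation score of each estimate."""

    shifts: np.ndarray  # (n_frames, 2) float
    scores: np.ndarray  # (n_frames,) float

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be (n_frames, 2)")
        if not np.allclose(self.shifts[0], 0.0):
            raise ValueError("shift of the reference frame must be (0, 0)")

    @property
    def n_frames(self) -> int:
        return self.shifts.shape[0]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "dy": self.shifts[:, 0],
                "dx": self.shifts[:, 1],
                "score": self.scores,
            }
        )
        df.to_csv(path, index=False)
        return path


def _gauss_newton_shift(
    frame: np.ndarray,
    template: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    d0: np.ndarray,
    sigmas: tuple[float, ...] = (3.0, 1.0),
    max_iter: int = 10,
) -> np.ndarray:
    """Refine a translation by Gauss-Newton on the selected template
    pixels, coarse-to-fine over ``sigmas``.  Residuals are mean-centred so
    a global intensity offset between frame and template cancels."""
    d = np.asarray(d0, dtype=float).copy()
    for sig in sigmas:
        ft = ndi.gaussian_filter(frame, sig)
        tt = ndi.gaussian_filter(template, sig)
        gy, gx = np.gradient(tt)
        J = np.stack([gy[rows, cols], gx[rows, cols]], axis=1)
        J -= J.mean(axis=0)
        JTJ = J.T @ J
        if np.linalg.det(JTJ) <= 0:
            continue
        t0 = tt[rows, cols]
        t0 = t0 - t0.mean()
        rows_f = rows.astype(float)
        cols_f = cols.astype(float)
        for _ in range(max_iter):
            samp = ndi.map_coordinates(
                ft, [rows_f + d[0], cols_f + d[1]], order=1, mode="nearest"
            )
            r = samp - samp.mean() - t0
            step = np.linalg.solve(JTJ, J.T @ r)
            d -= step
            if np.abs(step).max() < 1e-4:
                break
    return d


def _static_pixels(
    pixels: np.ndarray, shifts: np.ndarray, max_points: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pick informative static pixels: align the stack with the current
    shift estimates, flag every pixel a moving object ever visited (its
    temporal range is on the cell-intensity scale), and keep the
    highest-gradient static pixels of frame 0."""
    T = pixels.shape[0]
    fill = float(np.median(pixels[0]))
    aligned = np.empty_like(pixels)
    for t in range(T):
        if np.all(shifts[t] == 0):
            aligned[t] = pixels[t]
        else:
            aligned[t] = ndi.shift(
                pixels[t], -shifts[t], order=1, mode="constant", cval=fill
            )
    rng_img = aligned.max(axis=0) - aligned.min(axis=0)
    thr = max(0.35 * float(rng_img.max()), 8.0 * float(np.median(rng_img)))
    active = ndi.binary_dilation(rng_img > thr, iterations=3)
    static = ~active
    b = 6
    static[:b, :] = False
    static[-b:, :] = False
    static[:, :b] = False
    static[:, -b:] = False
    if static.sum() < 64:  # degenerate mask: fall back to the full interior
        static = np.zeros_like(static)
        static[b:-b, b:-b] = True
    gy, gx = np.gradient(ndi.gaussian_filter(pixels[0], 1.0))
    grad = np.hypot(gy, gx)
    grad[~static] = -1.0
    n = min(max_points, int(static.sum()))
    idx = np.argpartition(grad.ravel(), -n)[-n:]
    rows, cols = np.unravel_index(idx, grad.shape)
    return rows, cols


def estimate_drift(
    stack: TimeLapseStack,
    upsample_factor: int = 20,
    max_points: int = 40_000,
) -> DriftTrace:
    """Estimate per-frame translation against frame 0.

    Two stages: windowed phase correlation of every frame against frame 0
    initialises the shifts; a Gauss-Newton least-squares refinement against
    frame 0, restricted to pixels no moving object ever visits (so cell
    motion cannot bias the stage-drift estimate), polishes them to
    sub-pixel precision.  Refinement is repeated once when the initial
    estimates prove unreliable.  Raises :class:`ConstantImageError` when a
    frame has no intensity structure (correlation undefined).
    """
    pixels = stack.pixels.astype(np.float64)
    ref = pixels[0]
    if ref.max() == ref.min():
        raise ConstantImageError("reference frame is constant; drift undefined")
    T = stack.n_frames
    hann = np.outer(np.hanning(ref.shape[0]), np.hanning(ref.shape[1]))
    ref_w = ref * hann
    init = np.zeros((T, 2), dtype=float)
    scores = np.zeros(T, dtype=float)
    scores[0] = 1.0
    for t in range(1, T):
        mov = pixels[t]
        if mov.max() == mov.min():
            raise ConstantImageError(f"frame {t} is constant; drift undefined")
        # returned shift maps the moving frame onto the reference; the
        # frame's drift relative to frame 0 is the opposite
        shift, error, _ = phase_cross_correlation(
            ref_w, mov * hann, upsample_factor=upsample_factor, normalization=None
        )
        init[t] = -shift
        scores[t] = max(0.0, 1.0 - float(error))

    shifts = init.copy()
    for _ in range(2):
        rows, cols = _static_pixels(pixels, shifts, max_points)
        refined = np.zeros_like(shifts)
        for t in range(1, T):
            refined[t] = _gauss_newton_shift(pixels[t], ref, rows, cols, shifts[t])
        moved = np.abs(refined - shifts).max()
        shifts = refined
        if moved <= 0.75:
            break
    return DriftTrace(shifts=shifts, scores=scores)


def apply_shifts(stack: TimeLapseStack, trace: DriftTrace) -> TimeLapseStack:
    """Resample every frame by its negated shift (linear interpolation).

    Out-of-field pixels are set to 0 and marked invalid in the returned
    stack's mask.  Calibration is unchanged.
    """
    if trace.n_frames != stack.n_frames:
        raise ValueError(
            f"trace has {trace.n_frames} frames, stack has {stack.n_frames}"
        )
    T, H, W = stack.pixels.shape
    out = np.empty_like(stack.pixels)
    mask = np.empty((T, H, W), dtype=bool)
    ones = np.ones((H, W), dtype=np.float64)
    for t in range(T):
        dy, dx = trace.shifts[t]
        if dy == 0.0 and dx == 0.0:
            out[t] = stack.pixels[t]
            mask[t] = True
            continue
        frame = stack.pixels[t].astype(np.float64)
        moved = ndi.shift(frame, (-dy, -dx), order=1, mode="constant", cval=0.0)
        valid = ndi.shift(ones, (-dy, -dx), order=1, mode="constant", cval=0.0)
        out[t] = np.clip(np.round(moved), 0, 65535).astype(np.uint16)
        mask[t] = valid > 0.999
    prior = stack.valid_mask() if stack.mask is not None else None
    if prior is not None:
        mask &= prior
    return stack.with_pixels(out, mask=mask)
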