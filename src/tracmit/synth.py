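"""Ground-truthed synthetic micropattern time-lapse fields.

Emulates the screen acquisition the pipeline targets: a static grid of
L-shaped fluorescent micropatterns (700 µm², 20 µm apart, 0.65 µm pixels)
plus dynamic chromatin signal from HeLa-like cells, both in one 16-bit
channel, with stage drift, photobleaching and additive Gaussian noise.
Five pattern classes are laid out by exact quota: empty, crowded (two
cells), bad position (cell out on one arm), non-dividing, and dividing.
A dividing cell is an interphase nucleus that condenses into an elongated
metaphase plate at a known angle and then splits into two separating
anaphase masses — every onset frame and true angle is recorded in the
returned :class:`GroundTruth`.

Chromatin primitives are anti-aliased filled ellipses.  Texture,
chromosome arms, cytoplasm and camera-specific noise are deliberately not
modelled; the generator renders exactly the features the detectors key on.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

from .errors import ConfigValueError, GeometryError
from .stack import TimeLapseStack

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "Ellipse",
    "render_pattern_layer",
    "simulate_mitosis_sequence",
    "generate_field",
]

CLASSES = ("empty", "crowded", "bad_position", "non_dividing", "dividing")


@dataclass(frozen=True)
class SyntheticConfig:
    """Acquisition and biology parameters of a synthetic field.

    Intensities are additive atop the background, which sits at the low
    end of ``intensity_band_au``; the composite signal is clipped to the
    band's high end before noise, mirroring the 250–4000 AU dynamic range
    of the original recordings.
    """

    grid: tuple[int, int] = (4, 5)
    pattern_area_um2: float = 700.0
    pattern_spacing_um: float = 20.0
    arm_width_um: float = 10.0
    n_frames: int = 180
    pixel_size_um: float = 0.65
    frame_interval_min: float = 8.0
    intensity_band_au: tuple[float, float] = (250.0, 4000.0)
    pattern_intensity_au: float = 550.0
    nucleus_intensity_au: float = 1600.0
    chromatin_intensity_au: float = 3000.0
    noise_sigma_au: float = 30.0
    drift_amplitude_px: float = 2.0
    constant_shift_px: tuple[float, float] = (0.0, 0.0)
    bleach_rate_per_frame: float = 0.0015
    class_fractions: dict = field(
        default_factory=lambda: {
            "empty": 0.2,
            "crowded": 0.2,
            "bad_position": 0.2,
            "non_dividing": 0.2,
            "dividing": 0.2,
        }
    )
    division_window_frames: tuple[int, int] | None = None
    metaphase_duration_frames_band: tuple[int, int] = (4, 8)
    plate_angle_model: tuple = ("uniform", 25.0, 65.0)
    nucleus_radius_um: float = 7.0
    wander_amplitude_px: float = 3.5
    plate_semi_major_px: float = 8.0
    plate_semi_minor_px: float = 2.8
    mass_semi_major_px: float = 4.5
    mass_semi_minor_px: float = 2.8
    margin_px: int = 48
    random_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.get(c, 0.0) for c in CLASSES)
        unknown = set(self.class_fractions) - set(CLASSES)
        if unknown:
            raise ConfigValueError(f"unknown cell classes {sorted(unknown)}")
        if abs(total - 1.0) > 1e-9:
            raise ConfigValueError(f"class_fractions sum to {total}, not 1")
        lo, hi = self.intensity_band_au
        if not (0 <= lo < hi <= 0xFFFF):
            raise ConfigValueError("intensity band must be increasing and within 16-bit")
        if self.n_frames < 2:
            raise ConfigValueError("need at least two frames")

    # -- derived geometry (pixels) ---------------------------------------
    @property
    def arm_width_px(self) -> int:
        return max(2, int(round(self.arm_width_um / self.pixel_size_um)))

    @property
    def arm_length_px(self) -> int:
        w = self.arm_width_px
        target_px = self.pattern_area_um2 / self.pixel_size_um**2
        return int(round((target_px + w * w) / (2 * w)))

    @property
    def pitch_px(self) -> int:
        return self.arm_length_px + int(round(self.pattern_spacing_um / self.pixel_size_um))

    @property
    def image_shape(self) -> tuple[int, int]:
        n_rows, n_cols = self.grid
        h = 2 * self.margin_px + (n_rows - 1) * self.pitch_px + self.arm_length_px
        w = 2 * self.margin_px + (n_cols - 1) * self.pitch_px + self.arm_length_px
        return h, w

    @property
    def division_window(self) -> tuple[int, int]:
        if self.division_window_frames is not None:
            return self.division_window_frames
        lo = min(10, max(1, self.n_frames // 4))
        hi = max(lo, self.n_frames - 30)
        return (lo, hi)


@dataclass
class DivisionTruth:
    metaphase_onset_frame: int
    anaphase_onset_frame: int
    true_plate_angle_deg: float


@dataclass
class GroundTruth:
    """Everything the generator knows: per-pattern class labels and
    anchors, per-dividing-cell onsets and true plate angle, and the
    per-frame global drift applied to the whole field."""

    labels: list[str]
    anchors: list[tuple[int, int]]
    divisions: dict[int, DivisionTruth]
    drift: np.ndarray  # (n_frames, 2) (dy, dx) relative to frame 0

    def class_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CLASSES}
        for lab in self.labels:
            out[lab] += 1
        return out

    def patterns_of_class(self, label: str) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab == label]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "labels": self.labels,
            "anchors": [list(a) for a in self.anchors],
            "divisions": {str(k): asdict(v) for k, v in self.divisions.items()},
            "drift": self.drift.tolist(),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            labels=list(data["labels"]),
            anchors=[tuple(a) for a in data["anchors"]],
            divisions={
                int(k): DivisionTruth(**v) for k, v in data["divisions"].items()
            },
            drift=np.asarray(data["drift"], dtype=float),
        )


@dataclass(frozen=True)
class Ellipse:
    """Anti-aliased filled ellipse primitive: ``angle_deg`` is the major
    axis direction measured from the +x (column) axis, counter-clockwise
    in a y-up frame, in [0, 180)."""

    center: tuple[float, float]  # (row, col)
    a: float  # semi-major, px
    b: float  # semi-minor, px
    angle_deg: float
    intensity_au: float


def render_ellipse(canvas: np.ndarray, e: Ellipse, shift: tuple[float, float] = (0.0, 0.0)) -> None:
    """Additively render ``e`` (optionally drift-shifted) into ``canvas``."""
    cr = e.center[0] + shift[0]
    cc = e.center[1] + shift[1]
    rad = max(e.a, e.b) + 2.0
    r0 = max(0, int(math.floor(cr - rad)))
    r1 = min(canvas.shape[0], int(math.ceil(cr + rad)) + 1)
    c0 = max(0, int(math.floor(cc - rad)))
    c1 = min(canvas.shape[1], int(math.ceil(cc + rad)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc_grid = np.mgrid[r0:r1, c0:c1]
    dr = rr - cr
    dc = cc_grid - cc
    th = math.radians(e.angle_deg)
    # major-axis unit vector in (row, col); y-up angle -> row decreases with sin
    ur, uc = -math.sin(th), math.cos(th)
    vr, vc = -math.cos(th), -math.sin(th)
    x = dr * ur + dc * uc
    y = dr * vr + dc * vc
    q = np.sqrt((x / e.a) ** 2 + (y / e.b) ** 2)
    cover = np.clip(0.5 + (1.0 - q) * min(e.a, e.b), 0.0, 1.0)
    canvas[r0:r1, c0:c1] += cover * e.intensity_au


def _l_mask(cfg: SyntheticConfig) -> np.ndarray:
    """Binary mask of one L, anchored so [-1, 0] is the lower-left corner
    pixel; arms extend up (decreasing row) and right (increasing col)."""
    L, w = cfg.arm_length_px, cfg.arm_width_px
    if L <= w:
        raise GeometryError(f"arm length {L}px must exceed arm width {w}px")
    m = np.zeros((L, L), dtype=bool)
    m[:, :w] = True          # vertical arm
    m[L - w :, :] = True     # horizontal arm
    return m


def render_pattern_layer(cfg: SyntheticConfig) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Static additive pattern layer and per-L lower-left anchor coords.

    The filled area of each L is within 2% of ``pattern_area_um2``
    (pixel quantisation permitting); a larger mismatch raises
    :class:`GeometryError`, as does a grid that does not fit.
    """
    h, w = cfg.image_shape
    n_rows, n_cols = cfg.grid
    L = cfg.arm_length_px
    mask = _l_mask(cfg)
    area_um2 = mask.sum() * cfg.pixel_size_um**2
    if abs(area_um2 - cfg.pattern_area_um2) > 0.02 * cfg.pattern_area_um2:
        raise GeometryError(
            f"quantised L area {area_um2:.1f} um^2 misses target "
            f"{cfg.pattern_area_um2} um^2 by more than 2%"
        )
    layer = np.zeros((h, w), dtype=np.float64)
    anchors = []
    for i in range(n_rows):
        for j in range(n_cols):
            top = cfg.margin_px + i * cfg.pitch_px
            left = cfg.margin_px + j * cfg.pitch_px
            if top + L > h or left + L > w:
                raise GeometryError("pattern grid does not fit the image")
            layer[top : top + L, left : left + L][mask] = cfg.pattern_intensity_au
            anchors.append((top + L - 1, left))
    return layer, anchors


def _wander(rng: np.random.Generator, n: int, amplitude: float) -> np.ndarray:
    """Smooth zero-mean 2-D wander path of length ``n``, std ~ amplitude."""
    noise = rng.normal(size=(n + 20, 2))
    path = ndi.gaussian_filter1d(noise, sigma=4.0, axis=0)[10 : 10 + n]
    std = path.std(axis=0)
    std[std == 0] = 1.0
    return path / std * amplitude


def _perp_direction(angle_deg: float) -> tuple[float, float]:
    """(row, col) unit vector perpendicular to a y-up angle."""
    th = math.radians(angle_deg + 90.0)
    return (-math.sin(th), math.cos(th))


def separation_px(cfg: SyntheticConfig, k: int) -> float:
    """Centroid separation of the anaphase masses ``k`` frames after
    anaphase onset; strictly increasing in ``k``, saturating below the
    pair-distance search band's upper end."""
    return 8.0 + 16.0 * (1.0 - 0.72 ** k)


N_SEPARATION_FRAMES = 8


def simulate_mitosis_sequence(
    cfg: SyntheticConfig,
    metaphase_onset_frame: int,
    anaphase_onset_frame: int,
    true_angle_deg: float,
    center: tuple[float, float],
    rng: np.random.Generator | None = None,
    hidden_frames: frozenset[int] | set[int] = frozenset(),
) -> list[list[Ellipse]]:
    """Per-frame chromatin primitives for one dividing cell.

    Interphase: one round wandering nucleus.  Metaphase: a single
    elongated plate at ``true_angle_deg``.  Anaphase onward: two masses
    separating symmetrically along the axis perpendicular to the plate,
    then two wandering daughter nuclei.  ``hidden_frames`` suppresses the
    chromatin primitive in the listed frames (used to inject tracking
    gaps).  Deterministic given ``rng``.
    """
    if not (0 <= metaphase_onset_frame < anaphase_onset_frame < cfg.n_frames):
        raise ConfigValueError("onset frames must satisfy 0 <= metaphase < anaphase < n_frames")
    rng = rng or np.random.default_rng(0)
    T = cfg.n_frames
    r_n = cfg.nucleus_radius_um / cfg.pixel_size_um
    wander = _wander(rng, T, cfg.wander_amplitude_px)
    jitter = rng.normal(scale=0.35, size=(T, 2))
    perp = _perp_direction(true_angle_deg)
    frames: list[list[Ellipse]] = []
    for t in range(T):
        prims: list[Ellipse] = []
        if t in hidden_frames:
            frames.append(prims)
            continue
        if t < metaphase_onset_frame:
            cr = center[0] + wander[t, 0]
            cc = center[1] + wander[t, 1]
            prims.append(Ellipse((cr, cc), r_n, r_n, 0.0, cfg.nucleus_intensity_au))
        elif t < anaphase_onset_frame:
            cr = center[0] + jitter[t, 0]
            cc = center[1] + jitter[t, 1]
            prims.append(
                Ellipse(
                    (cr, cc),
                    cfg.plate_semi_major_px,
                    cfg.plate_semi_minor_px,
                    true_angle_deg % 180.0,
                    cfg.chromatin_intensity_au,
                )
            )
        else:
            k = t - anaphase_onset_frame
            sep = separation_px(cfg, min(k, N_SEPARATION_FRAMES))
            half = sep / 2.0
            if k < N_SEPARATION_FRAMES:
                a, b = cfg.mass_semi_major_px, cfg.mass_semi_minor_px
                angle = true_angle_deg % 180.0
                inten = cfg.chromatin_intensity_au
            else:  # daughters decondense into round nuclei
                a = b = 0.75 * r_n
                angle = 0.0
                inten = cfg.nucleus_intensity_au
            for sign in (-1.0, 1.0):
                cr = center[0] + sign * half * perp[0] + jitter[t, 0]
                cc = center[1] + sign * half * perp[1] + jitter[t, 1]
                prims.append(Ellipse((cr, cc), a, b, angle, inten))
        frames.append(prims)
    return frames


def _interphase_sequence(
    cfg: SyntheticConfig,
    center: tuple[float, float],
    rng: np.random.Generator,
    amplitude_scale: float = 1.0,
) -> list[list[Ellipse]]:
    r_n = cfg.nucleus_radius_um / cfg.pixel_size_um
    wander = _wander(rng, cfg.n_frames, cfg.wander_amplitude_px * amplitude_scale)
    return [
        [
            Ellipse(
                (center[0] + wander[t, 0], center[1] + wander[t, 1]),
                r_n,
                r_n,
                0.0,
                cfg.nucleus_intensity_au,
            )
        ]
        for t in range(cfg.n_frames)
    ]


def _quota_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` patterns over classes."""
    shares = {c: fractions.get(c, 0.0) * n for c in CLASSES}
    counts = {c: int(math.floor(s)) for c, s in shares.items()}
    leftover = n - sum(counts.values())
    order = sorted(CLASSES, key=lambda c: (-(shares[c] - counts[c]), CLASSES.index(c)))
    for c in order[:leftover]:
        counts[c] += 1
    return counts


def _sample_angles(cfg: SyntheticConfig, n: int, rng: np.random.Generator) -> list[float]:
    model = cfg.plate_angle_model
    kind = model[0]
    if kind == "uniform":
        lo, hi = float(model[1]), float(model[2])
        return [float(a) % 180.0 for a in rng.uniform(lo, hi, size=n)]
    if kind == "list":
        angles = list(model[1])
        return [float(angles[i % len(angles)]) % 180.0 for i in range(n)]
    raise ConfigValueError(f"unknown plate_angle_model kind {kind!r}")


def _home_center(cfg: SyntheticConfig, anchor: tuple[int, int]) -> tuple[float, float]:
    """Interphase home: on the diagonal between the two arms."""
    d = 11.0 / cfg.pixel_size_um  # 11 um up-right of the corner
    return (anchor[0] - d, anchor[1] + d)


def generate_field(cfg: SyntheticConfig) -> tuple[TimeLapseStack, GroundTruth]:
    """Render a full synthetic field and its ground truth.

    Pattern classes are assigned by exact largest-remainder quota and
    scattered over the grid with the seeded generator; the whole render is
    bit-reproducible from ``cfg.random_seed``.
    """
    rng = np.random.default_rng(cfg.random_seed)
    layer, anchors = render_pattern_layer(cfg)
    n = len(anchors)
    counts = _quota_counts(cfg.class_fractions, n)
    labels_pool: list[str] = []
    for c in CLASSES:
        labels_pool.extend([c] * counts[c])
    perm = rng.permutation(n)
    labels = [""] * n
    for slot, lab in zip(perm, labels_pool):
        labels[slot] = lab

    T = cfg.n_frames
    bg, band_hi = cfg.intensity_band_au

    # global drift: smooth random walk (amplitude ~ drift_amplitude_px)
    # plus an optional constant per-frame shift
    steps = rng.normal(scale=1.0, size=(T, 2))
    walk = np.cumsum(steps, axis=0)
    walk -= walk[0]
    if cfg.drift_amplitude_px > 0:
        walk *= cfg.drift_amplitude_px / math.sqrt(T)
    else:
        walk[:] = 0.0
    const = np.outer(np.arange(T), np.asarray(cfg.constant_shift_px, dtype=float))
    drift = walk + const

    # per-pattern primitive timelines
    divisions: dict[int, DivisionTruth] = {}
    timelines: list[list[list[Ellipse]] | None] = [None] * n
    n_dividing = counts["dividing"] + counts["bad_position"]
    angles = _sample_angles(cfg, n_dividing, rng)
    angle_i = 0
    lo_w, hi_w = cfg.division_window
    for pid in range(n):
        lab = labels[pid]
        anchor = anchors[pid]
        child = np.random.default_rng(rng.integers(2**31))
        if lab == "empty":
            continue
        if lab == "crowded":
            c1 = _home_center(cfg, anchor)
            offset = 11.0
            seq1 = _interphase_sequence(cfg, (c1[0] - offset, c1[1] - offset), child, 1.6)
            seq2 = _interphase_sequence(cfg, (c1[0] + offset, c1[1] + offset), child, 1.6)
            timelines[pid] = [a + b for a, b in zip(seq1, seq2)]
            continue
        if lab == "non_dividing":
            timelines[pid] = _interphase_sequence(cfg, _home_center(cfg, anchor), child)
            continue
        # dividing and bad_position both run a full mitosis; the latter is
        # parked far out on the horizontal arm, outside any analysis box
        m_on = int(child.integers(lo_w, hi_w + 1))
        dur_lo, dur_hi = cfg.metaphase_duration_frames_band
        a_on = m_on + int(child.integers(dur_lo, dur_hi + 1))
        a_on = min(a_on, cfg.n_frames - 2)
        m_on = min(m_on, a_on - 1)
        angle = angles[angle_i]
        angle_i += 1
        if lab == "dividing":
            center = _home_center(cfg, anchor)
            divisions[pid] = DivisionTruth(m_on, a_on, angle)
        else:
            arm_out = 33.0 / cfg.pixel_size_um
            center = (anchor[0] - cfg.arm_width_px / 2.0, anchor[1] + arm_out)
        timelines[pid] = simulate_mitosis_sequence(cfg, m_on, a_on, angle, center, child)

    # composite, drift, bleach, noise
    static = bg + layer
    pixels = np.empty((T, *layer.shape), dtype=np.uint16)
    noise_rng = np.random.default_rng(rng.integers(2**31))
    for t in range(T):
        dy, dx = drift[t]
        if dy == 0.0 and dx == 0.0:
            canvas = static.copy()
        else:
            canvas = ndi.shift(static, (dy, dx), order=1, mode="constant", cval=bg)
        bleach = (1.0 - cfg.bleach_rate_per_frame) ** t
        for seq in timelines:
            if seq is None:
                continue
            for prim in seq[t]:
                e = Ellipse(prim.center, prim.a, prim.b, prim.angle_deg, prim.intensity_au * bleach)
                render_ellipse(canvas, e, shift=(dy, dx))
        np.clip(canvas, 0.0, band_hi, out=canvas)
        if cfg.noise_sigma_au > 0:
            canvas = canvas + noise_rng.normal(scale=cfg.noise_sigma_au, size=canvas.shape)
        np.clip(canvas, 0.0, 65535.0, out=canvas)
        pixels[t] = np.round(canvas).astype(np.uint16)

    stack = TimeLapseStack(
        pixels=pixels,
        pixel_size_um=cfg.pixel_size_um,
        frame_interval_min=cfg.frame_interval_min,
    )
    truth = GroundTruth(labels=labels, anchors=anchors, divisions=divisions, drift=drift)
    return stack, truth
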