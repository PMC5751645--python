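"""Synthetic high-speed face video with programmable micro-expressions.

The generator renders a near-frontal "face": a smooth random skin field
anchored to a built-in 68-point landmark template, darker blob features at the
brows, eyes and mouth, and one localized "muscle feature" blob centered in
each of the 10 facial cells.  A micro-expression event moves the muscle
features of its class-specific cells along a class-specific unit direction
with a piecewise-cosine onset->apex->offset envelope, rendered at sub-pixel
positions over the static skin -- the way a brow edge or mouth corner slides
over the surrounding skin.  Rendering of each moving feature is confined to
its cell's pixel window, so pixels outside the affected cells are bit-
identical across frames when noise and flicker are off.  Per-pixel Gaussian
sensor noise and an optional global multiplicative flicker (the mains-lamp
artifact typical of high-speed capture) are added on top, and frames are
quantized to the integer [0, 255] range like a real 8-bit sensor.

Everything is a pure function of (parameters, seed), so every other module can
be trained and tested reproducibly without licensed datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .dataset import Dataset, SequenceRecord
from .descriptors import FrameSequence
from .errors import ParameterError
from .geometry import CELL_NAMES, FacialCellGrid, LandmarkSet, define_cells
from .recognition import CLASSES

_SQ = math.sqrt(0.5)

#: Which cells move, and in which unit direction (x right, y down), per class.
_DIRECTIONS: dict[str, dict[str, tuple[float, float]]] = {
    # surprise: brows and eyelids rise -> upward motion in the brow/eye cells
    "surprise": {
        "left_frontalis": (0.0, -1.0),
        "procerus": (0.0, -1.0),
        "right_frontalis": (0.0, -1.0),
        "left_orbicularis_oculi": (0.0, -1.0),
        "right_orbicularis_oculi": (0.0, -1.0),
    },
    # positive: mouth corners pull outward/upward (AU12, zygomaticus major)
    # and the zygomatic region sweeps up with the cheeks (AU6)
    "positive": {
        "left_mouth_corner": (-_SQ, -_SQ),
        "right_mouth_corner": (_SQ, -_SQ),
        "left_nostril_zygomatic": (-_SQ, -_SQ),
        "right_nostril_zygomatic": (_SQ, -_SQ),
    },
    # negative: brows knit downward/inward (AU4), mouth corners depress
    # (AU15) and the chin boss pushes up (AU17, mentalis)
    "negative": {
        "left_frontalis": (_SQ, _SQ),
        "procerus": (0.0, 1.0),
        "right_frontalis": (-_SQ, _SQ),
        "left_mouth_corner": (0.0, 1.0),
        "right_mouth_corner": (0.0, 1.0),
        "mentalis": (0.0, -1.0),
    },
}

# Landmark template drawn for a 160x160 image; scaled to other sizes.
_TEMPLATE_SIZE = 160.0


def _build_template() -> np.ndarray:
    pts = np.zeros((68, 2))
    # jaw outline 0-16: half ellipse from left temple through chin
    t = np.arange(17) * math.pi / 16.0
    pts[0:17, 0] = 80.0 - 42.0 * np.cos(t)
    pts[0:17, 1] = 70.0 + 62.0 * np.sin(t)
    # brows 17-21 (left), 22-26 (right)
    pts[17:22] = [(48, 66), (54, 62), (61, 60), (67, 61), (74, 63)]
    pts[22:27] = [(86, 63), (93, 61), (99, 60), (106, 62), (112, 66)]
    # nose bridge 27-30 and lower nose 31-35
    pts[27:31] = [(80, 66), (80, 74), (80, 82), (80, 90)]
    pts[31:36] = [(70, 96), (75, 98), (80, 100), (85, 98), (90, 96)]
    # eyes 36-41 (left), 42-47 (right)
    pts[36:42] = [(50, 72), (54, 69), (60, 69), (64, 72), (60, 75), (54, 75)]
    pts[42:48] = [(96, 72), (102, 69), (108, 69), (112, 72), (108, 75), (102, 75)]
    # outer lip 48-59 and inner lip 60-67
    pts[48:60] = [(62, 112), (68, 108), (74, 106), (80, 105), (86, 106),
                  (92, 108), (98, 112), (92, 116), (86, 118), (80, 119),
                  (74, 118), (68, 116)]
    pts[60:68] = [(65, 112), (73, 110), (80, 109), (87, 110), (95, 112),
                  (87, 114), (80, 115), (73, 114)]
    return pts


_TEMPLATE = _build_template()


def landmark_template(image_size: tuple[int, int] = (160, 160)) -> LandmarkSet:
    """The built-in synthetic frontal-face landmark layout, scaled to ``image_size``."""
    h, w = image_size
    scale = np.array([w / _TEMPLATE_SIZE, h / _TEMPLATE_SIZE])
    return LandmarkSet(points=_TEMPLATE * scale)


def class_direction_template(cls: str) -> dict[str, np.ndarray]:
    """Unit motion directions per cell for one expression class.

    Cells the class does not move get zero vectors.  Directions are in image
    coordinates (y points down), so raising the brows is (0, -1).
    """
    if cls not in _DIRECTIONS:
        raise ParameterError(f"unknown expression class {cls!r}")
    out: dict[str, np.ndarray] = {}
    for name in CELL_NAMES:
        v = np.asarray(_DIRECTIONS[cls].get(name, (0.0, 0.0)), dtype=float)
        n = np.linalg.norm(v)
        out[name] = v / n if n > 0 else v
    return out


@dataclass(frozen=True)
class ExpressionEvent:
    """One micro-expression: class, onset/apex/offset frames, peak magnitude (px)."""

    cls: str
    onset: int
    apex: int
    offset: int
    magnitude: float = 2.0

    def __post_init__(self) -> None:
        if self.cls not in _DIRECTIONS:
            raise ParameterError(f"unknown expression class {self.cls!r}")
        if not self.onset < self.apex < self.offset:
            raise ParameterError(f"need onset < apex < offset, got {self}")
        if self.magnitude <= 0:
            raise ParameterError("magnitude must be > 0")

    def envelope(self, t: int) -> float:
        """Piecewise-cosine activation: 0 at onset/offset, 1 at the apex."""
        if t <= self.onset or t >= self.offset:
            return 0.0
        if t <= self.apex:
            u = (t - self.onset) / (self.apex - self.onset)
        else:
            u = (self.offset - t) / (self.offset - self.apex)
        return 0.5 * (1.0 - math.cos(math.pi * u))


@dataclass
class SceneParams:
    """Scene-level knobs of the generator.

    noise_sigma is the per-pixel additive Gaussian sigma in 0-255 intensity
    units (2 by default, a realistic high-speed sensor level); flicker_amp is
    the amplitude of a global multiplicative sinusoid (off by default) with
    period flicker_period frames.
    """

    image_size: tuple[int, int] = (160, 160)
    fps: float = 100.0
    seq_len: int = 260
    noise_sigma: float = 2.0
    flicker_amp: float = 0.0
    flicker_period: float = 13.0
    events: tuple[ExpressionEvent, ...] = ()
    texture_seed: int = 0
    landmarks: LandmarkSet | None = None

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if not 0 <= self.flicker_amp <= 0.2:
            raise ParameterError("flicker_amp must be in [0, 0.2]")
        if self.seq_len < 1:
            raise ParameterError("seq_len must be >= 1")
        for ev in self.events:
            if ev.onset < 0 or ev.offset >= self.seq_len:
                raise ParameterError(
                    f"event {ev} lies outside the sequence [0, {self.seq_len})")

    def resolved_landmarks(self) -> LandmarkSet:
        return self.landmarks or landmark_template(self.image_size)


#: Amplitude/width (intensity units, px) of the per-cell muscle-feature blob.
FEATURE_AMP = 60.0
FEATURE_SIGMA = 3.0


def _subtract_blob(img: np.ndarray, px: float, py: float, amp: float,
                   sigma: float, window=None) -> None:
    """Darken ``img`` by a Gaussian blob at (px, py), optionally clipped to
    a half-open (x0, x1, y0, y1) pixel window."""
    h, w = img.shape
    if window is None:
        x0 = max(int(px - 4 * sigma), 0)
        x1 = min(int(px + 4 * sigma) + 1, w)
        y0 = max(int(py - 4 * sigma), 0)
        y1 = min(int(py + 4 * sigma) + 1, h)
    else:
        x0, x1, y0, y1 = window
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] -= amp * np.exp(
        -(((xx - px) ** 2 + (yy - py) ** 2) / (2.0 * sigma ** 2)))


def render_base_face(landmarks: LandmarkSet, image_size: tuple[int, int],
                     texture_seed: int) -> np.ndarray:
    """Static background: smooth random skin field with landmark-anchored features.

    A Gaussian-smoothed random field provides skin-like texture; darker blobs
    at the brow, eye and outer-lip landmarks mimic facial features.  The
    per-cell muscle features are rendered separately, per frame, because they
    move.  Values stay within a range that later noise rarely clips.
    """
    h, w = image_size
    rng = np.random.default_rng(texture_seed)
    field_ = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=3.0)
    field_ *= 12.0 / max(field_.std(), 1e-9)
    img = 128.0 + field_
    feature_pts = np.concatenate([
        landmarks.points[17:27],   # brows
        landmarks.points[36:48],   # eyes
        landmarks.points[48:60],   # outer lip
    ])
    for (px, py) in feature_pts:
        _subtract_blob(img, px, py, 25.0, 2.0)
    return np.clip(img, 20.0, 235.0)


def _cell_anchors(grid: FacialCellGrid,
                  shape: tuple[int, int]) -> dict[str, tuple]:
    """Rest position (pixel-grid centroid of the clipped cell) and pixel
    window for each cell's muscle feature.

    Anchoring at the grid centroid (rather than the real-valued cell center)
    keeps the rest position identical to the centroid of a uniform motion
    image over the cell, so centroid displacements measure pure motion.
    """
    anchors = {}
    for cell in grid:
        x0, x1, y0, y1 = cell.bounds(shape)
        anchors[cell.name] = (((x0 + x1 - 1) / 2.0, (y0 + y1 - 1) / 2.0),
                              (x0, x1, y0, y1))
    return anchors


def _render_features(frame: np.ndarray, anchors: dict[str, tuple],
                     shifts: dict[str, np.ndarray]) -> None:
    """Draw every cell's muscle feature at its (possibly displaced) position.

    Each feature is clipped to its cell's pixel window, so an event never
    changes pixels outside its cells.
    """
    for name, ((ax, ay), window) in anchors.items():
        dx, dy = shifts.get(name, (0.0, 0.0))
        _subtract_blob(frame, ax + dx, ay + dy, FEATURE_AMP, FEATURE_SIGMA,
                       window=window)


def generate_sequence(params: SceneParams, seed: int,
                      subject_id: str = "subj00",
                      sequence_id: str = "seq00",
                      ) -> tuple[FrameSequence, LandmarkSet, pd.DataFrame]:
    """Render one annotated sequence: frames, landmarks, ground-truth table.

    Frames are float32 but hold integer values in [0, 255] (8-bit sensor
    quantization), which makes the on-disk round trip lossless.  The
    annotation table follows the standard schema (subject_id, sequence_id,
    onset, apex, offset, label).  Deterministic given (params, seed).
    """
    landmarks = params.resolved_landmarks()
    grid = define_cells(landmarks)
    base = render_base_face(landmarks, params.image_size, params.texture_seed)
    anchors = _cell_anchors(grid, params.image_size)
    rng = np.random.default_rng(seed)

    h, w = params.image_size
    frames = np.empty((params.seq_len, h, w), dtype=np.float32)
    dir_maps = {ev: class_direction_template(ev.cls) for ev in params.events}
    for t in range(params.seq_len):
        frame = base.copy()
        shifts: dict[str, np.ndarray] = {}
        for ev in params.events:
            a = ev.envelope(t)
            if a > 0.0:
                for name, d in dir_maps[ev].items():
                    if d[0] != 0.0 or d[1] != 0.0:
                        shifts[name] = shifts.get(name, 0.0) + a * ev.magnitude * d
        _render_features(frame, anchors, shifts)
        if params.flicker_amp > 0.0:
            frame *= 1.0 + params.flicker_amp * math.sin(
                2.0 * math.pi * t / params.flicker_period)
        if params.noise_sigma > 0.0:
            frame = frame + rng.normal(0.0, params.noise_sigma, size=(h, w))
        frames[t] = np.clip(np.rint(frame), 0.0, 255.0)

    rows = [
        {"subject_id": subject_id, "sequence_id": sequence_id,
         "onset": ev.onset, "apex": ev.apex, "offset": ev.offset,
         "label": ev.cls}
        for ev in params.events
    ]
    annotations = pd.DataFrame(
        rows, columns=["subject_id", "sequence_id", "onset", "apex", "offset", "label"])
    return FrameSequence(frames=frames, fps=params.fps), landmarks, annotations


def _sample_events(rng: np.random.Generator, seq_len: int,
                   class_mix: dict[str, float],
                   event_count_probs: tuple[float, ...],
                   magnitude_range: tuple[float, float],
                   duration_range: tuple[int, int]) -> list[ExpressionEvent]:
    classes = list(class_mix)
    probs = np.asarray([class_mix[c] for c in classes], dtype=float)
    probs /= probs.sum()
    k = int(rng.choice(len(event_count_probs), p=np.asarray(event_count_probs)))
    events: list[ExpressionEvent] = []
    cursor_onset_lo, cursor_onset_hi = 30, 50
    for _ in range(k):
        duration = int(rng.integers(duration_range[0], duration_range[1] + 1))
        onset = int(rng.integers(cursor_onset_lo, cursor_onset_hi + 1))
        # slow build-up, fast release: the apex (moment of peak displacement)
        # sits late in the event, as in spontaneous expressions that are
        # rapidly suppressed
        apex = onset + int(round(duration * rng.uniform(0.78, 0.88)))
        offset = onset + duration
        if offset >= seq_len - 10:
            break  # no room left; keep fewer events
        cls = str(rng.choice(classes, p=probs))
        events.append(ExpressionEvent(
            cls=cls, onset=onset, apex=apex, offset=offset,
            magnitude=float(rng.uniform(*magnitude_range))))
        # next event starts well beyond the merge radius of the post-processing
        gap = int(rng.integers(90, 111))
        cursor_onset_lo = offset + gap
        cursor_onset_hi = cursor_onset_lo + 20
    return events


def generate_dataset(n_subjects: int = 8,
                     sequences_per_subject: int = 5,
                     class_mix: dict[str, float] | None = None,
                     params: SceneParams | None = None,
                     seed: int = 0,
                     event_count_probs: tuple[float, ...] = (0.2, 0.6, 0.2),
                     magnitude_range: tuple[float, float] = (1.0, 4.0),
                     duration_range: tuple[int, int] = (28, 44),
                     landmark_jitter: float = 0.8) -> Dataset:
    """Generate an annotated multi-subject dataset for leave-one-subject-out runs.

    Each subject gets a distinct base-face texture seed and a small Gaussian
    perturbation of the landmark template; each sequence carries 0, 1 or 2
    events (distribution ``event_count_probs``) with classes drawn from
    ``class_mix`` (uniform thirds by default), durations from
    ``duration_range`` frames and peak magnitudes from ``magnitude_range``
    pixels.  Deterministic given the arguments.
    """
    if n_subjects < 2:
        raise ParameterError("need at least 2 subjects")
    class_mix = class_mix or {c: 1.0 / 3.0 for c in CLASSES}
    base_params = params or SceneParams()
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(n_subjects)

    sequences: list[SequenceRecord] = []
    for si in range(n_subjects):
        subject_id = f"subj{si:02d}"
        s_rng = np.random.default_rng(subject_seeds[si])
        texture_seed = int(s_rng.integers(0, 2**31 - 1))
        template = landmark_template(base_params.image_size)
        jitter = s_rng.normal(0.0, landmark_jitter, size=(68, 2))
        landmarks = LandmarkSet(points=template.points + jitter)
        for qi in range(sequences_per_subject):
            events = _sample_events(
                s_rng, base_params.seq_len, class_mix, event_count_probs,
                magnitude_range, duration_range)
            seq_params = replace(
                base_params, events=tuple(events), texture_seed=texture_seed,
                landmarks=landmarks)
            seq_seed = int(s_rng.integers(0, 2**31 - 1))
            sequence_id = f"{subject_id}_seq{qi:02d}"
            frames, lms, ann = generate_sequence(
                seq_params, seq_seed, subject_id=subject_id,
                sequence_id=sequence_id)
            sequences.append(SequenceRecord(
                subject_id=subject_id, sequence_id=sequence_id,
                frames=frames, landmarks=lms, annotations=ann))
    return Dataset(sequences=sequences)
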