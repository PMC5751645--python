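"""Frame-difference motion descriptors.

The central quantity is the motion-magnitude image

    MM_t = (|frame_t - frame_{t - tau/2}| + 1) / (|frame_t - frame_{t - eps}| + 1)

where ``tau`` is the average micro-expression duration in frames and ``eps``
is a small offset (3 frames by default).  The numerator measures motion since
a potential onset frame half a micro-expression back; the denominator, motion
over a span too short for any facial movement, normalizes out sensor noise
and flicker.  On a static scene MM is exactly 1 everywhere.

Spotting consumes the per-cell mean of MM over time; recognition consumes the
drift of the intensity-weighted centroid of MM inside each cell across a
resampled window around the apex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ShapeError
from .geometry import CELL_NAMES, Cell, FacialCellGrid


@dataclass
class FrameSequence:
    """Ordered stack of 2D grayscale frames (values in [0, 255]) plus fps."""

    frames: np.ndarray  # (T, H, W)
    fps: float = 100.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ShapeError(f"frames must be a (T, H, W) stack, got {arr.shape}")
        self.frames = arr

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @classmethod
    def from_list(cls, frames, fps: float = 100.0) -> "FrameSequence":
        stack = np.stack([np.asarray(f) for f in frames])
        return cls(frames=stack, fps=fps)


@dataclass(frozen=True)
class DescriptorParams:
    """Descriptor parameters.

    tau : average micro-expression duration in frames (65 at 200 fps,
          37 at ~100 fps); also the spotting/recognition window size.
    eps : normalization offset in frames; 3 frames is short enough that no
          facial movement can occur between them at high frame rates.
    n_resample : number of frames the recognition window is resampled to.
    delta : half-width of the frame-labeling window around the apex, as a
            fraction of tau.
    """

    tau: int = 37
    eps: int = 3
    n_resample: int = 11
    delta: float = 0.25
    mm_baseline: str = "eq1"  # or "window_start": numerator reference is F_0

    def __post_init__(self) -> None:
        if self.tau < 2:
            raise ParameterError("tau must be >= 2")
        if self.eps < 1:
            raise ParameterError("eps must be >= 1")
        if not self.eps < self.tau / 2:
            raise ParameterError("eps must be < tau/2")
        if self.n_resample < 2:
            raise ParameterError("n_resample must be >= 2")
        if not 0 < self.delta < 0.5:
            raise ParameterError("delta must be in (0, 0.5)")
        if self.mm_baseline not in ("eq1", "window_start"):
            raise ParameterError("mm_baseline must be 'eq1' or 'window_start'")

    @property
    def half_tau(self) -> int:
        return self.tau // 2

    @property
    def signal_start(self) -> int:
        """First frame index with a defined cell signal (prefix is zeroed)."""
        return math.ceil(self.tau / 2)


@dataclass
class CellSignal:
    """Per-cell time series of mean motion magnitude; zero on the prefix."""

    series: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if tuple(self.series) != CELL_NAMES:
            raise ShapeError("cell signals must carry the 10 canonical cells in order")
        lengths = {len(v) for v in self.series.values()}
        if len(lengths) != 1:
            raise ShapeError("all cell series must have equal length")

    def __len__(self) -> int:
        return len(next(iter(self.series.values())))

    def as_matrix(self) -> np.ndarray:
        """(T, 10) matrix in canonical cell order."""
        return np.stack([self.series[n] for n in CELL_NAMES], axis=1)


@dataclass
class DisplacementFeature:
    """Per cell, the (n_resample - 1) weighted-centroid displacements (dx, dy)
    of the resampled apex window relative to its first frame, in pixels."""

    pairs: dict[str, np.ndarray]  # name -> (n_resample - 1, 2)

    def __post_init__(self) -> None:
        if tuple(self.pairs) != CELL_NAMES:
            raise ShapeError("displacement features must carry the 10 canonical cells")
        shapes = {v.shape for v in self.pairs.values()}
        if len(shapes) != 1 or next(iter(shapes))[1] != 2:
            raise ShapeError("each cell needs an (n-1, 2) displacement array")
        for v in self.pairs.values():
            if not np.all(np.isfinite(v)):
                raise ShapeError("displacements must be finite")

    @property
    def n_pairs(self) -> int:
        return next(iter(self.pairs.values())).shape[0]


def motion_magnitude(seq: FrameSequence, t: int, params: DescriptorParams) -> np.ndarray:
    """Motion-magnitude image at frame ``t`` (real arithmetic, always > 0).

    Reference indices ``t - tau//2`` and ``t - eps`` are clamped to 0 near the
    start of the sequence.
    """
    if not 0 <= t < len(seq):
        raise IndexError(f"frame index {t} out of range [0, {len(seq)})")
    f = seq.frames[t].astype(np.float64)
    f_onset = seq.frames[max(t - params.half_tau, 0)].astype(np.float64)
    f_near = seq.frames[max(t - params.eps, 0)].astype(np.float64)
    return (np.abs(f - f_onset) + 1.0) / (np.abs(f - f_near) + 1.0)


def cell_mean(mm: np.ndarray, cell: Cell) -> float:
    """Arithmetic mean of a motion-magnitude image over the clipped cell square."""
    x0, x1, y0, y1 = cell.bounds(mm.shape)
    return float(mm[y0:y1, x0:x1].mean())


def compute_cell_signals(seq: FrameSequence, grid: FacialCellGrid,
                         params: DescriptorParams) -> CellSignal:
    """Mean motion magnitude per cell over time.

    For t < ceil(tau/2) the motion-magnitude image is not meaningful (there is
    no onset reference half a window back), so the signal is stored as 0.
    Computation is restricted to each cell's pixel window for speed.
    """
    T = len(seq)
    idx = np.arange(T)
    i_onset = np.maximum(idx - params.half_tau, 0)
    i_near = np.maximum(idx - params.eps, 0)
    start = params.signal_start

    series: dict[str, np.ndarray] = {}
    shape = seq.shape
    for cell in grid:
        x0, x1, y0, y1 = cell.bounds(shape)
        sub = seq.frames[:, y0:y1, x0:x1].astype(np.float64)
        num = np.abs(sub - sub[i_onset]) + 1.0
        den = np.abs(sub - sub[i_near]) + 1.0
        s = (num / den).mean(axis=(1, 2))
        s[:start] = 0.0
        series[cell.name] = s
    return CellSignal(series=series)


def weighted_centroid(mm: np.ndarray, cell: Cell) -> tuple[float, float]:
    """Intensity-weighted centroid (cx, cy) of MM over the clipped cell.

    Pixel coordinates are integer centers; the total MM mass is positive by
    construction (MM > 0 everywhere), so the centroid is always defined.
    """
    x0, x1, y0, y1 = cell.bounds(mm.shape)
    sub = mm[y0:y1, x0:x1]
    total = sub.sum()
    xs = np.arange(x0, x1, dtype=np.float64)
    ys = np.arange(y0, y1, dtype=np.float64)
    cx = float((sub.sum(axis=0) * xs).sum() / total)
    cy = float((sub.sum(axis=1) * ys).sum() / total)
    return cx, cy


def resample_window(start: int, end: int, n: int) -> np.ndarray:
    """``n`` frame indices spread evenly over [start, end], rounded half-up.

    The first index is ``start`` and the last ``end``; indices are
    non-decreasing and may repeat when ``n`` exceeds the window length.
    """
    if end < start:
        raise ParameterError(f"end ({end}) must be >= start ({start})")
    if n < 2:
        raise ParameterError("n must be >= 2")
    pos = start + np.arange(n) * (end - start) / (n - 1)
    return np.floor(pos + 0.5).astype(int)


def displacement_features(seq: FrameSequence, grid: FacialCellGrid, apex: int,
                          params: DescriptorParams) -> DisplacementFeature:
    """Centroid-displacement feature for the window of size tau around ``apex``.

    The window [apex - tau//2, apex + tau//2] (clamped to the sequence) is
    resampled to ``n_resample`` frames F_0..F_{n-1}; for each cell the
    weighted centroid of MM at each resampled frame is computed, and the
    output pairs are centroid(F_i) - centroid(F_0) for i = 1..n-1.

    With ``mm_baseline="window_start"`` the numerator reference of MM is F_0
    itself instead of the frame tau//2 back.
    """
    if not 0 <= apex < len(seq):
        raise IndexError(f"apex {apex} out of range [0, {len(seq)})")
    w0 = max(apex - params.half_tau, 0)
    w1 = min(apex + params.half_tau, len(seq) - 1)
    idxs = resample_window(w0, w1, params.n_resample)

    centroids: dict[str, list[tuple[float, float]]] = {n: [] for n in CELL_NAMES}
    for t in idxs:
        if params.mm_baseline == "window_start":
            f = seq.frames[t].astype(np.float64)
            f0 = seq.frames[idxs[0]].astype(np.float64)
            f_near = seq.frames[max(t - params.eps, 0)].astype(np.float64)
            mm = (np.abs(f - f0) + 1.0) / (np.abs(f - f_near) + 1.0)
        else:
            mm = motion_magnitude(seq, int(t), params)
        for cell in grid:
            centroids[cell.name].append(weighted_centroid(mm, cell))

    pairs = {}
    for name in CELL_NAMES:
        c = np.asarray(centroids[name], dtype=np.float64)
        pairs[name] = c[1:] - c[0]
    return DisplacementFeature(pairs=pairs)
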