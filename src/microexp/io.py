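"""Readers and writers for the on-disk formats the pipeline consumes.

Frame directories hold BMP/PNG images ordered lexicographically by filename;
high-speed capture rigs commonly name files by the frame timestamp, so purely
numeric stems are parsed as integer microseconds and used to recover the frame
rate.  Landmarks come either in the plain-text pts dialect (version/n_points
header, one "x y" pair per line) or as a CSV of (frame_index, point_index, x,
y).  Annotations are a CSV of (subject_id, sequence_id, onset, apex, offset,
label) with 0-based inclusive frame indices.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .descriptors import FrameSequence
from .errors import FormatError
from .geometry import LandmarkSet

ANNOTATION_COLUMNS = ["subject_id", "sequence_id", "onset", "apex", "offset", "label"]
VALID_LABELS = {"positive", "negative", "surprise", "other"}

# ITU-R BT.601 luma weights for color -> grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse a color image to BT.601 luma; pass grayscale through."""
    if image.ndim == 2:
        return image.astype(np.float32)
    if image.ndim == 3 and image.shape[2] in (3, 4):
        return (image[..., :3].astype(np.float64) @ _LUMA).astype(np.float32)
    raise FormatError(f"cannot interpret image of shape {image.shape}")


def read_frame_dir(path, fps: float | None = None) -> FrameSequence:
    """Read a directory of BMP/PNG frames, lexicographic filename order.

    If every filename stem is an integer it is taken as a timestamp in
    microseconds and the fps is recovered from the median inter-frame gap;
    otherwise ``fps`` (default 100) is used.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in (".png", ".bmp"))
    if not files:
        raise FormatError(f"{path}: no .png/.bmp frames found")
    frames = [to_grayscale(iio.imread(p)) for p in files]
    stems = [p.stem for p in files]
    if fps is None and all(re.fullmatch(r"\d+", s) for s in stems) and len(files) > 1:
        ts = np.array([int(s) for s in stems], dtype=np.int64)
        dt = np.median(np.diff(ts))
        fps = 1e6 / float(dt) if dt > 0 else 100.0
    return FrameSequence.from_list(frames, fps=fps if fps else 100.0)


def write_frame_dir(seq: FrameSequence, path, fmt: str = "png") -> list[Path]:
    """Write frames as 8-bit images named by synthetic microsecond timestamps."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dt_us = int(round(1e6 / seq.fps))
    written = []
    for i in range(len(seq)):
        img = np.clip(np.rint(seq.frames[i]), 0, 255).astype(np.uint8)
        p = path / f"{i * dt_us:012d}.{fmt}"
        iio.imwrite(p, img)
        written.append(p)
    return written


def read_landmarks_pts(path) -> LandmarkSet:
    """Read one landmark set in the plain-text pts dialect."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    pts: list[tuple[float, float]] = []
    n_expected = None
    in_body = False
    for ln in lines:
        low = ln.lower()
        if low.startswith("version:"):
            continue
        if low.startswith("n_points:"):
            n_expected = int(ln.split(":")[1])
            continue
        if ln == "{":
            in_body = True
            continue
        if ln == "}":
            in_body = False
            continue
        if in_body or n_expected is not None:
            parts = ln.split()
            if len(parts) != 2:
                raise FormatError(f"{path}: malformed point line {ln!r}")
            pts.append((float(parts[0]), float(parts[1])))
    if n_expected is not None and len(pts) != n_expected:
        raise FormatError(f"{path}: header says {n_expected} points, found {len(pts)}")
    if len(pts) != 68:
        raise FormatError(f"{path}: expected 68 points, found {len(pts)}")
    return LandmarkSet(points=np.asarray(pts))


def write_landmarks_pts(landmarks: LandmarkSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("version: 1\nn_points: 68\n{\n")
        for x, y in landmarks.points:
            fh.write(f"{x:.6f} {y:.6f}\n")
        fh.write("}\n")


def read_landmarks_csv(path) -> dict[int, LandmarkSet]:
    """Read per-frame landmark sets from a (frame_index, point_index, x, y) CSV.

    A file carrying a single frame index means one set applies to the whole
    sequence; use :func:`single_landmark_set` to collapse it.
    """
    df = pd.read_csv(path)
    required = {"frame_index", "point_index", "x", "y"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    out: dict[int, LandmarkSet] = {}
    for frame_idx, grp in df.groupby("frame_index"):
        grp = grp.sort_values("point_index")
        if list(grp["point_index"]) != list(range(68)):
            raise FormatError(
                f"{path}: frame {frame_idx} must carry point_index 0..67 exactly")
        out[int(frame_idx)] = LandmarkSet(points=grp[["x", "y"]].to_numpy(float))
    return out


def write_landmarks_csv(landmark_sets: dict[int, LandmarkSet], path) -> None:
    rows = []
    for frame_idx in sorted(landmark_sets):
        pts = landmark_sets[frame_idx].points
        for pi, (x, y) in enumerate(pts):
            rows.append({"frame_index": frame_idx, "point_index": pi, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def single_landmark_set(landmark_sets: dict[int, LandmarkSet]) -> LandmarkSet:
    """Collapse a per-frame landmark mapping holding exactly one set."""
    if len(landmark_sets) != 1:
        raise FormatError(
            f"expected a single landmark set, found {len(landmark_sets)} frames")
    return next(iter(landmark_sets.values()))


def read_annotations(path) -> pd.DataFrame:
    """Read and validate the annotation CSV (header row required)."""
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns {missing}")
    df = df[ANNOTATION_COLUMNS].copy()
    for col in ("onset", "apex", "offset"):
        df[col] = df[col].astype(int)
    bad = df[~df["label"].isin(VALID_LABELS)]
    if len(bad):
        raise FormatError(f"{path}: invalid labels {sorted(bad['label'].unique())}")
    if ((df["onset"] > df["apex"]) | (df["apex"] > df["offset"])).any():
        raise FormatError(f"{path}: need onset <= apex <= offset in every row")
    return df


def write_annotations(df: pd.DataFrame, path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, index=False)


def write_predictions(rows: pd.DataFrame, path) -> None:
    """Write the prediction CSV (sequence_id, predicted_class, per-class scores)."""
    rows.to_csv(path, index=False)


def write_dataset(dataset, root, fmt: str = "png") -> Path:
    """Materialize a synthetic dataset as frame directories plus annotations.csv."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for rec in dataset:
        seq_dir = root / rec.sequence_id
        write_frame_dir(rec.frames, seq_dir, fmt=fmt)
        write_landmarks_pts(rec.landmarks, seq_dir / "landmarks.pts")
    write_annotations(dataset.annotations, root / "annotations.csv")
    return root
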