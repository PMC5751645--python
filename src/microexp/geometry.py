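"""Face geometry: 68-point landmarks, roll normalization, and muscle-aligned cells.

The analysis operates on 10 axis-aligned square regions ("cells") of the face,
each roughly covering the territory of one facial-expression muscle: the left
and right frontalis and the procerus above the brows, the two orbicularis oculi
around the eyes, two cells lateral to the nostrils over the zygomatic area, the
two mouth corners, and the mentalis on the chin.  Cells are positioned from a
68-point landmark set in the iBUG ordering (face outline 1-17, brows 18-27,
nose 28-36, eyes 37-48, mouth 49-68; names are 1-based, storage is 0-based) and
their common side length is half the mouth width.

Only in-plane rotation (roll) is corrected before placing cells; yaw and pitch
are out of scope since all available micro-expression recordings are frontal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import CellGeometryError, DegenerateGeometryError, ShapeError

#: Canonical order of the 10 facial cells.  All feature vectors follow it.
CELL_NAMES: tuple[str, ...] = (
    "left_frontalis",
    "procerus",
    "right_frontalis",
    "left_orbicularis_oculi",
    "right_orbicularis_oculi",
    "left_nostril_zygomatic",
    "right_nostril_zygomatic",
    "left_mouth_corner",
    "right_mouth_corner",
    "mentalis",
)

# 0-based indices of the landmarks used as anchors (1-based iBUG names in
# comments).
_OUTER_EYE_LEFT = 36   # 37: left outer eye corner
_OUTER_EYE_RIGHT = 45  # 46: right outer eye corner
_MOUTH_LEFT = 48       # 49: left mouth corner
_MOUTH_RIGHT = 54      # 55: right mouth corner
_LOWER_LIP = 57        # 58: bottom of the outer lower lip


@dataclass(frozen=True)
class LandmarkSet:
    """68 ordered 2D facial landmarks in pixel coordinates (x right, y down)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (68, 2):
            raise ShapeError(f"expected 68 landmarks of dim 2, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise DegenerateGeometryError("landmarks contain non-finite coordinates")
        if self._dist(_MOUTH_LEFT, _MOUTH_RIGHT, pts) <= 0:
            raise DegenerateGeometryError("mouth corners coincide (zero mouth width)")
        object.__setattr__(self, "points", pts)

    @staticmethod
    def _dist(i: int, j: int, pts: np.ndarray) -> float:
        return float(np.linalg.norm(pts[i] - pts[j]))

    @property
    def mouth_width(self) -> float:
        return self._dist(_MOUTH_LEFT, _MOUTH_RIGHT, self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def transformed(self, points: np.ndarray) -> "LandmarkSet":
        return LandmarkSet(points=points)


@dataclass(frozen=True)
class Cell:
    """One axis-aligned square cell: a name, a center and a side, in pixels."""

    name: str
    center: tuple[float, float]
    side: float

    def bounds(self, shape: tuple[int, int]) -> tuple[int, int, int, int]:
        """Half-open pixel bounds (x0, x1, y0, y1) of the cell clipped to ``shape``.

        ``shape`` is (height, width).  Rounding is half-up so bounds are
        deterministic.  Raises :class:`CellGeometryError` when the clipped
        cell contains no pixels.
        """
        h, w = shape
        half = self.side / 2.0
        cx, cy = self.center
        x0 = int(math.floor(cx - half + 0.5))
        x1 = int(math.floor(cx + half + 0.5))
        y0 = int(math.floor(cy - half + 0.5))
        y1 = int(math.floor(cy + half + 0.5))
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            raise CellGeometryError(
                f"cell {self.name!r} is empty after clipping to image {shape}"
            )
        return x0c, x1c, y0c, y1c


@dataclass(frozen=True)
class FacialCellGrid:
    """The 10 muscle-aligned cells, in canonical order, sharing one side length."""

    cells: tuple[Cell, ...]

    def __post_init__(self) -> None:
        names = tuple(c.name for c in self.cells)
        if names != CELL_NAMES:
            raise ShapeError(f"cells must be the 10 canonical cells in order, got {names}")
        sides = {c.side for c in self.cells}
        if len(sides) != 1 or next(iter(sides)) <= 0:
            raise DegenerateGeometryError("all cells must share one positive side length")

    def __iter__(self):
        return iter(self.cells)

    def __getitem__(self, name: str) -> Cell:
        for c in self.cells:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.cells)

    @property
    def side(self) -> float:
        return self.cells[0].side


@dataclass(frozen=True)
class CellLayout:
    """Offsets (in units of the cell side) that place cells from landmark anchors.

    The frontalis/procerus cells sit above the brow anchors, the
    nostril-zygomatic cells lateral to the nose wings, and the mentalis below
    the lower lip.  Defaults reproduce the standard layout; all are exposed so
    the grid can be adapted to unusual face proportions.
    """

    frontalis_up: float = 0.6
    nostril_out: float = 0.75
    mentalis_down: float = 0.75


def estimate_roll(landmarks: LandmarkSet) -> float:
    """In-plane (roll) angle of the face, radians.

    Measured as the angle of the line joining the two outer eye corners
    (landmarks 37 and 46, 1-based) with respect to the image x-axis.
    """
    p1 = landmarks.points[_OUTER_EYE_LEFT]
    p2 = landmarks.points[_OUTER_EYE_RIGHT]
    d = p2 - p1
    if np.hypot(*d) < 1e-12:
        raise DegenerateGeometryError("outer eye corners coincide; roll undefined")
    return float(math.atan2(d[1], d[0]))


def _rotation_matrix(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def rotate_landmarks(landmarks: LandmarkSet, theta: float,
                     center: np.ndarray | None = None) -> LandmarkSet:
    """Rotate landmarks by ``theta`` about ``center`` (default: their centroid)."""
    c = landmarks.centroid if center is None else np.asarray(center, dtype=float)
    pts = (landmarks.points - c) @ _rotation_matrix(theta).T + c
    return landmarks.transformed(pts)


def normalize_roll(frame: np.ndarray,
                   landmarks: LandmarkSet) -> tuple[np.ndarray, LandmarkSet]:
    """Rotate image and landmarks about the landmark centroid so roll becomes 0.

    The image is resampled with bilinear interpolation; pixels coming from
    outside the original frame are filled with 0.  When the roll is already
    exactly 0 the inputs are returned unchanged (bitwise for landmarks).
    """
    theta = estimate_roll(landmarks)
    if theta == 0.0:
        return frame.copy(), landmarks
    new_lms = rotate_landmarks(landmarks, -theta)
    c = landmarks.centroid  # rotation about the centroid keeps it fixed

    # Output pixel (x, y) samples input at R(theta) (x - c) + c.  ndimage
    # works in (row, col) = (y, x) order, so the matrix is transposed/flipped.
    ct, st = math.cos(theta), math.sin(theta)
    m_rc = np.array([[ct, st], [-st, ct]])  # acts on (y, x)
    c_rc = c[::-1]
    offset = c_rc - m_rc @ c_rc
    rotated = ndimage.affine_transform(
        np.asarray(frame, dtype=float), m_rc, offset=offset, order=1,
        mode="constant", cval=0.0,
    )
    return rotated, new_lms


def define_cells(landmarks: LandmarkSet,
                 layout: CellLayout | None = None) -> FacialCellGrid:
    """Place the 10 muscle-aligned square cells from roll-normalized landmarks.

    The side of every cell is half the mouth width (distance between landmarks
    49 and 55, 1-based).  Centers come from landmark anchors: mid-brow points
    for the frontalis cells, the inner-brow midline for the procerus, eye
    centroids for the orbicularis oculi, nose wings (offset outward) for the
    nostril-zygomatic cells, the mouth corners, and a point below the lower
    lip for the mentalis.
    """
    layout = layout or CellLayout()
    pts = landmarks.points
    side = 0.5 * landmarks.mouth_width
    if side <= 0:
        raise DegenerateGeometryError("zero mouth width")

    up = np.array([0.0, -layout.frontalis_up * side])
    out = layout.nostril_out * side
    down = np.array([0.0, layout.mentalis_down * side])

    centers = {
        # 1-based anchors in comments
        "left_frontalis": pts[[19, 20]].mean(axis=0) + up,        # 20, 21
        "procerus": pts[[21, 22]].mean(axis=0) + up,              # 22, 23
        "right_frontalis": pts[[23, 24]].mean(axis=0) + up,       # 24, 25
        "left_orbicularis_oculi": pts[36:42].mean(axis=0),        # 37-42
        "right_orbicularis_oculi": pts[42:48].mean(axis=0),       # 43-48
        "left_nostril_zygomatic": pts[31] + np.array([-out, 0.0]),   # 32
        "right_nostril_zygomatic": pts[35] + np.array([out, 0.0]),   # 36
        "left_mouth_corner": pts[_MOUTH_LEFT].copy(),             # 49
        "right_mouth_corner": pts[_MOUTH_RIGHT].copy(),           # 55
        "mentalis": pts[_LOWER_LIP] + down,                       # 58
    }
    cells = tuple(
        Cell(name=name, center=(float(centers[name][0]), float(centers[name][1])),
             side=float(side))
        for name in CELL_NAMES
    )
    return FacialCellGrid(cells=cells)
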