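"""Shared domain containers.

Coordinate convention used everywhere in this package: 0-based, ``x`` is the
column index and ``y`` the row index.  Landmark CSV files store ``(X=column,
Y=row)``.  Dense displacement fields are *backward* maps: the registered
image is ``output(p) = input(p + d(p))``, so a field (or any coordinate map)
sends fixed-frame coordinates to the frame of the image being resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np


@dataclass
class LandmarkSet:
    """Ordered list of (x, y) points with integer ids, tied to one section."""

    points: np.ndarray  # (n, 2) float, columns (x, y)
    ids: np.ndarray  # (n,) int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.ids = np.asarray(self.ids, dtype=int).reshape(-1)
        if len(self.ids) != len(self.points):
            raise ValueError("ids and points length mismatch")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("duplicate landmark ids")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite landmark coordinates")

    def __len__(self) -> int:
        return len(self.ids)

    def scaled(self, sx: float, sy: float) -> "LandmarkSet":
        pts = self.points * np.array([sx, sy])
        return LandmarkSet(pts, self.ids.copy())


@dataclass
class Section:
    """An RGB section raster plus its acquisition metadata.

    ``pixel_size_um`` is the physical size of one pixel at the *current*
    resolution; ``resolution_fraction`` records which fraction of the
    full-resolution rendition this raster is.
    """

    pixels: np.ndarray  # (rows, cols, 3) uint8
    pixel_size_um: float = 1.0
    resolution_fraction: float = 1.0
    stain: str = ""
    landmarks: LandmarkSet | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("Section pixels must be (rows, cols, 3)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not (0 < self.resolution_fraction <= 1):
            raise ValueError("resolution_fraction must be in (0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def diagonal_px(self) -> float:
        r, c = self.shape
        return float(np.hypot(r, c))

    def copy(self) -> "Section":
        lm = None
        if self.landmarks is not None:
            lm = LandmarkSet(self.landmarks.points.copy(), self.landmarks.ids.copy())
        return replace(self, pixels=self.pixels.copy(), landmarks=lm)


@dataclass
class BinaryMask:
    """Boolean raster with physical pixel size, same shape as its source."""

    values: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def area(self) -> int:
        return int(self.values.sum())


@dataclass
class DisplacementField:
    """Dense backward-mapping displacement, in pixels.

    ``u`` holds x-displacements and ``v`` y-displacements; sampling the
    source at ``(x + u, y + v)`` produces the registered image.
    """

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError("field components differ in shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    @classmethod
    def zero(cls, shape: tuple[int, int]) -> "DisplacementField":
        return cls(np.zeros(shape), np.zeros(shape))

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def map_points(self, points: np.ndarray) -> np.ndarray:
        """Apply the backward map p -> p + d(p) to (n, 2) (x, y) points.

        The field is interpolated bilinearly at the query points.
        """
        from scipy.ndimage import map_coordinates

        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        coords = np.stack([pts[:, 1], pts[:, 0]])  # (row, col)
        du = map_coordinates(self.u, coords, order=1, mode="nearest")
        dv = map_coordinates(self.v, coords, order=1, mode="nearest")
        return pts + np.stack([du, dv], axis=1)

    def jacobian_determinant(self) -> np.ndarray:
        """det of the Jacobian of the map p -> p + d(p), per pixel."""
        du_dy, du_dx = np.gradient(self.u)
        dv_dy, dv_dx = np.gradient(self.v)
        return (1.0 + du_dx) * (1.0 + dv_dy) - du_dy * dv_dx


@dataclass
class AffineMap:
    """2-D affine coordinate map x' = A x + t acting on (x, y) points."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("singular affine matrix")

    def map_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return pts @ self.matrix.T + self.offset

    def inverse(self) -> "AffineMap":
        inv = np.linalg.inv(self.matrix)
        return AffineMap(inv, -inv @ self.offset)

    @classmethod
    def identity(cls) -> "AffineMap":
        return cls()

    @classmethod
    def rotation(cls, degrees: float, center: Sequence[float]) -> "AffineMap":
        """Counter-clockwise rotation (in x-right / y-down raster axes the
        visual sense is clockwise) about ``center``."""
        th = np.deg2rad(degrees)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = np.asarray(center, dtype=float)
        return cls(rot, c - rot @ c)

    @classmethod
    def translation(cls, dx: float, dy: float) -> "AffineMap":
        return cls(np.eye(2), np.array([dx, dy]))


@dataclass
class RigidPrealign:
    """Pre-alignment: translation bringing centers of mass together followed
    by the best sweep rotation about the translated moving center of mass."""

    translation: tuple[float, float]
    rotation_deg: float
    rotation_center: tuple[float, float]

    def forward(self) -> AffineMap:
        """Map moving-frame coordinates into the fixed frame."""
        t = AffineMap.translation(*self.translation)
        r = AffineMap.rotation(self.rotation_deg, self.rotation_center)
        # translate first, then rotate about the (post-translation) center
        return compose_affine(r, t)

    def backward(self) -> AffineMap:
        return self.forward().inverse()


def compose_affine(outer: AffineMap, inner: AffineMap) -> AffineMap:
    """Affine map equal to outer(inner(x))."""
    return AffineMap(outer.matrix @ inner.matrix,
                     outer.matrix @ inner.offset + outer.offset)


CoordinateMap = Callable[[np.ndarray], np.ndarray]


class ComposedTransform:
    """Ordered chain of backward coordinate maps.

    ``stages`` are applied fixed-frame first: with stages [s1, s2, s3] the
    composed map is p -> s3(s2(s1(p))).  In the registration pipeline the
    innermost (first-applied) stage is the last-estimated one, so appending
    a new refinement stage *prepends* nothing — callers build the chain as
    [local, demons, affine, prealign] via :meth:`prepended`.
    """

    def __init__(self, stages: Sequence[CoordinateMap] = ()) -> None:
        self.stages = list(stages)

    def prepended(self, stage: CoordinateMap) -> "ComposedTransform":
        """New transform applying ``stage`` before the existing chain."""
        return ComposedTransform([stage, *self.stages])

    def map_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        for s in self.stages:
            pts = s(pts)
        return pts

    def dense_field(self, shape: tuple[int, int]) -> DisplacementField:
        rows, cols = shape
        yy, xx = np.mgrid[0:rows, 0:cols]
        pts = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
        mapped = self.map_points(pts)
        d = mapped - pts
        return DisplacementField(d[:, 0].reshape(shape), d[:, 1].reshape(shape))
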