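"""Shared 3D geometric primitives.

All public functions accept array-likes of shape ``(3,)`` for points and
``(n, 3)`` for polylines.  Coordinates are in Å everywhere at the API
boundary; internally the functions are unit-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Segment3",
    "euclidean",
    "point_to_line_distance",
    "point_to_segment_distance",
    "polyline_length",
]


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3D point, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("point coordinates must be finite")
    return a


@dataclass(frozen=True)
class Segment3:
    """A line segment between two 3D points.

    ``a`` may equal ``b``; the degenerate case is handled explicitly by the
    distance functions below (they fall back to point-to-point distance).
    """

    a: np.ndarray
    b: np.ndarray

    def __init__(self, a, b):
        object.__setattr__(self, "a", _as_point(a))
        object.__setattr__(self, "b", _as_point(b))

    @property
    def length(self) -> float:
        return euclidean(self.a, self.b)


def euclidean(p, q) -> float:
    """Euclidean distance between two 3D points."""
    return float(np.linalg.norm(_as_point(p) - _as_point(q)))


def point_to_line_distance(p, line: Segment3) -> float:
    """Perpendicular distance from ``p`` to the infinite line through ``line``.

    If the line's endpoints coincide the distance to that single point is
    returned.
    """
    p = _as_point(p)
    d = line.b - line.a
    dd = float(d @ d)
    if dd == 0.0:
        return float(np.linalg.norm(p - line.a))
    # component of (p - a) orthogonal to the line direction
    w = p - line.a
    t = float(w @ d) / dd
    return float(np.linalg.norm(w - t * d))


def point_to_segment_distance(p, seg: Segment3) -> float:
    """Distance from ``p`` to the *finite* segment ``seg``.

    Equals the perpendicular line distance when the foot of the perpendicular
    lies within the segment, otherwise the distance to the nearest endpoint.
    """
    p = _as_point(p)
    d = seg.b - seg.a
    dd = float(d @ d)
    if dd == 0.0:
        return float(np.linalg.norm(p - seg.a))
    t = float((p - seg.a) @ d) / dd
    t = min(1.0, max(0.0, t))
    return float(np.linalg.norm(p - (seg.a + t * d)))


def points_to_segment_distances(points: np.ndarray, seg: Segment3) -> np.ndarray:
    """Vectorized :func:`point_to_segment_distance` for an ``(n, 3)`` array."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = seg.b - seg.a
    dd = float(d @ d)
    if dd == 0.0:
        return np.linalg.norm(pts - seg.a, axis=1)
    t = np.clip((pts - seg.a) @ d / dd, 0.0, 1.0)
    feet = seg.a + t[:, None] * d
    return np.linalg.norm(pts - feet, axis=1)


def polyline_length(path) -> float:
    """Total length of a polyline given as an ``(n, 3)`` vertex array.

    Zero-length segments (repeated vertices) contribute 0; a single-vertex
    polyline has length 0.
    """
    v = np.atleast_2d(np.asarray(path, dtype=float))
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValueError("polyline must be an (n, 3) array")
    if v.shape[0] < 1:
        raise ValueError("polyline needs at least one vertex")
    if v.shape[0] == 1:
        return 0.0
    return float(np.linalg.norm(np.diff(v, axis=0), axis=1).sum())
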