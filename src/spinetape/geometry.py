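"""Small planar-geometry primitives shared across modules.

Everything operates on 2-D points in millimetres, as ``(x, y)`` arrays.
"""

from __future__ import annotations

import numpy as np


def as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"expected a 2-D point, got shape {a.shape}")
    return a


def cross2(a, b) -> float:
    """z-component of the cross product of two planar vectors."""
    return float(a[0] * b[1] - a[1] * b[0])


def point_line_distance(p, a, b) -> float:
    """Unsigned perpendicular distance of point ``p`` from the infinite
    line through ``a`` and ``b``."""
    p, a, b = as_point(p), as_point(a), as_point(b)
    d = b - a
    n = np.hypot(*d)
    if n == 0.0:
        raise ValueError("degenerate line: a == b")
    return abs(cross2(d, p - a)) / n


def signed_point_line_distance(p, a, normal) -> float:
    """Distance of ``p`` from the line through ``a`` with unit normal
    ``normal``; positive on the side the normal points to."""
    return float(np.dot(as_point(p) - as_point(a), as_point(normal)))


def circumcircle(p1, p2, p3) -> tuple[np.ndarray, float]:
    """Center and radius of the circle through three non-collinear points.

    Solves the two perpendicular-bisector equations as a 2x2 linear system.
    Raises ``np.linalg.LinAlgError`` via the solver for collinear input only
    when exactly singular; callers should pre-check collinearity.
    """
    p1, p2, p3 = as_point(p1), as_point(p2), as_point(p3)
    A = 2.0 * np.array([p2 - p1, p3 - p1])
    b = np.array([p2 @ p2 - p1 @ p1, p3 @ p3 - p1 @ p1])
    center = np.linalg.solve(A, b)
    return center, float(np.hypot(*(p1 - center)))


def rotate(points: np.ndarray, angle_rad: float, origin=(0.0, 0.0)) -> np.ndarray:
    """Rotate a point or (n, 2) point array counter-clockwise about ``origin``."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    R = np.array([[c, -s], [s, c]])
    o = as_point(origin)
    pts = np.asarray(points, dtype=float)
    out = (np.atleast_2d(pts) - o) @ R.T + o
    return out[0] if pts.ndim == 1 else out


def polyline_length(points: np.ndarray) -> float:
    pts = np.atleast_2d(points)
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def cumulative_arclength(points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(points)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def fit_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) least-squares circle fit to an (n, 3+) point set.

    Returns (center, radius). Linear in the unknowns, exact for points that
    lie on a circle; adequate for the near-noise-free fits used here.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points to fit a circle")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = np.sqrt(c + cx**2 + cy**2)
    return np.array([cx, cy]), float(r)


def hausdorff_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two planar point sets."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    d = np.hypot(a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1])
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))
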