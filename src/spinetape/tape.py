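"""Curvature-measurement-tape data model.

The sensor tape reports the back profile as an ordered list of short
elements, each described by three sagittal-plane points (start, mid, end).
An element is either a circular arc through the three points or, when the
midpoint is collinear with the chord, a straight line. Chaining the densely
sampled elements end to end reconstructs the continuous sagittal curve of
the back.

Coordinate convention: sagittal plane, +x caudal along the mattress top,
+y vertically away from the mattress, units mm throughout.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    ChainError,
    InvalidElementError,
    MustBeLineError,
    ResampleError,
    TapeParseError,
)
from .geometry import (
    as_point,
    circumcircle,
    cumulative_arclength,
    point_line_distance,
)

logger = logging.getLogger(__name__)

#: Native tape geometry: 870 mm of tape divided into 29 elements of 30 mm.
TAPE_LENGTH_MM = 870.0
TAPE_N_ELEMENTS = 29
ELEMENT_LENGTH_MM = TAPE_LENGTH_MM / TAPE_N_ELEMENTS

#: Default perpendicular-distance tolerance below which an element counts
#: as a straight line (mm); an order below plausible sensor resolution.
DEFAULT_TOL_LINE = 0.05

TAPE_CSV_COLUMNS = ["element_id", "x_start", "y_start", "x_mid", "y_mid", "x_end", "y_end"]


@dataclass(frozen=True)
class ArcElement:
    """One tape segment: three sagittal points plus its ordinal position."""

    p_start: np.ndarray
    p_mid: np.ndarray
    p_end: np.ndarray
    index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "p_start", as_point(self.p_start))
        object.__setattr__(self, "p_mid", as_point(self.p_mid))
        object.__setattr__(self, "p_end", as_point(self.p_end))
        if np.array_equal(self.p_start, self.p_end):
            raise InvalidElementError(
                f"element {self.index}: p_start equals p_end (zero chord)"
            )

    @property
    def chord_length(self) -> float:
        return float(np.hypot(*(self.p_end - self.p_start)))

    def check_native_length(self, tol_len: float = 0.05) -> bool:
        """Whether the element arclength is within ``tol_len`` of the native
        30 mm tape element length."""
        lo = ELEMENT_LENGTH_MM * (1 - tol_len)
        hi = ELEMENT_LENGTH_MM * (1 + tol_len)
        return lo <= element_arclength(self) <= hi


@dataclass(frozen=True)
class SpinalCurve:
    """Ordered sagittal polyline, cranial end first, with arclength chart.

    ``s`` is cumulative arclength (mm) per point: strictly increasing,
    ``s[0] == 0``.
    """

    points: np.ndarray
    s: np.ndarray

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        s = np.asarray(self.s, dtype=float)
        if pts.shape[0] != s.shape[0]:
            raise ValueError("points and s must have matching lengths")
        if s[0] != 0.0 or np.any(np.diff(s) <= 0):
            raise ValueError("s must be strictly increasing from 0")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "s", s)

    @classmethod
    def from_points(cls, points: np.ndarray) -> "SpinalCurve":
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return cls(pts, cumulative_arclength(pts))

    @property
    def length(self) -> float:
        return float(self.s[-1])

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def point_at(self, s_query) -> np.ndarray:
        """Linear interpolation of the polyline at arclength(s) ``s_query``."""
        sq = np.atleast_1d(np.asarray(s_query, dtype=float))
        x = np.interp(sq, self.s, self.points[:, 0])
        y = np.interp(sq, self.s, self.points[:, 1])
        out = np.column_stack([x, y])
        return out[0] if np.isscalar(s_query) else out


def classify_element(e: ArcElement, tol_line: float = DEFAULT_TOL_LINE) -> str:
    """Classify an element as ``"line"`` or ``"arc"``.

    A line is declared when the perpendicular distance of the midpoint from
    the start-end chord is below ``tol_line`` (mm).
    """
    if tol_line <= 0:
        raise ValueError("tol_line must be positive")
    d = point_line_distance(e.p_mid, e.p_start, e.p_end)
    return "line" if d < tol_line else "arc"


def fit_arc(e: ArcElement, tol_line: float = DEFAULT_TOL_LINE):
    """Circumscribed circle through the element's three points.

    Returns ``(center, radius, theta_start, theta_end)`` where the angular
    sweep from ``theta_start`` to ``theta_end`` (signed, so it may be
    negative for clockwise traversal) passes through the midpoint.
    """
    if classify_element(e, tol_line) == "line":
        raise MustBeLineError(f"element {e.index} is collinear; fit_arc undefined")
    center, radius = circumcircle(e.p_start, e.p_mid, e.p_end)
    a0 = np.arctan2(*(e.p_start - center)[::-1])
    a1 = np.arctan2(*(e.p_end - center)[::-1])
    am = np.arctan2(*(e.p_mid - center)[::-1])
    sweep_ccw = (a1 - a0) % (2 * np.pi)
    mid_ccw = (am - a0) % (2 * np.pi)
    sweep = sweep_ccw if mid_ccw <= sweep_ccw else sweep_ccw - 2 * np.pi
    return center, radius, float(a0), float(a0 + sweep)


def element_arclength(e: ArcElement, tol_line: float = DEFAULT_TOL_LINE) -> float:
    """Arclength of an element: chord length for lines, R*|sweep| for arcs."""
    if classify_element(e, tol_line) == "line":
        return e.chord_length
    _, radius, a0, a1 = fit_arc(e, tol_line)
    return radius * abs(a1 - a0)


def sample_element(
    e: ArcElement, n: int = 20, tol_line: float = DEFAULT_TOL_LINE
) -> np.ndarray:
    """``n`` points along the element from start to end (inclusive)."""
    if n < 2:
        raise ValueError("need at least 2 sample points")
    if classify_element(e, tol_line) == "line":
        t = np.linspace(0.0, 1.0, n)[:, None]
        return e.p_start * (1 - t) + e.p_end * t
    center, radius, a0, a1 = fit_arc(e, tol_line)
    theta = np.linspace(a0, a1, n)
    return center + radius * np.column_stack([np.cos(theta), np.sin(theta)])


def chain_elements(
    elements,
    gap_tol: float = 0.5,
    points_per_element: int = 20,
    tol_line: float = DEFAULT_TOL_LINE,
) -> SpinalCurve:
    """Chain ordered elements into one continuous sagittal curve.

    Each element is densely sampled and concatenated. Junctions are closed
    by rigidly translating the later element (no rotation, preserving the
    measured inclinations); a warning is logged when the original endpoint
    gap exceeds ``gap_tol`` mm.
    """
    elements = list(elements)
    if not elements:
        raise ChainError("cannot chain an empty element list")
    idx = [e.index for e in elements]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ChainError(f"elements not ordered by index: {idx}")

    pts = [sample_element(elements[0], points_per_element, tol_line)]
    offset = np.zeros(2)
    for prev, e in zip(elements, elements[1:]):
        p = sample_element(e, points_per_element, tol_line) + offset
        gap = pts[-1][-1] - p[0]
        if np.hypot(*gap) > gap_tol:
            logger.warning(
                "gap of %.3f mm between elements %d and %d exceeds gap_tol=%.3f; "
                "translating later element",
                np.hypot(*gap), prev.index, e.index, gap_tol,
            )
            warnings.warn(
                f"endpoint gap {np.hypot(*gap):.3f} mm between elements "
                f"{prev.index} and {e.index} repaired by translation",
                stacklevel=2,
            )
        offset += gap
        pts.append(p + gap[None, :])
    all_pts = np.vstack([pts[0]] + [p[1:] for p in pts[1:]])
    return SpinalCurve.from_points(all_pts)


def resample_curve(c: SpinalCurve, spacing: float) -> SpinalCurve:
    """Resample a curve at (near-)equal arclength spacing.

    The number of intervals is ``round(length / spacing)`` so the actual
    spacing may differ slightly from the request; endpoints are preserved
    exactly and the arclength chart (hence total length) is preserved.
    """
    if spacing <= 0:
        raise ResampleError("spacing must be positive")
    L = c.length
    if spacing >= L:
        raise ResampleError(f"spacing {spacing} mm >= curve length {L:.3f} mm")
    n_int = max(1, int(round(L / spacing)))
    targets = np.linspace(0.0, L, n_int + 1)
    pts = c.point_at(targets)
    pts[0] = c.points[0]
    pts[-1] = c.points[-1]
    return SpinalCurve(pts, targets)


# ---------------------------------------------------------------------------
# serialization


def _elements_from_frame(df: pd.DataFrame, source: str, expected_count) -> list:
    missing = [col for col in TAPE_CSV_COLUMNS if col not in df.columns]
    if missing:
        raise TapeParseError(f"{source}: missing column(s) {missing}")
    elements = []
    seen = set()
    for row_no, row in enumerate(df.itertuples(index=False)):
        vals = {}
        for col in TAPE_CSV_COLUMNS:
            v = getattr(row, col)
            try:
                vals[col] = float(v)
            except (TypeError, ValueError):
                raise TapeParseError(
                    f"{source}: non-numeric value {v!r} in column {col}, row {row_no}"
                ) from None
            if pd.isna(vals[col]):
                raise TapeParseError(
                    f"{source}: empty/NaN value in column {col}, row {row_no}"
                )
        eid = int(vals["element_id"])
        if eid in seen:
            raise TapeParseError(f"{source}: duplicate element_id {eid} at row {row_no}")
        seen.add(eid)
        elements.append(
            ArcElement(
                p_start=(vals["x_start"], vals["y_start"]),
                p_mid=(vals["x_mid"], vals["y_mid"]),
                p_end=(vals["x_end"], vals["y_end"]),
                index=eid,
            )
        )
    if expected_count is not None and len(elements) != expected_count:
        warnings.warn(
            f"{source}: expected {expected_count} elements, found {len(elements)}",
            stacklevel=3,
        )
    return elements


def read_tape_csv(path, expected_count: int | None = TAPE_N_ELEMENTS) -> list:
    """Read an ordered element list from tape CSV (row order defines order)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise TapeParseError(f"{path}: {exc}") from exc
    return _elements_from_frame(df, str(path), expected_count)


def write_tape_csv(elements, path) -> None:
    rows = [
        {
            "element_id": e.index,
            "x_start": e.p_start[0], "y_start": e.p_start[1],
            "x_mid": e.p_mid[0], "y_mid": e.p_mid[1],
            "x_end": e.p_end[0], "y_end": e.p_end[1],
        }
        for e in elements
    ]
    pd.DataFrame(rows, columns=TAPE_CSV_COLUMNS).to_csv(path, index=False)


def read_tape_json(path, expected_count: int | None = TAPE_N_ELEMENTS) -> list:
    """JSON equivalent of the tape CSV: a list of objects with the same keys."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    df = pd.DataFrame(data)
    return _elements_from_frame(df, str(path), expected_count)


def write_tape_json(elements, path) -> None:
    buf = io.StringIO()
    write_tape_csv(elements, buf)
    buf.seek(0)
    df = pd.read_csv(buf)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(df.to_dict(orient="records"), fh, indent=1)


def write_curve_csv(c: SpinalCurve, path) -> None:
    pd.DataFrame(
        {"s_mm": c.s, "x_mm": c.points[:, 0], "y_mm": c.points[:, 1]}
    ).to_csv(path, index=False)


def read_curve_csv(path) -> SpinalCurve:
    df = pd.read_csv(path)
    return SpinalCurve(df[["x_mm", "y_mm"]].to_numpy(), df["s_mm"].to_numpy())
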