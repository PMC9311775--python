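"""Sagittal spine alignment metrics from a reconstructed back profile.

The torso inclination (TI) line is the common support line of the thoracic
and sacral regions on the mattress side: the line through one thoracic and
one sacral curve point that leaves every point of both regions on the body
side. TI is the absolute angle of that line to the +x (mattress-top) axis.
The remaining metrics are perpendicular distances to the TI line, measured
on the away-from-mattress side:

* HD  - distance of the cranial curve endpoint (the head point);
* CLD - maximum distance over the cervical region (cervical lordosis apex);
* LLD - maximum distance over the lumbar region (lumbar lordosis apex).

Perpendicular (rather than vertical) distances make HD/CLD/LLD invariant
under rigid motions of the curve.

Region boundaries along the tape are not anatomically fixed by the device;
they are configurable arclength fractions (:class:`RegionPartition`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import NoTangentError, RegionError
from .geometry import cross2
from .tape import SpinalCurve

REGION_NAMES = ("head", "cervical", "thoracic", "lumbar", "sacral")


@dataclass(frozen=True)
class RegionPartition:
    """Arclength fractions (cranial -> caudal) delimiting spinal regions.

    head [0, f1), cervical [f1, f2), thoracic [f2, f3), lumbar [f3, f4),
    sacral [f4, f5]. The remainder (f5, 1] caudal of the sacral region is
    unassigned tape.
    """

    f1: float = 0.05
    f2: float = 0.20
    f3: float = 0.55
    f4: float = 0.75
    f5: float = 0.90

    def __post_init__(self):
        fs = (self.f1, self.f2, self.f3, self.f4, self.f5)
        if not (0 < fs[0] < fs[1] < fs[2] < fs[3] < fs[4] <= 1):
            raise ValueError(f"invalid region partition {fs}")

    def bounds(self, name: str) -> tuple[float, float]:
        lo = {"head": 0.0, "cervical": self.f1, "thoracic": self.f2,
              "lumbar": self.f3, "sacral": self.f4}[name]
        hi = {"head": self.f1, "cervical": self.f2, "thoracic": self.f3,
              "lumbar": self.f4, "sacral": self.f5}[name]
        return lo, hi

    def mask(self, name: str, c: SpinalCurve) -> np.ndarray:
        lo, hi = self.bounds(name)
        frac = c.s / c.length
        if name == "sacral":
            return (frac >= lo) & (frac <= hi)
        return (frac >= lo) & (frac < hi)


@dataclass(frozen=True)
class TILine:
    """The torso-inclination support line.

    ``point`` lies on the line, ``direction`` is a unit vector along it,
    ``normal`` is the unit normal pointing to the body (away-from-mattress)
    side, and ``tangent_points`` are the two touching curve points (thoracic
    first, sacral second).
    """

    point: np.ndarray
    direction: np.ndarray
    normal: np.ndarray
    tangent_points: np.ndarray

    def distance(self, p) -> np.ndarray:
        """Signed distance(s); positive on the body side."""
        q = np.atleast_2d(np.asarray(p, dtype=float)) - self.point
        d = q @ self.normal
        return float(d[0]) if np.asarray(p).ndim == 1 else d

    @property
    def angle_deg(self) -> float:
        """Absolute inclination to the +x axis, folded into [0, 90]."""
        a = abs(np.degrees(np.arctan2(self.direction[1], self.direction[0])))
        a = a % 180.0
        return float(min(a, 180.0 - a))


@dataclass(frozen=True)
class SpineParameters:
    TI_deg: float
    HD_mm: float
    CLD_mm: float
    LLD_mm: float
    tangent_points: np.ndarray

    def as_dict(self) -> dict:
        return {
            "TI_deg": self.TI_deg,
            "HD_mm": self.HD_mm,
            "CLD_mm": self.CLD_mm,
            "LLD_mm": self.LLD_mm,
            "tangent_points": np.asarray(self.tangent_points).tolist(),
        }


def _lower_chain(pts2: np.ndarray) -> list[int]:
    """Indices of the lower convex hull chain of points sorted by column 0."""
    order = np.lexsort((pts2[:, 1], pts2[:, 0]))
    chain: list[int] = []
    for i in order:
        while len(chain) >= 2:
            o, a = pts2[chain[-2]], pts2[chain[-1]]
            if cross2(a - o, pts2[i] - o) <= 0:
                chain.pop()
            else:
                break
        chain.append(int(i))
    return chain


def torso_inclination_line(
    c: SpinalCurve, part: RegionPartition | None = None
) -> tuple[TILine, np.ndarray, float]:
    """Common thoracic-sacral support line on the mattress side.

    Implemented via the lower convex hull (mattress side, package convention
    +y away from the mattress) of the union of the thoracic and sacral point
    sets; the hull edge spanning the two regions is the support line. Curves
    must be oriented within the package coordinate convention (support
    direction within 45 degrees of +x).

    Returns ``(line, tangent_points, TI_deg)``.
    """
    part = part or RegionPartition()
    thor = c.points[part.mask("thoracic", c)]
    sac = c.points[part.mask("sacral", c)]
    if len(thor) < 3 or len(sac) < 3:
        raise NoTangentError(
            f"need >=3 points per region (thoracic {len(thor)}, sacral {len(sac)})"
        )
    union = np.vstack([thor, sac])
    is_thor = np.arange(len(union)) < len(thor)

    chain = _lower_chain(union)
    edge = None
    for a, b in zip(chain, chain[1:]):
        if is_thor[a] != is_thor[b]:
            edge = (a, b) if is_thor[a] else (b, a)
            break
    if edge is None:
        raise NoTangentError("no hull edge spans the thoracic and sacral regions")
    pa, pb = union[edge[0]], union[edge[1]]
    d = pb - pa
    d = d / np.hypot(*d)
    n = np.array([-d[1], d[0]])
    # orient the normal to the body side (region centroid side)
    if (union.mean(axis=0) - pa) @ n < 0:
        n = -n
    line = TILine(point=pa, direction=d, normal=n, tangent_points=np.array([pa, pb]))
    return line, line.tangent_points, line.angle_deg


def head_distance(c: SpinalCurve, line: TILine) -> float:
    """Perpendicular distance of the cranial endpoint (s = 0) to the TI line.

    Negative values (head below the support line) are physically odd; they
    are clipped to 0 with a warning.
    """
    d = line.distance(c.points[0])
    if d < 0:
        warnings.warn(
            f"head point lies {-d:.2f} mm below the TI support line; clipping HD to 0",
            stacklevel=2,
        )
        return 0.0
    return float(d)


def _region_max_distance(c: SpinalCurve, line: TILine, part, name: str) -> float:
    mask = part.mask(name, c)
    if not mask.any():
        raise RegionError(f"region '{name}' holds no curve points")
    return float(max(0.0, np.max(line.distance(c.points[mask]))))


def cervical_lordosis_distance(
    c: SpinalCurve, line: TILine, part: RegionPartition | None = None
) -> float:
    """Apex height of the cervical lordosis above the TI line (mm)."""
    return _region_max_distance(c, line, part or RegionPartition(), "cervical")


def lumbar_lordosis_distance(
    c: SpinalCurve, line: TILine, part: RegionPartition | None = None
) -> float:
    """Apex height of the lumbar lordosis above the TI line (mm)."""
    return _region_max_distance(c, line, part or RegionPartition(), "lumbar")


def extract_all(c: SpinalCurve, part: RegionPartition | None = None) -> SpineParameters:
    """Extract (TI, HD, CLD, LLD) from a reconstructed sagittal curve."""
    part = part or RegionPartition()
    line, tangent_points, ti = torso_inclination_line(c, part)
    return SpineParameters(
        TI_deg=ti,
        HD_mm=head_distance(c, line),
        CLD_mm=cervical_lordosis_distance(c, line, part),
        LLD_mm=lumbar_lordosis_distance(c, line, part),
        tangent_points=tangent_points,
    )
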