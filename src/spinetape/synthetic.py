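"""Synthetic supine spinal curves, simulated tape measurements, cohorts.

The generator is the constructive inverse of the parameter extraction: given
a target quadruple (TI, HD, CLD, LLD) it lays a support baseline at angle
TI, places a thoracic and a sacral tangent point on it, superimposes
cervical and lumbar lordosis lobes of the requested apex heights and a
cranial endpoint at the requested head height, and interpolates with a
shape-preserving (monotone piecewise-cubic, PCHIP) spline. PCHIP guarantees
the lobes peak exactly at their apex knots and that the profile never dips
below the baseline, so extraction recovers the requested parameters.

Cohorts emulate a three-mattress randomized crossover: per participant and
condition, parameters are drawn from zero-truncated normals with the
per-condition means/SDs observed for soft (SM), medium (MM) and hard (HM)
mattresses; a shared participant random effect induces within-participant
correlation across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .exceptions import CohortError, InfeasibleProfileError
from .geometry import cumulative_arclength, rotate
from .spine_params import RegionPartition
from .tape import (
    ArcElement,
    SpinalCurve,
    TAPE_LENGTH_MM,
    TAPE_N_ELEMENTS,
    write_tape_csv,
)

PARAM_NAMES = ("TI_deg", "HD_mm", "CLD_mm", "LLD_mm")

#: Per-mattress spine-parameter (mean, SD) for the supine crossover
#: conditions: soft (SM), medium (MM) and hard (HM) mattresses.
DEFAULT_CONDITIONS: dict[str, dict[str, tuple[float, float]]] = {
    "SM": {"TI_deg": (6.86, 4.85), "HD_mm": (85.8, 21.5),
           "CLD_mm": (96.6, 18.3), "LLD_mm": (22.9, 6.5)},
    "MM": {"TI_deg": (3.64, 1.09), "HD_mm": (55.3, 8.9),
           "CLD_mm": (69.9, 6.8), "LLD_mm": (22.2, 4.8)},
    "HM": {"TI_deg": (1.56, 0.63), "HD_mm": (60.0, 11.0),
           "CLD_mm": (70.2, 6.3), "LLD_mm": (11.6, 5.2)},
}

#: Profile heights beyond this fraction of the tape length make the lobe
#: construction geometrically implausible (slopes steeper than a lying back).
MAX_HEIGHT_FRACTION = 0.35


@dataclass(frozen=True)
class SpineProfileParams:
    """Target spine parameters for one synthetic supine profile."""

    TI_deg: float
    HD_mm: float
    CLD_mm: float
    LLD_mm: float
    total_length_mm: float = TAPE_LENGTH_MM
    partition: RegionPartition = field(default_factory=RegionPartition)

    def __post_init__(self):
        for name in ("HD_mm", "CLD_mm", "LLD_mm"):
            if getattr(self, name) < 0:
                raise InfeasibleProfileError(f"{name} must be >= 0")
        if not (0 <= self.TI_deg < 45):
            raise InfeasibleProfileError("TI_deg must lie in [0, 45)")
        if self.total_length_mm <= 0:
            raise InfeasibleProfileError("total_length_mm must be positive")
        hmax = MAX_HEIGHT_FRACTION * self.total_length_mm
        for name in ("HD_mm", "CLD_mm", "LLD_mm"):
            if getattr(self, name) > hmax:
                raise InfeasibleProfileError(
                    f"{name}={getattr(self, name):.1f} mm exceeds the feasible "
                    f"height {hmax:.1f} mm for a {self.total_length_mm:.0f} mm curve"
                )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.TI_deg, self.HD_mm, self.CLD_mm, self.LLD_mm)


def _profile_knots(p: SpineProfileParams):
    """Arclength-fraction knot positions and heights for the profile spline."""
    part = p.partition
    fracs = [0.0]
    heights = [p.HD_mm]
    if p.HD_mm > p.CLD_mm:
        # descend to the cervical apex height by the head/cervical boundary
        # so the cervical-region maximum stays exactly CLD
        fracs.append(part.f1)
        heights.append(p.CLD_mm)
    fracs += [
        0.5 * (part.f1 + part.f2),   # cervical lordosis apex
        0.5 * (part.f2 + part.f3),   # thoracic tangent point
        0.5 * (part.f3 + part.f4),   # lumbar lordosis apex
        0.5 * (part.f4 + part.f5),   # sacral tangent point
        1.0,
    ]
    heights += [p.CLD_mm, 0.0, p.LLD_mm, 0.0, 0.0]
    return np.array(fracs), np.array(heights)


#: Maximum knot-to-knot height change per unit of arclength between knots.
#: A profile whose lobes require steeper mean slopes cannot keep the region
#: maxima at their apex knots (e.g. a head-to-cervical descent longer than
#: the head region's own arclength is geometrically impossible).
MAX_KNOT_SLOPE = 0.8


def is_feasible(p: SpineProfileParams) -> bool:
    """Whether a smooth curve realizing the parameters exists."""
    try:
        fracs, heights = _profile_knots(p)
    except InfeasibleProfileError:
        return False
    dh = np.abs(np.diff(heights))
    ds = np.diff(fracs) * p.total_length_mm
    return bool(np.all(dh <= MAX_KNOT_SLOPE * ds))


def make_profile(p: SpineProfileParams, spacing_mm: float = 1.0) -> SpinalCurve:
    """Construct a smooth supine sagittal curve realizing the parameters.

    The spline is built over horizontal position and iteratively
    reparametrized so that (i) total arclength equals ``total_length_mm``
    and (ii) knots sit at their target arclength fractions; extraction with
    the same partition then reproduces the parameters to well under
    1 mm / 0.2 degrees.
    """
    if not is_feasible(p):
        raise InfeasibleProfileError(
            f"no smooth profile realizes (TI={p.TI_deg:.2f}, HD={p.HD_mm:.1f}, "
            f"CLD={p.CLD_mm:.1f}, LLD={p.LLD_mm:.1f}) on a "
            f"{p.total_length_mm:.0f} mm curve: required lobe slopes too steep"
        )
    L = p.total_length_mm
    fracs, heights = _profile_knots(p)
    if np.all(heights == 0.0):
        n = int(round(L / spacing_mm)) + 1
        x = np.linspace(0.0, L, n)
        pts = rotate(np.column_stack([x, np.zeros(n)]), np.radians(p.TI_deg))
        return SpinalCurve(pts, x.copy())

    X = L                      # horizontal extent, shrunk as arclength grows
    xk = fracs * X
    n_dense = max(800, int(round(L / spacing_mm)) + 1)
    for _ in range(40):
        spline = PchipInterpolator(xk, heights)
        xs = np.linspace(0.0, X, n_dense)
        ys = spline(xs)
        s = cumulative_arclength(np.column_stack([xs, ys]))
        kf = np.interp(xk, xs, s) / s[-1]
        if abs(s[-1] - L) / L < 2e-4 and np.max(np.abs(kf - fracs)) < 2e-4:
            break
        scale = L / s[-1]
        # re-place knots at target arclength fractions, then rescale extent
        xk_new = np.interp(fracs * s[-1], s, xs) * scale
        if np.any(np.diff(xk_new) <= 0):
            raise InfeasibleProfileError(
                "profile knots collapsed during arclength reparametrization"
            )
        xk = xk_new
        X *= scale
    spline = PchipInterpolator(xk, heights)
    xs = np.linspace(0.0, X, n_dense)
    pts = np.column_stack([xs, spline(xs)])
    if p.TI_deg:
        pts = rotate(pts, np.radians(p.TI_deg))
    return SpinalCurve.from_points(pts)


def sample_tape(
    c: SpinalCurve,
    n_elements: int = TAPE_N_ELEMENTS,
    noise_mm: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[ArcElement]:
    """Cut a curve into equal-arclength tape elements with start/mid/end points.

    Isotropic Gaussian noise of SD ``noise_mm`` is added per coordinate when
    requested (pass a seeded ``rng`` for reproducibility). The tape is one
    continuous strip, so the junction shared by two adjacent elements gets a
    single noise draw (the end of element i equals the start of i+1).
    """
    if c.length < n_elements * 1.0:
        raise ValueError(
            f"curve of length {c.length:.1f} mm too short for {n_elements} elements"
        )
    bounds = np.linspace(0.0, c.length, n_elements + 1)
    junctions = c.point_at(bounds)
    mids = c.point_at(0.5 * (bounds[:-1] + bounds[1:]))
    if noise_mm > 0:
        rng = rng if rng is not None else np.random.default_rng()
        junctions = junctions + rng.normal(0.0, noise_mm, junctions.shape)
        mids = mids + rng.normal(0.0, noise_mm, mids.shape)
    starts = junctions[:-1]
    ends = junctions[1:]
    return [
        ArcElement(p_start=starts[i], p_mid=mids[i], p_end=ends[i], index=i)
        for i in range(n_elements)
    ]


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic crossover cohort.

    ``rho`` is the fraction of between-draw variance shared within a
    participant across conditions (a participant random effect); the
    condition marginals keep the stated means/SDs regardless of ``rho``.
    """

    n_participants: int = 16
    conditions: dict = field(default_factory=lambda: DEFAULT_CONDITIONS)
    seed: int = 0
    noise_mm: float = 0.5
    rho: float = 0.5
    n_elements: int = TAPE_N_ELEMENTS
    total_length_mm: float = TAPE_LENGTH_MM
    partition: RegionPartition = field(default_factory=RegionPartition)

    def __post_init__(self):
        if self.n_participants < 2:
            raise CohortError("need at least 2 participants")
        if not (0 <= self.rho <= 1):
            raise CohortError("rho must lie in [0, 1]")
        for cond, params in self.conditions.items():
            for name in PARAM_NAMES:
                if name not in params:
                    raise CohortError(f"condition {cond} missing parameter {name}")
                if params[name][1] < 0:
                    raise CohortError(f"negative SD for {cond}/{name}")


@dataclass(frozen=True)
class CohortRecord:
    participant: int
    condition: str
    params: SpineProfileParams
    curve: SpinalCurve | None
    elements: list | None


@dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    manifest: pd.DataFrame
    records: dict


def _draw_truncated(rng, mean, sd, shared, rho, max_tries=100):
    """One zero-truncated draw: mean + sd*(sqrt(rho)*shared + sqrt(1-rho)*z)."""
    if sd == 0.0:
        if mean < 0:
            raise CohortError(f"mean {mean} negative with zero SD")
        return float(mean)
    for _ in range(max_tries):
        z = rng.standard_normal()
        v = mean + sd * (np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * z)
        if v >= 0:
            return float(v)
    raise CohortError(
        f"failed to draw a non-negative value for mean={mean}, sd={sd} "
        f"after {max_tries} tries"
    )


def _make_params(spec: CohortSpec, row: dict) -> SpineProfileParams:
    return SpineProfileParams(
        TI_deg=row["TI_deg"], HD_mm=row["HD_mm"],
        CLD_mm=row["CLD_mm"], LLD_mm=row["LLD_mm"],
        total_length_mm=spec.total_length_mm, partition=spec.partition,
    )


def draw_parameters(spec: CohortSpec, require_feasible: bool = False) -> pd.DataFrame:
    """Draw the cohort parameter table (no curves); fully seeded.

    Each value is a zero-truncated normal draw sharing a participant random
    effect across conditions. With ``require_feasible`` the whole
    participant-condition vector is re-drawn (up to 100 times) whenever it
    admits no smooth profile (see :func:`is_feasible`); without it the
    marginal means/SDs are exactly the condition values, which is what
    moment checks should target.

    Returns a wide frame with columns
    ``participant, condition, TI_deg, HD_mm, CLD_mm, LLD_mm``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    shared = rng.standard_normal((spec.n_participants, len(PARAM_NAMES)))
    rows = []
    for i in range(spec.n_participants):
        for cond, cparams in spec.conditions.items():
            for _ in range(100):
                row = {"participant": i, "condition": cond}
                for k, name in enumerate(PARAM_NAMES):
                    mean, sd = cparams[name]
                    row[name] = _draw_truncated(rng, mean, sd, shared[i, k], spec.rho)
                if not require_feasible:
                    break
                try:
                    if is_feasible(_make_params(spec, row)):
                        break
                except InfeasibleProfileError:
                    pass
            else:
                raise CohortError(
                    f"no feasible parameter draw for participant {i}, "
                    f"condition {cond} after 100 tries"
                )
            rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec, include_curves: bool = True) -> Cohort:
    """Build a full synthetic cohort: parameters, profiles, tape elements.

    With ``include_curves=False`` only the parameter table is materialized
    (records carry ``curve=None, elements=None``), which is much faster for
    moment checks on large ``n``.
    """
    table = draw_parameters(spec, require_feasible=include_curves)
    noise_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    records = {}
    for row in table.itertuples(index=False):
        params = _make_params(spec, row._asdict())
        curve = elements = None
        if include_curves:
            curve = make_profile(params)
            elements = sample_tape(
                curve, spec.n_elements, spec.noise_mm, rng=noise_rng
            )
        records[(row.participant, row.condition)] = CohortRecord(
            participant=row.participant, condition=row.condition,
            params=params, curve=curve, elements=elements,
        )
    manifest = table.copy()
    manifest["seed"] = spec.seed
    return Cohort(spec=spec, manifest=manifest, records=records)


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write one directory per participant/condition (tape CSV + params JSON)
    plus a cohort manifest CSV; returns the manifest path."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for (pid, cond), rec in cohort.records.items():
        d = out_dir / f"participant_{pid:03d}" / cond
        d.mkdir(parents=True, exist_ok=True)
        if rec.elements is not None:
            write_tape_csv(rec.elements, d / "tape.csv")
        with open(d / "params.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "TI_deg": rec.params.TI_deg, "HD_mm": rec.params.HD_mm,
                    "CLD_mm": rec.params.CLD_mm, "LLD_mm": rec.params.LLD_mm,
                },
                fh, indent=1,
            )
    manifest_path = out_dir / "manifest.csv"
    cohort.manifest.to_csv(manifest_path, index=False)
    return manifest_path
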