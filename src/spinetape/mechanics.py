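"""Reduced-order sagittal body-on-mattress equilibrium model.

The supine body is an articulated chain of nodes (head, C1-L5, sacrum,
thigh, shank, heel) lying along +x with vertical positions as the unknowns.
It rests on a Winkler foundation: independent vertical foam columns whose
pressure-deflection law comes from :mod:`spinetape.foam`, with a
pillow-over-mattress series stack over the pillow footprint near the head.

Static equilibrium minimizes total potential energy

    E = gravity + joint axial strain + joint bending strain
        + tension-only ligament strain + foundation strain,

with unilateral contact (columns push, never pull). Outputs are the
deformed back profile, nodal contact pressures, contact areas above a
pressure threshold, and per-intervertebral-disc load proxies
(|F|/A + |M| c / I from the joint axial forces and bending moments).

This is explicitly a surrogate of a full 3-D contact simulation: only
orderings and mechanisms across mattress stiffnesses are meaningful, not
absolute pressures.

Units: mm, kg, N, kPa; energies in N mm. g in m/s^2 (masses in kg with
positions in mm give weights directly in N).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .exceptions import BodyModelError, ConvergenceError, DensificationError
from .foam import FoundationLaw, load_foundation
from .tape import SpinalCurve

GRAVITY = 9.81

# ---------------------------------------------------------------------------
# anthropometry (shipped defaults, config-overridable)

#: Body segment mass fractions; arms are folded into the trunk, matching the
#: supine arms-parallel posture.
SEGMENT_MASS_FRACTIONS = {
    "head": 0.081,
    "trunk": 0.497 + 0.100,   # trunk + both arms lumped
    "thighs": 0.200,
    "shanks": 0.093,
    "feet": 0.029,
}

_SPINE_NODES = (
    ["head"]
    + [f"C{i}" for i in range(1, 8)]
    + [f"T{i}" for i in range(1, 13)]
    + [f"L{i}" for i in range(1, 6)]
    + ["sacrum"]
)
NODE_NAMES = _SPINE_NODES + ["thigh", "shank", "heel"]

#: Longitudinal node positions as fractions of stature (crown at 0).
_NODE_X_FRACTIONS = {
    "head": 0.040,
    **{f"C{i}": 0.085 + 0.010 * (i - 1) for i in range(1, 8)},
    **{f"T{i}": 0.165 + 0.020 * (i - 1) for i in range(1, 13)},
    **{f"L{i}": 0.405 + 0.020 * (i - 1) for i in range(1, 6)},
    "sacrum": 0.520,
    "thigh": 0.660,
    "shank": 0.830,
    "heel": 0.970,
}

#: Rest back-surface heights (mm) above the contact plane of a rigid support:
#: occiput, mid-thoracic, sacrum, shank and heel touch; cervical and lumbar
#: lordosis arch away; thigh bulk rides slightly high.
_REST_OFFSETS = {
    "head": 0.0,
    "C1": 18.0, "C2": 30.0, "C3": 38.0, "C4": 40.0, "C5": 38.0,
    "C6": 32.0, "C7": 24.0,
    "T1": 16.0, "T2": 9.0, "T3": 4.0, "T4": 1.0, "T5": 0.0, "T6": 0.0,
    "T7": 0.0, "T8": 1.0, "T9": 3.0, "T10": 6.0, "T11": 10.0, "T12": 15.0,
    "L1": 20.0, "L2": 24.0, "L3": 25.0, "L4": 22.0, "L5": 14.0,
    "sacrum": 0.0,
    "thigh": 12.0, "shank": 2.0, "heel": 0.0,
}

#: Effective sagittal contact widths (mm) converting line loads to pressure.
_CONTACT_WIDTHS = {
    "head": 150.0,
    **{f"C{i}": 100.0 for i in range(1, 8)},
    **{f"T{i}": 300.0 for i in range(1, 13)},
    **{f"L{i}": 300.0 for i in range(1, 6)},
    "sacrum": 350.0,
    "thigh": 250.0, "shank": 150.0, "heel": 80.0,
}

#: Per-level intervertebral disc cross-section areas (mm^2), literature-scale
#: values (cervical a few hundred, lumbar well above a thousand).
DISC_AREAS_MM2 = {
    "C2-C3": 230.0, "C3-C4": 250.0, "C4-C5": 270.0, "C5-C6": 290.0,
    "C6-C7": 310.0, "C7-T1": 340.0,
    "T1-T2": 420.0, "T2-T3": 460.0, "T3-T4": 500.0, "T4-T5": 540.0,
    "T5-T6": 580.0, "T6-T7": 620.0, "T7-T8": 660.0, "T8-T9": 700.0,
    "T9-T10": 750.0, "T10-T11": 800.0, "T11-T12": 850.0, "T12-L1": 950.0,
    "L1-L2": 1250.0, "L2-L3": 1400.0, "L3-L4": 1550.0, "L4-L5": 1650.0,
    "L5-S1": 1700.0,
}

#: Axial joint stiffness (N/mm): discs stiffen caudally; leg "joints" are
#: bone-dominated and much stiffer.
_AXIAL_STIFFNESS = {"cervical": 500.0, "thoracic": 1000.0, "lumbar": 1800.0,
                    "leg": 5000.0, "head": 500.0}
#: Bending stiffness (N mm/rad) of the chain at each internal node.
_BENDING_STIFFNESS = {"cervical": 8.0e4, "thoracic": 1.5e5, "lumbar": 2.0e5,
                      "pelvis": 3.0e5, "leg": 2.0e4}

#: Spinal ligament elastic moduli (kPa) used for the tension-only springs,
#: behind a unit-scale config (see ``ligament_unit_scale``).
LIGAMENT_MODULI_KPA = {
    "anterior_longitudinal": 11.9,
    "posterior_longitudinal": 12.5,
    "capsular": 7.7,
    "flava": 2.4,
    "interspinous": 3.4,
    "intertransverse": 10.0,
}
_LIGAMENT_CROSS_SECTION_MM2 = 50.0

#: Pillow footprint: 550 x 350 mm, 90 mm high; the 350 mm side runs along
#: the body near the head, the 550 mm side is the across-bed width.
PILLOW_FOOTPRINT_MM = (550.0, 350.0)


def pillow_footprint_area_cm2(
    length_mm: float = PILLOW_FOOTPRINT_MM[0],
    width_mm: float = PILLOW_FOOTPRINT_MM[1],
) -> float:
    """Pillow bottom footprint area in cm^2 (default 55 x 35 cm -> 1925)."""
    return length_mm * width_mm / 100.0


def percent_change(a: float, b: float) -> tuple[int, float]:
    """Percent change of ``a`` relative to baseline ``b``.

    Returns ``(rounded, raw)`` where ``rounded`` is the nearest-integer
    percentage used for reporting.
    """
    if b <= 0:
        raise ValueError("baseline must be positive")
    raw = (a - b) / b * 100.0
    return int(round(raw)), raw


# ---------------------------------------------------------------------------
# body model


@dataclass(frozen=True)
class BodySegmentModel:
    """Lumped sagittal body chain; see module docstring for conventions."""

    names: tuple
    x: np.ndarray                 # mm, cranial -> caudal
    rest_offset: np.ndarray       # mm above rigid contact plane at rest
    mass: np.ndarray              # kg per node
    width: np.ndarray             # mm effective contact width
    k_axial: np.ndarray           # N/mm per joint (n-1)
    k_bend: np.ndarray            # N mm/rad per internal node (n)
    lig_k: np.ndarray             # N/mm per skip-one tension spring (n-2)
    disc_levels: dict             # level name -> joint index
    disc_area: dict               # level name -> mm^2

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    def tributary_lengths(self) -> np.ndarray:
        """Longitudinal span each node is responsible for (mm).

        A single-node body gets a square patch (span = contact width)."""
        x = self.x
        if len(x) == 1:
            return np.array([self.width[0]])
        mids = 0.5 * (x[:-1] + x[1:])
        left = np.concatenate([[x[0] - 0.5 * (mids[0] - x[0])], mids])
        right = np.concatenate([mids, [x[-1] + 0.5 * (x[-1] - mids[-1])]])
        return right - left


def _node_region(name: str) -> str:
    if name.startswith("C") and name != "C1":
        return "cervical"
    if name in ("head", "C1"):
        return "cervical" if name == "C1" else "head"
    if name.startswith("T"):
        return "thoracic"
    if name.startswith("L"):
        return "lumbar"
    if name == "sacrum":
        return "pelvis"
    return "leg"


def build_default_body(
    height_cm: float = 176.0,
    mass_kg: float = 74.0,
    ligament_unit_scale: float = 1.0,
) -> BodySegmentModel:
    """Anthropometric body chain scaled to stature and total mass.

    Node masses come from the shipped segment-fraction table (head 8.1%,
    trunk incl. arms 59.7%, thighs 20%, shanks 9.3%, feet 2.9%) and sum to
    ``mass_kg`` exactly; node spacing scales linearly with stature.
    ``ligament_unit_scale`` rescales the ligament moduli (kept in kPa as
    tabulated; literature values are MPa-scale, so a scale of 1000 restores
    those).
    """
    if not (140.0 <= height_cm <= 210.0):
        raise BodyModelError(f"height {height_cm} cm outside plausible 140-210")
    if not (40.0 <= mass_kg <= 150.0):
        raise BodyModelError(f"mass {mass_kg} kg outside plausible 40-150")

    names = tuple(NODE_NAMES)
    H = height_cm * 10.0
    x = np.array([_NODE_X_FRACTIONS[n] * H for n in names])
    rest = np.array([_REST_OFFSETS[n] for n in names])
    width = np.array([_CONTACT_WIDTHS[n] for n in names])

    mass = np.zeros(len(names))
    mass[0] = SEGMENT_MASS_FRACTIONS["head"]
    trunk_nodes = [i for i, n in enumerate(names) if n in _SPINE_NODES[1:]]
    # heavier caudal trunk: weight trunk nodes by 1 + caudal position
    w = np.array([1.0 + 1.5 * (x[i] - x[trunk_nodes[0]]) / (x[trunk_nodes[-1]] - x[trunk_nodes[0]]) for i in trunk_nodes])
    mass[trunk_nodes] = SEGMENT_MASS_FRACTIONS["trunk"] * w / w.sum()
    mass[names.index("thigh")] = SEGMENT_MASS_FRACTIONS["thighs"]
    mass[names.index("shank")] = SEGMENT_MASS_FRACTIONS["shanks"]
    mass[names.index("heel")] = SEGMENT_MASS_FRACTIONS["feet"]
    mass = mass / mass.sum() * mass_kg

    axial_by_region = {**_AXIAL_STIFFNESS, "pelvis": _AXIAL_STIFFNESS["lumbar"],
                       "head": _AXIAL_STIFFNESS["cervical"]}
    k_axial = np.array([axial_by_region[_node_region(b)] for b in names[1:]])
    k_bend = np.zeros(len(names))
    for i, n in enumerate(names[1:-1], start=1):
        k_bend[i] = _BENDING_STIFFNESS.get(_node_region(n), _BENDING_STIFFNESS["leg"])

    # tension-only ligament springs spanning next-nearest spine nodes
    E_sum = sum(LIGAMENT_MODULI_KPA.values()) * 1e-3 * ligament_unit_scale  # N/mm^2
    lig_k = np.zeros(len(names) - 2)
    for i in range(len(names) - 2):
        span = x[i + 2] - x[i]
        if names[i + 2] in _SPINE_NODES:
            lig_k[i] = E_sum * _LIGAMENT_CROSS_SECTION_MM2 / span

    # joints carrying an intervertebral disc (C2-C3 .. L5-S1)
    disc_levels = {}
    for j, (a, b) in enumerate(zip(names[:-1], names[1:])):
        lvl = f"{a}-S1" if b == "sacrum" else f"{a}-{b}"
        if lvl in DISC_AREAS_MM2:
            disc_levels[lvl] = j

    return BodySegmentModel(
        names=names, x=x, rest_offset=rest, mass=mass, width=width,
        k_axial=k_axial, k_bend=k_bend, lig_k=lig_k,
        disc_levels=disc_levels, disc_area=dict(DISC_AREAS_MM2),
    )


# ---------------------------------------------------------------------------
# support surface


class _TabulatedColumn:
    """Piecewise-linear pressure law with the consistent quadratic energy.

    Tabulating the (possibly stacked) foundation law once keeps the energy
    C1-consistent with its gradient during minimization.
    """

    def __init__(self, law: FoundationLaw, n_grid: int = 200):
        d_max = 0.94 * law.thickness
        self.d = np.linspace(0.0, d_max, n_grid)
        self.p = np.array([_safe_pressure(law, d) for d in self.d])
        self.e = np.concatenate(
            [[0.0], np.cumsum(0.5 * (self.p[1:] + self.p[:-1]) * np.diff(self.d))]
        )
        self.slope_end = (self.p[-1] - self.p[-2]) / (self.d[-1] - self.d[-2])

    def pressure(self, d):
        d = np.asarray(d, dtype=float)
        inside = np.interp(d, self.d, self.p)
        beyond = self.p[-1] + self.slope_end * (d - self.d[-1])
        return np.where(d <= self.d[-1], inside, beyond) * (d > 0)

    def energy(self, d):
        d = np.asarray(d, dtype=float)
        dc = np.clip(d, 0.0, self.d[-1])
        idx = np.clip(np.searchsorted(self.d, dc) - 1, 0, len(self.d) - 2)
        h = dc - self.d[idx]
        slope = (self.p[idx + 1] - self.p[idx]) / (self.d[idx + 1] - self.d[idx])
        e = self.e[idx] + self.p[idx] * h + 0.5 * slope * h * h
        over = d - self.d[-1]
        e_beyond = self.p[-1] * over + 0.5 * self.slope_end * over * over
        return np.where(d > self.d[-1], e + e_beyond, e) * (d > 0)


def _safe_pressure(law: FoundationLaw, d: float) -> float:
    from .foam import foundation_pressure

    try:
        return foundation_pressure(law, d)
    except DensificationError:  # pragma: no cover - grid stays below 0.95 t
        raise


@dataclass(frozen=True)
class SupportSurface:
    """Mattress foundation with an optional pillow stack near the head.

    Over the pillow x-extent the column is the pillow law in series on top
    of the mattress law, and the undeformed surface is higher by the pillow
    height.
    """

    mattress: FoundationLaw
    pillow: FoundationLaw | None = None
    pillow_x: tuple = (0.0, PILLOW_FOOTPRINT_MM[1])

    @classmethod
    def from_names(
        cls,
        mattress: str = "MM",
        pillow: str | None = "pillow",
        pillow_x: tuple = (0.0, PILLOW_FOOTPRINT_MM[1]),
    ) -> "SupportSurface":
        return cls(
            mattress=load_foundation(mattress),
            pillow=load_foundation(pillow) if pillow else None,
            pillow_x=pillow_x,
        )

    def on_pillow(self, x: np.ndarray) -> np.ndarray:
        if self.pillow is None:
            return np.zeros(len(x), dtype=bool)
        return (x >= self.pillow_x[0]) & (x <= self.pillow_x[1])

    def surface_height(self, x: np.ndarray) -> np.ndarray:
        h = np.full(len(x), self.mattress.thickness)
        if self.pillow is not None:
            h[self.on_pillow(x)] += self.pillow.thickness
        return h

    def columns(self, x: np.ndarray) -> list:
        mat_col = _TabulatedColumn(self.mattress)
        if self.pillow is None:
            return [mat_col] * len(x)
        stack_col = _TabulatedColumn(self.pillow.stacked_on(self.mattress))
        on = self.on_pillow(x)
        return [stack_col if o else mat_col for o in on]


# ---------------------------------------------------------------------------
# equilibrium


@dataclass
class EquilibriumResult:
    body: BodySegmentModel
    surface: SupportSurface
    g: float
    y: np.ndarray                  # nodal heights above ground plate (mm)
    deflection: np.ndarray         # foundation deflection per node (mm)
    pressure: np.ndarray           # contact pressure per node (kPa)
    tributary_area: np.ndarray     # mm^2 per node
    joint_force: np.ndarray        # axial force per joint (N)
    node_moment: np.ndarray        # bending moment per internal node (N mm)
    converged: bool
    energy_trace: np.ndarray

    @property
    def curve(self) -> SpinalCurve:
        """Deformed back-surface proxy through the node positions."""
        return SpinalCurve.from_points(np.column_stack([self.body.x, self.y]))

    @property
    def total_contact_force(self) -> float:
        """N; equals total weight at convergence."""
        return float(np.sum(self.pressure * self.tributary_area) * 1e-3)

    @property
    def weight(self) -> float:
        return self.body.total_mass * self.g

    @property
    def force_balance_error(self) -> float:
        """Relative error |contact force - weight| / weight."""
        w = self.weight
        if w == 0:
            return abs(self.total_contact_force)
        return abs(self.total_contact_force - w) / w

    def torso_sink_angle_deg(self) -> float:
        """Torso-inclination proxy: angle of the chest-to-pelvis sink line.

        Uses foundation deflections (how much deeper the sacrum presses into
        the support than the mid-thoracic contact), so a bridging,
        non-contacting upper back reads as zero rather than as inclination.
        """
        i = self.body.names.index("T7")
        j = self.body.names.index("sacrum")
        dd = self.deflection[j] - self.deflection[i]
        return float(np.degrees(np.arctan2(dd, self.body.x[j] - self.body.x[i])))


def _energy_and_grad(y, body, cols, h_surf, areas, rest_y, g):
    n = body.n
    x = body.x
    E = 0.0
    grad = np.zeros(n)

    # gravity
    E += g * float(body.mass @ y)
    grad += g * body.mass

    # joint axial springs on the exact inter-node distance
    dx = np.diff(x)
    dy = np.diff(y)
    ell = np.hypot(dx, dy)
    dy0 = np.diff(rest_y)
    ell0 = np.hypot(dx, dy0)
    ext = ell - ell0
    E += 0.5 * float(body.k_axial @ ext**2)
    f = body.k_axial * ext * dy / ell       # dE/d(dy)
    grad[:-1] -= f
    grad[1:] += f

    # bending: change of segment-angle difference at internal nodes
    theta = np.arctan2(dy, dx)
    theta0 = np.arctan2(dy0, dx)
    phi = np.diff(theta) - np.diff(theta0)
    kb = body.k_bend[1:-1]
    E += 0.5 * float(kb @ phi**2)
    # d theta_k / d y_k+1 = dx_k / ell_k^2 ; d theta_k / d y_k = -dx_k / ell_k^2
    dth = dx / ell**2
    m = kb * phi                              # N mm per internal node
    # phi_i = theta_i - theta_{i-1}; i = 1..n-2 over segments
    grad_theta = np.zeros(n - 1)
    grad_theta[1:] += m
    grad_theta[:-1] -= m
    grad[:-1] -= grad_theta * dth
    grad[1:] += grad_theta * dth

    # tension-only skip-one ligaments
    if np.any(body.lig_k > 0):
        dx2 = x[2:] - x[:-2]
        dy2 = y[2:] - y[:-2]
        ell2 = np.hypot(dx2, dy2)
        ell20 = np.hypot(dx2, rest_y[2:] - rest_y[:-2])
        ext2 = np.maximum(0.0, ell2 - ell20)
        E += 0.5 * float(body.lig_k @ ext2**2)
        f2 = body.lig_k * ext2 * dy2 / ell2
        grad[:-2] -= f2
        grad[2:] += f2

    # foundation (unilateral)
    d = h_surf - y
    p = np.empty(n)
    e = np.empty(n)
    for col, idx in cols:
        p[idx] = col.pressure(d[idx])
        e[idx] = col.energy(d[idx])
    E += 1e-3 * float(areas @ e)
    grad -= 1e-3 * areas * p

    return E, grad


def _column_groups(cols: list) -> list:
    """Group per-node columns by identity for vectorized evaluation."""
    groups: dict[int, list] = {}
    ref = {}
    for i, c in enumerate(cols):
        groups.setdefault(id(c), []).append(i)
        ref[id(c)] = c
    return [(ref[k], np.array(v)) for k, v in groups.items()]


def solve_equilibrium(
    body: BodySegmentModel,
    surface: SupportSurface,
    g: float = GRAVITY,
    max_iter: int = 5000,
    gtol: float = 1e-7,
) -> EquilibriumResult:
    """Minimize total potential energy; deterministic given inputs.

    The initial guess is the rest profile lowered until first contact.
    Raises :class:`ConvergenceError` (with the energy trace attached) if the
    optimizer stops without meeting the force-balance check.
    """
    x = body.x
    h_surf = surface.surface_height(x)
    col_groups = _column_groups(surface.columns(x))
    areas = body.tributary_lengths() * body.width
    rest_y = body.rest_offset.copy()

    c0 = np.max(h_surf - rest_y)
    y0 = rest_y + c0

    trace = []

    def fun(y):
        return _energy_and_grad(y, body, col_groups, h_surf, areas, rest_y, g)

    res = minimize(
        fun, y0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": gtol,
                 "maxcor": 30, "maxls": 200},
        callback=lambda yk: trace.append(fun(yk)[0]),
    )
    y = res.x
    d = np.maximum(0.0, h_surf - y)
    p = np.empty(body.n)
    for col, idx in col_groups:
        p[idx] = col.pressure(d[idx])

    dx = np.diff(x)
    dy = np.diff(y)
    ell = np.hypot(dx, dy)
    ell0 = np.hypot(dx, np.diff(rest_y))
    joint_force = body.k_axial * (ell - ell0)
    theta = np.arctan2(dy, dx)
    theta0 = np.arctan2(np.diff(rest_y), dx)
    node_moment = np.zeros(body.n)
    node_moment[1:-1] = body.k_bend[1:-1] * (np.diff(theta) - np.diff(theta0))

    result = EquilibriumResult(
        body=body, surface=surface, g=g, y=y, deflection=d, pressure=p,
        tributary_area=areas, joint_force=joint_force, node_moment=node_moment,
        converged=True, energy_trace=np.array([fun(y0)[0]] + trace),
    )
    if g > 0 and result.force_balance_error > 5e-3:
        raise ConvergenceError(
            f"equilibrium not converged: force balance error "
            f"{result.force_balance_error:.2e} (optimizer: {res.message})",
            energy_trace=result.energy_trace,
        )
    return result


# ---------------------------------------------------------------------------
# outputs

#: Body regions for reporting peak contact pressure.
PRESSURE_REGIONS = {
    "occiput": ["head"],
    "cervical": [f"C{i}" for i in range(1, 8)],
    "scapula": [f"T{i}" for i in range(1, 9)],
    "buttock": ["L4", "L5", "sacrum"],
    "calf": ["shank"],
    "heel": ["heel"],
}

DISC_REGIONS = {
    "cervical": ["C2-C3", "C3-C4", "C4-C5", "C5-C6", "C6-C7", "C7-T1"],
    "thoracic": [f"T{i}-T{i+1}" for i in range(1, 12)] + ["T12-L1"],
    "lumbar": ["L1-L2", "L2-L3", "L3-L4", "L4-L5", "L5-S1"],
}


def _require_converged(r: EquilibriumResult):
    if not r.converged:
        raise ConvergenceError("result is not converged", r.energy_trace)


def contact_pressure_profile(r: EquilibriumResult) -> tuple[np.ndarray, dict]:
    """Per-node pressures plus peak pressure per named body region (kPa)."""
    _require_converged(r)
    names = list(r.body.names)
    peaks = {}
    for region, members in PRESSURE_REGIONS.items():
        idx = [names.index(m) for m in members if m in names]
        peaks[region] = float(r.pressure[idx].max()) if idx else 0.0
    return r.pressure, peaks


def contact_area(r: EquilibriumResult, threshold_kpa: float = 1.0) -> dict:
    """Contact area (cm^2) above a pressure threshold, split pillow/mattress."""
    if threshold_kpa < 0:
        raise ValueError("threshold must be non-negative")
    _require_converged(r)
    on_pillow = r.surface.on_pillow(r.body.x)
    in_contact = r.pressure > threshold_kpa
    area = r.tributary_area / 100.0     # cm^2
    return {
        "pillow": float(area[in_contact & on_pillow].sum()),
        "mattress": float(area[in_contact & ~on_pillow].sum()),
        "total": float(area[in_contact].sum()),
    }


def ivd_peak_stress(r: EquilibriumResult, body: BodySegmentModel | None = None):
    """Per-disc load proxy (kPa): |F|/A + |M| c / I with circular-disc
    geometry (c = r, I = pi r^4 / 4, r from the tabulated area).

    Returns ``(per_level: DataFrame, region_peaks: dict)``.
    """
    _require_converged(r)
    body = body or r.body
    rows = []
    for level, j in body.disc_levels.items():
        if level not in body.disc_area:
            raise KeyError(f"no disc geometry for level {level}")
        A = body.disc_area[level]
        radius = np.sqrt(A / np.pi)
        I = np.pi * radius**4 / 4.0
        F = abs(r.joint_force[j])
        # moment at the disc: mean of its two node moments
        M = 0.5 * (abs(r.node_moment[j]) + abs(r.node_moment[j + 1]))
        stress_kpa = (F / A + M * radius / I) * 1e3   # N/mm^2 -> kPa
        rows.append({"level": level, "joint": j, "stress_kPa": stress_kpa})
    per_level = pd.DataFrame(rows)
    peaks = {}
    for region, levels in DISC_REGIONS.items():
        sel = per_level[per_level.level.isin(levels)]
        peaks[region] = float(sel.stress_kPa.max()) if len(sel) else 0.0
    return per_level, peaks
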