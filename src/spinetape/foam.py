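"""Foam material laws and nonlinear foundation (Winkler) models.

Compressive stress-strain tables for the three mattresses (soft SM, medium
MM, hard HM) and the cervical pillow are turned into monotone strain->stress
laws, a surrogate 25% indentation-load-deflection (ILD) measure, and
pressure-deflection foundation laws for foam slabs of given thickness.

The columnar (independent vertical springs) reduction is justified by the
foams' near-zero Poisson ratio (nu = 0.01): lateral coupling is negligible,
so each surface column compresses independently under the local pressure.

The bundled stress-strain tables are synthetic: smooth curves with the
classic foam shape (elastic toe, plateau, densification) calibrated so the
surrogate ILD at 25% strain is 20 / 42 / 120 lbf for SM / MM / HM on the
standard 323 cm^2 indenter, and so the pillow tracks the MM law.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .exceptions import DensificationError, FoamFitError

# unit conversions, centralized
KPA_TO_PSI = 0.1450
CM2_PER_IN2 = 6.4516
N_PER_LBF = 4.4482216152605
KPA_CM2_TO_N = 0.1          # 1 kPa over 1 cm^2 = 0.1 N

#: Standard 50 in^2 circular IFD indenter.
DEFAULT_INDENTER_AREA_CM2 = 50 * CM2_PER_IN2

#: Strain beyond which the foam is considered fully densified.
DENSIFICATION_STRAIN = 0.95

MATTRESS_THICKNESS_MM = 200.0
PILLOW_HEIGHT_MM = 90.0


@dataclass(frozen=True)
class StressStrainCurve:
    """Compressive stress-strain data: strain (dimensionless) vs stress (kPa)."""

    strain: np.ndarray
    stress: np.ndarray
    name: str = ""

    def __post_init__(self):
        strain = np.asarray(self.strain, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        if strain.shape != stress.shape or strain.ndim != 1:
            raise FoamFitError("strain and stress must be matching 1-D arrays")
        if strain[0] != 0.0 or stress[0] != 0.0:
            raise FoamFitError("stress-strain data must start at (0, 0)")
        if strain[-1] >= 1.0:
            raise FoamFitError("strains must stay below 1 (full densification)")
        bad = np.nonzero(np.diff(strain) <= 0)[0]
        if bad.size:
            raise FoamFitError(f"strains not strictly increasing at index {bad[0] + 1}")
        bad = np.nonzero(np.diff(stress) < 0)[0]
        if bad.size:
            raise FoamFitError(f"stress decreases at index {bad[0] + 1}")
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "stress", stress)

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "StressStrainCurve":
        df = pd.read_csv(path)
        return cls(
            df["strain"].to_numpy(), df["stress_kPa"].to_numpy(),
            name=name or Path(str(path)).stem,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame({"strain": self.strain, "stress_kPa": self.stress}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class FoamMaterial:
    """Monotone compressive law strain -> stress (kPa) for one foam."""

    interpolant: PchipInterpolator
    eps_max: float
    terminal_slope: float
    poisson: float = 0.01
    name: str = ""

    def law(self, strain):
        """Stress (kPa) at compressive strain; linear extrapolation beyond
        the data range using the terminal slope."""
        eps = np.asarray(strain, dtype=float)
        out = np.where(
            eps <= self.eps_max,
            self.interpolant(np.clip(eps, 0.0, self.eps_max)),
            self.interpolant(self.eps_max) + self.terminal_slope * (eps - self.eps_max),
        )
        out = np.where(eps <= 0.0, 0.0, out)
        return float(out) if np.isscalar(strain) else out

    def __call__(self, strain):
        return self.law(strain)

    def scaled(self, factor: float) -> "FoamMaterial":
        """A pointwise stiffness-scaled copy (stress multiplied by ``factor``)."""
        xs = self.interpolant.x
        return FoamMaterial(
            interpolant=PchipInterpolator(xs, factor * self.interpolant(xs)),
            eps_max=self.eps_max,
            terminal_slope=factor * self.terminal_slope,
            poisson=self.poisson,
            name=f"{self.name}*{factor:g}" if self.name else "",
        )


def fit_foam_law(data: StressStrainCurve, poisson: float = 0.01) -> FoamMaterial:
    """Monotone cubic (PCHIP) interpolant through compressive test data.

    Exact at the data points; beyond the last strain the law continues
    linearly with the terminal slope.
    """
    if len(data.strain) < 4:
        raise FoamFitError("need at least 4 stress-strain points")
    interp = PchipInterpolator(data.strain, data.stress)
    slope = float(interp.derivative()(data.strain[-1]))
    return FoamMaterial(
        interpolant=interp,
        eps_max=float(data.strain[-1]),
        terminal_slope=max(slope, 0.0),
        poisson=poisson,
        name=data.name,
    )


def ild_25(
    m: FoamMaterial,
    indenter_area_cm2: float = DEFAULT_INDENTER_AREA_CM2,
    thickness_mm: float = MATTRESS_THICKNESS_MM,
) -> float:
    """Surrogate 25% indentation load deflection (lbf).

    A uniaxial approximation of the IFD test: the force on the indenter at
    25% compression of the slab, ``law(0.25) * area``. Only stiffness
    orderings -- not absolute lbf values -- should be read off this number,
    since the real test involves indenter edge effects and preflex cycles.
    """
    if indenter_area_cm2 <= 0:
        raise ValueError("indenter area must be positive")
    force_N = m.law(0.25) * indenter_area_cm2 * KPA_CM2_TO_N
    return force_N / N_PER_LBF


@dataclass(frozen=True)
class FoundationLaw:
    """Pressure-deflection law of a stack of foam layers compressed in series.

    ``layers`` are (material, thickness_mm) pairs, top first.
    """

    layers: tuple

    def __post_init__(self):
        layers = tuple((m, float(t)) for m, t in self.layers)
        if not layers or any(t <= 0 for _, t in layers):
            raise ValueError("every layer needs positive thickness")
        object.__setattr__(self, "layers", layers)

    @classmethod
    def single(cls, material: FoamMaterial, thickness_mm: float) -> "FoundationLaw":
        return cls(layers=((material, thickness_mm),))

    @property
    def thickness(self) -> float:
        return sum(t for _, t in self.layers)

    def stacked_on(self, other: "FoundationLaw") -> "FoundationLaw":
        return FoundationLaw(layers=self.layers + other.layers)

    def max_deflection(self) -> float:
        return DENSIFICATION_STRAIN * self.thickness


def _total_deflection_at(f: FoundationLaw, p: float) -> float:
    """Total stack deflection when every layer carries stress ``p`` (kPa)."""
    total = 0.0
    for mat, t in f.layers:
        if p <= 0:
            continue
        hi = DENSIFICATION_STRAIN
        if mat.law(hi) < p:
            # linear-extrapolation region of the layer law
            eps = hi + (p - mat.law(hi)) / max(mat.terminal_slope, 1e-12)
        else:
            eps = brentq(lambda e: mat.law(e) - p, 0.0, hi, xtol=1e-12)
        total += eps * t
    return total


def foundation_pressure(f: FoundationLaw, deflection_mm: float) -> float:
    """Contact pressure (kPa) of the stack at a given total deflection.

    Single layer: ``law(deflection / thickness)``. Stacked layers: the
    unique equal-stress (springs-in-series) split, found by monotone root
    solving to 1e-6 kPa.
    """
    if deflection_mm < 0:
        raise ValueError("deflection must be non-negative")
    if deflection_mm >= f.max_deflection():
        raise DensificationError(
            f"deflection {deflection_mm:.1f} mm >= 95% of stack thickness "
            f"{f.thickness:.1f} mm"
        )
    if deflection_mm == 0.0:
        return 0.0
    if len(f.layers) == 1:
        mat, t = f.layers[0]
        return float(mat.law(deflection_mm / t))
    # bracket the equal stress from above
    p_hi = 1.0
    while _total_deflection_at(f, p_hi) < deflection_mm:
        p_hi *= 2.0
        if p_hi > 1e9:
            raise DensificationError("stack pressure bracket exceeded 1e9 kPa")
    return float(
        brentq(
            lambda p: _total_deflection_at(f, p) - deflection_mm,
            0.0, p_hi, xtol=1e-6,
        )
    )


# ---------------------------------------------------------------------------
# bundled synthetic material registry


def _data_path(name: str):
    return resources.files("spinetape").joinpath("data").joinpath(name)


def load_registry(path=None) -> dict:
    """Material registry: name -> {csv, thickness_mm, poisson}."""
    if path is None:
        with _data_path("materials.yaml").open("r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_material(name: str, registry: dict | None = None) -> FoamMaterial:
    """Load a bundled (or registry-defined) foam material by name."""
    reg = registry if registry is not None else load_registry()
    if name not in reg:
        raise KeyError(f"unknown material {name!r}; registry has {sorted(reg)}")
    entry = reg[name]
    csv_name = entry["csv"]
    if registry is None:
        with _data_path(csv_name).open("r", encoding="utf-8") as fh:
            data = StressStrainCurve.from_csv(fh, name=name)
    else:
        data = StressStrainCurve.from_csv(csv_name, name=name)
    return fit_foam_law(data, poisson=entry.get("poisson", 0.01))


def load_foundation(name: str, registry: dict | None = None) -> FoundationLaw:
    reg = registry if registry is not None else load_registry()
    entry = reg[name]
    return FoundationLaw.single(load_material(name, registry), entry["thickness_mm"])
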