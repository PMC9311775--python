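"""Cohort contrasts, model-validation correlation, end-to-end pipeline.

A three-mattress crossover yields one spine-parameter quadruple per
participant and condition. Per parameter, all pairwise condition contrasts
are tested with a paired two-sided t-test (Wilcoxon signed-rank available
as an alternative) and Holm-adjusted across the pairs.

Validation follows the standard strong-correlation rule: Pearson r between
predicted and reference parameter values, with r in [0.7, 1.0] labelled a
strong positive linear relationship.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .exceptions import (
    MissingCellError,
    PipelineError,
    UndefinedCorrelationError,
)
from .mechanics import (
    SupportSurface,
    build_default_body,
    contact_area,
    contact_pressure_profile,
    ivd_peak_stress,
    percent_change,
    solve_equilibrium,
)
from .spine_params import extract_all
from .synthetic import (
    PARAM_NAMES,
    Cohort,
    CohortSpec,
    generate_cohort,
    write_cohort,
)
from .tape import chain_elements, write_curve_csv

logger = logging.getLogger(__name__)

STRONG_RANGE = (0.7, 1.0)


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, clipped at 1)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def _paired_p(diffs: np.ndarray, test: str) -> tuple[float, float]:
    """(statistic, p) for mean difference zero; degenerate cases defined as
    p=1 for identically-zero differences, p=0 for nonzero zero-variance."""
    if np.allclose(diffs, diffs[0]):
        if abs(diffs[0]) < 1e-12:
            return 0.0, 1.0
        return np.inf, 0.0
    if test == "t":
        res = stats.ttest_rel(diffs, np.zeros_like(diffs))
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon":
        res = stats.wilcoxon(diffs)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def paired_contrasts(
    table: pd.DataFrame,
    parameters=PARAM_NAMES,
    test: str = "t",
) -> pd.DataFrame:
    """All pairwise condition contrasts of a crossover parameter table.

    ``table`` must contain ``participant``, ``condition`` and one column per
    parameter; every participant must have every condition. Returns one row
    per parameter x condition pair with the participant-wise mean
    difference, SD of paired differences, test statistic, raw and
    Holm-adjusted p-values (adjustment across the pairs of one parameter).
    """
    conditions = list(dict.fromkeys(table["condition"]))
    participants = sorted(table["participant"].unique())
    cells = table.set_index(["participant", "condition"])
    missing = [
        (int(p), c) for p in participants for c in conditions
        if (p, c) not in cells.index
    ]
    if missing:
        raise MissingCellError(f"missing participant x condition cells: {missing}")

    rows = []
    for param in parameters:
        wide = table.pivot(index="participant", columns="condition", values=param)
        pvals = []
        for a, b in combinations(conditions, 2):
            diffs = (wide[a] - wide[b]).to_numpy(dtype=float)
            statistic, p = _paired_p(diffs, test)
            rows.append({
                "parameter": param, "pair": f"{a}-{b}",
                "mean_diff": float(diffs.mean()),
                "sd_diff": float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0,
                "statistic": statistic, "p_value": p,
            })
            pvals.append(p)
        adj = _holm(np.array(pvals))
        for k in range(len(pvals)):
            rows[len(rows) - len(pvals) + k]["p_adjusted"] = float(adj[k])
    return pd.DataFrame(rows)


def validate_correlation(predicted, reference) -> tuple[float, str]:
    """Pearson r between predicted and reference values, with the
    strong-relationship label (r in [0.7, 1.0])."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise UndefinedCorrelationError("need two equal-length vectors of >= 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    label = "strong" if STRONG_RANGE[0] <= r <= STRONG_RANGE[1] else "not strong"
    return r, label


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """End-to-end run configuration (cohort, measurement, mechanics)."""

    seed: int = 0
    n_participants: int = 16
    noise_mm: float = 0.5
    rho: float = 0.5
    conditions: dict | None = None        # None -> package defaults
    body_height_cm: float = 176.0
    body_mass_kg: float = 74.0
    mattress_by_condition: dict = field(
        default_factory=lambda: {"SM": "SM", "MM": "MM", "HM": "HM"}
    )
    pillow: str | None = "pillow"
    test: str = "t"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def cohort_spec(self) -> CohortSpec:
        kwargs = dict(
            n_participants=self.n_participants, seed=self.seed,
            noise_mm=self.noise_mm, rho=self.rho,
        )
        if self.conditions is not None:
            kwargs["conditions"] = {
                c: {k: tuple(v) for k, v in params.items()}
                for c, params in self.conditions.items()
            }
        return CohortSpec(**kwargs)


def extract_cohort_parameters(cohort: Cohort) -> pd.DataFrame:
    """Run the measurement chain (tape -> reconstruction -> extraction) on
    every cohort record; returns truth and extracted values side by side."""
    rows = []
    for (pid, cond), rec in sorted(cohort.records.items()):
        if rec.elements is None:
            raise PipelineError("cohort was generated without curves")
        curve = chain_elements(rec.elements)
        est = extract_all(curve, cohort.spec.partition)
        row = {"participant": pid, "condition": cond}
        for name in PARAM_NAMES:
            row[name] = getattr(est, name)
        for name in PARAM_NAMES:
            row[f"true_{name}"] = getattr(rec.params, name)
        rows.append(row)
    return pd.DataFrame(rows)


def _mechanics_summary(config: PipelineConfig) -> dict:
    out = {}
    body = build_default_body(config.body_height_cm, config.body_mass_kg)
    for cond, mat in config.mattress_by_condition.items():
        surface = SupportSurface.from_names(mat, pillow=config.pillow)
        result = solve_equilibrium(body, surface)
        _, region_peaks = contact_pressure_profile(result)
        per_level, disc_peaks = ivd_peak_stress(result)
        out[cond] = {
            "pressure_peaks_kPa": region_peaks,
            "contact_area_cm2": contact_area(result),
            "ivd_region_peaks_kPa": disc_peaks,
            "ivd_per_level_kPa": dict(
                zip(per_level.level, np.round(per_level.stress_kPa, 3))
            ),
            "torso_sink_angle_deg": result.torso_sink_angle_deg(),
            "force_balance_error": result.force_balance_error,
        }
    if {"SM", "MM"} <= set(out):
        rounded, raw = percent_change(
            out["SM"]["ivd_region_peaks_kPa"]["cervical"],
            out["MM"]["ivd_region_peaks_kPa"]["cervical"],
        )
        out["cervical_ivd_percent_change_SM_vs_MM"] = {
            "percent": rounded, "raw": raw,
        }
    return out


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full pipeline and write the report bundle.

    Stages: cohort generation -> tape simulation -> reconstruction ->
    parameter extraction -> paired contrasts -> measurement-validation
    correlation -> per-condition mechanics. Fully reproducible from the
    config seed. Returns the report dict (also written as JSON).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        logger.info("pipeline stage: %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    cohort = stage("generate_cohort", generate_cohort, config.cohort_spec())
    stage("write_cohort", write_cohort, cohort, out_dir / "cohort")
    extracted = stage("extract_parameters", extract_cohort_parameters, cohort)
    extracted.to_csv(out_dir / "parameters.csv", index=False)

    long = extracted.melt(
        id_vars=["participant", "condition"],
        value_vars=list(PARAM_NAMES),
        var_name="parameter", value_name="value",
    )
    long.to_csv(out_dir / "parameters_long.csv", index=False)

    n_conditions = extracted["condition"].nunique()
    if n_conditions >= 2:
        contrasts = stage("paired_contrasts", paired_contrasts, extracted,
                          test=config.test)
    else:
        contrasts = pd.DataFrame(
            columns=["parameter", "pair", "mean_diff", "sd_diff",
                     "statistic", "p_value", "p_adjusted"]
        )
    contrasts.to_csv(out_dir / "contrasts.csv", index=False)

    pred = extracted[list(PARAM_NAMES)].to_numpy().ravel()
    ref = extracted[[f"true_{n}" for n in PARAM_NAMES]].to_numpy().ravel()
    r, label = stage("validate_correlation", validate_correlation, pred, ref)

    mech = stage("mechanics", _mechanics_summary, config)

    report = {
        "config": asdict(config),
        "n_records": len(extracted),
        "validation": {"pearson_r": r, "label": label},
        "contrasts": contrasts.to_dict(orient="records"),
        "mechanics": mech,
    }
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    return report


def bundle_checksum(out_dir) -> str:
    """SHA-256 over the sorted report bundle files (determinism checks)."""
    h = hashlib.sha256()
    for path in sorted(Path(out_dir).rglob("*")):
        if path.is_file():
            h.update(path.relative_to(out_dir).as_posix().encode())
            h.update(path.read_bytes())
    return h.hexdigest()
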