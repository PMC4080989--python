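"""End-to-end analysis pipeline: plate table -> QC -> inhibition profiles ->
sensitivity results -> combination indices -> report tables.

Plates are analysed independently (each normalised by its own MO/MI
controls).  Plates belonging to the same cell line are tied together by the
layout file's ``groups`` mapping so that combination indices can pair a
combination plate with its single-agent plates; without a mapping each
plate forms its own group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .combination import NOT_ESTIMABLE, CombinationDesign, ci_report
from .dose_response import SensitivityResult, analyze_profile
from .plate import (
    CONTROL_CONDITIONS,
    CONTROL_OUTLIER_SD,
    DoseSeries,
    InhibitionProfile,
    control_means,
    qc_profile,
    summarize_condition,
)

log = logging.getLogger(__name__)

try:
    _VERSION = version("atptca")
except PackageNotFoundError:  # pragma: no cover
    _VERSION = "unknown"


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    ``alpha`` and ``cv_limit`` default to the layout file's values (falling
    back to 0 and 10%); ``backend`` selects the ICF estimator
    ("interpolation" or "hill"); ``cv_on`` selects whether replicate CV is
    taken on raw counts (default) or derived inhibition.
    """

    plates: Path
    layout: Path
    out_dir: Path | None = None
    alpha: int | None = None
    cv_limit: float | None = None
    backend: str = "interpolation"
    cv_on: str = "counts"
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class RunResult:
    profiles: pd.DataFrame
    qc: pd.DataFrame
    sensitivity: pd.DataFrame
    combinations: pd.DataFrame
    ci_matrix: pd.DataFrame
    manifest: dict
    results: dict = field(default_factory=dict)  # (group, condition) -> SensitivityResult


def _resolve_condition(
    condition: str, series: dict[str, DoseSeries]
) -> tuple[DoseSeries, CombinationDesign | None]:
    """Map a condition label to its concentration axis.

    A label "A+B" with both components among the configured drugs is a
    fixed-ratio combination measured on A's concentration axis.
    """
    if condition in series:
        return series[condition], None
    if "+" in condition:
        a, b = condition.split("+", 1)
        if a in series and b in series:
            design = CombinationDesign(series[a], series[b])
            return design.axis, design
    raise KeyError(f"condition {condition!r} is not defined in the layout")


def _ic_fields(ic) -> tuple[float | None, str]:
    return (ic.concentration, "") if ic.estimable else (None, f"{ic.censored} {ic.bound:g}")


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full analysis and (optionally) write the result bundle."""
    cfg = io.read_layout(config.layout)
    alpha = int(cfg.get("alpha", 0) if config.alpha is None else config.alpha)
    if alpha not in (0, 1):
        raise ValueError("alpha must be 0 or 1")
    cv_limit = float(cfg.get("cv_limit", 10.0) if config.cv_limit is None else config.cv_limit)
    series = {d: DoseSeries.from_tdc(d, float(s["tdc"])) for d, s in cfg["drugs"].items()}

    wells = io.read_plate_csv(config.plates)
    group_of: dict[str, str] = {}
    for group, plate_ids in (cfg.get("groups") or {}).items():
        for pid in plate_ids:
            group_of[pid] = group

    profile_rows, qc_rows, sens_rows = [], [], []
    results: dict[tuple[str, str], SensitivityResult] = {}
    designs: dict[tuple[str, str], CombinationDesign] = {}

    for plate_id, plate in wells.groupby("plate_id", sort=False):
        group = group_of.get(str(plate_id), str(plate_id))
        mo_mean, mi_mean = control_means(plate)
        for condition in plate["condition"].unique():
            if condition in CONTROL_CONDITIONS:
                continue
            axis, design = _resolve_condition(str(condition), series)
            profile = summarize_condition(
                plate, str(condition), axis, mo_mean, mi_mean, cv_on=config.cv_on
            )
            report = qc_profile(profile, cv_limit)
            sens = analyze_profile(profile, backend=config.backend)
            results[(group, str(condition))] = sens
            if design is not None:
                designs[(group, str(condition))] = design

            for k in range(len(profile.inhibition)):
                profile_rows.append({
                    "group": group, "plate_id": plate_id, "condition": condition,
                    "dilution_step": k + 1,
                    "concentration_uM": profile.concentrations[k],
                    "inhibition_raw": profile.inhibition[k],
                    "inhibition": float(profile.clipped[k]),
                    "cv_pct": profile.cv[k],
                    "n_replicates": profile.n_replicates[k],
                    "flag": profile.flags[k],
                })
            qc_rows.append({
                "group": group, "plate_id": plate_id, "condition": condition,
                "cv_limit": cv_limit,
                "steps_flagged": sum(report.step_flagged),
                "passed": report.passed,
            })
            ic50, ic50_c = _ic_fields(sens.ic50)
            ic90, ic90_c = _ic_fields(sens.ic90)
            sens_rows.append({
                "group": group, "plate_id": plate_id, "condition": condition,
                "ic50_uM": ic50, "ic50_censored": ic50_c,
                "ic90_uM": ic90, "ic90_censored": ic90_c,
                "index_sum": sens.index_sum, "active": sens.active,
            })

    combo_rows = []
    for (group, condition), design in designs.items():
        key_a, key_b = (group, design.drug_a.drug_id), (group, design.drug_b.drug_id)
        if key_a not in results or key_b not in results:
            log.warning("group %s: single agents for %s not found; skipping CI", group, condition)
            continue
        for res in ci_report(results[key_a], results[key_b],
                             results[(group, condition)], design, alpha=alpha):
            combo_rows.append({
                "group": group, "combination": condition,
                "effect_pct": int(res.effect_fraction * 100),
                "ci": res.ci, "alpha": res.alpha,
                "classification": res.classification,
                "dose_a_combo_uM": res.dose_a_combo,
                "dose_b_combo_uM": res.dose_b_combo,
                "dose_a_single_uM": res.dose_a_single,
                "dose_b_single_uM": res.dose_b_single,
            })

    profiles = pd.DataFrame(profile_rows)
    qc = pd.DataFrame(qc_rows)
    sensitivity = pd.DataFrame(sens_rows)
    combinations = pd.DataFrame(combo_rows)
    ci_matrix = _ci_matrix(combinations)

    manifest = {
        "package": "atptca",
        "version": _VERSION,
        "inputs": {"plates": str(config.plates), "layout": str(config.layout)},
        "seed": config.seed,
        "decisions": {
            "alpha": alpha,
            "cv_limit": cv_limit,
            "cv_on": config.cv_on,
            "backend": config.backend,
            "interpolation": "linear in inhibition vs log2(concentration)",
            "clipping": "inhibition clipped to [0, 100] before IndexSUM and ICF",
            "activity_threshold": "IndexSUM < 300 (strict)",
            "ci_thresholds": {"synergy": "< 0.8", "additive": "0.8 - 1.2", "antagonism": "> 1.2"},
            "control_outlier_sd": CONTROL_OUTLIER_SD,
            "combination_axis": "A-component concentration of the fixed-ratio ray",
        },
    }

    result = RunResult(profiles, qc, sensitivity, combinations, ci_matrix, manifest, results)
    if config.out_dir is not None:
        _write_bundle(result, Path(config.out_dir))
    return result


def _ci_matrix(combinations: pd.DataFrame) -> pd.DataFrame:
    """Wide CI table: one row per group, CI50 and CI90 columns per combination."""
    if combinations.empty:
        return pd.DataFrame()
    wide = combinations.pivot(
        index="group", columns=["combination", "effect_pct"], values="ci"
    )
    wide = wide.sort_index(axis=1)
    wide.columns = [f"{combo} CI{eff}" for combo, eff in wide.columns]
    return wide.reset_index()


def _write_bundle(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    # human tables at 2-decimal precision, JSON mirrors at full precision
    for name, df in (("profiles", result.profiles), ("qc", result.qc),
                     ("sensitivity", result.sensitivity),
                     ("combinations", result.combinations),
                     ("ci_matrix", result.ci_matrix)):
        df.round(2).to_csv(out_dir / f"{name}.csv", index=False)
    io.write_json(result.sensitivity.to_dict(orient="records"), out_dir / "sensitivity.json")
    io.write_json(result.combinations.to_dict(orient="records"), out_dir / "combinations.json")
    io.write_json(result.manifest, out_dir / "manifest.json")
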