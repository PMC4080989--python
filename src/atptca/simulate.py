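"""Synthetic ATP-TCA plate generator.

Emits well-level luminescence tables with the statistical structure the
analysis pipeline assumes: Hill-shaped single-agent inhibition, fixed-ratio
combination rays whose mixture effect solves the Loewe additivity equation
(optionally shifted in potency to emulate synergy or antagonism),
multiplicative replicate noise with a constant coefficient of variance, and
MO/MI control wells in one row of each plate.

The preset isogenic panel emulates the MCF10a knock-in series (parental
plus EGFR, BRAF, PIK3CA and AKT mutants) tested against gefitinib,
erlotinib, ZSTK474 and sirolimus, with ground-truth potencies chosen to
reproduce the qualitative sensitivity ordering of that panel: PIK3CA
mutants most sensitive to EGFR inhibition (E545K more than H1047R), BRAF
V600E most resistant to sirolimus, and every combination more active than
its component single agents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .combination import CombinationDesign
from .plate import (
    MI,
    MO,
    N_STEPS,
    DoseSeries,
    PlateLayout,
    default_layout,
)

__all__ = [
    "DrugResponseModel",
    "CombinationSpec",
    "SyntheticScenario",
    "loewe_mixture_inhibition",
    "simulate_plate",
    "simulate_combination",
    "simulate_panel",
    "scenario_isogenic_panel",
    "ec50_for_index",
    "ISOGENIC_CELL_LINES",
    "ISOGENIC_DRUGS",
]


@dataclass(frozen=True)
class DrugResponseModel:
    """Ground-truth Hill response of one cell line to one drug.

    inhibition(c) = imax * c^h / (ec50^h + c^h), in percent.
    """

    cell_line: str
    drug_id: str
    imax: float
    ec50: float
    hill_slope: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.imax <= 100.0:
            raise ValueError("imax must lie in [0, 100]")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be positive")

    def inhibition(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        ch = c ** self.hill_slope
        return self.imax * ch / (self.ec50 ** self.hill_slope + ch)

    def dose_for(self, effect_pct: float) -> float:
        """Dose giving ``effect_pct`` inhibition; inf when unreachable."""
        if effect_pct >= self.imax:
            return math.inf
        if effect_pct <= 0:
            return 0.0
        return self.ec50 * (effect_pct / (self.imax - effect_pct)) ** (1.0 / self.hill_slope)

    @property
    def ic50(self) -> float:
        """Analytic IC50 (inf when imax <= 50)."""
        return self.dose_for(50.0)


@dataclass(frozen=True)
class CombinationSpec:
    """One simulated fixed-ratio combination with its interaction model.

    ``rho`` is the potency-shift factor in the generalised Loewe equation
    dA/DA(I) + dB/DB(I) = rho: rho = 1 is exact Loewe additivity, rho < 1
    shifts potency upwards (synergistic ground truth, recovered downstream
    as CI = rho for equal-shape pairs), rho > 1 emulates antagonism.
    """

    drug_a: str
    drug_b: str
    rho: float = 1.0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")

    @property
    def label(self) -> str:
        return f"{self.drug_a}+{self.drug_b}"


def loewe_mixture_inhibition(
    dose_a: float,
    dose_b: float,
    model_a: DrugResponseModel,
    model_b: DrugResponseModel,
    rho: float = 1.0,
) -> float:
    """Mixture inhibition (%) solving the Loewe equation at fixed doses.

    Solves dA/DA(I) + dB/DB(I) = rho for I by bisection, where DX(I) is the
    single-agent dose of X giving effect I.  Above a drug's imax its
    equipotent dose is infinite and its term vanishes, the usual convention
    for partial agonists.  Raises if the bracketing fails (non-convergent
    solve) rather than imputing a value.
    """
    if dose_a < 0 or dose_b < 0:
        raise ValueError("doses must be non-negative")
    if dose_a == 0 and dose_b == 0:
        return 0.0
    if dose_a == 0:
        return float(min(model_b.inhibition(dose_b / rho), 100.0))
    if dose_b == 0:
        return float(min(model_a.inhibition(dose_a / rho), 100.0))

    upper = max(model_a.imax, model_b.imax)

    def g(effect: float) -> float:
        total = -rho
        for dose, model in ((dose_a, model_a), (dose_b, model_b)):
            d_eq = model.dose_for(effect)
            if math.isfinite(d_eq) and d_eq > 0:
                total += dose / d_eq
        return total

    lo, hi = 1e-12, upper - 1e-12
    if g(hi) > 0:  # effect pinned at the joint maximum
        return float(upper)
    if g(lo) < 0:
        return 0.0
    try:
        return float(brentq(g, lo, hi, xtol=1e-12, rtol=1e-14, maxiter=200))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"Loewe solve failed for doses ({dose_a:g}, {dose_b:g}): {exc}"
        ) from exc


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground truth for a simulated assay campaign.

    ``models`` maps (cell_line, drug_id) to a Hill response; ``series`` maps
    each drug to its dilution series; ``combinations`` lists the fixed-ratio
    rays tested and their interaction model.  Noise is multiplicative with a
    constant CV (default 8%, inside the assay's <10% working band); control
    emission means default to 50,000 (MO) and 500 (MI) counts - an arbitrary
    instrument scale, since the analysis is scale invariant.
    """

    models: tuple[DrugResponseModel, ...]
    series: Mapping[str, DoseSeries]
    combinations: tuple[CombinationSpec, ...] = ()
    noise_cv: float = 8.0
    mo_mean: float = 50_000.0
    mi_mean: float = 500.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mo_mean <= self.mi_mean or self.mi_mean < 0:
            raise ValueError("need mo_mean > mi_mean >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv cannot be negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    @property
    def cell_lines(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for m in self.models:
            seen.setdefault(m.cell_line, None)
        return tuple(seen)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(self.series)

    def model_for(self, cell_line: str, drug_id: str) -> DrugResponseModel:
        for m in self.models:
            if m.cell_line == cell_line and m.drug_id == drug_id:
                return m
        raise KeyError(f"no response model for ({cell_line!r}, {drug_id!r})")

    def design_for(self, spec: CombinationSpec) -> CombinationDesign:
        return CombinationDesign(self.series[spec.drug_a], self.series[spec.drug_b])


def _condition_inhibition(
    scenario: SyntheticScenario, cell_line: str, condition: str | CombinationSpec
) -> np.ndarray:
    """Expected %inhibition at the six steps (series order, 200% first)."""
    if isinstance(condition, CombinationSpec):
        model_a = scenario.model_for(cell_line, condition.drug_a)
        model_b = scenario.model_for(cell_line, condition.drug_b)
        ca = scenario.series[condition.drug_a].concentrations
        cb = scenario.series[condition.drug_b].concentrations
        return np.array(
            [
                loewe_mixture_inhibition(a, b, model_a, model_b, condition.rho)
                for a, b in zip(ca, cb)
            ]
        )
    model = scenario.model_for(cell_line, condition)
    return np.asarray(model.inhibition(scenario.series[condition].concentrations))


def _draw_counts(rng: np.random.Generator, expected: float, cv: float, n: int) -> np.ndarray:
    """Replicate counts: normal around the expectation with SD = CV * mean,
    truncated at zero."""
    if cv == 0:
        return np.full(n, expected)
    draws = rng.normal(expected, (cv / 100.0) * expected, size=n)
    return np.maximum(draws, 0.0)


def simulate_plate(
    scenario: SyntheticScenario,
    cell_line: str,
    conditions: Sequence[str | CombinationSpec],
    plate_id: str | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one 96-well plate for up to four conditions of one cell line.

    Expected counts per well are MI + (MO - MI) * (1 - I/100) with I the
    ground-truth inhibition; replicate noise is multiplicative with the
    scenario's CV.  MO and MI control wells occupy row H.  Output is the
    canonical plate table, bit-reproducible from the seed.
    """
    if not 1 <= len(conditions) <= 4:
        raise ValueError("a plate holds between one and four conditions")
    if scenario.n_replicates > 3:
        raise ValueError("the default plate layout holds three replicate columns")
    labels = [c.label if isinstance(c, CombinationSpec) else c for c in conditions]
    plate_id = plate_id or f"{cell_line}|{'_'.join(labels)}"
    layout = default_layout(plate_id, labels)
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    cv = scenario.noise_cv
    span = scenario.mo_mean - scenario.mi_mean

    rows: list[tuple] = []
    for j, cond in enumerate(conditions):
        inh = _condition_inhibition(scenario, cell_line, cond)
        for step in range(1, N_STEPS + 1):
            expected = scenario.mi_mean + span * (1.0 - inh[step - 1] / 100.0)
            counts = _draw_counts(rng, expected, cv, scenario.n_replicates)
            for rep in range(1, scenario.n_replicates + 1):
                rows.append(
                    (plate_id, layout.well_for(j, step, rep), labels[j],
                     step, rep, float(counts[rep - 1]))
                )
    for wells, label, mean in ((layout.mo_wells, MO, scenario.mo_mean),
                               (layout.mi_wells, MI, scenario.mi_mean)):
        counts = _draw_counts(rng, mean, cv, len(wells))
        for k, well in enumerate(wells):
            rows.append((plate_id, well, label, None, k + 1, float(counts[k])))

    df = pd.DataFrame(rows, columns=["plate_id", "well", "condition",
                                     "dilution_step", "replicate", "counts"])
    df["dilution_step"] = df["dilution_step"].astype("Int64")
    return df


def simulate_combination(
    scenario: SyntheticScenario,
    drug_a: str,
    drug_b: str,
    cell_line: str,
    rho: float = 1.0,
    plate_id: str | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a single-combination plate along the fixed-ratio ray of
    ``drug_a`` and ``drug_b`` under the (potency-shifted) Loewe model."""
    spec = CombinationSpec(drug_a, drug_b, rho)
    return simulate_plate(scenario, cell_line, [spec], plate_id=plate_id, seed=seed)


def simulate_panel(scenario: SyntheticScenario) -> tuple[pd.DataFrame, dict]:
    """Simulate the whole campaign: per cell line, one plate of single agents
    (four per plate) and one plate per four combinations.

    Returns the concatenated well table and a ground-truth sidecar mapping
    every condition to its generating parameters.  Per-plate seeds are
    spawned deterministically from the scenario seed.
    """
    ss = np.random.SeedSequence(scenario.seed)
    frames: list[pd.DataFrame] = []
    truth: dict = {
        "seed": scenario.seed,
        "noise_cv": scenario.noise_cv,
        "mo_mean": scenario.mo_mean,
        "mi_mean": scenario.mi_mean,
        "n_replicates": scenario.n_replicates,
        "models": {},
        "combinations": {},
        "groups": {},
    }
    for m in scenario.models:
        truth["models"].setdefault(m.cell_line, {})[m.drug_id] = {
            "imax": m.imax, "ec50": m.ec50, "hill_slope": m.hill_slope,
            "analytic_ic50": None if math.isinf(m.ic50) else m.ic50,
        }
    for spec in scenario.combinations:
        truth["combinations"][spec.label] = {
            "drug_a": spec.drug_a, "drug_b": spec.drug_b, "rho": spec.rho,
        }

    drugs = list(scenario.drugs)
    for line in scenario.cell_lines:
        plate_ids: list[str] = []
        for i in range(0, len(drugs), 4):
            chunk = drugs[i : i + 4]
            pid = f"{line}|singles{i // 4 + 1}" if len(drugs) > 4 else f"{line}|singles"
            child = ss.spawn(1)[0]
            frames.append(simulate_plate(scenario, line, chunk, plate_id=pid,
                                         seed=int(child.generate_state(1)[0] % 2**31)))
            plate_ids.append(pid)
        combos = list(scenario.combinations)
        for i in range(0, len(combos), 4):
            chunk = combos[i : i + 4]
            pid = f"{line}|combos{i // 4 + 1}" if len(combos) > 4 else f"{line}|combos"
            child = ss.spawn(1)[0]
            frames.append(simulate_plate(scenario, line, chunk, plate_id=pid,
                                         seed=int(child.generate_state(1)[0] % 2**31)))
            plate_ids.append(pid)
        truth["groups"][line] = plate_ids

    return pd.concat(frames, ignore_index=True), truth


# --------------------------------------------------------------------------
# Isogenic MCF10a preset
# --------------------------------------------------------------------------

ISOGENIC_CELL_LINES = (
    "MCF10a-Wt",
    "MCF10a-PI3K-H1047R",
    "MCF10a-PI3K-E545K",
    "MCF10a-EGFR-dE746-A750",
    "MCF10a-BRAF-V600E",
    "MCF10a-AKT-E17K",
)

ISOGENIC_DRUGS = ("gefitinib", "erlotinib", "ZSTK474", "sirolimus")

#: TDC (uM) per drug; the 200%..6.25% series then spans the tested range
#: (gefitinib 0.06-2, erlotinib 0.2-6.5, ZSTK474 0.07-2.2, sirolimus 0.06-2 uM)
ISOGENIC_TDC = {"gefitinib": 1.0, "erlotinib": 3.25, "ZSTK474": 1.1, "sirolimus": 1.0}

#: shared curve shape per drug: (imax %, hill slope); sirolimus is modelled as
#: a shallow partial inhibitor, characteristic of mTOR blockade
_ISOGENIC_SHAPE = {
    "gefitinib": (100.0, 1.3),
    "erlotinib": (100.0, 1.3),
    "ZSTK474": (100.0, 1.5),
    "sirolimus": (85.0, 0.9),
}

#: ground-truth IndexSUM targets encoding the panel's sensitivity ordering:
#: PIK3CA mutants most sensitive to EGFR/PI3K inhibition (E545K < H1047R),
#: every mutant more gefitinib-sensitive than parental, AKT E17K slightly
#: erlotinib-resistant, BRAF V600E most sirolimus-resistant
_ISOGENIC_INDEX = {
    "gefitinib": {
        "MCF10a-Wt": 423.0, "MCF10a-PI3K-H1047R": 120.0, "MCF10a-PI3K-E545K": 64.0,
        "MCF10a-EGFR-dE746-A750": 200.0, "MCF10a-BRAF-V600E": 390.0,
        "MCF10a-AKT-E17K": 400.0,
    },
    "erlotinib": {
        "MCF10a-Wt": 188.0, "MCF10a-PI3K-H1047R": 140.0, "MCF10a-PI3K-E545K": 90.0,
        "MCF10a-EGFR-dE746-A750": 170.0, "MCF10a-BRAF-V600E": 200.0,
        "MCF10a-AKT-E17K": 227.0,
    },
    "ZSTK474": {
        "MCF10a-Wt": 250.0, "MCF10a-PI3K-H1047R": 150.0, "MCF10a-PI3K-E545K": 140.0,
        "MCF10a-EGFR-dE746-A750": 245.0, "MCF10a-BRAF-V600E": 290.0,
        "MCF10a-AKT-E17K": 255.0,
    },
    "sirolimus": {
        "MCF10a-Wt": 333.0, "MCF10a-PI3K-H1047R": 420.0, "MCF10a-PI3K-E545K": 254.0,
        "MCF10a-EGFR-dE746-A750": 272.0, "MCF10a-BRAF-V600E": 533.0,
        "MCF10a-AKT-E17K": 340.0,
    },
}

#: combinations tested in the panel; rho = 0.5 gives a clearly synergistic
#: ground truth while keeping every crossing inside the tested dose window
_ISOGENIC_COMBINATIONS = (
    ("gefitinib", "ZSTK474"),
    ("erlotinib", "ZSTK474"),
    ("gefitinib", "sirolimus"),
    ("erlotinib", "sirolimus"),
)
_ISOGENIC_RHO = 0.5


def ec50_for_index(
    target_index: float, series: DoseSeries, imax: float, hill_slope: float
) -> float:
    """EC50 such that the noiseless IndexSUM over ``series`` equals the target.

    The noiseless index 600 - sum_k I(c_k) is strictly increasing in EC50, so
    the inversion is a one-dimensional root find on log10(EC50).
    """
    if not 0.0 <= target_index <= 600.0:
        raise ValueError("target index must lie in [0, 600]")
    floor = 600.0 - N_STEPS * imax
    if target_index <= floor:
        raise ValueError(
            f"index {target_index} unreachable with imax {imax} (floor {floor})"
        )
    conc = np.asarray(series.concentrations)

    def f(log_ec50: float) -> float:
        m = DrugResponseModel("_", series.drug_id, imax, 10.0 ** log_ec50, hill_slope)
        return 600.0 - float(np.sum(m.inhibition(conc))) - target_index

    mid = math.log10(math.sqrt(series.top * series.bottom))
    return float(10.0 ** brentq(f, mid - 8.0, mid + 8.0, xtol=1e-12))


def scenario_isogenic_panel(seed: int = 0, noise_cv: float = 8.0) -> SyntheticScenario:
    """Preset six-line MCF10a panel against the four pathway inhibitors.

    Ground-truth EC50s are derived by inverting the noiseless IndexSUM to the
    per-line targets above, so the simulated campaign reproduces the panel's
    qualitative potency ordering by construction; all four combinations use
    a synergistic potency shift (rho = 0.5).
    """
    series = {d: DoseSeries.from_tdc(d, tdc) for d, tdc in ISOGENIC_TDC.items()}
    models = []
    for drug in ISOGENIC_DRUGS:
        imax, slope = _ISOGENIC_SHAPE[drug]
        for line in ISOGENIC_CELL_LINES:
            ec50 = ec50_for_index(_ISOGENIC_INDEX[drug][line], series[drug], imax, slope)
            models.append(DrugResponseModel(line, drug, imax, ec50, slope))
    combos = tuple(CombinationSpec(a, b, _ISOGENIC_RHO) for a, b in _ISOGENIC_COMBINATIONS)
    return SyntheticScenario(
        models=tuple(models),
        series=series,
        combinations=combos,
        noise_cv=noise_cv,
        seed=seed,
    )
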