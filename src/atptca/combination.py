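"""Chou-Talalay combination indices and synergy classification.

For a fixed-ratio combination of drugs A and B measured along a dilution
ray, the combination index at effect level F is

    CI = dA/DA + dB/DB + alpha * (dA * dB) / (DA * DB)

where dA, dB are the component doses of the combination at its F crossing
and DA, DB the single-agent doses giving the same effect.  alpha = 0 treats
the drugs as mutually exclusive (the two-term Loewe sum); alpha = 1 adds the
product term for mutually non-exclusive drugs.

Classification thresholds: CI < 0.8 synergy, 0.8 <= CI <= 1.2 additive
(boundaries assigned to additive), CI > 1.2 antagonism.

Any censored dose (an effect level never reached by the combination or by a
single agent within its tested range) propagates as "not estimable": no CI
is fabricated from a substituted bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dose_response import ICEstimate, SensitivityResult
from .plate import DoseSeries, InhibitionProfile

SYNERGY = "synergy"
ADDITIVE = "additive"
ANTAGONISM = "antagonism"
NOT_ESTIMABLE = "not_estimable"

#: CI below this is synergy
SYNERGY_THRESHOLD = 0.8
#: CI above this is antagonism
ANTAGONISM_THRESHOLD = 1.2


@dataclass(frozen=True)
class CombinationDesign:
    """Fixed-ratio ray pairing two dose series step for step.

    Both drugs are added simultaneously: at dilution step k the mixture
    contains step k of A's series plus step k of B's series, so the
    concentration ratio cA/cB is constant across the ray.  The combination
    profile is indexed on the A-component concentration axis.
    """

    drug_a: DoseSeries
    drug_b: DoseSeries

    def __post_init__(self) -> None:
        ca = np.asarray(self.drug_a.concentrations)
        cb = np.asarray(self.drug_b.concentrations)
        ratios = ca / cb
        if not np.allclose(ratios, ratios[0], rtol=1e-9, atol=0.0):
            raise ValueError("combination ray must keep a constant cA/cB ratio")

    @property
    def ratio(self) -> float:
        """Constant component ratio cA / cB along the ray."""
        return self.drug_a.tdc / self.drug_b.tdc

    @property
    def label(self) -> str:
        return f"{self.drug_a.drug_id}+{self.drug_b.drug_id}"

    @property
    def axis(self) -> DoseSeries:
        """Concentration axis of the combination profile (the A component)."""
        return self.drug_a


@dataclass(frozen=True)
class ComponentDoses:
    """Component doses of the combination at an effect crossing."""

    effect_fraction: float
    dose_a: float | None
    dose_b: float | None
    censored: str | None = None

    @property
    def estimable(self) -> bool:
        return self.censored is None


@dataclass(frozen=True)
class CombinationResult:
    """CI at one effect level with the doses that produced it."""

    drug_a: str
    drug_b: str
    effect_fraction: float
    ci: float | None
    alpha: int
    classification: str
    dose_a_combo: float | None = None
    dose_b_combo: float | None = None
    dose_a_single: float | None = None
    dose_b_single: float | None = None


def combo_components_at_effect(
    combo_profile: InhibitionProfile,
    design: CombinationDesign,
    effect_fraction: float,
    backend: str = "interpolation",
) -> ComponentDoses:
    """Locate the mixture's F crossing and split it into component doses.

    The crossing is found with the same ICF estimator used for single
    agents, on the A-component axis; the B dose follows from the ray's
    fixed ratio.  A censored crossing yields a non-estimable result.
    """
    from .dose_response import estimate_icf

    ic = estimate_icf(combo_profile, effect_fraction, backend=backend)
    if not ic.estimable:
        return ComponentDoses(effect_fraction, None, None, ic.censored)
    dose_a = ic.concentration
    return ComponentDoses(effect_fraction, dose_a, dose_a / design.ratio)


def combination_index(
    da_combo: float,
    db_combo: float,
    da_single: float,
    db_single: float,
    alpha: int = 0,
) -> float:
    """Chou-Talalay CI from the four doses at a common effect level."""
    if alpha not in (0, 1):
        raise ValueError("alpha must be 0 (mutually exclusive) or 1 (non-exclusive)")
    doses = (da_combo, db_combo, da_single, db_single)
    if any(not math.isfinite(d) or d <= 0 for d in doses):
        raise ValueError("all four doses must be positive and finite")
    ci = da_combo / da_single + db_combo / db_single
    if alpha:
        ci += (da_combo * db_combo) / (da_single * db_single)
    return ci


def classify_ci(ci: float) -> str:
    """Interaction class from the CI thresholds (boundaries are additive)."""
    if ci <= 0:
        raise ValueError("CI must be positive")
    if ci < SYNERGY_THRESHOLD:
        return SYNERGY
    if ci > ANTAGONISM_THRESHOLD:
        return ANTAGONISM
    return ADDITIVE


def _ci_at_level(
    ic_a: ICEstimate,
    ic_b: ICEstimate,
    ic_combo: ICEstimate,
    design: CombinationDesign,
    alpha: int,
    effect_fraction: float,
) -> CombinationResult:
    a_id, b_id = design.drug_a.drug_id, design.drug_b.drug_id
    if not (ic_a.estimable and ic_b.estimable and ic_combo.estimable):
        return CombinationResult(a_id, b_id, effect_fraction, None, alpha, NOT_ESTIMABLE)
    da_c = ic_combo.concentration
    db_c = da_c / design.ratio
    ci = combination_index(da_c, db_c, ic_a.concentration, ic_b.concentration, alpha)
    return CombinationResult(
        a_id, b_id, effect_fraction, ci, alpha, classify_ci(ci),
        dose_a_combo=da_c, dose_b_combo=db_c,
        dose_a_single=ic_a.concentration, dose_b_single=ic_b.concentration,
    )


def ci_report(
    single_a: SensitivityResult,
    single_b: SensitivityResult,
    combo: SensitivityResult,
    design: CombinationDesign,
    alpha: int = 0,
) -> tuple[CombinationResult, CombinationResult]:
    """CI at 50% and 90% effect from single-agent and combination results.

    The combination's IC estimates must have been computed on the design's
    A-component axis.  Each effect level is censored independently: CI90 may
    be estimable when CI50 is not, and vice versa.
    """
    ci50 = _ci_at_level(single_a.ic50, single_b.ic50, combo.ic50, design, alpha, 0.5)
    ci90 = _ci_at_level(single_a.ic90, single_b.ic90, combo.ic90, design, alpha, 0.9)
    return ci50, ci90
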