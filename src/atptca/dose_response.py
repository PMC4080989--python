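"""Dose-response statistics: IC50/IC90, the IndexSUM sensitivity index, and
Hill-curve fitting.

IndexSUM summarises a six-step inhibition profile into a single number in
[0, 600]: the sum over the dilution steps of (100 - clipped inhibition).
Zero means complete inhibition at every concentration, 600 no inhibition at
any; an index below 300 (equivalently, mean inhibition above 50% across the
tested range) classifies the drug as active on that cell line.

ICF estimation locates the first concentration at which inhibition crosses
100*F, scanning from the lowest concentration upwards, by linear
interpolation of clipped inhibition against log2(concentration) - the
natural axis for a doubling-dilution design.  A smooth Hill-fit backend is
available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .plate import N_STEPS, InhibitionProfile, clip_inhibition

#: censoring side markers
CENSOR_BELOW = "below"  # effect already exceeded at the lowest concentration
CENSOR_ABOVE = "above"  # effect never reached within the tested range

#: IndexSUM activity threshold: active iff index < 300 (strict)
ACTIVITY_THRESHOLD = 300.0


@dataclass(frozen=True)
class ICEstimate:
    """Concentration producing a fractional effect F, possibly censored.

    When censored, ``concentration`` is None and ``bound`` carries the
    bounding concentration of the tested range (the bottom step for
    ``censored == "below"``, the top step for ``"above"``).
    """

    effect_fraction: float
    concentration: float | None
    censored: str | None = None
    bound: float | None = None

    def __post_init__(self) -> None:
        if self.censored not in (None, CENSOR_BELOW, CENSOR_ABOVE):
            raise ValueError(f"unknown censoring side {self.censored!r}")
        if (self.concentration is None) != (self.censored is not None):
            raise ValueError("censored estimates carry no concentration, and vice versa")

    @property
    def estimable(self) -> bool:
        return self.censored is None

    def __str__(self) -> str:
        if self.estimable:
            return f"{self.concentration:.4g}"
        sign = "<" if self.censored == CENSOR_BELOW else ">"
        return f"{sign}{self.bound:.4g}"


@dataclass(frozen=True)
class HillFit:
    """Least-squares Hill model I(c) = imax * c^h / (ec50^h + c^h)."""

    imax: float
    ec50: float
    slope: float
    converged: bool
    residual_norm: float
    note: str = ""

    def inhibition(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        ch = c ** self.slope
        return self.imax * ch / (self.ec50 ** self.slope + ch)

    def inverse(self, effect_pct: float) -> float:
        """Concentration giving ``effect_pct`` inhibition; inf if unreachable."""
        if effect_pct >= self.imax:
            return math.inf
        if effect_pct <= 0:
            return 0.0
        return self.ec50 * (effect_pct / (self.imax - effect_pct)) ** (1.0 / self.slope)


@dataclass(frozen=True)
class SensitivityResult:
    """IC50/IC90, IndexSUM and activity call for one condition."""

    condition: str
    ic50: ICEstimate
    ic90: ICEstimate
    index_sum: float
    active: bool


def index_sum(profile: InhibitionProfile | Sequence[float]) -> float:
    """IndexSUM over the six dilution steps: sum of (100 - clipped inhibition).

    Accepts either a profile or a bare sequence of six inhibition values (%).
    """
    if isinstance(profile, InhibitionProfile):
        inh = profile.clipped
    else:
        inh = clip_inhibition(profile)
    if inh.shape != (N_STEPS,):
        raise ValueError(f"IndexSUM is defined over exactly {N_STEPS} dilution steps")
    return float(np.sum(100.0 - inh))


def classify_activity(index: float) -> bool:
    """Active iff IndexSUM < 300, strictly: an index of exactly 300 is inactive."""
    if not 0.0 <= index <= 600.0:
        raise ValueError("IndexSUM must lie in [0, 600]")
    return index < ACTIVITY_THRESHOLD


def _interpolate_crossing(
    conc_asc: np.ndarray, inh_asc: np.ndarray, target: float
) -> ICEstimate:
    F = target / 100.0
    if inh_asc[0] > target:
        return ICEstimate(F, None, CENSOR_BELOW, float(conc_asc[0]))
    for i in range(len(conc_asc)):
        if inh_asc[i] == target:
            return ICEstimate(F, float(conc_asc[i]))
        if i + 1 < len(conc_asc) and inh_asc[i] < target < inh_asc[i + 1]:
            lo, hi = math.log2(conc_asc[i]), math.log2(conc_asc[i + 1])
            frac = (target - inh_asc[i]) / (inh_asc[i + 1] - inh_asc[i])
            return ICEstimate(F, float(2.0 ** (lo + frac * (hi - lo))))
    return ICEstimate(F, None, CENSOR_ABOVE, float(conc_asc[-1]))


def estimate_icf(
    profile: InhibitionProfile,
    effect_fraction: float,
    backend: str = "interpolation",
) -> ICEstimate:
    """Concentration at which inhibition reaches the fraction F of full effect.

    ``backend="interpolation"`` (default) takes the first crossing of 100*F
    scanning from the lowest to the highest concentration, interpolating
    clipped inhibition linearly against log2(concentration).  If the lowest
    step already exceeds the target the estimate is censored below; if the
    target is never reached it is censored above.

    ``backend="hill"`` fits a Hill curve and inverts it analytically; the
    result is censored against the same tested-range bounds.
    """
    if not 0.0 < effect_fraction < 1.0:
        raise ValueError("effect_fraction must lie in (0, 1)")
    inh_desc = np.asarray(profile.inhibition, dtype=float)
    if not np.all(np.isfinite(inh_desc)):
        raise ValueError("profile contains non-finite inhibition values")
    target = 100.0 * effect_fraction
    conc_asc = profile.series.ascending
    inh_asc = clip_inhibition(inh_desc)[::-1]

    if backend == "interpolation":
        return _interpolate_crossing(conc_asc, inh_asc, target)
    if backend == "hill":
        fit = fit_hill(profile)
        if not fit.converged or fit.imax <= target:
            return ICEstimate(effect_fraction, None, CENSOR_ABOVE, float(conc_asc[-1]))
        conc = fit.inverse(target)
        if conc < conc_asc[0]:
            return ICEstimate(effect_fraction, None, CENSOR_BELOW, float(conc_asc[0]))
        if conc > conc_asc[-1]:
            return ICEstimate(effect_fraction, None, CENSOR_ABOVE, float(conc_asc[-1]))
        return ICEstimate(effect_fraction, float(conc))
    raise ValueError(f"unknown backend {backend!r}")


def fit_hill(profile: InhibitionProfile) -> HillFit:
    """Least-squares Hill fit to the raw (unclipped) inhibition profile.

    Constraints: imax in (0, 100], ec50 > 0, slope in (0, 10].  A profile
    with essentially no signal (maximum inhibition below 5% or dynamic range
    under 1 point) is reported as a degenerate non-converged fit rather than
    a fabricated parameter set.
    """
    conc = profile.concentrations[::-1]
    inh = np.asarray(profile.inhibition, dtype=float)[::-1]
    if not np.all(np.isfinite(inh)):
        raise ValueError("profile contains non-finite inhibition values")
    if inh.max() < 5.0 or (inh.max() - inh.min()) < 1.0:
        return HillFit(math.nan, math.nan, math.nan, False, math.nan, "no signal")

    def hill(c, imax, log_ec50, slope):
        ec50 = 10.0 ** log_ec50
        ch = c ** slope
        return imax * ch / (ec50 ** slope + ch)

    imax0 = float(np.clip(inh.max(), 1.0, 100.0))
    half = imax0 / 2.0
    above = np.nonzero(inh >= half)[0]
    ec50_0 = conc[above[0]] if above.size else float(np.sqrt(conc[0] * conc[-1]))
    p0 = (imax0, math.log10(ec50_0), 1.0)
    lo = (1e-6, math.log10(conc[0]) - 6.0, 0.05)
    hi = (100.0, math.log10(conc[-1]) + 6.0, 10.0)
    try:
        popt, _ = curve_fit(hill, conc, inh, p0=p0, bounds=(lo, hi), maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        return HillFit(math.nan, math.nan, math.nan, False, math.nan, f"fit failed: {exc}")
    resid = float(np.linalg.norm(inh - hill(conc, *popt)))
    return HillFit(float(popt[0]), float(10.0 ** popt[1]), float(popt[2]), True, resid)


def analyze_profile(
    profile: InhibitionProfile, backend: str = "interpolation"
) -> SensitivityResult:
    """Full per-condition summary: IC50, IC90, IndexSUM and activity call."""
    idx = index_sum(profile)
    return SensitivityResult(
        condition=profile.condition,
        ic50=estimate_icf(profile, 0.5, backend=backend),
        ic90=estimate_icf(profile, 0.9, backend=backend),
        index_sum=idx,
        active=classify_activity(idx),
    )
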