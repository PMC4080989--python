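"""Plate-level model of the ATP tumour chemosensitivity assay (ATP-TCA).

Cell viability is read out as luciferin-luciferase luminescence proportional
to cellular ATP.  Each 96-well plate carries up to four drugs or drug
combinations, each tested in triplicate at six doubling dilutions spanning
200% down to 6.25% of the test-drug concentration (TDC).  One row of the
plate holds the two normalisation controls: medium-only wells (MO, no drug,
the 0% inhibition reference) and maximum-inhibitor wells (MI, complete kill,
the 100% inhibition reference).

Percentage growth inhibition for a test reading is

    %Inhibition = (1 - (Test - MI) / (MO - MI)) * 100

with MO and MI the per-plate control means.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: condition labels reserved for the plate controls
MO = "MO"
MI = "MI"
CONTROL_CONDITIONS = frozenset({MO, MI})

#: number of dilution steps per condition
N_STEPS = 6

#: multiple of the TDC at each dilution step, highest first (200% .. 6.25%)
DILUTION_FACTORS = tuple(2.0 ** k for k in range(1, 1 - N_STEPS, -1))
DILUTION_LABELS = ("200%", "100%", "50%", "25%", "12.5%", "6.25%")

#: columns of the delimited plate table
PLATE_COLUMNS = ("plate_id", "well", "condition", "dilution_step", "replicate", "counts")

#: control readings beyond this many sample SDs from their group mean are dropped
CONTROL_OUTLIER_SD = 3.0

_WELL_RE = re.compile(r"^([A-H])([1-9]|1[0-2])$")


class ControlFailureError(ValueError):
    """Raised when MO/MI controls are missing or inverted (MO <= MI).

    Without a positive MO-MI window the plate cannot be normalised and every
    inhibition value derived from it would be meaningless.
    """


def _validate_well(well: str) -> None:
    if not _WELL_RE.match(well):
        raise ValueError(f"invalid 96-well coordinate {well!r} (expected A1..H12)")


@dataclass(frozen=True)
class DoseSeries:
    """Six-point doubling-dilution series for one drug.

    Concentrations run from 200% of the TDC down to 6.25%, i.e. a 32-fold
    range, stored highest first.
    """

    drug_id: str
    concentrations: tuple[float, ...]
    tdc: float

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.size != N_STEPS:
            raise ValueError(f"{self.drug_id}: expected {N_STEPS} concentrations, got {c.size}")
        if not np.all(c > 0):
            raise ValueError(f"{self.drug_id}: concentrations must be positive")
        if not np.all(np.diff(c) < 0):
            raise ValueError(f"{self.drug_id}: concentrations must be strictly decreasing")
        ratios = c[:-1] / c[1:]
        if not np.allclose(ratios, 2.0, rtol=1e-9, atol=0.0):
            raise ValueError(f"{self.drug_id}: successive dilution ratio must be 2 (got {ratios})")
        if not math.isclose(c[0], 2.0 * self.tdc, rel_tol=1e-9):
            raise ValueError(f"{self.drug_id}: top concentration must equal 2 x TDC")
        object.__setattr__(self, "concentrations", tuple(float(x) for x in c))

    @classmethod
    def from_tdc(cls, drug_id: str, tdc: float) -> "DoseSeries":
        """Build the canonical 200%..6.25% series from the TDC (in uM)."""
        if tdc <= 0:
            raise ValueError("tdc must be positive")
        return cls(drug_id, tuple(f * tdc for f in DILUTION_FACTORS), tdc)

    @property
    def ascending(self) -> np.ndarray:
        """Concentrations from lowest to highest (the scan order for IC estimation)."""
        return np.asarray(self.concentrations[::-1], dtype=float)

    @property
    def top(self) -> float:
        return self.concentrations[0]

    @property
    def bottom(self) -> float:
        return self.concentrations[-1]


@dataclass(frozen=True)
class WellMeasurement:
    """One well's luminescence reading with its experimental annotation."""

    plate_id: str
    well: str
    condition: str
    dilution_step: int | None  # 1 (200%) .. 6 (6.25%); None for control wells
    replicate: int
    counts: float

    def __post_init__(self) -> None:
        _validate_well(self.well)
        if self.counts < 0:
            raise ValueError(f"{self.well}: counts must be non-negative")
        is_control = self.condition in CONTROL_CONDITIONS
        if is_control and self.dilution_step is not None:
            raise ValueError(f"{self.well}: control wells carry no dilution step")
        if not is_control:
            if self.dilution_step is None:
                raise ValueError(f"{self.well}: drug wells need a dilution step")
            if not 1 <= self.dilution_step <= N_STEPS:
                raise ValueError(f"{self.well}: dilution step out of range 1..{N_STEPS}")
        if self.replicate < 1:
            raise ValueError(f"{self.well}: replicate index is 1-based")


@dataclass(frozen=True)
class PlateLayout:
    """Assignment of conditions and control wells on one 96-well plate."""

    plate_id: str
    conditions: tuple[str, ...]
    mo_wells: tuple[str, ...]
    mi_wells: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.conditions) > 4:
            raise ValueError("a plate holds at most four drugs or combinations")
        if len(self.mo_wells) < 3 or len(self.mi_wells) < 3:
            raise ValueError("need at least 3 MO and 3 MI control wells per plate")
        for w in (*self.mo_wells, *self.mi_wells):
            _validate_well(w)
        if set(self.mo_wells) & set(self.mi_wells):
            raise ValueError("MO and MI wells must be disjoint")

    def well_for(self, condition_index: int, step: int, replicate: int) -> str:
        """Canonical well for (condition, dilution step, replicate).

        Steps occupy rows A-F (step 1 = row A), each condition a block of
        three replicate columns; controls live in row H.
        """
        if not 0 <= condition_index < len(self.conditions):
            raise ValueError("condition index out of range")
        row = "ABCDEF"[step - 1]
        col = 3 * condition_index + replicate
        return f"{row}{col}"


def default_layout(plate_id: str, conditions: Sequence[str]) -> PlateLayout:
    """Standard layout: rows A-F hold the six dilution steps, three replicate
    columns per condition; row H holds six MO wells (H1-H6) and six MI wells
    (H7-H12)."""
    return PlateLayout(
        plate_id=plate_id,
        conditions=tuple(conditions),
        mo_wells=tuple(f"H{c}" for c in range(1, 7)),
        mi_wells=tuple(f"H{c}" for c in range(7, 13)),
    )


@dataclass(frozen=True)
class CalibratedAmount:
    """ATP amount inferred from a luminescence reading via the standard curve."""

    amount: float
    in_range: bool


@dataclass(frozen=True)
class StandardCurve:
    """Linear ATP standard curve (counts = slope * amount + intercept).

    Run before each plate read; used for instrument QC.  Inhibition itself is
    computed on raw counts normalised by the in-plate controls, so the curve
    never enters the inhibition arithmetic.
    """

    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        amounts = {p[0] for p in self.points}
        if len(amounts) < 2:
            raise ValueError("standard curve needs at least 2 distinct ATP amounts")
        if self.slope <= 0:
            raise ValueError("standard-curve slope must be positive")

    @classmethod
    def fit(cls, points: Iterable[tuple[float, float]]) -> "StandardCurve":
        """Ordinary least-squares line through (ATP amount, counts) pairs."""
        pts = tuple((float(a), float(c)) for a, c in points)
        if len({p[0] for p in pts}) < 2:
            raise ValueError("standard curve needs at least 2 distinct ATP amounts")
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        slope, intercept = np.polyfit(x, y, 1)
        return cls(pts, float(slope), float(intercept))

    def atp_amount(self, counts: float) -> CalibratedAmount:
        """Invert the fitted line; flag readings outside the calibrated range."""
        lo = min(p[1] for p in self.points)
        hi = max(p[1] for p in self.points)
        amount = (counts - self.intercept) / self.slope
        in_range = lo <= counts <= hi
        if not in_range:
            log.warning("counts %.3g outside calibrated range [%.3g, %.3g]", counts, lo, hi)
        return CalibratedAmount(float(amount), in_range)


def calibrate_atp(curve: StandardCurve, counts: float) -> CalibratedAmount:
    """Map a luminescence reading to an ATP amount on the standard curve."""
    return curve.atp_amount(counts)


def compute_inhibition(test_counts: float, mo_counts: float, mi_counts: float) -> float:
    """Percentage tumour growth inhibition from mean counts.

    Returns the unclipped value: noise can push the test reading above the MO
    mean (negative inhibition) or below the MI mean (> 100%).  Use
    :func:`clip_inhibition` before summing into the sensitivity index.

    Raises
    ------
    ControlFailureError
        If MO <= MI, i.e. the controls give no usable normalisation window.
    ValueError
        If any count is negative.
    """
    if test_counts < 0 or mo_counts < 0 or mi_counts < 0:
        raise ValueError("luminescence counts must be non-negative")
    if mo_counts <= mi_counts:
        raise ControlFailureError(
            f"MO mean ({mo_counts:g}) must exceed MI mean ({mi_counts:g}); assay invalid"
        )
    return (1.0 - (test_counts - mi_counts) / (mo_counts - mi_counts)) * 100.0


def clip_inhibition(inhibition) -> np.ndarray:
    """Clip inhibition values into [0, 100]."""
    return np.clip(np.asarray(inhibition, dtype=float), 0.0, 100.0)


@dataclass(frozen=True)
class InhibitionProfile:
    """Per-condition dose-response summary over the six dilution steps.

    ``inhibition`` holds the raw (unclipped) mean %inhibition per step in
    series order (200% first); ``cv`` the replicate coefficient of variance
    (%) per step; ``flags`` any per-step QC notes (e.g. fewer than two
    replicates).
    """

    condition: str
    series: DoseSeries
    inhibition: tuple[float, ...]
    cv: tuple[float, ...]
    n_replicates: tuple[int, ...]
    flags: tuple[str, ...] = field(default=("",) * N_STEPS)

    def __post_init__(self) -> None:
        for name in ("inhibition", "cv", "n_replicates", "flags"):
            if len(getattr(self, name)) != N_STEPS:
                raise ValueError(f"{name} must have exactly {N_STEPS} entries")
        for v in self.cv:
            if np.isfinite(v) and v < 0:
                raise ValueError("CV cannot be negative")

    @property
    def clipped(self) -> np.ndarray:
        """Mean inhibition clipped to [0, 100], series order."""
        return clip_inhibition(self.inhibition)

    @property
    def concentrations(self) -> np.ndarray:
        """Step concentrations in uM, series order (descending)."""
        return np.asarray(self.series.concentrations, dtype=float)


@dataclass(frozen=True)
class QCReport:
    """Replicate-variability check of one profile against a CV limit."""

    condition: str
    cv_limit: float
    step_flagged: tuple[bool, ...]
    passed: bool


def wells_to_frame(wells: Iterable[WellMeasurement]) -> pd.DataFrame:
    """Collect validated well measurements into the canonical plate table."""
    rows = [
        (w.plate_id, w.well, w.condition, w.dilution_step, w.replicate, w.counts)
        for w in wells
    ]
    df = pd.DataFrame(rows, columns=list(PLATE_COLUMNS))
    df["dilution_step"] = df["dilution_step"].astype("Int64")
    return df


def validate_plate_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Check a plate table for the required columns and well-level invariants."""
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    if (df["counts"] < 0).any():
        raise ValueError("plate table contains negative counts")
    for well in df["well"]:
        _validate_well(str(well))
    is_control = df["condition"].isin(CONTROL_CONDITIONS)
    if df.loc[is_control, "dilution_step"].notna().any():
        raise ValueError("control wells must not carry a dilution step")
    if df.loc[~is_control, "dilution_step"].isna().any():
        raise ValueError("drug wells must carry a dilution step")
    return df


def control_means(
    plate: pd.DataFrame, outlier_sd: float = CONTROL_OUTLIER_SD
) -> tuple[float, float]:
    """Per-plate MO and MI control means with outlier rejection.

    Control readings farther than ``outlier_sd`` SDs from the mean of the
    *remaining* wells (leave-one-out, so a single aberrant well cannot mask
    itself by inflating the pooled SD) are dropped with a logged warning
    before averaging.

    Raises :class:`ControlFailureError` when either control group is absent
    or the resulting means are inverted.
    """
    means = {}
    for label in (MO, MI):
        counts = plate.loc[plate["condition"] == label, "counts"].to_numpy(dtype=float)
        if counts.size == 0:
            plate_id = plate["plate_id"].iloc[0] if len(plate) else "?"
            raise ControlFailureError(f"plate {plate_id}: no {label} control wells")
        if counts.size >= 3:
            keep = np.ones(counts.size, dtype=bool)
            for i in range(counts.size):
                rest = np.delete(counts, i)
                sd = rest.std(ddof=1)
                if sd > 0 and abs(counts[i] - rest.mean()) > outlier_sd * sd:
                    keep[i] = False
            if not keep.all() and keep.sum() >= 2:
                log.warning(
                    "plate %s: dropping %d outlier %s control well(s)",
                    plate["plate_id"].iloc[0], int((~keep).sum()), label,
                )
                counts = counts[keep]
        means[label] = float(counts.mean())
    if means[MO] <= means[MI]:
        plate_id = plate["plate_id"].iloc[0]
        raise ControlFailureError(
            f"plate {plate_id}: MO mean ({means[MO]:g}) <= MI mean ({means[MI]:g})"
        )
    return means[MO], means[MI]


def summarize_condition(
    plate: pd.DataFrame,
    condition: str,
    series: DoseSeries,
    mo_mean: float | None = None,
    mi_mean: float | None = None,
    cv_on: str = "counts",
) -> InhibitionProfile:
    """Collapse one condition's wells into an :class:`InhibitionProfile`.

    Per step, inhibition is computed from the replicate-mean counts against
    the plate's control means.  The replicate CV is taken on the raw counts
    by default (``cv_on="counts"``) because that is where the well-to-well
    variability originates; ``cv_on="inhibition"`` switches it to the derived
    per-replicate inhibition values.

    Steps with fewer than two replicates are flagged but still summarised.
    """
    if cv_on not in ("counts", "inhibition"):
        raise ValueError("cv_on must be 'counts' or 'inhibition'")
    if mo_mean is None or mi_mean is None:
        mo_mean, mi_mean = control_means(plate)

    sub = plate[plate["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no wells for condition {condition!r}")

    inhibition, cv, n_reps, flags = [], [], [], []
    for step in range(1, N_STEPS + 1):
        counts = sub.loc[sub["dilution_step"] == step, "counts"].to_numpy(dtype=float)
        if counts.size == 0:
            raise ValueError(f"condition {condition!r}: no wells at dilution step {step}")
        flag = "" if counts.size >= 2 else "single-replicate"
        mean_counts = counts.mean()
        inh = compute_inhibition(mean_counts, mo_mean, mi_mean)
        if counts.size >= 2:
            if cv_on == "counts":
                base, spread = mean_counts, counts.std(ddof=1)
            else:
                per_rep = [compute_inhibition(c, mo_mean, mi_mean) for c in counts]
                base, spread = float(np.mean(per_rep)), float(np.std(per_rep, ddof=1))
            step_cv = 100.0 * spread / abs(base) if base != 0 else (0.0 if spread == 0 else math.inf)
        else:
            step_cv = math.nan
        inhibition.append(inh)
        cv.append(step_cv)
        n_reps.append(int(counts.size))
        flags.append(flag)

    return InhibitionProfile(
        condition=condition,
        series=series,
        inhibition=tuple(inhibition),
        cv=tuple(cv),
        n_replicates=tuple(n_reps),
        flags=tuple(flags),
    )


def qc_profile(profile: InhibitionProfile, cv_limit: float = 10.0) -> QCReport:
    """Flag steps whose replicate CV exceeds the limit (default 10%).

    The assay's working assumption is a typical replicate CV below 10%; a
    step above the limit marks the profile as failing overall QC.  Steps with
    undefined CV (single replicate) are not flagged here - they already carry
    a profile flag.
    """
    flagged = tuple(bool(np.isfinite(v) and v > cv_limit) for v in profile.cv)
    return QCReport(
        condition=profile.condition,
        cv_limit=float(cv_limit),
        step_flagged=flagged,
        passed=not any(flagged),
    )
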