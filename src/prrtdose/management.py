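"""Treatment-continuation logic driven by cumulative dose thresholds.

Therapy is planned as up to four cycles.  After each cycle the cumulative
absorbed dose to the organs at risk is updated; if the cumulative dose
expected after one more cycle would exceed 25 Gy for kidneys or 2 Gy for
bone marrow, no further cycle is given.  "Expected" means cumulative dose
plus the arithmetic mean of the completed cycles' doses — a deliberately
minimal estimator, isolated here so a clinic-specific one can be swapped in.
"Exceed" is strict: an expected total of exactly 25.000 Gy continues.

An early "predicted" classification extrapolates the mean per-cycle dose to
the full planned series and buckets the patient by where the cumulative
trajectory crosses the threshold (see :func:`classify_predicted_management`).
Decisions are advisory outputs; clinical override is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .datamodel import CycleDoseRecord
from .errors import DataValidationError, MissingRegionError
from .units import MGY_PER_GY

DEFAULT_KIDNEY_THRESHOLD_GY = 25.0
DEFAULT_MARROW_THRESHOLD_GY = 2.0
DEFAULT_PLANNED_CYCLES = 4


@dataclass
class DoseHistory:
    """Per-cycle dose records of one patient plus the safety thresholds."""

    patient_id: str
    records: list[CycleDoseRecord] = field(default_factory=list)
    kidney_threshold_Gy: float = DEFAULT_KIDNEY_THRESHOLD_GY
    marrow_threshold_Gy: float = DEFAULT_MARROW_THRESHOLD_GY
    planned_cycles: int = DEFAULT_PLANNED_CYCLES

    def __post_init__(self):
        if self.kidney_threshold_Gy <= 0 or self.marrow_threshold_Gy <= 0:
            raise DataValidationError("thresholds must be > 0")
        cycles = [r.cycle_index for r in self.records]
        if cycles != list(range(1, len(cycles) + 1)):
            raise DataValidationError(
                f"cycles must be contiguous from 1, got {cycles}")

    @property
    def n_completed(self) -> int:
        return len(self.records)

    def threshold_Gy(self, region: str) -> float:
        return (self.marrow_threshold_Gy if region == "bone_marrow"
                else self.kidney_threshold_Gy)

    def doses_Gy(self, region: str) -> list[float]:
        """Per-cycle doses in Gy for cycles where the region was assessed."""
        return [r.doses_mGy[region] / MGY_PER_GY
                for r in self.records if region in r.doses_mGy]

    def cumulative_Gy(self, region: str) -> float:
        return sum(self.doses_Gy(region))

    def mean_per_cycle_Gy(self, region: str) -> float:
        doses = self.doses_Gy(region)
        if not doses:
            raise MissingRegionError(
                f"{self.patient_id}: region {region!r} absent from every cycle")
        return sum(doses) / len(doses)


def expected_next_cycle_dose(history: DoseHistory, region: str) -> float:
    """Cumulative dose in Gy expected after one further cycle.

    Defined as cumulative + mean of completed-cycle doses for the region.
    """
    return history.cumulative_Gy(region) + history.mean_per_cycle_Gy(region)


@dataclass(frozen=True)
class ContinuationDecision:
    """Continuation verdict with the audit numbers that produced it."""

    decision: str  # continue | stop_kidney | stop_marrow | stop_both
    expected_kidney_Gy: float
    expected_marrow_Gy: float
    kidney_threshold_Gy: float
    marrow_threshold_Gy: float

    @property
    def continue_treatment(self) -> bool:
        return self.decision == "continue"


def decide_continuation(history: DoseHistory) -> ContinuationDecision:
    """Stop when the expected cumulative dose strictly exceeds a threshold."""
    exp_k = expected_next_cycle_dose(history, "kidneys")
    exp_m = expected_next_cycle_dose(history, "bone_marrow")
    stop_k = exp_k > history.kidney_threshold_Gy
    stop_m = exp_m > history.marrow_threshold_Gy
    if stop_k and stop_m:
        decision = "stop_both"
    elif stop_k:
        decision = "stop_kidney"
    elif stop_m:
        decision = "stop_marrow"
    else:
        decision = "continue"
    return ContinuationDecision(decision=decision,
                                expected_kidney_Gy=exp_k,
                                expected_marrow_Gy=exp_m,
                                kidney_threshold_Gy=history.kidney_threshold_Gy,
                                marrow_threshold_Gy=history.marrow_threshold_Gy)


def hypothetic_activity(activity_MBq: float, time_h: float,
                        lambda_cycle1_per_h: float,
                        target_time_h: float) -> float:
    """Activity decayed forward to a later, unimaged time.

    ``A(target) = A(t)·e^{-λ·(target - t)}`` with the cycle-1 decay constant;
    lets the single-time-point models be evaluated at 96 h or 168 h for
    cycles that were only imaged at 24 h.
    """
    if lambda_cycle1_per_h <= 0:
        raise DataValidationError("decay constant must be > 0")
    if target_time_h <= time_h:
        raise DataValidationError(
            f"target time {target_time_h} h must be after the measurement "
            f"time {time_h} h")
    return activity_MBq * math.exp(-lambda_cycle1_per_h * (target_time_h - time_h))


@dataclass(frozen=True)
class ManagementCategory:
    """Early classification of how many cycles a patient can safely receive."""

    category: str
    predicted_total_Gy: float
    threshold_Gy: float
    n_scans: int


def classify_predicted_management(history: DoseHistory,
                                  region: str = "kidneys") -> ManagementCategory:
    """Bucket a patient by the predicted cumulative dose trajectory.

    The predicted total after the full planned series is cumulative +
    (planned − completed)·mean per-cycle dose.  Let ``x`` be the (fractional)
    cycle count at which the linear trajectory crosses the threshold; with a
    4-cycle plan the buckets are::

        x >= 4          -> 4_cycles_safe
        3.5 <= x < 4    -> consider_4th
        3 <= x < 3.5    -> 3_cycles_safe
        2 <= x < 3      -> consider_3rd
        otherwise       -> stop_now   (incl. cumulative already above threshold)

    The half-cycle boundary reconstructs the "consider one more cycle" band:
    a trajectory that only just overshoots the planned total is flagged for
    case-by-case review rather than a hard stop at the previous cycle.
    ``n_scans`` is the number of completed cycles with post-treatment
    imaging on which the classification rests.
    """
    def ordinal(n: int) -> str:
        return {1: "1st", 2: "2nd", 3: "3rd"}.get(n, f"{n}th")

    thr = history.threshold_Gy(region)
    cum = history.cumulative_Gy(region)
    mean = history.mean_per_cycle_Gy(region)
    completed = history.n_completed
    planned = history.planned_cycles
    predicted_total = cum + (planned - completed) * mean

    if cum > thr:
        category = "stop_now"
    else:
        x = math.inf if mean == 0 else completed + (thr - cum) / mean
        if x >= planned:
            category = f"{planned}_cycles_safe"
        elif x >= planned - 0.5:
            category = f"consider_{ordinal(planned)}"
        elif x >= planned - 1:
            category = f"{planned - 1}_cycles_safe"
        elif x >= planned - 2:
            category = f"consider_{ordinal(planned - 1)}"
        else:
            category = "stop_now"
    return ManagementCategory(category=category,
                              predicted_total_Gy=predicted_total,
                              threshold_Gy=thr, n_scans=completed)
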