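"""Domain types for VOI-level Lu-177 PRRT dosimetry.

The pipeline starts from tabulated volume-of-interest (VOI) measurements —
one count rate, VOI volume and camera sensitivity per region per imaging
time — plus blood-sample activity concentrations, and ends in per-cycle
absorbed-dose records that drive treatment-continuation decisions.

Region vocabulary is open (tumor lesions carry arbitrary labels such as
``tumor`` or ``tumor-3``) but a handful of names are reserved words with
fixed semantics: ``kidneys``, ``liver``, ``spleen``, ``remainder``
(remainder of the body), ``blood`` and ``bone_marrow``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DataValidationError
from .units import volume_cc_to_mass_kg

RESERVED_REGIONS = frozenset(
    {"kidneys", "liver", "spleen", "remainder", "blood", "bone_marrow"}
)

#: organ regions that receive a dose of their own in the standard protocol
SOLID_ORGANS = ("kidneys", "liver", "spleen")

VALID_TF_LABELS = frozenset({"t1", "t2", "t3", "t1t2t3", "t1t3"})

PROTOCOLS = ("standard_multipoint", "standard_single_point", "mlr_single_point")


def is_tumor(region_id: str) -> bool:
    """True for tumor lesion labels (any region starting with ``tumor``)."""
    return region_id.startswith("tumor")


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise DataValidationError(message)


@dataclass(frozen=True)
class VOIMeasurement:
    """One SPECT measurement of one region at one time post-injection.

    Activity is derived as ``S * C`` (sensitivity times count rate, MBq) and
    concentration as activity over VOI volume (MBq/cc).
    """

    region_id: str
    time_h: float
    count_rate_cps: float
    volume_cc: float
    sensitivity_MBq_per_cps: float

    def __post_init__(self):
        _require(self.time_h > 0, f"{self.region_id}: time_h must be > 0, got {self.time_h}")
        _require(self.count_rate_cps >= 0,
                 f"{self.region_id}: count_rate_cps must be >= 0, got {self.count_rate_cps}")
        _require(self.volume_cc > 0,
                 f"{self.region_id}: volume_cc must be > 0, got {self.volume_cc}")
        _require(self.sensitivity_MBq_per_cps > 0,
                 f"{self.region_id}: sensitivity must be > 0, got {self.sensitivity_MBq_per_cps}")

    @property
    def activity_MBq(self) -> float:
        return self.sensitivity_MBq_per_cps * self.count_rate_cps

    @property
    def concentration_MBq_per_cc(self) -> float:
        return self.activity_MBq / self.volume_cc

    def mass_kg(self, density_g_per_cc: float = 1.0) -> float:
        return volume_cc_to_mass_kg(self.volume_cc, density_g_per_cc)


@dataclass(frozen=True)
class BloodSample:
    """Activity concentration of one venous blood sample (MBq/cc)."""

    time_h: float
    concentration_MBq_per_cc: float

    def __post_init__(self):
        _require(self.time_h > 0, f"blood sample time_h must be > 0, got {self.time_h}")
        _require(self.concentration_MBq_per_cc >= 0,
                 f"blood concentration must be >= 0, got {self.concentration_MBq_per_cc}")


@dataclass(frozen=True)
class KineticFit:
    """Fitted mono-exponential A(t) = A0 * exp(-lambda * t) for one region.

    ``fit_kind`` records whether the amplitude is an activity (MBq) or a
    concentration (MBq/cc); downstream dose formulas require the right kind.
    A fit with a non-positive decay constant never leaves the fitting
    routine — it is rejected there as non-decaying kinetics.
    """

    region_id: str
    amplitude_at_t0: float
    lambda_eff_per_h: float
    fit_kind: str  # "activity" | "concentration"
    n_points: int

    def __post_init__(self):
        _require(self.fit_kind in ("activity", "concentration"),
                 f"fit_kind must be activity|concentration, got {self.fit_kind!r}")
        _require(self.amplitude_at_t0 >= 0,
                 f"{self.region_id}: amplitude must be >= 0, got {self.amplitude_at_t0}")
        _require(self.lambda_eff_per_h > 0,
                 f"{self.region_id}: lambda_eff must be > 0, got {self.lambda_eff_per_h}")

    @property
    def half_life_h(self) -> float:
        return math.log(2.0) / self.lambda_eff_per_h

    def value_at(self, time_h: float) -> float:
        return self.amplitude_at_t0 * math.exp(-self.lambda_eff_per_h * time_h)


@dataclass(frozen=True)
class ResidenceInput:
    """Cumulated activity of one source region, with its mass.

    The mass is used by the self-dose (mass-scaled coupling) route; the
    phantom-based MIRD sum uses the dose-factor table directly.
    """

    region_id: str
    cumulated_activity_MBq_h: float
    mass_kg: float

    def __post_init__(self):
        _require(self.cumulated_activity_MBq_h >= 0,
                 f"{self.region_id}: cumulated activity must be >= 0")
        _require(self.mass_kg > 0, f"{self.region_id}: mass must be > 0")


@dataclass(frozen=True)
class DoseFactorTable:
    """Source→target dose factors for one phantom, plus marrow couplings.

    ``entries`` maps ``(source, target)`` to DF in mGy/(MBq·s) for the
    phantom-based MIRD sum.  ``organ_self_theta`` holds the lumped
    self-coupling Θ per organ in mGy·kg/(MBq·h) — the equilibrium dose
    constant times self-absorbed fraction, used by the mass-scaled self-dose
    route where the patient's own VOI mass replaces the phantom mass.
    ``theta_bm_bm`` / ``theta_bm_rm`` couple the blood self-term and the
    remainder-of-body cross-term to the marrow dose; they are opaque fitted
    constants in mGy per (mCi·h/cc).
    """

    phantom: str
    entries: dict[tuple[str, str], float]
    theta_bm_bm: float
    theta_bm_rm: float
    organ_self_theta: dict[str, float] = field(default_factory=dict)
    organ_masses_kg: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        _require(self.phantom in ("adult_male", "adult_female"),
                 f"unknown phantom {self.phantom!r}")
        for (src, tgt), df in self.entries.items():
            _require(df >= 0, f"DF({tgt} <- {src}) must be >= 0, got {df}")
        for organ, theta in self.organ_self_theta.items():
            _require(theta >= 0, f"theta({organ}) must be >= 0, got {theta}")
        _require(self.theta_bm_bm >= 0, "theta_bm_bm must be >= 0")
        _require(self.theta_bm_rm >= 0, "theta_bm_rm must be >= 0")

    def dose_factor(self, target: str, source: str) -> float:
        """DF(target ← source) in mGy/(MBq·s); missing pairs fail explicitly."""
        from .errors import MissingDoseFactorError

        try:
            return self.entries[(source, target)]
        except KeyError:
            raise MissingDoseFactorError(
                f"no dose factor for target {target!r} <- source {source!r} "
                f"(phantom {self.phantom})"
            ) from None

    def self_theta(self, region: str) -> float:
        """Self-coupling Θ for an organ, mGy·kg/(MBq·h)."""
        from .errors import MissingDoseFactorError

        try:
            return self.organ_self_theta[region]
        except KeyError:
            raise MissingDoseFactorError(
                f"no self-coupling theta for region {region!r} (phantom {self.phantom})"
            ) from None


@dataclass(frozen=True)
class CycleStudy:
    """All measurements of one patient after one treatment cycle."""

    patient_id: str
    cycle_index: int
    injected_activity_MBq: float
    phantom: str
    measurements: tuple[VOIMeasurement, ...]
    blood_samples: tuple[BloodSample, ...]

    def __post_init__(self):
        _require(self.cycle_index >= 1,
                 f"cycle_index must be >= 1, got {self.cycle_index}")
        _require(self.injected_activity_MBq > 0, "injected activity must be > 0")
        _require(self.phantom in ("adult_male", "adult_female"),
                 f"unknown phantom {self.phantom!r}")
        for region, times in self.times_by_region().items():
            for a, b in zip(times, times[1:]):
                _require(a < b,
                         f"{region}: measurement times must be strictly increasing "
                         f"(got {a} then {b})")

    def times_by_region(self) -> dict[str, list[float]]:
        out: dict[str, list[float]] = {}
        for m in self.measurements:
            out.setdefault(m.region_id, []).append(m.time_h)
        return out

    def region_measurements(self, region_id: str) -> list[VOIMeasurement]:
        return [m for m in self.measurements if m.region_id == region_id]

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for m in self.measurements:
            if m.region_id not in seen:
                seen.append(m.region_id)
        return seen


@dataclass(frozen=True)
class CycleDoseRecord:
    """Absorbed doses (mGy) per region for one cycle, with protocol provenance.

    A region that could not be assessed is simply absent from ``doses_mGy``
    — never recorded as zero.
    """

    patient_id: str
    cycle_index: int
    doses_mGy: dict[str, float]
    protocol: str

    def __post_init__(self):
        _require(self.protocol in PROTOCOLS, f"unknown protocol {self.protocol!r}")
        _require(self.cycle_index >= 1, "cycle_index must be >= 1")
        for region, d in self.doses_mGy.items():
            _require(d >= 0, f"{region}: dose must be >= 0, got {d}")


@dataclass(frozen=True)
class MLRCoefficients:
    """One trained log-log regression coefficient set for one target.

    ``ln(dose) = intercept + slope_conc * ln(conc) + slope_time * t``.

    For solid organs and tumors (``kind='solid'``) the coefficients are the
    (α₀, α₁, α₂) of the concentration model; for ``kind='marrow'`` they are
    the (β₀, β₁, β₂) of the composite blood+remainder model and the fitted
    marrow couplings Θ_BM,BM / Θ_BM,RM travel with the set, because the
    prediction re-uses exactly the couplings the model was trained with.

    Unit contract: concentration in mCi/cc, time in hours post-injection,
    dose in mGy.  Predictions check the contract and refuse mismatches.
    """

    target: str
    t_f_label: str
    kind: str  # "solid" | "marrow"
    intercept: float
    slope_conc: float
    slope_time: float
    theta_bm_bm: float | None = None
    theta_bm_rm: float | None = None
    r2_train: float | None = None
    n_train: int | None = None
    conc_units: str = "mCi/cc"

    def __post_init__(self):
        _require(self.kind in ("solid", "marrow"), f"unknown kind {self.kind!r}")
        _require(self.t_f_label in VALID_TF_LABELS,
                 f"unknown t_f_label {self.t_f_label!r}")
        for name in ("intercept", "slope_conc", "slope_time"):
            _require(math.isfinite(getattr(self, name)), f"{name} must be finite")
        if self.kind == "marrow":
            _require(self.theta_bm_bm is not None and self.theta_bm_rm is not None,
                     f"marrow coefficients for {self.target!r} need theta_bm_bm "
                     "and theta_bm_rm")

    # Field-notation aliases
    @property
    def alpha0(self) -> float:
        return self.intercept

    @property
    def alpha1(self) -> float:
        return self.slope_conc

    @property
    def alpha2(self) -> float:
        return self.slope_time

    beta0 = alpha0
    beta1 = alpha1
    beta2 = alpha2
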