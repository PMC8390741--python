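"""Standard multi-time-point dosimetry: kinetics, cumulated activity, dose.

The standard protocol images a patient at roughly 24, 96 and 168 h after the
first treatment cycle and once (≈24 h) after later cycles.  Per region the
time–activity curve is modelled as a single exponential
``A(t) = A0 exp(-λ t)``; the cumulated activity is its integral from
injection to infinity, ``Ã = A0/λ``.  Organ and tumor doses follow the MIRD
schema ``D = Σ_s Ã_s · DF(target ← source)``; because Lu-177 dose is
dominated by short-range β particles, the self term with a mass-scaled
coupling ``DF = Θ/m`` is the workhorse, with the patient's own VOI mass
standing in for the phantom organ mass.  Bone-marrow dose combines the blood
self-term with a remainder-of-body cross-term through two lumped couplings
Θ_BM,BM and Θ_BM,RM.

For cycles after the first, the single measurement is back-extrapolated with
the same patient's cycle-1 decay constant (unchanged-effective-half-life
assumption); a region with no cycle-1 fit fails loudly rather than borrowing
a population value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    SOLID_ORGANS,
    CycleDoseRecord,
    CycleStudy,
    DoseFactorTable,
    KineticFit,
    ResidenceInput,
    is_tumor,
)
from .errors import (
    DataValidationError,
    MissingRegionError,
    NonDecayingKineticsError,
)
from .units import MBQ_PER_MCI, SECONDS_PER_HOUR, volume_cc_to_mass_kg


@dataclass(frozen=True)
class SphereThetaTable:
    """Self-coupling Θ(m) for unit-density spheres, mGy·kg/(MBq·h) vs kg.

    Lookup is piecewise-linear in mass; queries outside the tabulated range
    are refused (extrapolating absorbed fractions is not meaningful).
    """

    mass_kg: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        m, th = np.asarray(self.mass_kg, float), np.asarray(self.theta, float)
        if m.ndim != 1 or m.shape != th.shape or m.size < 2:
            raise DataValidationError("sphere table needs matching 1-d arrays, n >= 2")
        if not np.all(np.diff(m) > 0):
            raise DataValidationError("sphere table masses must be strictly increasing")
        if np.any(th < 0):
            raise DataValidationError("sphere table theta values must be >= 0")

    def __call__(self, mass_kg: float) -> float:
        if not (self.mass_kg[0] <= mass_kg <= self.mass_kg[-1]):
            raise DataValidationError(
                f"mass {mass_kg} kg outside sphere table range "
                f"[{self.mass_kg[0]}, {self.mass_kg[-1]}] (no extrapolation)")
        return float(np.interp(mass_kg, self.mass_kg, self.theta))


def fit_monoexponential(samples, region_id: str = "", fit_kind: str = "activity"
                        ) -> KineticFit:
    """Unweighted least squares of ln(value) on time; exact for two points.

    Parameters
    ----------
    samples : sequence of (time_h, value)
        At least two points with strictly increasing times and strictly
        positive values (zeros cannot be log-transformed).

    Raises
    ------
    NonDecayingKineticsError
        If the fitted decay constant is ≤ 0; the rejected fit parameters are
        attached to the exception.
    """
    pts = [(float(t), float(v)) for t, v in samples]
    if len(pts) < 2:
        raise DataValidationError(
            f"{region_id or 'fit'}: need >= 2 samples, got {len(pts)}")
    times = np.array([t for t, _ in pts])
    values = np.array([v for _, v in pts])
    if np.any(values <= 0):
        raise DataValidationError(
            f"{region_id or 'fit'}: all sample values must be > 0 for the "
            "log transform")
    if np.any(np.diff(times) <= 0):
        raise DataValidationError(
            f"{region_id or 'fit'}: sample times must be strictly increasing")

    slope, intercept = np.polyfit(times, np.log(values), 1)
    lam = -float(slope)
    amplitude = float(np.exp(intercept))
    if lam <= 0:
        raise NonDecayingKineticsError(
            f"{region_id or 'fit'}: fitted decay constant {lam:.4g} h^-1 is "
            "not positive (non-decaying kinetics)",
            fit={"region_id": region_id, "amplitude_at_t0": amplitude,
                 "lambda_eff_per_h": lam, "n_points": len(pts)})
    return KineticFit(region_id=region_id, amplitude_at_t0=amplitude,
                      lambda_eff_per_h=lam, fit_kind=fit_kind, n_points=len(pts))


def cumulated_activity_multipoint(fit: KineticFit) -> float:
    """Ã = A0/λ in MBq·h (or, for concentration fits, MBq·h/cc)."""
    return fit.amplitude_at_t0 / fit.lambda_eff_per_h


def cumulated_activity_single_point(activity_at_ts: float, ts_h: float,
                                    lambda_prior_per_h: float) -> float:
    """Ã from one measurement plus a decay-constant prior.

    Back-extrapolates ``A(ts)`` to injection with the prior λ and integrates:
    ``Ã = A(ts)·e^{λ·ts}/λ``.  The prior is the same patient's cycle-1 value.
    """
    if activity_at_ts < 0:
        raise DataValidationError(f"activity must be >= 0, got {activity_at_ts}")
    if ts_h <= 0:
        raise DataValidationError(f"ts must be > 0, got {ts_h}")
    if lambda_prior_per_h <= 0:
        raise NonDecayingKineticsError(
            f"decay-constant prior must be > 0, got {lambda_prior_per_h}")
    return activity_at_ts * math.exp(lambda_prior_per_h * ts_h) / lambda_prior_per_h


def single_point_fit(activity_at_ts: float, ts_h: float, lambda_prior_per_h: float,
                     region_id: str = "", fit_kind: str = "activity") -> KineticFit:
    """Equivalent KineticFit from one measurement and a λ prior."""
    if activity_at_ts < 0:
        raise DataValidationError(f"activity must be >= 0, got {activity_at_ts}")
    if ts_h <= 0:
        raise DataValidationError(f"ts must be > 0, got {ts_h}")
    if lambda_prior_per_h <= 0:
        raise NonDecayingKineticsError(
            f"decay-constant prior must be > 0, got {lambda_prior_per_h}")
    amplitude = activity_at_ts * math.exp(lambda_prior_per_h * ts_h)
    return KineticFit(region_id=region_id, amplitude_at_t0=amplitude,
                      lambda_eff_per_h=lambda_prior_per_h, fit_kind=fit_kind,
                      n_points=1)


def organ_dose_mird(residences: list[ResidenceInput], target: str,
                    dft: DoseFactorTable) -> float:
    """Full MIRD sum ``D = Σ_s Ã_s · DF(target ← s)`` in mGy.

    Cumulated activities are in MBq·h and converted to MBq·s against dose
    factors in mGy/(MBq·s).  The target must appear among the sources (its
    self term dominates); a listed source with no table entry raises rather
    than silently contributing zero.
    """
    by_region = {r.region_id: r for r in residences}
    if target not in by_region:
        raise MissingRegionError(
            f"target {target!r} has no self residence entry among sources "
            f"{sorted(by_region)}")
    dose = 0.0
    for r in residences:
        df = dft.dose_factor(target, r.region_id)
        dose += r.cumulated_activity_MBq_h * SECONDS_PER_HOUR * df
    return dose


def organ_dose_self(cumulated_activity_MBq_h: float, mass_kg: float,
                    theta: float) -> float:
    """Self-dose with a mass-scaled coupling: ``D = Ã·Θ/m`` in mGy.

    Θ is the lumped self-coupling in mGy·kg/(MBq·h); the patient's VOI mass
    replaces the phantom organ mass.
    """
    if mass_kg <= 0:
        raise DataValidationError(f"mass must be > 0, got {mass_kg}")
    return cumulated_activity_MBq_h * theta / mass_kg


def tumor_dose_self(fit: KineticFit, mass_kg: float,
                    theta_sphere: SphereThetaTable) -> float:
    """Tumor self-dose ``D = A0/(m·λ) · Θ(m)`` via the sphere-model table."""
    if fit.fit_kind != "activity":
        raise DataValidationError("tumor dose needs an activity fit")
    theta = theta_sphere(mass_kg)
    return organ_dose_self(cumulated_activity_multipoint(fit), mass_kg, theta)


def bone_marrow_dose_standard(blood_fit: KineticFit, remainder_fit: KineticFit,
                              remainder_mass_kg: float,
                              dft: DoseFactorTable) -> float:
    """Marrow dose: blood self-term plus remainder-of-body cross-term (mGy).

    ``D(BM) = (a_blood,0/λ_blood)·Θ_BM,BM + (c_RM,0/λ_RM)·Θ_BM,RM`` with both
    time-integrated concentrations in mCi·h/cc (the couplings' unit
    contract) and the remainder concentration obtained from its activity
    amplitude over the remainder mass at unit density.
    """
    if blood_fit.fit_kind != "concentration":
        raise DataValidationError("blood fit must be a concentration fit")
    if remainder_fit.fit_kind != "activity":
        raise DataValidationError("remainder fit must be an activity fit")
    if remainder_mass_kg <= 0:
        raise DataValidationError(f"remainder mass must be > 0, got {remainder_mass_kg}")
    blood_term = (blood_fit.amplitude_at_t0 / MBQ_PER_MCI
                  / blood_fit.lambda_eff_per_h)
    rm_conc0 = remainder_fit.amplitude_at_t0 / (remainder_mass_kg * 1000.0)
    rm_term = rm_conc0 / MBQ_PER_MCI / remainder_fit.lambda_eff_per_h
    return blood_term * dft.theta_bm_bm + rm_term * dft.theta_bm_rm


def marrow_integrated_terms(blood_fit: KineticFit, remainder_fit: KineticFit,
                            remainder_mass_kg: float) -> tuple[float, float]:
    """The two bracketed time-integrated terms of the marrow dose, mCi·h/cc.

    Used to estimate the couplings Θ_BM,BM / Θ_BM,RM from standard-protocol
    dose data by regression through the origin.
    """
    blood_term = (blood_fit.amplitude_at_t0 / MBQ_PER_MCI
                  / blood_fit.lambda_eff_per_h)
    rm_conc0 = remainder_fit.amplitude_at_t0 / (remainder_mass_kg * 1000.0)
    rm_term = rm_conc0 / MBQ_PER_MCI / remainder_fit.lambda_eff_per_h
    return blood_term, rm_term


# ---------------------------------------------------------------------------
# Whole-study pipeline

@dataclass
class CycleDoseResult:
    """Doses plus the kinetic fits and masses the calculation used."""

    record: CycleDoseRecord
    fits: dict[str, KineticFit] = field(default_factory=dict)
    masses_kg: dict[str, float] = field(default_factory=dict)


def compute_cycle_doses(study: CycleStudy, dft: DoseFactorTable,
                        sphere: SphereThetaTable,
                        lambda_priors: dict[str, float] | None = None,
                        density_g_per_cc: float = 1.0) -> CycleDoseResult:
    """Standard-protocol doses for every region of one cycle study.

    Regions with ≥ 2 time points are fitted; single-point regions require a
    λ prior (the same patient's cycle-1 fit) under ``lambda_priors`` keyed by
    region (``'blood'`` for the blood samples).  Organ and tumor doses use
    the mass-scaled self-coupling; bone marrow combines the blood and
    remainder fits.  Marrow dose is only emitted when blood samples and a
    remainder VOI are both present.
    """
    priors = lambda_priors or {}
    fits: dict[str, KineticFit] = {}
    masses: dict[str, float] = {}
    doses: dict[str, float] = {}

    for region in study.regions:
        meas = sorted(study.region_measurements(region), key=lambda m: m.time_h)
        masses[region] = volume_cc_to_mass_kg(
            float(np.mean([m.volume_cc for m in meas])), density_g_per_cc)
        pts = [(m.time_h, m.activity_MBq) for m in meas]
        if len(pts) >= 2:
            fits[region] = fit_monoexponential(pts, region_id=region,
                                               fit_kind="activity")
        else:
            if region not in priors:
                raise MissingRegionError(
                    f"{region}: single time point and no cycle-1 decay constant "
                    "available for this patient")
            t, a = pts[0]
            fits[region] = single_point_fit(a, t, priors[region],
                                            region_id=region, fit_kind="activity")

    for region, fit in fits.items():
        if region == "remainder":
            continue
        a_tilde = cumulated_activity_multipoint(fit)
        if is_tumor(region):
            doses[region] = organ_dose_self(a_tilde, masses[region],
                                            sphere(masses[region]))
        elif region in SOLID_ORGANS:
            doses[region] = organ_dose_self(a_tilde, masses[region],
                                            dft.self_theta(region))

    if study.blood_samples and "remainder" in fits:
        bpts = sorted((b.time_h, b.concentration_MBq_per_cc)
                      for b in study.blood_samples)
        if len(bpts) >= 2:
            blood_fit = fit_monoexponential(bpts, region_id="blood",
                                            fit_kind="concentration")
        else:
            if "blood" not in priors:
                raise MissingRegionError(
                    "blood: single sample and no cycle-1 decay constant available")
            t, c = bpts[0]
            blood_fit = single_point_fit(c, t, priors["blood"],
                                         region_id="blood",
                                         fit_kind="concentration")
        fits["blood"] = blood_fit
        doses["bone_marrow"] = bone_marrow_dose_standard(
            blood_fit, fits["remainder"], masses["remainder"], dft)

    protocol = ("standard_multipoint"
                if any(f.n_points >= 2 for f in fits.values())
                else "standard_single_point")
    record = CycleDoseRecord(patient_id=study.patient_id,
                             cycle_index=study.cycle_index,
                             doses_mGy=doses, protocol=protocol)
    return CycleDoseResult(record=record, fits=fits, masses_kg=masses)
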