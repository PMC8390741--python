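"""Agreement statistics and end-to-end study orchestration.

The statistics mirror how single-time-point dose models are judged against
the standard multi-time-point protocol: per-region relative differences
(model/standard − 1), Bland–Altman limits of agreement, Pearson correlation
with the fitted slope, and the power of a one-sided binomial test for
detecting management discordance.  :func:`run_study` wires the whole
pipeline together on a synthetic cohort: simulate → standard dosimetry →
train the regression models → predict from a single study → manage patients
under both protocols → agreement report and decision concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, CohortSpec, SyntheticPatient, generate_cohort
from .datamodel import CycleDoseRecord, MLRCoefficients, is_tumor
from .errors import DataValidationError
from .io import load_packaged_dose_factors, load_packaged_sphere_theta
from .management import DoseHistory, decide_continuation
from .mlr import (
    BoneMarrowDoseRegressor,
    SolidOrganDoseRegressor,
    estimate_theta_bm,
)
from .standard import compute_cycle_doses, marrow_integrated_terms
from .units import MBQ_PER_MCI

_TIME_INDEX = {"t1": 0, "t2": 1, "t3": 2}
_LABEL_INDICES = {"t1": (0,), "t2": (1,), "t3": (2,),
                  "t1t2t3": (0, 1, 2), "t1t3": (0, 2)}
#: nominal protocol times, used as the target for hypothetic later-cycle doses
_NOMINAL_TIMES_H = {"t1": 24.0, "t2": 96.0, "t3": 168.0}


# ---------------------------------------------------------------------------
# Agreement statistics

@dataclass(frozen=True)
class RelativeDifferenceSummary:
    per_item_pct: np.ndarray
    mean_pct: float
    sd_pct: float


def relative_difference(model, reference) -> RelativeDifferenceSummary:
    """Per-item 100·(model/reference − 1) with mean ± sd summary."""
    m = np.asarray(model, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape:
        raise DataValidationError("model and reference must have equal length")
    if np.any(r <= 0):
        raise DataValidationError("reference doses must be > 0")
    d = 100.0 * (m / r - 1.0)
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return RelativeDifferenceSummary(per_item_pct=d, mean_pct=float(np.mean(d)),
                                     sd_pct=sd)


def bland_altman(model, reference) -> tuple[float, float, float]:
    """(mean difference, lower, upper 95% limit): mean ± 1.96·sd (ddof=1)."""
    m = np.asarray(model, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.size < 2:
        raise DataValidationError("need >= 2 paired values")
    d = m - r
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def pearson_and_slope(model, reference) -> tuple[float, float, float]:
    """(Pearson r, angular coefficient a, r²).

    ``a`` is the OLS slope of model on reference with intercept; r² is the
    squared correlation between the two dose sets.
    """
    m = np.asarray(model, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.size < 2:
        raise DataValidationError("need >= 2 paired values")
    if np.std(m) == 0 or np.std(r) == 0:
        raise DataValidationError("zero variance: correlation undefined")
    pear = float(np.corrcoef(r, m)[0, 1])
    slope = float(np.polyfit(r, m, 1)[0])
    return pear, slope, pear * pear


def binomial_power(n: int, p_alt: float, alpha: float = 0.05) -> float:
    """Power (%) of the one-sided binomial test against a zero null.

    Under a null of zero discordance probability, any observed discordance
    rejects at any level, so the rejection region is X ≥ 1 and
    power = 1 − (1 − p_alt)^n.
    """
    if not (0 < p_alt < 1):
        raise DataValidationError(f"p_alt must be in (0, 1), got {p_alt}")
    if not (0 < alpha < 1):
        raise DataValidationError(f"alpha must be in (0, 1), got {alpha}")
    if n < 1:
        raise DataValidationError(f"n must be >= 1, got {n}")
    return 100.0 * (1.0 - (1.0 - p_alt) ** n)


@dataclass(frozen=True)
class AgreementReport:
    """Per-region agreement between model and reference doses."""

    region: str
    n: int
    mean_rel_diff_pct: float
    sd_rel_diff_pct: float
    mean_diff: float
    loa_low: float
    loa_high: float
    pearson_r: float
    slope_a: float
    r2: float


def agreement_report(region: str, model, reference) -> AgreementReport:
    rd = relative_difference(model, reference)
    mean_diff, lo, hi = bland_altman(model, reference)
    r, a, r2 = pearson_and_slope(model, reference)
    return AgreementReport(region=region, n=len(rd.per_item_pct),
                           mean_rel_diff_pct=rd.mean_pct,
                           sd_rel_diff_pct=rd.sd_pct, mean_diff=mean_diff,
                           loa_low=lo, loa_high=hi, pearson_r=r, slope_a=a,
                           r2=r2)


# ---------------------------------------------------------------------------
# Study orchestration

@dataclass
class StudyConfig:
    """Cohort spec plus the (t_f, t_s) protocol combination and thresholds.

    Separate coefficient sets serve the first and the later cycles: the
    headline protocol trains on all first-cycle times and predicts at t3
    after cycle 1, then switches to t1-trained equations applied at t1 for
    every later cycle, so predictions always stay inside the time support
    the coefficients were fitted on.
    """

    spec: CohortSpec
    t_f_solid: str = "t1t2t3"
    t_s_first_cycle: str = "t3"
    t_f_solid_later: str = "t1"
    t_s_later_cycles: str = "t1"
    t_f_marrow: str = "t3"
    t_s_marrow_first: str = "t3"
    t_f_marrow_later: str = "t1"
    t_s_marrow_later: str = "t1"
    kidney_threshold_Gy: float = 25.0
    marrow_threshold_Gy: float = 2.0
    planned_cycles: int = 4


@dataclass
class PatientDoses:
    """Standard-protocol output for one patient, reused across combinations."""

    patient: SyntheticPatient
    records: list[CycleDoseRecord]
    cycle1_fits: dict
    cycle1_masses: dict


def standard_patient_doses(patient: SyntheticPatient, dft_by_phantom,
                           sphere) -> PatientDoses:
    """Run the standard protocol on every cycle of one patient.

    Cycle 1 is the multi-time-point fit; later cycles use the cycle-1 decay
    constants as priors.
    """
    dft = dft_by_phantom[patient.phantom]
    first = compute_cycle_doses(patient.studies[0], dft, sphere)
    priors = {region: fit.lambda_eff_per_h
              for region, fit in first.fits.items()}
    records = [first.record]
    for study in patient.studies[1:]:
        res = compute_cycle_doses(study, dft, sphere, lambda_priors=priors)
        records.append(res.record)
    return PatientDoses(patient=patient, records=records,
                        cycle1_fits=first.fits, cycle1_masses=first.masses_kg)


def _solid_target(region: str) -> str:
    return "tumors" if is_tumor(region) else region


def _conc_mci(study, region: str, index: int) -> tuple[float, float]:
    """(concentration mCi/cc, time h) of one region at one study time index."""
    meas = sorted(study.region_measurements(region), key=lambda m: m.time_h)
    m = meas[index]
    return m.concentration_MBq_per_cc / MBQ_PER_MCI, m.time_h


def _blood_mci(study, label: str) -> tuple[float, float]:
    """(blood concentration mCi/cc, time) for sample tag t1 or t3."""
    samples = sorted(study.blood_samples, key=lambda b: b.time_h)
    b = samples[0] if label == "t1" else samples[-1]
    return b.concentration_MBq_per_cc / MBQ_PER_MCI, b.time_h


def _train_solid_label(train_doses: list[PatientDoses],
                       t_f_label: str) -> dict[str, MLRCoefficients]:
    rows: dict[str, list[tuple[float, float, float]]] = {}
    for pd in train_doses:
        study = pd.patient.studies[0]
        record = pd.records[0]
        for region in study.regions:
            if region == "remainder":
                continue
            target = _solid_target(region)
            if region not in record.doses_mGy:
                continue
            dose = record.doses_mGy[region]
            for idx in _LABEL_INDICES[t_f_label]:
                conc, t = _conc_mci(study, region, idx)
                rows.setdefault(target, []).append((conc, t, dose))
    out: dict[str, MLRCoefficients] = {}
    for target, data in rows.items():
        arr = np.asarray(data, dtype=float)
        est = SolidOrganDoseRegressor().fit(arr[:, :2], arr[:, 2])
        out[target] = est.to_coefficients(target, t_f_label)
    return out


def _train_marrow_label(train_doses: list[PatientDoses], t_f_label: str,
                        theta_hat: tuple[float, float]) -> MLRCoefficients:
    bm_rows = []
    labels = {"t1": ("t1",), "t3": ("t3",), "t1t3": ("t1", "t3")}[t_f_label]
    for pd in train_doses:
        study = pd.patient.studies[0]
        record = pd.records[0]
        if "bone_marrow" not in record.doses_mGy:
            continue
        for lab in labels:
            bconc, bt_h = _blood_mci(study, lab)
            ridx = (0 if lab == "t1"
                    else len(study.times_by_region()["remainder"]) - 1)
            rconc, _ = _conc_mci(study, "remainder", ridx)
            bm_rows.append((bconc, rconc, bt_h, record.doses_mGy["bone_marrow"]))
    arr = np.asarray(bm_rows, dtype=float)
    bm_est = BoneMarrowDoseRegressor(theta_bm_bm=theta_hat[0],
                                     theta_bm_rm=theta_hat[1])
    bm_est.fit(arr[:, :3], arr[:, 3])
    return bm_est.to_coefficients(t_f_label)


def train_models(train_doses: list[PatientDoses], t_f_solid: str,
                 t_f_marrow: str) -> tuple[dict[str, MLRCoefficients],
                                           tuple[float, float]]:
    """Train all targets on the training patients' first cycles.

    Returns one coefficient set per target (keyed kidneys/liver/spleen/
    tumors/bone_marrow) for the requested training-time tags, plus the
    marrow couplings estimated by origin-through non-negative regression of
    the standard marrow dose on its blood and remainder terms.
    """
    coefficients = _train_solid_label(train_doses, t_f_solid)

    blood_terms, rm_terms, bm_doses = [], [], []
    for pd in train_doses:
        record = pd.records[0]
        if "bone_marrow" not in record.doses_mGy:
            continue
        bt, rt = marrow_integrated_terms(pd.cycle1_fits["blood"],
                                         pd.cycle1_fits["remainder"],
                                         pd.cycle1_masses["remainder"])
        blood_terms.append(bt)
        rm_terms.append(rt)
        bm_doses.append(record.doses_mGy["bone_marrow"])
    theta_hat = estimate_theta_bm(blood_terms, rm_terms, bm_doses)
    coefficients["bone_marrow"] = _train_marrow_label(train_doses, t_f_marrow,
                                                      theta_hat)
    return coefficients, theta_hat


def mlr_patient_doses(pd: PatientDoses,
                      coefficients: dict[str, MLRCoefficients],
                      config: StudyConfig,
                      coefficients_later: dict[str, MLRCoefficients] | None = None
                      ) -> list[CycleDoseRecord]:
    """Single-time-point dose records for every cycle of one patient.

    Cycle 1 uses the measured study at ``t_s_first_cycle`` with the
    first-cycle coefficient sets; later cycles are imaged at t1 only and use
    ``coefficients_later`` (default: the first-cycle sets).  When a later
    t_s is requested, the measured activity is decayed forward to the
    nominal t_s with the patient's own cycle-1 decay constants (hypothetic
    activity).
    """
    if coefficients_later is None:
        coefficients_later = coefficients
    solid_first = {t: SolidOrganDoseRegressor.from_coefficients(c)
                   for t, c in coefficients.items() if c.kind == "solid"}
    solid_later = {t: SolidOrganDoseRegressor.from_coefficients(c)
                   for t, c in coefficients_later.items() if c.kind == "solid"}
    bm_first = BoneMarrowDoseRegressor.from_coefficients(
        coefficients["bone_marrow"])
    bm_later = BoneMarrowDoseRegressor.from_coefficients(
        coefficients_later["bone_marrow"])

    records = []
    for study in pd.patient.studies:
        first = study.cycle_index == 1
        solid_est = solid_first if first else solid_later
        bm_est = bm_first if first else bm_later
        ts_label = config.t_s_first_cycle if first else config.t_s_later_cycles
        bm_label = config.t_s_marrow_first if first else config.t_s_marrow_later
        doses: dict[str, float] = {}
        for region in study.regions:
            if region == "remainder":
                continue
            target = _solid_target(region)
            if target not in solid_est:
                continue
            if first:
                conc, t = _conc_mci(study, region, _TIME_INDEX[ts_label])
            else:
                conc, t = _conc_mci(study, region, 0)
                if ts_label != "t1":
                    lam = pd.cycle1_fits[region].lambda_eff_per_h
                    t_target = _NOMINAL_TIMES_H[ts_label]
                    conc = conc * np.exp(-lam * (t_target - t))
                    t = t_target
            doses[region] = float(
                solid_est[target].predict(np.array([[conc, t]]))[0])

        if study.blood_samples and "remainder" in study.regions:
            if first:
                bconc, bt_h = _blood_mci(study, bm_label)
                ridx = (0 if bm_label == "t1"
                        else len(study.times_by_region()["remainder"]) - 1)
                rconc, _ = _conc_mci(study, "remainder", ridx)
            else:
                bconc, bt_h = _blood_mci(study, "t1")
                rconc, rt_h = _conc_mci(study, "remainder", 0)
                if bm_label != "t1":
                    t_target = _NOMINAL_TIMES_H[bm_label]
                    lam_b = pd.cycle1_fits["blood"].lambda_eff_per_h
                    lam_r = pd.cycle1_fits["remainder"].lambda_eff_per_h
                    bconc = bconc * np.exp(-lam_b * (t_target - bt_h))
                    rconc = rconc * np.exp(-lam_r * (t_target - rt_h))
                    bt_h = t_target
            doses["bone_marrow"] = float(
                bm_est.predict(np.array([[bconc, rconc, bt_h]]))[0])

        records.append(CycleDoseRecord(
            patient_id=study.patient_id, cycle_index=study.cycle_index,
            doses_mGy=doses, protocol="mlr_single_point"))
    return records


def _decision_sequence(records: list[CycleDoseRecord],
                       config: StudyConfig) -> list[str]:
    seq = []
    for k in range(1, len(records) + 1):
        hist = DoseHistory(patient_id=records[0].patient_id,
                           records=records[:k],
                           kidney_threshold_Gy=config.kidney_threshold_Gy,
                           marrow_threshold_Gy=config.marrow_threshold_Gy,
                           planned_cycles=config.planned_cycles)
        seq.append(decide_continuation(hist).decision)
    return seq


def _cumulative(records: list[CycleDoseRecord]) -> dict[str, float]:
    out: dict[str, float] = {}
    for r in records:
        for region, d in r.doses_mGy.items():
            out[region] = out.get(region, 0.0) + d
    return out


@dataclass
class StudyReport:
    """Everything one protocol-combination run produces."""

    config: StudyConfig
    coefficients: dict[str, MLRCoefficients]
    theta_hat: tuple[float, float]
    agreement: dict[str, AgreementReport]
    concordance_pct: float
    n_discordant: int
    n_train: int
    n_test: int
    decisions: dict[str, dict[str, list[str]]] = field(default_factory=dict)


def run_study(config: StudyConfig, cohort: Cohort | None = None) -> StudyReport:
    """Full pipeline for one (t_f, t_s) combination on a synthetic cohort."""
    dft_by_phantom = {p: load_packaged_dose_factors(p)
                      for p in ("adult_male", "adult_female")}
    sphere = load_packaged_sphere_theta()
    if cohort is None:
        cohort = generate_cohort(config.spec, dft_by_phantom, sphere)

    train_doses = [standard_patient_doses(p, dft_by_phantom, sphere)
                   for p in cohort.train]
    test_doses = [standard_patient_doses(p, dft_by_phantom, sphere)
                  for p in cohort.test]

    coefficients, theta_hat = train_models(train_doses, config.t_f_solid,
                                           config.t_f_marrow)
    # Later cycles run on their own coefficient sets (trained at the times
    # the later-cycle prediction uses), sharing the same couplings.
    coefficients_later = dict(coefficients)
    if config.t_f_solid_later != config.t_f_solid:
        coefficients_later.update(
            _train_solid_label(train_doses, config.t_f_solid_later))
    if config.t_f_marrow_later != config.t_f_marrow:
        coefficients_later["bone_marrow"] = _train_marrow_label(
            train_doses, config.t_f_marrow_later, theta_hat)

    # Predict, manage and compare on the test patients.
    decisions: dict[str, dict[str, list[str]]] = {}
    n_discordant = 0
    cum_model: dict[str, list[float]] = {}
    cum_std: dict[str, list[float]] = {}
    for pd in test_doses:
        mlr_records = mlr_patient_doses(pd, coefficients, config,
                                        coefficients_later)
        seq_std = _decision_sequence(pd.records, config)
        seq_mlr = _decision_sequence(mlr_records, config)
        decisions[pd.patient.patient_id] = {"standard": seq_std, "mlr": seq_mlr}
        if seq_std != seq_mlr:
            n_discordant += 1
        std_cum = _cumulative(pd.records)
        mlr_cum = _cumulative(mlr_records)
        for region in std_cum:
            if region in mlr_cum:
                key = _solid_target(region) if region != "bone_marrow" else region
                cum_std.setdefault(key, []).append(std_cum[region])
                cum_model.setdefault(key, []).append(mlr_cum[region])

    agreement = {region: agreement_report(region, cum_model[region],
                                          cum_std[region])
                 for region in sorted(cum_std) if len(cum_std[region]) >= 2}
    n_test = len(test_doses)
    concordance = 100.0 * (n_test - n_discordant) / n_test if n_test else 100.0
    return StudyReport(config=config, coefficients=coefficients,
                       theta_hat=theta_hat, agreement=agreement,
                       concordance_pct=concordance, n_discordant=n_discordant,
                       n_train=len(train_doses), n_test=n_test,
                       decisions=decisions)


def sweep_combinations(config: StudyConfig,
                       cohort: Cohort | None = None) -> dict[tuple[str, str, str], float]:
    """Decision concordance for every training/prediction time combination.

    The grid crosses solid training tags {t1, t2, t3, t1t2t3} with first-cycle
    prediction times {t1, t2, t3} and marrow training tags {t1, t3, t1t3};
    the marrow prediction time follows the solid one (t2 maps to t3, since no
    blood sample exists at t2).  Returns ``{(t_f, t_s, bm_t_f): concordance %}``
    with one cell per combination.
    """
    import dataclasses as _dc

    if cohort is None:
        dft_by_phantom = {p: load_packaged_dose_factors(p)
                          for p in ("adult_male", "adult_female")}
        cohort = generate_cohort(config.spec, dft_by_phantom,
                                 load_packaged_sphere_theta())
    grid: dict[tuple[str, str, str], float] = {}
    for t_f in ("t1", "t2", "t3", "t1t2t3"):
        for t_s in ("t1", "t2", "t3"):
            for bm_tf in ("t1", "t3", "t1t3"):
                bm_ts = t_s if t_s in ("t1", "t3") else "t3"
                cfg = _dc.replace(config, t_f_solid=t_f, t_s_first_cycle=t_s,
                                  t_f_marrow=bm_tf, t_s_marrow_first=bm_ts)
                grid[(t_f, t_s, bm_tf)] = run_study(cfg, cohort).concordance_pct
    return grid
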