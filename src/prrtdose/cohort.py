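"""Synthetic patient cohorts with closed-form ground-truth doses.

Each synthetic patient carries mono-exponential kinetics per region (organ
uptake amplitude and effective decay constant drawn from lognormal
populations), a blood compartment and a remainder-of-body compartment.
Measurements are the true exponentials sampled at the protocol times
(t₁ ≈ 24 h, t₂ ≈ 96 h, t₃ ≈ 168 h after the first cycle, t₁ only after
later cycles) under multiplicative lognormal noise that is unbiased in log
space.  Ground truth records the generating amplitudes, decay constants and
the closed-form doses, so every downstream module can be checked against
exact expected values.

Defaults mirror the clinical setting the models were built for: mean
injected activity 7.3 ± 0.5 GBq per cycle, population mean effective decay
constants 0.0129 (kidneys), 0.0098 (liver), 0.0095 (spleen) and
0.0082 h⁻¹ (tumor) with 20% CV, 5% measurement noise, and a 1–4 cycles per
patient distribution matching a typical treated population.  Uptake
fractions and VOI volumes are plausible placeholders (not population
estimates); see docs/methods.md.

All randomness flows from one integer seed; patient ``i`` uses an
independent substream derived from ``(seed, i)``, so cohorts are bit-stable
under a fixed seed and patients are reproducible individually.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import BloodSample, CycleStudy, DoseFactorTable, VOIMeasurement
from .errors import DataValidationError
from .io import load_packaged_dose_factors, load_packaged_sphere_theta, \
    read_cycle_study, write_cycle_study
from .standard import SphereThetaTable
from .units import MBQ_PER_MCI


@dataclass(frozen=True)
class RegionPopulation:
    """Lognormal population of one region's uptake, volume and kinetics."""

    uptake_fraction: float        # fraction of injected activity at t=0
    volume_cc: float              # mean VOI volume
    lambda_mean_per_h: float      # mean effective decay constant
    uptake_cv: float = 0.30
    volume_cv: float = 0.15
    lambda_cv: float = 0.20

    def __post_init__(self):
        if not (0 < self.uptake_fraction < 1):
            raise DataValidationError("uptake fraction must be in (0, 1)")
        if self.volume_cc <= 0 or self.lambda_mean_per_h <= 0:
            raise DataValidationError("volume and lambda must be > 0")
        for cv in (self.uptake_cv, self.volume_cv, self.lambda_cv):
            if cv < 0:
                raise DataValidationError("CVs must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterisation of a synthetic cohort.  Seed is mandatory."""

    seed: int
    n_patients: int = 72
    regions: dict[str, RegionPopulation] = field(default_factory=lambda: {
        "kidneys": RegionPopulation(0.020, 300.0, 0.0129),
        "liver": RegionPopulation(0.045, 1800.0, 0.0098),
        "spleen": RegionPopulation(0.012, 180.0, 0.0095),
        "tumor": RegionPopulation(0.020, 150.0, 0.0082, volume_cv=0.50),
    })
    remainder: RegionPopulation = field(default_factory=lambda: RegionPopulation(
        0.40, 60000.0, 0.0100, uptake_cv=0.15, volume_cv=0.10))
    blood_uptake_fraction: float = 0.10
    blood_uptake_cv: float = 0.20
    blood_volume_cc: float = 5200.0
    blood_lambda_per_h: float = 0.025
    blood_lambda_cv: float = 0.20
    noise_cv: float = 0.05
    schedule_times_h: tuple[float, ...] = (24.0, 96.0, 168.0)
    schedule_jitter_h: tuple[float, ...] = (2.0, 8.0, 12.0)
    injected_mean_MBq: float = 7300.0
    injected_sd_MBq: float = 500.0
    cycle_count_probs: tuple[float, ...] = (0.125, 0.0625, 0.28125, 0.53125)
    sensitivity_MBq_per_cps: float = 0.012
    density_g_per_cc: float = 1.0
    p_male: float = 0.55
    lambda_cycle_jitter_cv: float = 0.0  # per-cycle drift of lambda (0 = stable)
    n_train: int | None = None  # default: proportional 40/72 split

    def __post_init__(self):
        if self.n_patients < 1:
            raise DataValidationError("n_patients must be >= 1")
        if self.noise_cv < 0:
            raise DataValidationError("noise_cv must be >= 0")
        if abs(sum(self.cycle_count_probs) - 1.0) > 1e-9:
            raise DataValidationError("cycle_count_probs must sum to 1")
        if len(self.schedule_times_h) != len(self.schedule_jitter_h):
            raise DataValidationError("schedule times and jitters must align")


def model_matched(spec: CohortSpec) -> CohortSpec:
    """Variant of a spec under which the log-log dose models are *exact*.

    Zeroes the decay-constant and volume spread (each region shares one λ
    and one Θ(m) across patients), equates the blood and remainder decay
    constants (so the composite marrow model holds with a single λ_BM) and
    removes measurement noise.  Uptake spread is kept: it exercises the
    concentration regressor without breaking exactness.
    """
    regions = {name: dataclasses.replace(pop, lambda_cv=0.0, volume_cv=0.0)
               for name, pop in spec.regions.items()}
    remainder = dataclasses.replace(spec.remainder, lambda_cv=0.0, volume_cv=0.0,
                                    lambda_mean_per_h=0.011)
    return dataclasses.replace(
        spec, regions=regions, remainder=remainder,
        blood_lambda_per_h=0.011, blood_lambda_cv=0.0, noise_cv=0.0)


@dataclass
class PatientTruth:
    """Generating parameters and closed-form doses, by cycle and region."""

    kinetics: dict[int, dict[str, tuple[float, float]]]  # (A0 or a0, lambda)
    doses_mGy: dict[int, dict[str, float]]
    volumes_cc: dict[str, float]
    masses_kg: dict[str, float]


@dataclass
class SyntheticPatient:
    patient_id: str
    phantom: str
    studies: list[CycleStudy]
    truth: PatientTruth


@dataclass
class Cohort:
    spec: CohortSpec
    train: list[SyntheticPatient]
    test: list[SyntheticPatient]

    @property
    def patients(self) -> list[SyntheticPatient]:
        return self.train + self.test


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Lognormal draw with the given *mean* and coefficient of variation."""
    if cv == 0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(np.exp(rng.normal(mu, np.sqrt(sigma2))))


def _log_noise(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative noise factor, unbiased in log space."""
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(np.exp(rng.normal(0.0, sigma)))


def _true_dose_organ(a0: float, lam: float, mass_kg: float, theta: float) -> float:
    return a0 / lam * theta / mass_kg


def _true_dose_marrow(a_blood0: float, lam_blood: float, c_rm0: float,
                      lam_rm: float, dft: DoseFactorTable) -> float:
    blood_term = a_blood0 / MBQ_PER_MCI / lam_blood
    rm_term = c_rm0 / MBQ_PER_MCI / lam_rm
    return blood_term * dft.theta_bm_bm + rm_term * dft.theta_bm_rm


def generate_patient(spec: CohortSpec, index: int,
                     dft_by_phantom: dict[str, DoseFactorTable] | None = None,
                     sphere: SphereThetaTable | None = None) -> SyntheticPatient:
    """One synthetic patient, deterministic in (spec.seed, index)."""
    if dft_by_phantom is None:
        dft_by_phantom = {p: load_packaged_dose_factors(p)
                          for p in ("adult_male", "adult_female")}
    if sphere is None:
        sphere = load_packaged_sphere_theta()
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(index)]))

    patient_id = f"P{index + 1:03d}"
    phantom = "adult_male" if rng.random() < spec.p_male else "adult_female"
    dft = dft_by_phantom[phantom]

    # Patient-level biology: uptake fractions, volumes, decay constants.
    uptake: dict[str, float] = {}
    volumes: dict[str, float] = {}
    lambdas: dict[str, float] = {}
    for name, pop in spec.regions.items():
        uptake[name] = min(_lognormal(rng, pop.uptake_fraction, pop.uptake_cv), 0.95)
        volumes[name] = _lognormal(rng, pop.volume_cc, pop.volume_cv)
        lambdas[name] = _lognormal(rng, pop.lambda_mean_per_h, pop.lambda_cv)
    rp = spec.remainder
    uptake["remainder"] = min(_lognormal(rng, rp.uptake_fraction, rp.uptake_cv), 0.95)
    volumes["remainder"] = _lognormal(rng, rp.volume_cc, rp.volume_cv)
    lambdas["remainder"] = _lognormal(rng, rp.lambda_mean_per_h, rp.lambda_cv)
    blood_uptake = _lognormal(rng, spec.blood_uptake_fraction, spec.blood_uptake_cv)
    lambdas["blood"] = _lognormal(rng, spec.blood_lambda_per_h, spec.blood_lambda_cv)
    masses = {name: v * spec.density_g_per_cc / 1000.0 for name, v in volumes.items()}

    n_cycles = 1 + int(rng.choice(len(spec.cycle_count_probs),
                                  p=spec.cycle_count_probs))

    studies: list[CycleStudy] = []
    truth = PatientTruth(kinetics={}, doses_mGy={}, volumes_cc=dict(volumes),
                         masses_kg=dict(masses))
    for cycle in range(1, n_cycles + 1):
        injected = max(rng.normal(spec.injected_mean_MBq, spec.injected_sd_MBq),
                       0.1 * spec.injected_mean_MBq)
        # Imaging schedule: three studies after cycle 1, one afterwards.
        n_times = len(spec.schedule_times_h) if cycle == 1 else 1
        times = []
        for mean_t, jit in zip(spec.schedule_times_h[:n_times],
                               spec.schedule_jitter_h[:n_times]):
            times.append(max(rng.normal(mean_t, jit), 2.0))
        times = sorted(times)

        cyc_lambdas = {
            name: (lam if spec.lambda_cycle_jitter_cv == 0 or cycle == 1
                   else _lognormal(rng, lam, spec.lambda_cycle_jitter_cv))
            for name, lam in lambdas.items()
        }

        kin: dict[str, tuple[float, float]] = {}
        doses: dict[str, float] = {}
        measurements: list[VOIMeasurement] = []
        for name in list(spec.regions) + ["remainder"]:
            a0 = uptake[name] * injected
            lam = cyc_lambdas[name]
            kin[name] = (a0, lam)
            if name == "remainder":
                pass
            elif name.startswith("tumor"):
                doses[name] = _true_dose_organ(a0, lam, masses[name],
                                               sphere(masses[name]))
            else:
                doses[name] = _true_dose_organ(a0, lam, masses[name],
                                               dft.self_theta(name))
            for t in times:
                a_true = a0 * np.exp(-lam * t)
                cps = a_true * _log_noise(rng, spec.noise_cv) \
                    / spec.sensitivity_MBq_per_cps
                measurements.append(VOIMeasurement(
                    region_id=name, time_h=float(t), count_rate_cps=float(cps),
                    volume_cc=float(volumes[name]),
                    sensitivity_MBq_per_cps=spec.sensitivity_MBq_per_cps))

        # Blood: samples at t1 and t3 after cycle 1, t1 only afterwards.
        a_blood0 = blood_uptake * injected / spec.blood_volume_cc
        lam_blood = cyc_lambdas["blood"]
        kin["blood"] = (a_blood0, lam_blood)
        blood_times = [times[0], times[-1]] if cycle == 1 else [times[0]]
        blood_samples = tuple(
            BloodSample(time_h=float(t),
                        concentration_MBq_per_cc=float(
                            a_blood0 * np.exp(-lam_blood * t)
                            * _log_noise(rng, spec.noise_cv)))
            for t in blood_times)

        c_rm0 = kin["remainder"][0] / (masses["remainder"] * 1000.0)
        doses["bone_marrow"] = _true_dose_marrow(
            a_blood0, lam_blood, c_rm0, kin["remainder"][1], dft)

        truth.kinetics[cycle] = kin
        truth.doses_mGy[cycle] = doses
        studies.append(CycleStudy(
            patient_id=patient_id, cycle_index=cycle,
            injected_activity_MBq=float(injected), phantom=phantom,
            measurements=tuple(measurements), blood_samples=blood_samples))

    return SyntheticPatient(patient_id=patient_id, phantom=phantom,
                            studies=studies, truth=truth)


def generate_cohort(spec: CohortSpec,
                    dft_by_phantom: dict[str, DoseFactorTable] | None = None,
                    sphere: SphereThetaTable | None = None) -> Cohort:
    """Generate and split a cohort into training and test bundles.

    The split is proportional to the 40:32 design (training patients first);
    at least one patient lands on each side.
    """
    if spec.n_patients < 2:
        raise DataValidationError("need n_patients >= 2 for a train/test split")
    if dft_by_phantom is None:
        dft_by_phantom = {p: load_packaged_dose_factors(p)
                          for p in ("adult_male", "adult_female")}
    if sphere is None:
        sphere = load_packaged_sphere_theta()
    patients = [generate_patient(spec, i, dft_by_phantom, sphere)
                for i in range(spec.n_patients)]
    n_train = spec.n_train
    if n_train is None:
        n_train = int(round(spec.n_patients * 40.0 / 72.0))
    n_train = min(max(n_train, 1), spec.n_patients - 1)
    return Cohort(spec=spec, train=patients[:n_train], test=patients[n_train:])


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write every study as a cycle-study bundle under train/ and test/."""
    path = Path(path)
    for split, patients in (("train", cohort.train), ("test", cohort.test)):
        for p in patients:
            for study in p.studies:
                write_cycle_study(
                    study, path / split / p.patient_id / f"cycle{study.cycle_index}")
    return path


def read_cohort_studies(path: str | Path) -> dict[str, list[CycleStudy]]:
    """Re-read written cohort fixtures: ``{'train'|'test': [CycleStudy...]}``."""
    path = Path(path)
    out: dict[str, list[CycleStudy]] = {}
    for split in ("train", "test"):
        studies = []
        split_dir = path / split
        if not split_dir.exists():
            continue
        for patient_dir in sorted(split_dir.iterdir()):
            for cycle_dir in sorted(patient_dir.iterdir()):
                studies.append(read_cycle_study(cycle_dir))
        out[split] = studies
    return out
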