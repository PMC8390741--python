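"""Kinetic fitting, cumulated activity and the MIRD dose engine."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import prrtdose as pr
from prrtdose.datamodel import ResidenceInput
from prrtdose.errors import (
    DataValidationError,
    MissingDoseFactorError,
    MissingRegionError,
    NonDecayingKineticsError,
)
from prrtdose.evaluation import standard_patient_doses
from prrtdose.standard import single_point_fit


class TestMonoexponentialFit:
    def test_two_points_determine_the_curve(self):
        pts = [(24, 100 * math.exp(-0.01 * 24)), (168, 100 * math.exp(-0.01 * 168))]
        fit = pr.fit_monoexponential(pts, "kidneys")
        assert fit.amplitude_at_t0 == pytest.approx(100.0, rel=1e-12)
        assert fit.lambda_eff_per_h == pytest.approx(0.01, rel=1e-12)

    def test_noiseless_three_point_recovery(self):
        a0, lam = 50.0, 0.0129
        pts = [(t, a0 * math.exp(-lam * t)) for t in (24.0, 96.0, 168.0)]
        fit = pr.fit_monoexponential(pts, "kidneys")
        assert fit.amplitude_at_t0 == pytest.approx(a0, rel=1e-12)
        assert fit.lambda_eff_per_h == pytest.approx(lam, rel=1e-12)
        assert fit.n_points == 3

    def test_mean_lambda_unbiased_under_multiplicative_noise(self, rng):
        # 200 replicate 3-point fits with 5% lognormal noise: the log-space
        # regression is unbiased for lambda, so the replicate mean must sit
        # within 2% of the generating value.
        a0, lam = 100.0, 0.0129
        sigma = math.sqrt(math.log(1 + 0.05 ** 2))
        lams = []
        for _ in range(200):
            pts = [(t, a0 * math.exp(-lam * t) * math.exp(rng.normal(0, sigma)))
                   for t in (24.0, 96.0, 168.0)]
            lams.append(pr.fit_monoexponential(pts).lambda_eff_per_h)
        assert np.mean(lams) == pytest.approx(lam, rel=0.02)

    @pytest.mark.parametrize("pts,err", [
        ([(24.0, 100.0)], DataValidationError),
        ([(24.0, 100.0), (96.0, 0.0)], DataValidationError),
        ([(96.0, 100.0), (24.0, 50.0)], DataValidationError),
        ([(24.0, 50.0), (96.0, 100.0)], NonDecayingKineticsError),
    ])
    def test_rejects_bad_samples(self, pts, err):
        with pytest.raises(err):
            pr.fit_monoexponential(pts)

    def test_nondecaying_error_carries_fit(self):
        with pytest.raises(NonDecayingKineticsError) as exc:
            pr.fit_monoexponential([(24.0, 50.0), (96.0, 100.0)], "liver")
        assert exc.value.fit["lambda_eff_per_h"] < 0


class TestCumulatedActivity:
    def test_analytic_integral(self):
        fit = pr.KineticFit("kidneys", 100.0, 0.01, "activity", 3)
        assert pr.cumulated_activity_multipoint(fit) == pytest.approx(10000.0)

    def test_zero_amplitude_gives_zero(self):
        fit = pr.KineticFit("kidneys", 0.0, 0.01, "activity", 3)
        assert pr.cumulated_activity_multipoint(fit) == 0.0

    def test_multipoint_against_quadrature(self):
        a0, lam = 7300.0, 0.0129
        fit = pr.KineticFit("kidneys", a0, lam, "activity", 3)
        expected, _ = quad(lambda t: a0 * math.exp(-lam * t), 0, np.inf)
        assert pr.cumulated_activity_multipoint(fit) == pytest.approx(expected,
                                                                      rel=1e-9)

    def test_single_point_consistent_with_multipoint(self):
        a0, lam = 120.0, 0.0098
        for ts in (24.0, 96.0, 168.0):
            a_ts = a0 * math.exp(-lam * ts)
            assert pr.cumulated_activity_single_point(a_ts, ts, lam) \
                == pytest.approx(a0 / lam, rel=1e-12)

    def test_single_point_direct_formula(self):
        expected = 50.0 * math.exp(0.24) / 0.01
        assert pr.cumulated_activity_single_point(50.0, 24.0, 0.01) \
            == pytest.approx(expected, rel=1e-12)

    def test_single_point_against_quadrature(self, rng):
        # integral of the back-extrapolated exponential over [0, inf)
        for _ in range(20):
            a = float(rng.uniform(1, 500))
            ts = float(rng.uniform(5, 200))
            lam = float(rng.uniform(0.004, 0.03))
            a0 = a * math.exp(lam * ts)
            expected, _ = quad(lambda t: a0 * math.exp(-lam * t), 0, np.inf)
            assert pr.cumulated_activity_single_point(a, ts, lam) \
                == pytest.approx(expected, rel=1e-8)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(NonDecayingKineticsError):
            pr.cumulated_activity_single_point(50.0, 24.0, 0.0)


class TestMirdDose:
    def test_single_source_equals_product(self, dft):
        res = [ResidenceInput("kidneys", 1.0 / 3600.0, 0.3)]  # 1 MBq*s
        d = pr.organ_dose_mird(res, "kidneys", dft)
        assert d == pytest.approx(dft.dose_factor("kidneys", "kidneys"), rel=1e-12)

    def test_brute_force_sum_over_sources(self, dft, rng):
        regions = ["kidneys", "liver", "spleen"]
        res = [ResidenceInput(r, float(rng.uniform(1e3, 1e5)),
                              float(rng.uniform(0.1, 2.0))) for r in regions]
        expected = sum(r.cumulated_activity_MBq_h * 3600.0
                       * dft.dose_factor("liver", r.region_id) for r in res)
        assert pr.organ_dose_mird(res, "liver", dft) == pytest.approx(expected,
                                                                      rel=1e-12)

    def test_permutation_invariance(self, dft, rng):
        regions = ["kidneys", "liver", "spleen"]
        res = [ResidenceInput(r, float(rng.uniform(1e3, 1e5)), 0.5)
               for r in regions]
        d1 = pr.organ_dose_mird(res, "spleen", dft)
        d2 = pr.organ_dose_mird(list(reversed(res)), "spleen", dft)
        assert d1 == pytest.approx(d2, rel=1e-14)

    def test_missing_pair_raises_not_zero(self, dft):
        res = [ResidenceInput("kidneys", 1e4, 0.3),
               ResidenceInput("brain", 1e3, 1.4)]
        with pytest.raises(MissingDoseFactorError):
            pr.organ_dose_mird(res, "kidneys", dft)

    def test_target_without_self_entry_rejected(self, dft):
        with pytest.raises(MissingRegionError):
            pr.organ_dose_mird([ResidenceInput("liver", 1e4, 1.8)], "kidneys", dft)


class TestMarrowAndTumorDose:
    def test_marrow_reduces_to_blood_term_when_remainder_uncoupled(self, dft):
        import dataclasses
        dft0 = dataclasses.replace(dft, theta_bm_rm=0.0)
        blood = pr.KineticFit("blood", 0.14, 0.025, "concentration", 2)
        rm = pr.KineticFit("remainder", 2900.0, 0.010, "activity", 3)
        d = pr.bone_marrow_dose_standard(blood, rm, 57.0, dft0)
        expected = 0.14 / 37.0 / 0.025 * dft.theta_bm_bm
        assert d == pytest.approx(expected, rel=1e-12)

    def test_marrow_zero_amplitudes_give_zero(self, dft):
        blood = pr.KineticFit("blood", 0.0, 0.025, "concentration", 2)
        rm = pr.KineticFit("remainder", 0.0, 0.010, "activity", 3)
        assert pr.bone_marrow_dose_standard(blood, rm, 57.0, dft) == 0.0

    def test_marrow_term_by_term_hand_evaluation(self, dft, rng):
        for _ in range(10):
            ab = float(rng.uniform(0.01, 0.5))
            lb = float(rng.uniform(0.01, 0.05))
            arm = float(rng.uniform(500, 5000))
            lrm = float(rng.uniform(0.005, 0.02))
            m = float(rng.uniform(40, 70))
            blood = pr.KineticFit("blood", ab, lb, "concentration", 2)
            rm = pr.KineticFit("remainder", arm, lrm, "activity", 3)
            expected = (ab / 37.0 / lb) * dft.theta_bm_bm \
                + (arm / (m * 1000.0) / 37.0 / lrm) * dft.theta_bm_rm
            assert pr.bone_marrow_dose_standard(blood, rm, m, dft) \
                == pytest.approx(expected, rel=1e-12)

    def test_tumor_dose_direct_formula_with_flat_table(self):
        sphere = pr.SphereThetaTable(np.array([0.001, 1.0]),
                                     np.array([0.08, 0.08]))
        fit = pr.KineticFit("tumor", 10.0, 0.01, "activity", 3)
        assert pr.tumor_dose_self(fit, 0.02, sphere) \
            == pytest.approx(10.0 / (0.02 * 0.01) * 0.08, rel=1e-12)

    def test_tumor_zero_amplitude(self, sphere):
        fit = pr.KineticFit("tumor", 0.0, 0.01, "activity", 3)
        assert pr.tumor_dose_self(fit, 0.15, sphere) == 0.0

    def test_tumor_theta_exact_on_grid_node(self, sphere):
        m = float(sphere.mass_kg[3])
        fit = pr.KineticFit("tumor", 25.0, 0.0082, "activity", 3)
        expected = 25.0 / 0.0082 / m * float(sphere.theta[3])
        assert pr.tumor_dose_self(fit, m, sphere) == pytest.approx(expected,
                                                                   rel=1e-12)

    def test_tumor_mass_outside_table_rejected(self, sphere):
        fit = pr.KineticFit("tumor", 25.0, 0.0082, "activity", 3)
        with pytest.raises(DataValidationError):
            pr.tumor_dose_self(fit, 100.0, sphere)


class TestStudyPipeline:
    def test_dose_homogeneous_in_injected_activity(self, dft, sphere):
        # scaling every amplitude by c scales every dose by c
        fit = pr.KineticFit("kidneys", 150.0, 0.0129, "activity", 3)
        fit2 = pr.KineticFit("kidneys", 450.0, 0.0129, "activity", 3)
        d1 = pr.organ_dose_self(pr.cumulated_activity_multipoint(fit), 0.3,
                                dft.self_theta("kidneys"))
        d2 = pr.organ_dose_self(pr.cumulated_activity_multipoint(fit2), 0.3,
                                dft.self_theta("kidneys"))
        assert d2 == pytest.approx(3.0 * d1, rel=1e-12)

    def test_noiseless_pipeline_matches_generator_truth(self, dfts, sphere):
        spec = pr.CohortSpec(seed=5, n_patients=6, noise_cv=0.0)
        cohort = pr.generate_cohort(spec, dfts, sphere)
        worst = 0.0
        for patient in cohort.patients:
            pd = standard_patient_doses(patient, dfts, sphere)
            for rec in pd.records:
                truth = patient.truth.doses_mGy[rec.cycle_index]
                for region, dose in rec.doses_mGy.items():
                    rel = abs(dose - truth[region]) / truth[region]
                    worst = max(worst, rel)
        assert worst < 1e-9

    def test_later_cycle_without_cycle1_region_fails_loudly(self, dft, sphere):
        # a single-point study with no prior decay constant must refuse
        m = pr.VOIMeasurement("kidneys", 24.0, 5000.0, 300.0, 0.012)
        study = pr.CycleStudy("P1", 2, 7300.0, "adult_male", (m,), ())
        with pytest.raises(MissingRegionError):
            pr.compute_cycle_doses(study, dft, sphere, lambda_priors={})

    def test_single_point_fit_equivalent_to_back_extrapolation(self):
        lam, ts, a = 0.0129, 24.0, 80.0
        fit = single_point_fit(a, ts, lam, "kidneys")
        assert fit.value_at(ts) == pytest.approx(a, rel=1e-12)
        assert pr.cumulated_activity_multipoint(fit) \
            == pytest.approx(pr.cumulated_activity_single_point(a, ts, lam),
                             rel=1e-12)
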