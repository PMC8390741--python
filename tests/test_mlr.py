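"""Log-log dose regressors: training, prediction, coupling estimation."""

import math

import numpy as np
import pytest
from sklearn.base import clone

import prrtdose as pr
from prrtdose.errors import (
    DataValidationError,
    SingularDesignError,
    UnitContractError,
)
from prrtdose.mlr import BoneMarrowDoseRegressor, SolidOrganDoseRegressor


def exact_solid_rows(rng, n=30, lam=0.0111, theta_over_lam=2.5e5):
    """Rows generated exactly from ln D = ln K + ln c + lam*t."""
    conc = rng.uniform(0.005, 0.1, n)
    ts = rng.uniform(15, 180, n)
    dose = theta_over_lam * conc * np.exp(lam * ts)
    return conc, ts, dose


class TestSolidTraining:
    def test_exact_model_recovered_with_unit_slope(self, rng):
        conc, ts, dose = exact_solid_rows(rng, lam=0.0111)
        coef = pr.train_mlr_solid(conc, ts, dose, "kidneys", "t1t2t3")
        assert coef.alpha1 == pytest.approx(1.0, abs=1e-9)
        assert coef.alpha2 == pytest.approx(0.0111, abs=1e-9)
        assert coef.r2_train == pytest.approx(1.0, abs=1e-12)

    def test_scaling_doses_by_e_shifts_only_intercept(self, rng):
        conc, ts, dose = exact_solid_rows(rng)
        c1 = pr.train_mlr_solid(conc, ts, dose, "kidneys", "t1")
        c2 = pr.train_mlr_solid(conc, ts, dose * math.e, "kidneys", "t1")
        assert c2.alpha0 == pytest.approx(c1.alpha0 + 1.0, abs=1e-9)
        assert c2.alpha1 == pytest.approx(c1.alpha1, abs=1e-9)
        assert c2.alpha2 == pytest.approx(c1.alpha2, abs=1e-9)

    def test_matches_independent_regression_oracle(self, rng):
        import statsmodels.api as sm

        conc = rng.uniform(0.005, 0.1, 50)
        ts = rng.uniform(15, 180, 50)
        dose = 2e5 * conc ** 0.9 * np.exp(0.01 * ts) \
            * np.exp(rng.normal(0, 0.1, 50))
        est = SolidOrganDoseRegressor().fit(np.column_stack([conc, ts]), dose)
        X = sm.add_constant(np.column_stack([np.log(conc), ts]))
        fit = sm.OLS(np.log(dose), X).fit()
        assert est.alpha0_ == pytest.approx(fit.params[0], abs=1e-8)
        assert est.alpha1_ == pytest.approx(fit.params[1], abs=1e-8)
        assert est.alpha2_ == pytest.approx(fit.params[2], abs=1e-8)
        assert est.r2_ == pytest.approx(fit.rsquared, abs=1e-8)

    def test_constant_time_column_is_rank_deficient(self, rng):
        conc = rng.uniform(0.01, 0.1, 10)
        ts = np.full(10, 24.0)
        dose = 1e5 * conc
        with pytest.raises(SingularDesignError):
            pr.train_mlr_solid(conc, ts, dose, "kidneys", "t1")

    def test_zero_activity_rows_excluded_with_warning(self, rng, caplog):
        conc, ts, dose = exact_solid_rows(rng, n=10)
        conc[0] = 0.0
        with caplog.at_level("WARNING", logger="prrtdose.mlr"):
            coef = pr.train_mlr_solid(conc, ts, dose, "kidneys", "t1t2t3")
        assert coef.n_train == 9
        assert "excluding 1" in caplog.text

    def test_too_few_rows_rejected(self):
        with pytest.raises(DataValidationError):
            pr.train_mlr_solid([0.1, 0.2, 0.3], [24, 96, 168],
                               [100, 200, 300], "kidneys", "t1")


class TestMarrowTrainingAndTheta:
    def test_theta_recovered_exactly_from_exact_records(self, rng):
        bt = rng.uniform(0.05, 0.3, 12)
        rt = rng.uniform(0.05, 0.3, 12)
        dose = bt * 1889.0 + rt * 315.0
        theta = pr.estimate_theta_bm(bt, rt, dose)
        assert theta[0] == pytest.approx(1889.0, rel=1e-10)
        assert theta[1] == pytest.approx(315.0, rel=1e-10)

    def test_all_zero_remainder_terms_singular(self, rng):
        bt = rng.uniform(0.05, 0.3, 12)
        with pytest.raises(SingularDesignError):
            pr.estimate_theta_bm(bt, np.zeros(12), bt * 1889.0)

    def test_theta_recovery_under_dose_noise(self, rng):
        # n=40, 5% lognormal dose noise; bounds established by a 500-rep
        # Monte-Carlo of this exact scenario (worst-case relative errors
        # 0.064 for the blood coupling, 0.29 for the remainder coupling).
        sigma = math.sqrt(math.log(1 + 0.05 ** 2))
        bt = rng.uniform(0.05, 0.3, 40)
        rt = rng.uniform(0.05, 0.3, 40)
        dose = (bt * 1889.0 + rt * 315.0) * np.exp(rng.normal(0, sigma, 40))
        theta = pr.estimate_theta_bm(bt, rt, dose)
        assert theta[0] == pytest.approx(1889.0, rel=0.08)
        assert theta[1] == pytest.approx(315.0, rel=0.30)

    def test_exact_composite_model_recovery(self, rng):
        lam_bm = 0.0069
        blood = rng.uniform(0.002, 0.01, 20)
        rm = rng.uniform(0.0005, 0.003, 20)
        ts = rng.uniform(15, 180, 20)
        comp = blood * 1889.0 + rm * 315.0
        dose = comp * np.exp(lam_bm * ts) / lam_bm
        coef = pr.train_mlr_bm(blood, rm, ts, dose, 1889.0, 315.0, "t3")
        assert coef.beta1 == pytest.approx(1.0, abs=1e-9)
        assert coef.beta2 == pytest.approx(lam_bm, abs=1e-9)
        assert coef.beta0 == pytest.approx(-math.log(lam_bm), abs=1e-9)

    def test_constant_composite_is_rank_deficient(self):
        blood = np.full(10, 0.005)
        rm = np.full(10, 0.001)
        ts = np.full(10, 163.0)
        with pytest.raises(SingularDesignError):
            pr.train_mlr_bm(blood, rm, ts, np.full(10, 400.0), 1889.0, 315.0, "t3")

    def test_marrow_matches_independent_regression_oracle(self, rng):
        import statsmodels.api as sm

        blood = rng.uniform(0.002, 0.01, 40)
        rm = rng.uniform(0.0005, 0.003, 40)
        ts = rng.uniform(15, 180, 40)
        comp = blood * 1889.0 + rm * 315.0
        dose = comp ** 0.85 * np.exp(0.007 * ts + 5.0) \
            * np.exp(rng.normal(0, 0.15, 40))
        est = BoneMarrowDoseRegressor(1889.0, 315.0)
        est.fit(np.column_stack([blood, rm, ts]), dose)
        X = sm.add_constant(np.column_stack([np.log(comp), ts]))
        fit = sm.OLS(np.log(dose), X).fit()
        assert est.beta0_ == pytest.approx(fit.params[0], abs=1e-8)
        assert est.beta1_ == pytest.approx(fit.params[1], abs=1e-8)
        assert est.beta2_ == pytest.approx(fit.params[2], abs=1e-8)


class TestPrediction:
    def test_unit_concentration_zero_time_gives_exp_intercept(
            self, packaged_coefficients):
        # at conc = 1 mCi/cc the log term vanishes; at ts -> 0 the time term
        # vanishes, so the prediction collapses to e^alpha0 for every target
        for target, by_label in packaged_coefficients.items():
            for coef in by_label.values():
                if coef.kind == "solid":
                    d = pr.predict_dose_solid(coef, 1.0, 1e-12)
                else:
                    # composite = 1 via blood term alone
                    d = pr.predict_dose_bm(coef, 1.0 / coef.theta_bm_bm, 0.0,
                                           1e-12)
                assert d == pytest.approx(math.exp(coef.intercept), rel=1e-9)

    def test_solid_reduces_to_closed_form_self_dose(self, rng):
        # with alpha1=1 and alpha2=lam the regression equals the
        # back-extrapolated self-dose formula for every (conc, ts)
        lam, K = 0.0129, 3.7e5  # K = 37000 * theta * (V/m) / lam factor, lumped
        coef = pr.MLRCoefficients(target="kidneys", t_f_label="t3", kind="solid",
                                  intercept=math.log(K), slope_conc=1.0,
                                  slope_time=lam)
        conc = rng.uniform(1e-4, 1.0, 10000)
        ts = rng.uniform(1.0, 200.0, 10000)
        predicted = pr.predict_dose_solid(coef, conc, ts)
        closed_form = conc * np.exp(lam * ts) * K
        np.testing.assert_allclose(predicted, closed_form, rtol=1e-12)

    def test_marrow_reduces_to_composite_closed_form(self, rng):
        lam_bm = 0.0069
        coef = pr.MLRCoefficients(target="bone_marrow", t_f_label="t3",
                                  kind="marrow", intercept=-math.log(lam_bm),
                                  slope_conc=1.0, slope_time=lam_bm,
                                  theta_bm_bm=1889.0, theta_bm_rm=315.0)
        blood = rng.uniform(1e-4, 0.02, 10000)
        rm = rng.uniform(1e-5, 0.005, 10000)
        ts = rng.uniform(1.0, 200.0, 10000)
        predicted = pr.predict_dose_bm(coef, blood, rm, ts)
        comp = blood * 1889.0 + rm * 315.0
        np.testing.assert_allclose(predicted, comp * np.exp(lam_bm * ts) / lam_bm,
                                   rtol=1e-12)

    def test_nonpositive_concentration_rejected(self, packaged_coefficients):
        coef = packaged_coefficients["kidneys"]["t3"]
        with pytest.raises(DataValidationError):
            pr.predict_dose_solid(coef, 0.0, 24.0)

    def test_monotone_in_concentration_and_time(self, packaged_coefficients):
        coef = packaged_coefficients["kidneys"]["t1t2t3"]  # alpha1, alpha2 > 0
        conc = np.linspace(0.001, 0.1, 50)
        d = pr.predict_dose_solid(coef, conc, 96.0)
        assert np.all(np.diff(d) > 0)
        ts = np.linspace(10, 180, 50)
        d = pr.predict_dose_solid(coef, 0.02, ts)
        assert np.all(np.diff(d) > 0)

    def test_mbq_units_converted_once(self):
        coef = pr.MLRCoefficients(target="kidneys", t_f_label="t3", kind="solid",
                                  intercept=10.0, slope_conc=1.0, slope_time=0.0)
        est_mci = SolidOrganDoseRegressor.from_coefficients(coef)
        est_mbq = SolidOrganDoseRegressor.from_coefficients(coef,
                                                            conc_units="MBq/cc")
        d_mci = est_mci.predict(np.array([[1.0, 24.0]]))[0]
        d_mbq = est_mbq.predict(np.array([[37.0, 24.0]]))[0]
        assert d_mbq == pytest.approx(d_mci, rel=1e-12)

    def test_unsupported_units_refused(self):
        est = SolidOrganDoseRegressor(conc_units="Bq/mL")
        with pytest.raises(UnitContractError):
            est.fit(np.array([[1.0, 24.0]] * 5), np.ones(5))

    def test_wrong_kind_coefficients_refused(self, packaged_coefficients):
        with pytest.raises(UnitContractError):
            SolidOrganDoseRegressor.from_coefficients(
                packaged_coefficients["bone_marrow"]["t3"])


class TestSklearnContract:
    def test_get_set_params_and_clone(self):
        est = BoneMarrowDoseRegressor(1889.0, 315.0)
        params = est.get_params()
        assert params["theta_bm_bm"] == 1889.0
        cloned = clone(est)
        assert cloned.get_params() == params
        cloned.set_params(theta_bm_rm=300.0)
        assert cloned.theta_bm_rm == 300.0

    def test_train_predict_consistency_on_model_family(self, rng):
        conc, ts, dose = exact_solid_rows(rng, n=40)
        X = np.column_stack([conc, ts])
        est = SolidOrganDoseRegressor().fit(X, dose)
        np.testing.assert_allclose(est.predict(X), dose, rtol=1e-9)

    def test_coefficient_roundtrip_preserves_predictions(self, rng):
        conc, ts, dose = exact_solid_rows(rng, n=40)
        X = np.column_stack([conc, ts])
        est = SolidOrganDoseRegressor().fit(X, dose)
        back = SolidOrganDoseRegressor.from_coefficients(
            est.to_coefficients("kidneys", "t1t2t3"))
        np.testing.assert_array_equal(est.predict(X), back.predict(X))
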