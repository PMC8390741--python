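"""Single-time-point dose models: log-log regression on one SPECT study.

For a region whose kinetics are mono-exponential, the self-dose can be
written ``D = conc(ts)·e^{λ·ts}·K/λ`` for a region-specific constant K, so

    ln D = a0 + a1·ln conc(ts) + a2·ts

holds exactly with ``a1 = 1`` and ``a2 = λ``.  Training this linear model in
log space on standard multi-time-point doses absorbs population kinetics and
calibration into (a0, a1, a2) and lets a single SPECT/CT study stand in for
the full protocol.  The marrow variant first estimates the two couplings
Θ_BM,BM and Θ_BM,RM by non-negative regression through the origin of the
standard marrow dose on its blood and remainder time-integrated terms, then
regresses ln(dose) on the log of the composite instantaneous term
``a_blood·Θ_BM,BM + c_RM·Θ_BM,RM`` and time.

Estimators follow the scikit-learn contract (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) and compose with
sklearn pipelines; the module-level ``train_*`` / ``predict_*`` functions
are thin wrappers over them.

Unit contract: concentrations in mCi/cc, time in hours, dose in mGy.
Inputs in MBq/cc are converted (÷37) exactly once, at this boundary.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datamodel import MLRCoefficients
from .errors import DataValidationError, SingularDesignError, UnitContractError
from .units import MBQ_PER_MCI

logger = logging.getLogger(__name__)

_RCOND = 1e-12


def _as_2d(X, n_cols: int, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != n_cols:
        raise DataValidationError(
            f"{name}: expected a 2-d array with {n_cols} columns, got shape "
            f"{X.shape}")
    if not np.all(np.isfinite(X)):
        raise DataValidationError(f"{name}: inputs must be finite")
    return X


def _log_ols(design: np.ndarray, ln_y: np.ndarray) -> tuple[np.ndarray, float]:
    """Plain OLS of ln_y on the design; returns (coefficients, r² in log space)."""
    if np.linalg.matrix_rank(design, tol=_RCOND * np.abs(design).max()) < design.shape[1]:
        raise SingularDesignError(
            "design matrix is rank-deficient (constant regressor or collinear "
            "columns); cannot identify all coefficients")
    coef, _, _, _ = np.linalg.lstsq(design, ln_y, rcond=None)
    resid = ln_y - design @ coef
    ss_res = float(resid @ resid)
    centered = ln_y - ln_y.mean()
    ss_tot = float(centered @ centered)
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return coef, r2


def _convert_conc(conc: np.ndarray, units: str) -> np.ndarray:
    if units == "mCi/cc":
        return conc
    if units == "MBq/cc":
        return conc / MBQ_PER_MCI
    raise UnitContractError(
        f"unsupported concentration units {units!r}; use 'mCi/cc' or 'MBq/cc'")


class SolidOrganDoseRegressor(RegressorMixin, BaseEstimator):
    """Log-log dose model for a solid organ or tumor target.

    ``fit(X, y)`` takes ``X`` with columns ``[concentration, time_h]`` and
    ``y`` the standard-protocol absorbed dose in mGy; the regression is OLS
    of ``ln y`` on ``(1, ln conc, t)``.  ``predict(X)`` returns doses in mGy.

    Parameters
    ----------
    conc_units : {'mCi/cc', 'MBq/cc'}
        Units of the concentration column.  MBq/cc inputs are divided by 37
        before entering the model, whose coefficients are defined on mCi/cc.

    Attributes
    ----------
    alpha0_, alpha1_, alpha2_ : float
        Intercept, log-concentration slope and time slope.  For a cohort
        with a common effective decay constant λ the model is exact with
        ``alpha1_ = 1`` and ``alpha2_ = λ``.
    r2_ : float
        Coefficient of determination of the fit in log space.
    n_train_ : int
        Number of training rows used.
    """

    _MIN_ROWS = 4

    def __init__(self, conc_units: str = "mCi/cc"):
        self.conc_units = conc_units

    def fit(self, X, y):
        X = _as_2d(X, 2, "X")
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],):
            raise DataValidationError("y must be 1-d with one dose per row of X")
        keep = (X[:, 0] > 0) & (y > 0)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning("excluding %d row(s) with zero/negative activity or "
                           "dose from training (not log-transformable)", n_dropped)
            X, y = X[keep], y[keep]
        if X.shape[0] < self._MIN_ROWS:
            raise DataValidationError(
                f"need >= {self._MIN_ROWS} usable training rows, got {X.shape[0]}")
        conc = _convert_conc(X[:, 0], self.conc_units)
        design = np.column_stack([np.ones(len(conc)), np.log(conc), X[:, 1]])
        coef, r2 = _log_ols(design, np.log(y))
        self.alpha0_, self.alpha1_, self.alpha2_ = map(float, coef)
        self.r2_ = float(r2)
        self.n_train_ = int(X.shape[0])
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "alpha0_")
        X = _as_2d(X, 2, "X")
        if np.any(X[:, 0] <= 0):
            raise DataValidationError(
                "concentration must be > 0 for prediction (log of non-positive)")
        conc = _convert_conc(X[:, 0], self.conc_units)
        return np.exp(self.alpha0_ + self.alpha1_ * np.log(conc)
                      + self.alpha2_ * X[:, 1])

    # -- coefficient-object interop ---------------------------------------
    def to_coefficients(self, target: str, t_f_label: str) -> MLRCoefficients:
        check_is_fitted(self, "alpha0_")
        return MLRCoefficients(target=target, t_f_label=t_f_label, kind="solid",
                               intercept=self.alpha0_, slope_conc=self.alpha1_,
                               slope_time=self.alpha2_, r2_train=self.r2_,
                               n_train=self.n_train_)

    @classmethod
    def from_coefficients(cls, coef: MLRCoefficients,
                          conc_units: str = "mCi/cc") -> "SolidOrganDoseRegressor":
        if coef.kind != "solid":
            raise UnitContractError(
                f"coefficients for {coef.target!r} are {coef.kind}, not solid")
        est = cls(conc_units=conc_units)
        est.alpha0_, est.alpha1_, est.alpha2_ = (coef.intercept, coef.slope_conc,
                                                 coef.slope_time)
        est.r2_ = coef.r2_train if coef.r2_train is not None else float("nan")
        est.n_train_ = coef.n_train if coef.n_train is not None else 0
        est.n_features_in_ = 2
        return est


class BoneMarrowDoseRegressor(RegressorMixin, BaseEstimator):
    """Log-log marrow dose model over the composite blood+remainder term.

    ``X`` columns are ``[blood_concentration, remainder_concentration,
    time_h]``; the composite regressor is ``blood·Θ_BM,BM + rm·Θ_BM,RM``.
    The couplings must be supplied (estimate them with
    :func:`estimate_theta_bm`); the same pair is used at prediction time.

    Attributes
    ----------
    beta0_, beta1_, beta2_ : float
        Intercept, log-composite slope and time slope; for a common marrow
        decay constant λ_BM the model is exact with ``beta1_ = 1``,
        ``beta2_ = λ_BM`` and ``beta0_ = -ln λ_BM``.
    r2_, n_train_ : see SolidOrganDoseRegressor.
    """

    _MIN_ROWS = 4

    def __init__(self, theta_bm_bm: float | None = None,
                 theta_bm_rm: float | None = None,
                 conc_units: str = "mCi/cc"):
        self.theta_bm_bm = theta_bm_bm
        self.theta_bm_rm = theta_bm_rm
        self.conc_units = conc_units

    def _composite(self, X: np.ndarray) -> np.ndarray:
        if self.theta_bm_bm is None or self.theta_bm_rm is None:
            raise DataValidationError(
                "theta_bm_bm/theta_bm_rm must be set (see estimate_theta_bm)")
        blood = _convert_conc(X[:, 0], self.conc_units)
        rm = _convert_conc(X[:, 1], self.conc_units)
        return blood * self.theta_bm_bm + rm * self.theta_bm_rm

    def fit(self, X, y):
        X = _as_2d(X, 3, "X")
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],):
            raise DataValidationError("y must be 1-d with one dose per row of X")
        comp = self._composite(X)
        keep = (comp > 0) & (y > 0)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning("excluding %d marrow row(s) with non-positive "
                           "composite term or dose from training", n_dropped)
            X, y, comp = X[keep], y[keep], comp[keep]
        if X.shape[0] < self._MIN_ROWS:
            raise DataValidationError(
                f"need >= {self._MIN_ROWS} usable training rows, got {X.shape[0]}")
        design = np.column_stack([np.ones(len(comp)), np.log(comp), X[:, 2]])
        coef, r2 = _log_ols(design, np.log(y))
        self.beta0_, self.beta1_, self.beta2_ = map(float, coef)
        self.r2_ = float(r2)
        self.n_train_ = int(X.shape[0])
        self.n_features_in_ = 3
        return self

    def predict(self, X):
        check_is_fitted(self, "beta0_")
        X = _as_2d(X, 3, "X")
        comp = self._composite(X)
        if np.any(comp <= 0):
            raise DataValidationError(
                "composite marrow term must be > 0 for prediction")
        return np.exp(self.beta0_ + self.beta1_ * np.log(comp)
                      + self.beta2_ * X[:, 2])

    def to_coefficients(self, t_f_label: str,
                        target: str = "bone_marrow") -> MLRCoefficients:
        check_is_fitted(self, "beta0_")
        return MLRCoefficients(target=target, t_f_label=t_f_label, kind="marrow",
                               intercept=self.beta0_, slope_conc=self.beta1_,
                               slope_time=self.beta2_,
                               theta_bm_bm=float(self.theta_bm_bm),
                               theta_bm_rm=float(self.theta_bm_rm),
                               r2_train=self.r2_, n_train=self.n_train_)

    @classmethod
    def from_coefficients(cls, coef: MLRCoefficients,
                          conc_units: str = "mCi/cc") -> "BoneMarrowDoseRegressor":
        if coef.kind != "marrow":
            raise UnitContractError(
                f"coefficients for {coef.target!r} are {coef.kind}, not marrow")
        est = cls(theta_bm_bm=coef.theta_bm_bm, theta_bm_rm=coef.theta_bm_rm,
                  conc_units=conc_units)
        est.beta0_, est.beta1_, est.beta2_ = (coef.intercept, coef.slope_conc,
                                              coef.slope_time)
        est.r2_ = coef.r2_train if coef.r2_train is not None else float("nan")
        est.n_train_ = coef.n_train if coef.n_train is not None else 0
        est.n_features_in_ = 3
        return est


def estimate_theta_bm(blood_terms, remainder_terms, doses_mGy
                      ) -> tuple[float, float]:
    """Couplings (Θ_BM,BM, Θ_BM,RM) by NNLS through the origin.

    Regresses the standard-protocol marrow dose on its two time-integrated
    terms (mCi·h/cc) with non-negative coefficients and no intercept; the
    non-negativity encodes that both source terms can only deposit dose.

    Raises
    ------
    SingularDesignError
        If the two term columns do not span two dimensions (e.g. all
        remainder terms zero, or fewer than two records).
    """
    bt = np.asarray(blood_terms, dtype=float)
    rt = np.asarray(remainder_terms, dtype=float)
    y = np.asarray(doses_mGy, dtype=float)
    if bt.shape != rt.shape or bt.shape != y.shape or bt.ndim != 1:
        raise DataValidationError("terms and doses must be equal-length 1-d arrays")
    if bt.size < 2:
        raise SingularDesignError("need >= 2 records to identify two couplings")
    A = np.column_stack([bt, rt])
    if np.linalg.matrix_rank(A, tol=_RCOND * max(np.abs(A).max(), 1.0)) < 2:
        raise SingularDesignError(
            "blood/remainder term columns are collinear or degenerate; the two "
            "couplings are not separately identifiable")
    theta, _ = nnls(A, y)
    return float(theta[0]), float(theta[1])


# ---------------------------------------------------------------------------
# Thin functional wrappers

def train_mlr_solid(conc_mCi_per_cc, ts_h, dose_mGy, target: str,
                    t_f_label: str) -> MLRCoefficients:
    """Train the solid-organ/tumor model on pooled rows for one t_f tag."""
    X = np.column_stack([np.asarray(conc_mCi_per_cc, float),
                         np.asarray(ts_h, float)])
    est = SolidOrganDoseRegressor().fit(X, np.asarray(dose_mGy, float))
    return est.to_coefficients(target, t_f_label)


def train_mlr_bm(blood_conc_mCi_per_cc, rm_conc_mCi_per_cc, ts_h, dose_mGy,
                 theta_bm_bm: float, theta_bm_rm: float,
                 t_f_label: str) -> MLRCoefficients:
    """Train the marrow model with previously estimated couplings."""
    X = np.column_stack([np.asarray(blood_conc_mCi_per_cc, float),
                         np.asarray(rm_conc_mCi_per_cc, float),
                         np.asarray(ts_h, float)])
    est = BoneMarrowDoseRegressor(theta_bm_bm=theta_bm_bm,
                                  theta_bm_rm=theta_bm_rm)
    est.fit(X, np.asarray(dose_mGy, float))
    return est.to_coefficients(t_f_label)


def predict_dose_solid(coef: MLRCoefficients, conc_mCi_per_cc, ts_h):
    """Dose (mGy) from one study: ``conc^α₁ · exp(α₂·ts + α₀)``."""
    est = SolidOrganDoseRegressor.from_coefficients(coef)
    conc, ts = np.broadcast_arrays(np.asarray(conc_mCi_per_cc, float),
                                   np.asarray(ts_h, float))
    scalar = conc.ndim == 0
    out = est.predict(np.column_stack([np.atleast_1d(conc), np.atleast_1d(ts)]))
    return float(out[0]) if scalar else out


def predict_dose_bm(coef: MLRCoefficients, blood_conc_mCi_per_cc,
                    rm_conc_mCi_per_cc, ts_h):
    """Marrow dose (mGy) from one study via the composite term."""
    est = BoneMarrowDoseRegressor.from_coefficients(coef)
    blood, rm, ts = np.broadcast_arrays(
        np.asarray(blood_conc_mCi_per_cc, float),
        np.asarray(rm_conc_mCi_per_cc, float), np.asarray(ts_h, float))
    scalar = blood.ndim == 0
    out = est.predict(np.column_stack([np.atleast_1d(blood),
                                       np.atleast_1d(rm), np.atleast_1d(ts)]))
    return float(out[0]) if scalar else out
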