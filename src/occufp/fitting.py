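"""Maximum-likelihood fitting of single-season occupancy models.

:class:`OccupancyModel` is a scikit-learn style estimator: construct it with
formula strings for the occupancy (``psi``) and detection (``p``) linear
predictors, call ``fit(covariates, detections)``, then read fitted
attributes (``coef_psi_``, ``coef_p_``, ``p10_``, ``aic_``, ``se_``, …) or
predict probabilities on new covariate tables (a prediction grid) with
``predict_psi`` / ``predict_p``.  Covariates are standardized internally on
the training table and the same centering/scaling record is reused for
prediction, so callers always pass raw covariate values.

Optimization minimizes the negative marginal log-likelihood with L-BFGS-B
using the analytic gradient, from a structured start (zero coefficients,
detection intercept +1, ``logit p10 = -3`` for misclassification models)
plus seeded random restarts; the best interior optimum is kept and
convergence is reported honestly rather than raised.  The misclassification
model has a label-switching mode (``p11`` and ``p10`` exchanging roles);
when the fitted site-mean ``p11`` falls below ``p10`` the model is refitted
from a swapped start and the higher-likelihood interior solution retained,
with a warning either way.  Standard errors come from the inverse of a
central-finite-difference Hessian of the objective at the MLE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit as _slogit
from sklearn.base import BaseEstimator

from .design import ModelFormula, Standardizer, build_design_matrix
from .likelihood import (
    LikelihoodProblem,
    ParameterVector,
    negative_loglik,
    negative_loglik_grad,
    site_logliks,
)

__all__ = ["ModelSpec", "OccupancyModel", "fit_spec", "aic"]


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: ψ formula, p formula, misclassification flag."""

    psi_formula: str
    p_formula: str
    misclassification: bool = False

    @property
    def label(self) -> str:
        tag = ", p10" if self.misclassification else ""
        return f"psi({self.psi_formula}), p({self.p_formula}){tag}"

    @property
    def model_class(self) -> str:
        return "MM" if self.misclassification else "OM"


def aic(loglik: float, n_params: int) -> float:
    """Akaike's information criterion, ``2k − 2·logL``."""
    return 2.0 * n_params - 2.0 * loglik


class OccupancyModel(BaseEstimator):
    """Single-season occupancy model with optional false-positive errors.

    Parameters
    ----------
    psi_formula, p_formula : str
        Linear-predictor formulas over site covariates, e.g.
        ``"pop * elev + for"``; ``"1"`` for intercept-only.
    false_positives : bool
        If True, estimate a constant false-positive probability ``p10``
        alongside the detection model (misclassification model).
    n_restarts : int
        Total optimizer starts: one structured start plus seeded random
        restarts drawn around zero coefficients.
    tol : float
        Convergence tolerance on the objective.
    hessian_step : float
        Central-difference step for the numeric Hessian.
    random_state : int
        Seed for restart draws.
    """

    def __init__(
        self,
        psi_formula: str = "1",
        p_formula: str = "1",
        false_positives: bool = False,
        n_restarts: int = 5,
        tol: float = 1e-8,
        max_iter: int = 500,
        hessian_step: float = 1e-5,
        restart_scale: float = 1.0,
        random_state: int = 0,
    ):
        self.psi_formula = psi_formula
        self.p_formula = p_formula
        self.false_positives = false_positives
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.hessian_step = hessian_step
        self.restart_scale = restart_scale
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "OccupancyModel":
        """Fit by maximum likelihood.

        Parameters
        ----------
        X : DataFrame
            Site covariate table (raw scale), one row per site.
        y : array-like (M, J)
            Detection histories; entries 0/1, NaN for missing replicates.
        """
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[0] != len(X):
            raise ValueError("detections must be (n_sites, n_replicates) matching X")

        psi_f = ModelFormula.parse(self.psi_formula)
        p_f = ModelFormula.parse(self.p_formula)
        used = tuple(dict.fromkeys(psi_f.covariates + p_f.covariates))
        self.standardizer_ = Standardizer().fit(X[list(used)]) if used else None
        Xs = self.standardizer_.transform(X) if used else X
        psi_design = build_design_matrix(psi_f, Xs)
        p_design = build_design_matrix(p_f, Xs)
        problem = LikelihoodProblem(y, psi_design, p_design, self.false_positives)

        self._psi_formula_ = psi_f
        self._p_formula_ = p_f
        self.psi_labels_ = psi_design.column_labels
        self.p_labels_ = p_design.column_labels
        self.warnings_: list[str] = []

        nb, na = len(self.psi_labels_), len(self.p_labels_)
        result = self._optimize(problem, nb, na)
        theta, nll, success, n_used = result

        params = ParameterVector.unflatten(theta, nb, na, self.false_positives)
        if self.false_positives:
            params, nll, success = self._swap_correct(
                problem, params, nll, success, nb, na
            )
            theta = params.flatten()

        self.problem_ = problem
        self.params_ = params
        self.coef_psi_ = pd.Series(params.beta, index=list(self.psi_labels_))
        self.coef_p_ = pd.Series(params.alpha, index=list(self.p_labels_))
        self.p10_ = params.p10
        self.loglik_ = -nll
        self.n_params_ = params.n_params
        self.aic_ = aic(self.loglik_, self.n_params_)
        self.converged_ = bool(success and np.isfinite(nll))
        self.n_restarts_used_ = n_used
        self.vcov_, self.se_ = self._covariance(problem, theta, nb, na)
        return self

    # -------------------------------------------------------- optimization
    def _objective(self, problem, nb, na):
        def f(theta):
            p = ParameterVector.unflatten(theta, nb, na, self.false_positives)
            return negative_loglik(problem, p)

        def g(theta):
            p = ParameterVector.unflatten(theta, nb, na, self.false_positives)
            return negative_loglik_grad(problem, p)

        return f, g

    def _starts(self, nb, na):
        k = nb + na + (1 if self.false_positives else 0)
        base = np.zeros(k)
        base[nb] = 1.0  # detection intercept at +1: detection usually > 0.5
        if self.false_positives:
            base[-1] = -3.0  # p10 ≈ 0.047, small as misidentification rates are
        starts = [base]
        rng = np.random.default_rng(self.random_state)
        for _ in range(max(0, self.n_restarts - 1)):
            jitter = rng.normal(scale=self.restart_scale, size=k)
            s = base + jitter
            if self.false_positives:
                s[-1] = -3.0 + 0.5 * jitter[-1]  # keep p10 starts small
            starts.append(s)
        return starts

    def _minimize_from(self, f, g, start):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return minimize(
                f,
                start,
                jac=g,
                method="L-BFGS-B",
                options={"ftol": self.tol, "gtol": 1e-7, "maxiter": self.max_iter},
            )

    def _optimize(self, problem, nb, na):
        f, g = self._objective(problem, nb, na)
        best = None
        n_used = 0
        for start in self._starts(nb, na):
            n_used += 1
            try:
                res = self._minimize_from(f, g, start)
            except (ValueError, FloatingPointError):
                continue
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None:
            self.warnings_.append("all optimizer restarts failed")
            k = nb + na + (1 if self.false_positives else 0)
            return np.zeros(k), np.inf, False, n_used
        return np.asarray(best.x), float(best.fun), bool(best.success), n_used

    def _swap_correct(self, problem, params, nll, success, nb, na):
        """Resolve p11/p10 label switching toward the p11 > p10 branch."""
        p11_mean = float(np.mean(expit(self._p_eta(problem, params))))
        if p11_mean >= params.p10:
            return params, nll, success
        self.warnings_.append(
            f"label swap detected (mean p11 {p11_mean:.3f} < p10 {params.p10:.3f}); "
            "refitting from swapped start"
        )
        f, g = self._objective(problem, nb, na)
        swapped = params.flatten().copy()
        swapped[nb] = float(params.logit_p10)  # p intercept takes p10's logit
        swapped[nb + 1 : nb + na] = 0.0
        swapped[-1] = float(_slogit(np.clip(p11_mean, 1e-6, 1 - 1e-6)))
        try:
            res = self._minimize_from(f, g, swapped)
        except (ValueError, FloatingPointError):
            return params, nll, success
        if np.isfinite(res.fun):
            cand = ParameterVector.unflatten(res.x, nb, na, True)
            cand_p11 = float(np.mean(expit(self._p_eta(problem, cand))))
            if res.fun <= nll + 1e-8 and cand_p11 >= cand.p10:
                return cand, float(res.fun), bool(res.success)
        return params, nll, success

    @staticmethod
    def _p_eta(problem, params):
        pv = problem._p_values()
        if pv.ndim == 2:
            return pv @ params.alpha
        return (pv @ params.alpha).ravel()

    # ---------------------------------------------------------- covariance
    def _covariance(self, problem, theta, nb, na):
        k = len(theta)
        nan = np.full(k, np.nan)
        if not self.converged_:
            return np.full((k, k), np.nan), pd.Series(nan, index=self._param_labels())
        _, g = self._objective(problem, nb, na)
        h = self.hessian_step
        H = np.empty((k, k))
        try:
            for j in range(k):
                e = np.zeros(k)
                e[j] = h
                H[:, j] = (g(theta + e) - g(theta - e)) / (2.0 * h)
        except (ValueError, FloatingPointError):
            self.warnings_.append("Hessian evaluation failed; SEs undefined")
            return np.full((k, k), np.nan), pd.Series(nan, index=self._param_labels())
        H = 0.5 * (H + H.T)
        try:
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            self.warnings_.append(
                "Hessian not invertible (boundary or identifiability issue); "
                "SEs undefined"
            )
            return np.full((k, k), np.nan), pd.Series(nan, index=self._param_labels())
        diag = np.diag(vcov)
        if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
            self.warnings_.append(
                "non-positive Hessian curvature (parameter at boundary?); "
                "affected SEs undefined"
            )
        se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
        se[~np.isfinite(diag)] = np.nan
        return vcov, pd.Series(se, index=self._param_labels())

    def _param_labels(self) -> list[str]:
        labels = [f"psi:{c}" for c in self.psi_labels_]
        labels += [f"p:{c}" for c in self.p_labels_]
        if self.false_positives:
            labels.append("logit_p10")
        return labels

    # ---------------------------------------------------------- prediction
    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")

    def _design_for(self, formula: ModelFormula, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        needed = formula.covariates
        missing = [c for c in needed if c not in X.columns]
        if missing:
            raise KeyError(f"prediction table lacks covariate(s): {', '.join(missing)}")
        Xs = self.standardizer_.transform(X) if self.standardizer_ is not None else X
        return build_design_matrix(formula, Xs).values

    def predict_psi(self, X: pd.DataFrame) -> np.ndarray:
        """Occupancy probability ψ for each row of a raw covariate table."""
        self._check_fitted()
        D = self._design_for(self._psi_formula_, X)
        return expit(D @ self.params_.beta)

    def predict_p(self, X: pd.DataFrame) -> np.ndarray:
        """Detection probability p11 (detection given presence) per row."""
        self._check_fitted()
        D = self._design_for(self._p_formula_, X)
        return expit(D @ self.params_.alpha)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Alias for :meth:`predict_psi` (the primary surface)."""
        return self.predict_psi(X)

    def score(self, X=None, y=None) -> float:
        """Maximized log-likelihood of the fitted model."""
        self._check_fitted()
        return self.loglik_

    def site_logliks(self) -> np.ndarray:
        self._check_fitted()
        return site_logliks(self.problem_, self.params_)

    # ----------------------------------------------------------- reporting
    @property
    def spec_(self) -> ModelSpec:
        return ModelSpec(self.psi_formula, self.p_formula, self.false_positives)

    def summary_frame(self) -> pd.DataFrame:
        """Coefficients with standard errors, one row per parameter."""
        self._check_fitted()
        est = np.concatenate(
            [
                self.params_.beta,
                self.params_.alpha,
                [] if self.params_.logit_p10 is None else [self.params_.logit_p10],
            ]
        )
        return pd.DataFrame(
            {"estimate": est, "se": self.se_.to_numpy()}, index=self._param_labels()
        )


def fit_spec(
    spec: ModelSpec,
    covariates: pd.DataFrame,
    detections: np.ndarray,
    **fit_options,
) -> OccupancyModel:
    """Thin wrapper: fit one :class:`ModelSpec` and return the fitted model."""
    model = OccupancyModel(
        psi_formula=spec.psi_formula,
        p_formula=spec.p_formula,
        false_positives=spec.misclassification,
        **fit_options,
    )
    return model.fit(covariates, detections)
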