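"""Marginal log-likelihoods for single-season occupancy models.

Two model classes share one likelihood skeleton.  For site *i* with latent
occupancy state ``z_i ~ Bernoulli(psi_i)`` and detection history
``y_i1 … y_iJ`` (missing replicates skipped), the site-marginal likelihood is

* conventional model (false negatives only)::

      L_i = psi_i * prod_j p_ij^y (1 - p_ij)^(1-y)  +  (1 - psi_i) * 1{all y = 0}

* misclassification model (false negatives and false positives)::

      L_i = psi_i * prod_j p_ij^y (1 - p_ij)^(1-y)
          + (1 - psi_i) * prod_j p10^y (1 - p10)^(1-y)

with ``psi_i`` and ``p_ij`` logit-linear in covariates and ``p10`` a single
scalar false-positive probability (intercept-only, matching one reported
value per species).  Everything is accumulated in the log domain with a
log-sum-exp over the two mixture terms, since optimizers routinely visit
parameter values with probabilities numerically at 0 or 1.

``brute_force_site_loglik`` re-derives the same quantity by explicit
enumeration of the latent state, ``log sum_z P(z) prod_j P(y_ij | z)``,
sharing no code with the fast path; it exists purely as an oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, xlog1py, xlogy

from .design import DesignMatrix

__all__ = [
    "ParameterVector",
    "LikelihoodProblem",
    "site_loglik",
    "site_logliks",
    "negative_loglik",
    "negative_loglik_grad",
    "brute_force_site_loglik",
]


@dataclass
class ParameterVector:
    """Coefficients for one model: occupancy, detection, optional logit p10."""

    beta: np.ndarray
    alpha: np.ndarray
    logit_p10: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))

    @property
    def p10(self) -> float | None:
        if self.logit_p10 is None:
            return None
        return float(expit(self.logit_p10))

    @property
    def n_params(self) -> int:
        return len(self.beta) + len(self.alpha) + (self.logit_p10 is not None)

    def flatten(self) -> np.ndarray:
        parts = [self.beta, self.alpha]
        if self.logit_p10 is not None:
            parts.append([self.logit_p10])
        return np.concatenate(parts)

    @classmethod
    def unflatten(
        cls, theta: np.ndarray, n_beta: int, n_alpha: int, misclassification: bool
    ) -> "ParameterVector":
        theta = np.asarray(theta, dtype=float)
        beta = theta[:n_beta]
        alpha = theta[n_beta : n_beta + n_alpha]
        lp10 = float(theta[n_beta + n_alpha]) if misclassification else None
        return cls(beta, alpha, lp10)


@dataclass
class LikelihoodProblem:
    """Detection histories plus design matrices for one fitting problem.

    ``p_design.values`` may be 2-D (one row per site; detection probability
    constant across replicates) or 3-D ``(M, J, k)`` when survey-specific
    covariates vary by replicate.
    """

    detections: np.ndarray
    psi_design: DesignMatrix
    p_design: DesignMatrix | np.ndarray
    misclassification: bool = False

    def __post_init__(self) -> None:
        y = np.asarray(self.detections, dtype=float)
        if y.ndim != 2:
            raise ValueError("detections must be a sites x replicates matrix")
        vals = np.unique(y[~np.isnan(y)])
        if not np.all(np.isin(vals, [0.0, 1.0])):
            raise ValueError("detections must contain only 0, 1 or missing")
        self.detections = y
        M = y.shape[0]
        if self.psi_design.values.shape[0] != M:
            raise ValueError("psi design rows do not match detection rows")
        pv = self._p_values()
        if pv.shape[0] != M:
            raise ValueError("p design rows do not match detection rows")
        if pv.ndim == 3 and pv.shape[1] != y.shape[1]:
            raise ValueError("replicate-level p design does not match J")
        if np.any(np.all(np.isnan(y), axis=1)):
            raise ValueError("every site needs at least one non-missing replicate")

    def _p_values(self) -> np.ndarray:
        v = self.p_design.values if isinstance(self.p_design, DesignMatrix) else self.p_design
        return np.asarray(v, dtype=float)

    @property
    def n_sites(self) -> int:
        return self.detections.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.detections.shape[1]

    def _check_params(self, params: ParameterVector) -> None:
        if len(params.beta) != self.psi_design.values.shape[1]:
            raise ValueError("beta length does not match psi design")
        if len(params.alpha) != self._p_values().shape[-1]:
            raise ValueError("alpha length does not match p design")
        if self.misclassification and params.logit_p10 is None:
            raise ValueError("misclassification model requires logit_p10")
        if not self.misclassification and params.logit_p10 is not None:
            raise ValueError("conventional model takes no logit_p10")


def _linear_predictors(
    problem: LikelihoodProblem, params: ParameterVector
) -> tuple[np.ndarray, np.ndarray]:
    """Return (psi linear predictor (M,), p linear predictor (M, J))."""
    eta_psi = problem.psi_design.values @ params.beta
    pv = problem._p_values()
    if pv.ndim == 2:
        eta_p = (pv @ params.alpha)[:, None]
        eta_p = np.broadcast_to(eta_p, problem.detections.shape).copy()
    else:
        eta_p = pv @ params.alpha
    return eta_psi, eta_p


def _log_expit(x: np.ndarray) -> np.ndarray:
    """log(expit(x)) = -softplus(-x), elementwise and overflow-safe."""
    return -np.logaddexp(0.0, -x)


def _pairwise_logsumexp(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.logaddexp(a, b)


def site_logliks(problem: LikelihoodProblem, params: ParameterVector) -> np.ndarray:
    """Vector of site-marginal log-likelihood contributions (length M)."""
    problem._check_params(params)
    y = problem.detections
    mask = ~np.isnan(y)
    y0 = np.where(mask, y, 0.0)

    eta_psi, eta_p = _linear_predictors(problem, params)
    log_psi = _log_expit(eta_psi)
    log_1mpsi = _log_expit(-eta_psi)
    log_p = _log_expit(eta_p)
    log_1mp = _log_expit(-eta_p)

    # log prod_j p^y (1-p)^(1-y) over non-missing replicates
    log_a = np.where(mask, y0 * log_p + (1.0 - y0) * log_1mp, 0.0).sum(axis=1)

    if problem.misclassification:
        p10 = expit(params.logit_p10)
        n_det = np.where(mask, y0, 0.0).sum(axis=1)
        n_nondet = mask.sum(axis=1) - n_det
        log_b = xlogy(n_det, p10) + xlog1py(n_nondet, -p10)
    else:
        any_det = np.any(mask & (y0 > 0), axis=1)
        log_b = np.where(any_det, -np.inf, 0.0)

    return _pairwise_logsumexp(log_psi + log_a, log_1mpsi + log_b)


def site_loglik(
    problem: LikelihoodProblem, params: ParameterVector, site_index: int
) -> float:
    """Site-marginal log-likelihood for one site."""
    if np.all(np.isnan(problem.detections[site_index])):
        raise ValueError(f"site {site_index} has no non-missing replicates")
    return float(site_logliks(problem, params)[site_index])


def negative_loglik(problem: LikelihoodProblem, params: ParameterVector) -> float:
    """Negative log-likelihood summed over sites (the objective minimized)."""
    return float(-site_logliks(problem, params).sum())


def negative_loglik_grad(
    problem: LikelihoodProblem, params: ParameterVector
) -> np.ndarray:
    """Analytic gradient of :func:`negative_loglik` w.r.t. the flat parameter vector.

    With mixture terms ``t1 = log psi + log A`` and ``t2 = log(1-psi) + log B``
    and posterior occupancy weight ``w1 = exp(t1 - ll)``:

    * d ll / d beta_k  = (w1 - psi) x_ik
    * d ll / d alpha_k = w1 * sum_j m_ij (y_ij - p_ij) x_p[..., k]
    * d ll / d logit_p10 = (1 - w1) * sum_j m_ij (y_ij - p10)
    """
    problem._check_params(params)
    y = problem.detections
    mask = ~np.isnan(y)
    y0 = np.where(mask, y, 0.0)

    eta_psi, eta_p = _linear_predictors(problem, params)
    psi = expit(eta_psi)
    p = expit(eta_p)
    log_psi = _log_expit(eta_psi)
    log_1mpsi = _log_expit(-eta_psi)
    log_p = _log_expit(eta_p)
    log_1mp = _log_expit(-eta_p)
    log_a = np.where(mask, y0 * log_p + (1.0 - y0) * log_1mp, 0.0).sum(axis=1)

    if problem.misclassification:
        p10 = float(expit(params.logit_p10))
        n_det = np.where(mask, y0, 0.0).sum(axis=1)
        n_obs = mask.sum(axis=1)
        log_b = xlogy(n_det, p10) + xlog1py(n_obs - n_det, -p10)
    else:
        any_det = np.any(mask & (y0 > 0), axis=1)
        log_b = np.where(any_det, -np.inf, 0.0)

    t1 = log_psi + log_a
    t2 = log_1mpsi + log_b
    ll = np.logaddexp(t1, t2)
    w1 = np.exp(t1 - ll)  # posterior P(z=1 | y); in [0,1] even at extremes

    X_psi = problem.psi_design.values
    g_beta = -((w1 - psi) @ X_psi)

    resid = np.where(mask, y0 - p, 0.0)  # (M, J)
    pv = problem._p_values()
    if pv.ndim == 2:
        g_alpha = -((w1 * resid.sum(axis=1)) @ pv)
    else:
        g_alpha = -np.einsum("i,ij,ijk->k", w1, resid, pv)

    grads = [g_beta, g_alpha]
    if problem.misclassification:
        resid10 = np.where(mask, y0 - p10, 0.0).sum(axis=1)
        grads.append(np.atleast_1d(-np.sum((1.0 - w1) * resid10)))
    return np.concatenate(grads)


def brute_force_site_loglik(
    problem: LikelihoodProblem, params: ParameterVector, site_index: int
) -> float:
    """Oracle: enumerate the latent state explicitly, one replicate at a time.

    Deliberately scalar, product-form arithmetic (no log-domain tricks, no
    shared helpers with :func:`site_loglik`) so the two paths are independent.
    """
    problem._check_params(params)
    y = problem.detections[site_index]
    x_psi = problem.psi_design.values[site_index]
    pv = problem._p_values()
    psi = 1.0 / (1.0 + np.exp(-float(np.dot(x_psi, params.beta))))

    total = 0.0
    for z in (0, 1):
        prior = psi if z == 1 else 1.0 - psi
        prob = 1.0
        for j, yj in enumerate(y):
            if np.isnan(yj):
                continue  # missing replicate: contributes factor 1
            if z == 1:
                row = pv[site_index] if pv.ndim == 2 else pv[site_index, j]
                p_det = 1.0 / (1.0 + np.exp(-float(np.dot(row, params.alpha))))
            elif problem.misclassification:
                p_det = 1.0 / (1.0 + np.exp(-params.logit_p10))
            else:
                p_det = 0.0
            prob *= p_det if yj == 1 else 1.0 - p_det
        total += prior * prob
    if total <= 0.0:
        return -np.inf
    return float(np.log(total))
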