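"""Exact inference for the conditionally linear model.

Conditioned on the covariate sequence, the model is a time-varying
linear-Gaussian state-space model, so filtering, smoothing and the marginal
log-likelihood are exact.  Covariance updates use the Joseph form with
symmetrization each step for numerical robustness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .model import CLDSModel, Trial

__all__ = ["FilterResult", "SmoothedPosterior", "kalman_filter",
           "kalman_smoother", "posterior_mode", "NumericalFailure"]


class NumericalFailure(RuntimeError):
    """Raised when an intermediate covariance loses positive definiteness."""


@dataclass
class FilterResult:
    means: np.ndarray        # (T, D) filtered means E[x_t | y_1:t]
    covs: np.ndarray         # (T, D, D)
    pred_means: np.ndarray   # (T, D) one-step predictive means E[x_t | y_1:t-1]
    pred_covs: np.ndarray    # (T, D, D)
    loglik: float


@dataclass
class SmoothedPosterior:
    """Smoothing posterior p(x_{1:T} | y_{1:T}, F, u_{1:T}).

    ``cross[t]`` stores the posterior adjacent second moment
    E[x_{t+1} x_t^T | y_{1:T}], the statistic consumed by the dynamics M-step.
    """

    means: np.ndarray        # (T, D)
    covs: np.ndarray         # (T, D, D)
    cross: np.ndarray        # (T-1, D, D): E[x_{t+1} x_t^T]
    loglik: float

    @property
    def T(self) -> int:
        return self.means.shape[0]


def _symmetrize(M):
    return 0.5 * (M + M.T)


def kalman_filter(model: CLDSModel, trial: Trial) -> FilterResult:
    """Forward pass with per-step parameters F(u_t); accumulates the marginal
    log-likelihood from the innovation densities."""
    params = model.params_along(trial.u)
    T, D, N = trial.T, model.D, trial.N
    I = np.eye(D)
    means = np.empty((T, D))
    covs = np.empty((T, D, D))
    pred_means = np.empty((T, D))
    pred_covs = np.empty((T, D, D))
    loglik = 0.0

    mu_pred = params[0].m.copy()
    P_pred = model.Q1.copy()
    for t in range(T):
        p = params[t]
        pred_means[t] = mu_pred
        pred_covs[t] = P_pred
        # observation update
        innov = trial.y[t] - (p.C @ mu_pred + p.d)
        S = _symmetrize(p.C @ P_pred @ p.C.T + model.R)
        try:
            cf = cho_factor(S, lower=True)
        except np.linalg.LinAlgError as exc:
            raise NumericalFailure(f"innovation covariance not PD at t={t}") from exc
        K = cho_solve(cf, p.C @ P_pred).T      # (D, N)
        mu = mu_pred + K @ innov
        IKC = I - K @ p.C
        P = _symmetrize(IKC @ P_pred @ IKC.T + K @ model.R @ K.T)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        loglik += -0.5 * (innov @ cho_solve(cf, innov) + logdet + N * np.log(2 * np.pi))
        means[t] = mu
        covs[t] = P
        # time update
        if t + 1 < T:
            mu_pred = p.A @ mu + p.b
            P_pred = _symmetrize(p.A @ P @ p.A.T + model.Q)
    if not np.isfinite(loglik):
        raise NumericalFailure("non-finite log-likelihood")
    return FilterResult(means, covs, pred_means, pred_covs, float(loglik))


def kalman_smoother(model: CLDSModel, trial: Trial) -> SmoothedPosterior:
    """Rauch–Tung–Striebel backward pass on top of the filter.

    Returns smoothed marginals, adjacent second moments E[x_{t+1} x_t^T],
    and the (filter) marginal log-likelihood.
    """
    fr = kalman_filter(model, trial)
    params = model.params_along(trial.u)
    T, D = trial.T, model.D
    means = np.empty((T, D))
    covs = np.empty((T, D, D))
    cross = np.empty((max(T - 1, 0), D, D))
    means[-1] = fr.means[-1]
    covs[-1] = fr.covs[-1]
    for t in range(T - 2, -1, -1):
        A = params[t].A
        P_f = fr.covs[t]
        P_pred = fr.pred_covs[t + 1]
        J = np.linalg.solve(P_pred.T, (P_f @ A.T).T).T   # P_f A^T P_pred^{-1}
        means[t] = fr.means[t] + J @ (means[t + 1] - fr.pred_means[t + 1])
        covs[t] = _symmetrize(P_f + J @ (covs[t + 1] - P_pred) @ J.T)
        # Cov(x_{t+1}, x_t | y) = P^s_{t+1} J_t^T ; add mean outer product
        cross[t] = covs[t + 1] @ J.T + np.outer(means[t + 1], means[t])
    return SmoothedPosterior(means=means, covs=covs, cross=cross,
                             loglik=fr.loglik)


def posterior_mode(model: CLDSModel, trial: Trial) -> np.ndarray:
    """MAP latent trajectory: for the Gaussian model the posterior mode
    coincides with the smoothed means."""
    return kalman_smoother(model, trial).means
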