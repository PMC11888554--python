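"""E- and M-steps for MAP learning of a CLDS.

The E-step runs the Kalman smoother per trial and accumulates posterior
moments in the expanded feature space; every M-step for the parameter
functions is a single conditionally-linear-regression (Sylvester) solve.
A(.) and b(.) are updated jointly by augmenting the latent state with a
constant 1 before feature expansion, and likewise C(.) and d(.) when the
output baseline is learned.  Noise covariances {Q1, Q, R} are updated from
expected residual outer products under the freshly updated functions
(conditional maximizations, so the penalized objective stays monotone).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import FunctionWeights
from .kalman import kalman_smoother
from .model import CLDSModel, TrialSet
from .regression import RegressionProblem, solve_map_weights

__all__ = ["SufficientStats", "FitTrace", "e_step", "m_step_dynamics",
           "m_step_emissions", "m_step_initial", "update_covariances",
           "penalized_objective"]


@dataclass
class SufficientStats:
    """Accumulated E-step moments.

    The dynamics block regresses x_{t+1} on z~_t = phi(u_t) x [x_t; 1]; the
    emissions block regresses y_t on phi(u_t) x [x_t; 1] (or phi x x_t when
    the baseline d is frozen).  Per-trial smoothed posteriors and basis rows
    are kept for the covariance updates.
    """

    dyn_gram: np.ndarray
    dyn_cross: np.ndarray
    em_gram: np.ndarray | None
    em_cross: np.ndarray | None
    init_gram: np.ndarray
    init_cross: np.ndarray
    n_transitions: int
    n_observations: int
    posteriors: list = field(default_factory=list)
    phis: list = field(default_factory=list)
    total_loglik: float = 0.0


@dataclass
class FitTrace:
    """Per-iteration penalized marginal log-likelihood and parameter drift."""

    objectives: list = field(default_factory=list)
    param_deltas: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def _learning_emissions(model: CLDSModel):
    learn_C = "C" not in model.fixed
    learn_d = "d" not in model.fixed
    return learn_C, learn_d


def e_step(model: CLDSModel, trialset: TrialSet) -> SufficientStats:
    """Kalman-smooth every trial and accumulate expected regression moments."""
    L = model.basis.L
    D = model.D
    N = model.N
    learn_C, learn_d = _learning_emissions(model)
    De = D + 1 if learn_d else D  # emission regressor dimension per basis fn

    dyn_gram = np.zeros(((D + 1) * L, (D + 1) * L))
    dyn_cross = np.zeros(((D + 1) * L, D))
    if learn_C:
        em_gram = np.zeros((De * L, De * L))
        em_cross = np.zeros((De * L, N))
    elif learn_d:
        em_gram = np.zeros((L, L))
        em_cross = np.zeros((L, N))
    else:
        em_gram = em_cross = None
    init_gram = np.zeros((L, L))
    init_cross = np.zeros((L, D))
    n_trans = 0
    n_obs = 0
    posteriors = []
    phis = []
    total_loglik = 0.0

    for trial in trialset:
        post = kalman_smoother(model, trial)
        Phi = model.basis.evaluate_many(trial.u)
        T = trial.T
        mu = post.means
        seconds = post.covs + np.einsum("ti,tj->tij", mu, mu)
        Gaug = np.empty((T, D + 1, D + 1))
        Gaug[:, :D, :D] = seconds
        Gaug[:, :D, D] = mu
        Gaug[:, D, :D] = mu
        Gaug[:, D, D] = 1.0
        mean_aug = np.concatenate([mu, np.ones((T, 1))], axis=1)

        if T > 1:
            Pt = Phi[:-1]
            # E[x~_t x_{t+1}^T] = [E[x_t x_{t+1}^T]; E[x_{t+1}]^T]
            cross_xt = np.concatenate(
                [post.cross.transpose(0, 2, 1), mu[1:, None, :]], axis=1)
            dyn_gram += np.einsum("ta,tij,tb->aibj", Pt, Gaug[:-1], Pt,
                                  optimize=True).reshape(dyn_gram.shape)
            dyn_cross += np.einsum("ta,tij->aij", Pt, cross_xt).reshape(
                dyn_cross.shape)
        if learn_C:
            if learn_d:
                target = trial.y
                em_gram += np.einsum("ta,tij,tb->aibj", Phi, Gaug, Phi,
                                     optimize=True).reshape(em_gram.shape)
                em_cross += np.einsum("ta,ti,tj->aij", Phi, mean_aug,
                                      target).reshape(em_cross.shape)
            else:
                d_all = model.d.batch(model.basis, trial.u)
                target = trial.y - d_all
                em_gram += np.einsum("ta,tij,tb->aibj", Phi, seconds, Phi,
                                     optimize=True).reshape(em_gram.shape)
                em_cross += np.einsum("ta,ti,tj->aij", Phi, mu,
                                      target).reshape(em_cross.shape)
        elif learn_d:
            C_all = model.C.batch(model.basis, trial.u)
            resid = trial.y - np.einsum("tij,tj->ti", C_all, mu)
            em_gram += Phi.T @ Phi
            em_cross += Phi.T @ resid
        init_gram += np.outer(Phi[0], Phi[0])
        init_cross += np.outer(Phi[0], mu[0])
        n_trans += T - 1
        n_obs += T
        total_loglik += post.loglik
        posteriors.append(post)
        phis.append(Phi)

    return SufficientStats(
        dyn_gram=dyn_gram, dyn_cross=dyn_cross,
        em_gram=em_gram, em_cross=em_cross,
        init_gram=init_gram, init_cross=init_cross,
        n_transitions=n_trans, n_observations=n_obs,
        posteriors=posteriors, phis=phis, total_loglik=float(total_loglik),
    )


def _split_augmented(W_aug: np.ndarray, L: int, D_out: int):
    """Split weights of the augmented map [M(u) c(u)] into M and c blocks."""
    D2aug = W_aug.shape[0] // L
    W3 = W_aug.reshape(L, D2aug, D_out)
    W_M = W3[:, : D2aug - 1, :].reshape(L * (D2aug - 1), D_out)
    W_c = W3[:, D2aug - 1, :]
    return W_M, W_c


def m_step_dynamics(stats: SufficientStats, Q: np.ndarray, D: int, L: int):
    """Joint MAP update of the dynamics weights (A, b) given noise Q."""
    W_aug = solve_map_weights(
        RegressionProblem(gram=stats.dyn_gram, cross=stats.dyn_cross, sigma=Q)
    )
    W_A, W_b = _split_augmented(W_aug, L, D)
    return (FunctionWeights(D1=D, D2=D, W=W_A, label="A"),
            FunctionWeights(D1=D, D2=1, W=W_b, label="b"))


def m_step_emissions(stats: SufficientStats, R: np.ndarray, D: int, N: int,
                     L: int, learn_C: bool, learn_d: bool):
    """MAP update of the emission weights; returns (weights_C, weights_d),
    either possibly None when that function is frozen."""
    if not (learn_C or learn_d):
        return None, None
    W = solve_map_weights(
        RegressionProblem(gram=stats.em_gram, cross=stats.em_cross, sigma=R)
    )
    if learn_C and learn_d:
        W_C, W_d = _split_augmented(W, L, N)
        return (FunctionWeights(D1=N, D2=D, W=W_C, label="C"),
                FunctionWeights(D1=N, D2=1, W=W_d, label="d"))
    if learn_C:
        return FunctionWeights(D1=N, D2=D, W=W, label="C"), None
    return None, FunctionWeights(D1=N, D2=1, W=W, label="d")


def m_step_initial(stats: SufficientStats, Q1: np.ndarray, D: int):
    """MAP update of the initial-mean weights m(.) given Q1."""
    W = solve_map_weights(
        RegressionProblem(gram=stats.init_gram, cross=stats.init_cross, sigma=Q1)
    )
    return FunctionWeights(D1=D, D2=1, W=W, label="m")


def _floor_spd(M: np.ndarray, floor: float) -> np.ndarray:
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    return (V * np.maximum(w, floor)) @ V.T


def update_covariances(model: CLDSModel, trialset: TrialSet,
                       stats: SufficientStats, floor: float = 1e-6,
                       update_Q1: bool = True):
    """Expected-residual updates for {Q1, Q, R} under the model's current
    (freshly updated) parameter functions."""
    D, N = model.D, model.N
    Q_acc = np.zeros((D, D))
    R_acc = np.zeros((N, N))
    Q1_acc = np.zeros((D, D))
    for trial, post in zip(trialset, stats.posteriors):
        A_all, b_all, C_all, d_all, _ = model.param_arrays(trial.u)
        mu = post.means
        T = trial.T
        seconds = post.covs + np.einsum("ti,tj->tij", mu, mu)
        Gaug = np.empty((T, D + 1, D + 1))
        Gaug[:, :D, :D] = seconds
        Gaug[:, :D, D] = mu
        Gaug[:, D, :D] = mu
        Gaug[:, D, D] = 1.0
        mean_aug = np.concatenate([mu, np.ones((T, 1))], axis=1)
        H = np.concatenate([C_all, d_all[:, :, None]], axis=2)   # (T, N, D+1)
        Y = trial.y
        hm = np.einsum("tia,ta,tj->ij", H, mean_aug, Y)
        R_acc += (Y.T @ Y - hm - hm.T
                  + np.einsum("tia,tab,tjb->ij", H, Gaug, H, optimize=True))
        if T > 1:
            B = np.concatenate([A_all[:-1], b_all[:-1, :, None]], axis=2)
            Mx = np.concatenate([post.cross, mu[1:, :, None]], axis=2)
            bm = np.einsum("tia,tja->ij", B, Mx)
            Q_acc += (seconds[1:].sum(axis=0) - bm - bm.T
                      + np.einsum("tia,tab,tjb->ij", B, Gaug[:-1], B,
                                  optimize=True))
        m1 = model.m(model.basis, trial.u[0]).reshape(D)
        dev = mu[0] - m1
        Q1_acc += post.covs[0] + np.outer(dev, dev)
    Q = _floor_spd(Q_acc / max(stats.n_transitions, 1), floor)
    R = _floor_spd(R_acc / stats.n_observations, floor)
    Q1 = _floor_spd(Q1_acc / trialset.K, floor) if update_Q1 else model.Q1
    return Q1, Q, R


def penalized_objective(model: CLDSModel, total_loglik: float) -> float:
    """Marginal log-likelihood plus the log prior of all learned weights
    (up to an additive constant)."""
    logprior = 0.0
    for name in ("A", "b", "C", "d", "m"):
        if name in model.fixed:
            continue
        pf = getattr(model, name)
        if pf.is_parametric:
            logprior -= 0.5 * float(np.sum(pf.weights.W ** 2))
    return total_loglik + logprior
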