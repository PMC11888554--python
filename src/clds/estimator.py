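"""Scikit-learn style estimator for conditionally linear dynamical systems.

``CLDS`` follows the fit/predict/score protocol (``get_params``/``set_params``
via :class:`sklearn.base.BaseEstimator`), so it composes with sklearn model
selection.  ``fit`` runs MAP expectation-maximization: Kalman-smoothing
E-steps and Sylvester-equation M-steps.  The fitted generative model is
exposed as ``model_`` and the optimization trace as ``trace_``.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import em as _em
from .basis import BasisSet, ConditionDomain, build_basis, sample_function
from .model import CLDSModel, ParamFunction, Trial, TrialSet

__all__ = ["CLDS", "fit_em", "select_hyperparameters"]


def _as_trialset(X, domain) -> TrialSet:
    if isinstance(X, TrialSet):
        return X
    trials = []
    for item in X:
        if isinstance(item, Trial):
            trials.append(item)
        else:
            y, u = item[0], item[1]
            trials.append(Trial(y=y, u=u))
    if domain is None:
        raise ValueError("a ConditionDomain is required when passing raw trials")
    return TrialSet(trials=trials, domain=domain)


def _make_fixed_function(value, shape, name) -> ParamFunction:
    if callable(value):
        return ParamFunction(shape, func=value, name=name)
    arr = np.asarray(value, dtype=float).reshape(shape)
    return ParamFunction(shape, func=lambda u, _a=arr: _a, name=name)


class CLDS(BaseEstimator):
    """Conditionally linear dynamical system learned by closed-form EM.

    Parameters
    ----------
    n_latents : int
        Latent state dimension D.
    domain : ConditionDomain, optional
        Condition space with per-dimension kernel hyperparameters
        (length-scale kappa, variance sigma^2).  May also be attached to the
        :class:`TrialSet` passed to ``fit``.
    n_basis : int or tuple of int
        Fourier-feature truncation level per condition dimension; the total
        basis size is the product.
    max_iter : int
        Maximum EM iterations.
    tol : float
        Relative change of the penalized objective for convergence.
    fixed_C : array or callable, optional
        Freeze the emission map to this value (matrix, or callable of u)
        instead of learning it — used to pin identifiability.
    learn_d : bool
        Learn a condition-dependent output baseline d(u); default off
        (d frozen at zero).
    learn_Q1 : bool
        Update the initial-state covariance during EM; with few trials this
        estimate is noisy and can be frozen at the identity.
    cov_floor : float
        Eigenvalue floor applied to {Q1, Q, R} to prevent degeneracy.
    init_spectral_radius : float
        Prior-sampled dynamics weights are rescaled once at initialization
        so that the spectral radius of A(u) over the training covariates does
        not exceed this value; keeps the first E-step well-conditioned.
    random_state : int or None
        Seed for the prior-sample initialization.

    Attributes
    ----------
    model_ : CLDSModel
        Fitted generative model.
    trace_ : FitTrace
        Penalized-objective trace (non-decreasing) and convergence flag.
    loglik_ : float
        Final training marginal log-likelihood.
    n_iter_ : int
        EM iterations performed.
    """

    def __init__(self, n_latents: int = 2,
                 domain: Optional[ConditionDomain] = None,
                 n_basis: Union[int, Sequence[int]] = 13,
                 max_iter: int = 200, tol: float = 1e-6,
                 fixed_C=None, learn_d: bool = False, learn_Q1: bool = True,
                 cov_floor: float = 1e-6, init_spectral_radius: float = 0.95,
                 random_state: Optional[int] = None):
        self.n_latents = n_latents
        self.domain = domain
        self.n_basis = n_basis
        self.max_iter = max_iter
        self.tol = tol
        self.fixed_C = fixed_C
        self.learn_d = learn_d
        self.learn_Q1 = learn_Q1
        self.cov_floor = cov_floor
        self.init_spectral_radius = init_spectral_radius
        self.random_state = random_state

    # -- initialization ------------------------------------------------------

    def _initial_model(self, trialset: TrialSet, basis: BasisSet) -> CLDSModel:
        rng = np.random.default_rng(self.random_state)
        D = self.n_latents
        N = trialset.N
        fixed = set()
        wA = sample_function(basis, D, D, rng, label="A")
        wb = sample_function(basis, D, 1, rng, label="b")
        wm = sample_function(basis, D, 1, rng, label="m")

        # temper explosive prior draws of the dynamics map
        U_pool = np.concatenate([tr.u for tr in trialset])
        sub = U_pool[:: max(1, len(U_pool) // 200)]
        W3 = wA.W.reshape(basis.L, D, D)
        rho = 0.0
        for u in sub:
            A = np.einsum("l,lji->ij", basis.evaluate(u), W3)
            rho = max(rho, np.abs(np.linalg.eigvals(A)).max())
        if rho > self.init_spectral_radius:
            wA.W *= self.init_spectral_radius / rho

        if self.fixed_C is not None:
            C_fn = _make_fixed_function(self.fixed_C, (N, D), "C")
            fixed.add("C")
        else:
            C_fn = ParamFunction((N, D), weights=sample_function(basis, N, D, rng, label="C"), name="C")
        if self.learn_d:
            d_fn = ParamFunction((N,), weights=sample_function(basis, N, 1, rng, label="d"), name="d")
        else:
            d_fn = ParamFunction.zero((N,), name="d")
            fixed.add("d")

        y_var = np.concatenate([tr.y for tr in trialset]).var(axis=0)
        R0 = np.diag(np.maximum(y_var, 10 * self.cov_floor))
        return CLDSModel(
            D=D, N=N,
            A=ParamFunction((D, D), weights=wA, name="A"),
            b=ParamFunction((D,), weights=wb, name="b"),
            C=C_fn, d=d_fn,
            m=ParamFunction((D,), weights=wm, name="m"),
            Q1=np.eye(D), Q=0.1 * np.eye(D), R=R0,
            basis=basis, domain=basis.domain, fixed=frozenset(fixed),
        )

    # -- EM ------------------------------------------------------------------

    def fit(self, X, y=None):
        """Fit by MAP EM.

        X : TrialSet, or an iterable of Trial / (y, u) pairs (the latter
        requires ``domain``).
        """
        trialset = _as_trialset(X, self.domain)
        domain = trialset.domain
        basis = build_basis(domain, self.n_basis)
        model = self._initial_model(trialset, basis)
        trace = _em.FitTrace()

        learn_C, learn_d = "C" not in model.fixed, "d" not in model.fixed
        D, N, L = model.D, model.N, basis.L
        prev_obj = None
        for it in range(self.max_iter):
            stats = _em.e_step(model, trialset)
            obj = _em.penalized_objective(model, stats.total_loglik)
            if not np.isfinite(obj):
                raise RuntimeError(f"non-finite EM objective at iteration {it}")
            trace.objectives.append(obj)
            if prev_obj is not None and abs(obj - prev_obj) <= self.tol * abs(prev_obj):
                trace.converged = True
                break
            prev_obj = obj

            wA, wb = _em.m_step_dynamics(stats, model.Q, D, L)
            wC, wd = _em.m_step_emissions(stats, model.R, D, N, L, learn_C, learn_d)
            wm = _em.m_step_initial(stats, model.Q1, D)
            delta = sum(
                float(np.linalg.norm(new.W - getattr(model, new.label).weights.W))
                for new in (wA, wb, wm)
            )
            model.A = ParamFunction((D, D), weights=wA, name="A")
            model.b = ParamFunction((D,), weights=wb, name="b")
            if wC is not None:
                model.C = ParamFunction((N, D), weights=wC, name="C")
            if wd is not None:
                model.d = ParamFunction((N,), weights=wd, name="d")
            model.m = ParamFunction((D,), weights=wm, name="m")
            model.Q1, model.Q, model.R = _em.update_covariances(
                model, trialset, stats, floor=self.cov_floor,
                update_Q1=self.learn_Q1,
            )
            trace.param_deltas.append(delta)
            trace.n_iter = it + 1

        if trace.n_iter == len(trace.objectives):
            # M-steps ran after the last recorded objective (or max_iter=0):
            # record the final model's objective with one more E-step
            stats = _em.e_step(model, trialset)
            trace.objectives.append(
                _em.penalized_objective(model, stats.total_loglik))
        self.model_ = model
        self.trace_ = trace
        self.n_iter_ = trace.n_iter
        self.loglik_ = trace.objectives[-1] - _em.penalized_objective(model, 0.0)
        return self

    # -- prediction / scoring ------------------------------------------------

    def smooth(self, X):
        """Smoothed latent posteriors for each trial."""
        self._check_fitted()
        trialset = _as_trialset(X, self.model_.domain)
        from .kalman import kalman_smoother
        return [kalman_smoother(self.model_, tr) for tr in trialset]

    def predict(self, X):
        """Data reconstruction: mean emission along the posterior mode."""
        self._check_fitted()
        from .metrics import reconstruct
        trialset = _as_trialset(X, self.model_.domain)
        return [reconstruct(self.model_, tr) for tr in trialset]

    def score(self, X, y=None, top_k: int = 5) -> float:
        """Mean co-smoothing R^2 over the top-variance neurons of X."""
        self._check_fitted()
        from .metrics import cosmoothing
        trialset = _as_trialset(X, self.model_.domain)
        per_neuron, mean_r2 = cosmoothing(self.model_, trialset, top_k=top_k)
        return mean_r2

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")


def fit_em(trialset: TrialSet, n_latents: int = 2, **kwargs):
    """Functional wrapper: fit a CLDS by EM and return (model, trace)."""
    est = CLDS(n_latents=n_latents, **kwargs).fit(trialset)
    return est.model_, est.trace_


def select_hyperparameters(trialset: TrialSet, grid, seed: int = 0,
                           n_latents: int = 2, top_k: int = 5,
                           test_fraction: float = 0.2, **fit_kwargs):
    """Grid search over {L, kappa, sigma} scored by held-out co-smoothing.

    ``grid`` is an iterable of dicts with any of the keys ``n_basis``,
    ``lengthscale``, ``variance``.  Trials are split 80/20 (seeded); each
    configuration is fit on the training split and scored by mean
    co-smoothing R^2 on the held-out split.  Ties break in grid order.

    Returns (best_config, table) with a pandas DataFrame of scores.
    """
    grid = list(grid)
    if len(grid) == 0:
        raise ValueError("hyperparameter grid is empty")
    K = trialset.K
    rng = np.random.default_rng(seed)
    perm = rng.permutation(K)
    n_test = max(1, int(round(test_fraction * K)))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    train, test = trialset[train_idx], trialset[test_idx]

    rows = []
    best = None
    for cfg in grid:
        domain = trialset.domain.with_hyperparameters(
            lengthscale=cfg.get("lengthscale"), variance=cfg.get("variance"))
        est = CLDS(n_latents=n_latents, domain=domain,
                   n_basis=cfg.get("n_basis", 13),
                   random_state=seed, **fit_kwargs)
        est.fit(TrialSet(train.trials, domain, dict(train.metadata)))
        score = est.score(TrialSet(test.trials, domain, dict(test.metadata)),
                          top_k=top_k)
        rows.append({**cfg, "cosmoothing_r2": score, "loglik": est.loglik_})
        if best is None or score > best[0]:
            best = (score, cfg)
    table = pd.DataFrame(rows)
    return best[1], table
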