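"""Generative conditionally linear dynamical system (CLDS).

Conditioned on a covariate sequence u_{1:T}, the model is a linear-Gaussian
state-space model with per-step parameters:

    x_1     ~ N(m(u_1), Q1)
    x_{t+1} = A(u_t) x_t + b(u_t) + eps_t,    eps_t ~ N(0, Q)
    y_t     = C(u_t) x_t + d(u_t) + omega_t,  omega_t ~ N(0, R)

The parameter functions {A, b, C, d, m} carry approximate GP priors realized
by basis-weight expansions (:mod:`clds.basis`); they may alternatively be
fixed analytic callables (used for ground-truth simulators and for freezing
the emission map during fitting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .basis import BasisSet, ConditionDomain, FunctionWeights, evaluate_function

__all__ = ["ParamFunction", "Trial", "TrialSet", "ParamSet", "CLDSModel",
           "evaluate_params", "sample_trial"]


PARAM_NAMES = ("A", "b", "C", "d", "m")


class ParamFunction:
    """A matrix-valued function of the covariate: either weight-parameterized
    (``FunctionWeights`` against a basis) or an arbitrary callable."""

    def __init__(self, shape, weights: Optional[FunctionWeights] = None,
                 func: Optional[Callable] = None, name: str = ""):
        if (weights is None) == (func is None):
            raise ValueError("provide exactly one of weights or func")
        self.shape = tuple(shape)
        self.weights = weights
        self.func = func
        self.name = name
        if weights is not None:
            expect = (self.shape[0], self.shape[1] if len(self.shape) > 1 else 1)
            if (weights.D1, weights.D2) != expect:
                raise ValueError(
                    f"weights for {name} have dims ({weights.D1},{weights.D2}), "
                    f"expected {expect}"
                )

    @property
    def is_parametric(self) -> bool:
        return self.weights is not None

    def __call__(self, basis: Optional[BasisSet], u) -> np.ndarray:
        if self.weights is not None:
            M = evaluate_function(self.weights, basis, u)
        else:
            uu = np.atleast_1d(np.asarray(u, dtype=float))
            M = np.asarray(self.func(uu[0] if uu.size == 1 else uu), dtype=float)
        out = M.reshape(self.shape)
        if not np.all(np.isfinite(out)):
            raise ValueError(f"non-finite values in parameter function {self.name}")
        return out

    def batch(self, basis: Optional[BasisSet], U: np.ndarray) -> np.ndarray:
        """Evaluate at every row of a (n, d) covariate array; returns
        (n, *shape) with vectorized basis evaluation for parametric
        functions."""
        U = np.asarray(U, dtype=float)
        if U.ndim == 1:
            U = U[:, None]
        if self.weights is not None:
            Phi = basis.evaluate_many(U)
            W3 = self.weights.W.reshape(self.weights.L, self.weights.D2,
                                        self.weights.D1)
            M = np.einsum("tl,lji->tij", Phi, W3)
            out = M.reshape((len(U),) + self.shape)
        else:
            out = np.stack([self(None, u) for u in U])
        if not np.all(np.isfinite(out)):
            raise ValueError(f"non-finite values in parameter function {self.name}")
        return out

    @classmethod
    def zero(cls, shape, name: str = "") -> "ParamFunction":
        z = np.zeros(shape)
        return cls(shape, func=lambda u, _z=z: _z, name=name)


@dataclass
class Trial:
    """One trial: observations y (T x N), covariates u (T x d), and — for
    simulated data — the true latents x (T x D)."""

    y: np.ndarray
    u: np.ndarray
    x: Optional[np.ndarray] = None

    def __post_init__(self):
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim == 1:
            self.u = self.u[:, None]
        if self.y.shape[0] != self.u.shape[0]:
            raise ValueError("y and u must share the number of time steps")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.u))):
            raise ValueError("trials must not contain NaN/inf")
        if self.x is not None:
            self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
            if self.x.shape[0] != self.T:
                raise ValueError("latents must share T with observations")

    @property
    def T(self) -> int:
        return self.y.shape[0]

    @property
    def N(self) -> int:
        return self.y.shape[1]


@dataclass
class TrialSet:
    """A collection of trials sharing neuron count and covariate domain."""

    trials: list
    domain: ConditionDomain
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.trials) == 0:
            raise ValueError("a trial set needs at least one trial")
        N = self.trials[0].N
        d = self.trials[0].u.shape[1]
        for tr in self.trials:
            if tr.N != N or tr.u.shape[1] != d:
                raise ValueError("all trials must share N and covariate dim")
        if d != self.domain.ndim:
            raise ValueError("covariate dimension does not match domain")

    @property
    def K(self) -> int:
        return len(self.trials)

    @property
    def N(self) -> int:
        return self.trials[0].N

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, idx):
        if isinstance(idx, (list, np.ndarray)):
            return TrialSet([self.trials[i] for i in idx], self.domain,
                            dict(self.metadata))
        return self.trials[idx]


@dataclass
class ParamSet:
    """The linear system at one covariate value."""

    A: np.ndarray
    b: np.ndarray
    C: np.ndarray
    d: np.ndarray
    m: np.ndarray


def _check_spd(name, M, dim):
    M = np.asarray(M, dtype=float)
    if M.shape != (dim, dim):
        raise ValueError(f"{name} must be {dim}x{dim}")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(M).min() <= 0:
        raise ValueError(f"{name} must be positive definite")
    return M


@dataclass
class CLDSModel:
    """All parameter functions plus noise covariances of a CLDS.

    ``fixed`` lists parameter names excluded from EM updates; ``d`` defaults
    to the frozen zero function (no condition-dependent output baseline).
    """

    D: int
    N: int
    A: ParamFunction
    b: ParamFunction
    C: ParamFunction
    d: ParamFunction
    m: ParamFunction
    Q1: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    basis: Optional[BasisSet] = None
    domain: Optional[ConditionDomain] = None
    fixed: frozenset = frozenset({"d"})

    def __post_init__(self):
        self.Q1 = _check_spd("Q1", self.Q1, self.D)
        self.Q = _check_spd("Q", self.Q, self.D)
        self.R = _check_spd("R", self.R, self.N)
        self.fixed = frozenset(self.fixed)
        if self.domain is None and self.basis is not None:
            self.domain = self.basis.domain

    def params_at(self, u) -> ParamSet:
        return ParamSet(
            A=self.A(self.basis, u).reshape(self.D, self.D),
            b=self.b(self.basis, u).reshape(self.D),
            C=self.C(self.basis, u).reshape(self.N, self.D),
            d=self.d(self.basis, u).reshape(self.N),
            m=self.m(self.basis, u).reshape(self.D),
        )

    def params_along(self, u_seq):
        """List of ParamSet at each row of a (T, d) covariate sequence
        (batched basis evaluation)."""
        A, b, C, d, m = self.param_arrays(u_seq)
        return [ParamSet(A=A[t], b=b[t], C=C[t], d=d[t], m=m[t])
                for t in range(len(A))]

    def param_arrays(self, u_seq):
        """Batched parameter evaluation: arrays (T,D,D), (T,D), (T,N,D),
        (T,N), (T,D) along a covariate sequence."""
        u_seq = np.asarray(u_seq, dtype=float)
        if u_seq.ndim == 1:
            u_seq = u_seq[:, None]
        return (self.A.batch(self.basis, u_seq),
                self.b.batch(self.basis, u_seq),
                self.C.batch(self.basis, u_seq),
                self.d.batch(self.basis, u_seq),
                self.m.batch(self.basis, u_seq))

    def sample_trial(self, u_seq, rng) -> Trial:
        """Simulate one trial along a covariate sequence (latents retained)."""
        rng = np.random.default_rng(rng)
        u_seq = np.asarray(u_seq, dtype=float)
        if u_seq.ndim == 1:
            u_seq = u_seq[:, None]
        T = u_seq.shape[0]
        if T < 1:
            raise ValueError("need at least one time step")
        params = self.params_along(u_seq)
        sQ1 = np.linalg.cholesky(self.Q1)
        sQ = np.linalg.cholesky(self.Q)
        sR = np.linalg.cholesky(self.R)
        x = np.empty((T, self.D))
        y = np.empty((T, self.N))
        x[0] = params[0].m + sQ1 @ rng.standard_normal(self.D)
        for t in range(T):
            p = params[t]
            y[t] = p.C @ x[t] + p.d + sR @ rng.standard_normal(self.N)
            if t + 1 < T:
                x[t + 1] = p.A @ x[t] + p.b + sQ @ rng.standard_normal(self.D)
        return Trial(y=y, u=u_seq, x=x)


def evaluate_params(model: CLDSModel, u) -> ParamSet:
    """Evaluate {A(u), b(u), C(u), d(u), m(u)} at one covariate value."""
    return model.params_at(u)


def sample_trial(model: CLDSModel, u_seq, rng_seed) -> Trial:
    """Module-level wrapper over :meth:`CLDSModel.sample_trial`."""
    return model.sample_trial(u_seq, rng_seed)
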