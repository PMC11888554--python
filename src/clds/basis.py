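"""Truncated Fourier-feature bases approximating squared-exponential GP priors.

A matrix-valued parameter function ``M(u)`` is modeled entrywise as
``M_ij(u) = sum_l w_l^(ij) phi_l(u)`` with i.i.d. standard-normal weights and
fixed basis functions ``phi_l``.  The basis functions are scaled so that the
implied kernel ``k(u, u') = phi(u) . phi(u')`` approximates a squared-
exponential (SE) kernel with variance ``sigma2`` and length-scale
``lengthscale`` — the periodically wrapped SE on periodic dimensions, the
plain SE on interval dimensions (realized on a padded surrogate period so
boundary wrap-around is negligible).  Multi-dimensional condition spaces use
the tensor product of per-dimension bases, giving a product kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "DomainDimension",
    "ConditionDomain",
    "BasisSet",
    "FunctionWeights",
    "build_basis",
    "evaluate_basis",
    "sample_function",
    "evaluate_function",
    "project_function",
    "InvalidDomainError",
    "OutOfDomainError",
]


class InvalidDomainError(ValueError):
    """Raised when a condition-domain descriptor violates its invariants."""


class OutOfDomainError(ValueError):
    """Raised when a covariate falls outside a non-periodic dimension."""


_KINDS = ("periodic", "interval", "discrete_embedded")


@dataclass(frozen=True)
class DomainDimension:
    """One dimension of the condition space.

    Parameters
    ----------
    kind : {"periodic", "interval", "discrete_embedded"}
        ``periodic`` wraps covariates modulo the period (``upper - lower``);
        ``interval`` rejects out-of-range covariates; ``discrete_embedded``
        places a finite set of levels on a continuous interval so that the
        SE length-scale controls correlation between levels.
    lower, upper : float
        Domain bounds in covariate units.
    lengthscale : float
        SE kernel length-scale kappa (> 0, covariate units).  ``np.inf``
        yields a constant basis (condition-independent functions).
    variance : float
        SE kernel variance sigma^2 (> 0, dimensionless prior variance).
    levels : tuple of float, optional
        Admissible values for ``discrete_embedded`` dimensions.
    """

    kind: str
    lower: float
    upper: float
    lengthscale: float
    variance: float = 1.0
    levels: tuple = field(default=())

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise InvalidDomainError(f"unknown dimension kind {self.kind!r}")
        if not self.lower < self.upper:
            raise InvalidDomainError("require lower < upper")
        if not self.lengthscale > 0:
            raise InvalidDomainError("length-scale must be > 0")
        if not self.variance > 0:
            raise InvalidDomainError("variance must be > 0")
        if self.kind == "discrete_embedded":
            if len(self.levels) < 1:
                raise InvalidDomainError("discrete_embedded needs levels")
            lv = np.asarray(self.levels, dtype=float)
            if lv.min() < self.lower or lv.max() > self.upper:
                raise InvalidDomainError("levels must lie within bounds")

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class ConditionDomain:
    """Cartesian product of :class:`DomainDimension` descriptors."""

    dims: tuple

    def __post_init__(self):
        object.__setattr__(self, "dims", tuple(self.dims))
        if len(self.dims) == 0:
            raise InvalidDomainError("domain needs at least one dimension")

    @property
    def ndim(self) -> int:
        return len(self.dims)

    def validate_point(self, u) -> np.ndarray:
        """Check a covariate point and return it as a 1-D float array."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        if u.shape != (self.ndim,):
            raise OutOfDomainError(
                f"covariate has shape {u.shape}, expected ({self.ndim},)"
            )
        self.validate_points(u[None, :])
        return u

    def validate_points(self, U: np.ndarray) -> np.ndarray:
        """Vectorized domain check for a (n, ndim) array of covariates."""
        U = np.asarray(U, dtype=float)
        if U.ndim != 2 or U.shape[1] != self.ndim:
            raise OutOfDomainError(
                f"covariates have shape {U.shape}, expected (n, {self.ndim})"
            )
        tol = 1e-9
        for j, dim in enumerate(self.dims):
            col = U[:, j]
            if dim.kind == "periodic":
                continue
            if np.any(col < dim.lower - tol) or np.any(col > dim.upper + tol):
                raise OutOfDomainError(
                    f"covariate outside [{dim.lower}, {dim.upper}] in dim {j}"
                )
            if dim.kind == "discrete_embedded":
                lv = np.asarray(dim.levels, dtype=float)
                if np.abs(lv[None, :] - col[:, None]).min(axis=1).max() > 1e-6:
                    raise OutOfDomainError(
                        f"covariate not an admissible level of dim {j}"
                    )
        return U

    def with_hyperparameters(self, lengthscale=None, variance=None) -> "ConditionDomain":
        """Copy of the domain with kappa / sigma^2 replaced on every dimension."""
        dims = []
        for d in self.dims:
            dims.append(
                DomainDimension(
                    kind=d.kind,
                    lower=d.lower,
                    upper=d.upper,
                    lengthscale=d.lengthscale if lengthscale is None else lengthscale,
                    variance=d.variance if variance is None else variance,
                    levels=d.levels,
                )
            )
        return ConditionDomain(tuple(dims))


def periodic_domain(lower=0.0, upper=2 * np.pi, lengthscale=1.0, variance=1.0):
    """Convenience constructor for a single periodic (angular) condition."""
    return ConditionDomain(
        (DomainDimension("periodic", lower, upper, lengthscale, variance),)
    )


def constant_domain(lower=-1.0, upper=1.0, variance=1.0):
    """Domain whose basis degenerates to a constant (kappa -> infinity).

    Together with ``L=1`` this recovers a condition-independent model: the
    classical time-invariant linear dynamical system.
    """
    return ConditionDomain(
        (DomainDimension("interval", lower, upper, np.inf, variance),)
    )


# -- per-dimension feature construction --------------------------------------


def _fourier_coefficients(period: float, lengthscale: float, variance: float,
                          n_harmonics: int):
    """Cosine-series coefficients of the wrapped SE kernel, normalized to
    k(0) = variance.

    The wrapped SE kernel on a circle of circumference P has Fourier
    coefficients proportional to q_l = exp(-kappa^2 (2 pi l / P)^2 / 2)
    (Poisson summation).  Returns (c_0, c_1..c_n) with
    k(delta) = c_0 + sum_l c_l cos(2 pi l delta / P).
    """
    if math.isinf(lengthscale):
        q = np.zeros(n_harmonics + 1)
        q[0] = 1.0
        return variance * q
    omega = 2 * np.pi / period
    ell = np.arange(n_harmonics + 1, dtype=float)
    q = np.exp(-0.5 * (lengthscale * omega * ell) ** 2)
    # normalization uses the full series so k(0) -> variance as L grows
    l_full = np.arange(1, max(n_harmonics, 2) * 8 + 1000, dtype=float)
    z = 1.0 + 2.0 * np.exp(-0.5 * (lengthscale * omega * l_full) ** 2).sum()
    c = np.empty(n_harmonics + 1)
    c[0] = variance * q[0] / z
    c[1:] = variance * 2.0 * q[1:] / z
    return c


@dataclass(frozen=True)
class _DimFeatures:
    """Feature description for one dimension: offset, period, frequencies
    and scales; features are [s0, s1 cos(w1 x), s1' sin(w1 x), ...]."""

    offset: float
    period: float
    n_harmonics: int
    extra_cos: bool          # odd feature count parity: one unpaired cosine
    scales: np.ndarray       # per-feature sqrt-coefficients, length L_dim

    @property
    def size(self) -> int:
        return len(self.scales)

    def __call__(self, x: float) -> np.ndarray:
        return self.batch(np.asarray([x], dtype=float))[0]

    def batch(self, x: np.ndarray) -> np.ndarray:
        """Features for a 1-D array of covariate values; returns (n, L_dim)."""
        n = len(x)
        out = np.empty((n, self.size))
        out[:, 0] = self.scales[0]
        omega = 2 * np.pi / self.period
        xx = x - self.offset
        if self.n_harmonics > 0:
            h = np.arange(1, self.n_harmonics + 1)
            ang = omega * xx[:, None] * h[None, :]
            out[:, 1 : 2 * self.n_harmonics + 1 : 2] = (
                self.scales[1::2][: self.n_harmonics] * np.cos(ang))
            out[:, 2 : 2 * self.n_harmonics + 1 : 2] = (
                self.scales[2::2][: self.n_harmonics] * np.sin(ang))
        if self.extra_cos:
            h = self.n_harmonics + 1
            out[:, -1] = self.scales[-1] * np.cos(omega * h * xx)
        return out


def _build_dim_features(dim: DomainDimension, L: int) -> _DimFeatures:
    if L < 1:
        raise InvalidDomainError("per-dimension truncation level must be >= 1")
    if dim.kind == "periodic":
        period = dim.width
        offset = dim.lower
    else:
        # pad the interval so the surrogate period's wrap-around correlation
        # is negligible even when kappa is comparable to the interval width
        pad = dim.width * 0.25
        if not math.isinf(dim.lengthscale):
            pad = max(pad, 3.0 * dim.lengthscale)
        period = dim.width + 2 * pad
        offset = dim.lower - pad
    n_pairs = (L - 1) // 2
    extra_cos = (L % 2) == 0
    n_coef = n_pairs + (1 if extra_cos else 0)
    coef = _fourier_coefficients(period, dim.lengthscale, dim.variance, n_coef)
    scales = np.empty(L)
    scales[0] = math.sqrt(coef[0])
    for h in range(1, n_pairs + 1):
        s = math.sqrt(coef[h])
        scales[2 * h - 1] = s
        scales[2 * h] = s
    if extra_cos:
        scales[-1] = math.sqrt(coef[n_pairs + 1])
    return _DimFeatures(offset, period, n_pairs, extra_cos, scales)


@dataclass(frozen=True)
class BasisSet:
    """Tensor-product Fourier feature basis over a :class:`ConditionDomain`.

    ``evaluate(u)`` returns the length-``L`` feature vector phi(u); the
    implied kernel is ``kernel(u, v) = phi(u) . phi(v)``.
    """

    domain: ConditionDomain
    dim_features: tuple
    L_per_dim: tuple

    @property
    def L(self) -> int:
        return int(np.prod(self.L_per_dim))

    def evaluate(self, u) -> np.ndarray:
        u = self.domain.validate_point(u)
        return self.evaluate_many(u[None, :])[0]

    def evaluate_many(self, U) -> np.ndarray:
        """Evaluate at rows of a (n, ndim) array; returns (n, L)."""
        U = np.asarray(U, dtype=float)
        if U.ndim == 1:
            U = U[:, None] if self.domain.ndim == 1 else U[None, :]
        U = self.domain.validate_points(U)
        out = self.dim_features[0].batch(U[:, 0])
        for j in range(1, len(self.dim_features)):
            nxt = self.dim_features[j].batch(U[:, j])
            out = (out[:, :, None] * nxt[:, None, :]).reshape(len(U), -1)
        return out

    def kernel(self, U1, U2) -> np.ndarray:
        """Gram matrix of the implied (finite-rank) kernel between two point
        sets, each given as (n, ndim) arrays or 1-D arrays for scalar u."""
        U1 = np.asarray(U1, dtype=float)
        U2 = np.asarray(U2, dtype=float)
        if U1.ndim == 1:
            U1 = U1[:, None]
        if U2.ndim == 1:
            U2 = U2[:, None]
        P1 = self.evaluate_many(U1)
        P2 = self.evaluate_many(U2)
        return P1 @ P2.T


def build_basis(domain: ConditionDomain, L_per_dim) -> BasisSet:
    """Construct the Fourier-feature basis realizing the approximate GP prior.

    Parameters
    ----------
    domain : ConditionDomain
    L_per_dim : int or sequence of int
        Truncation level per dimension; the total basis size is the product.
    """
    if np.isscalar(L_per_dim):
        L_per_dim = (int(L_per_dim),) * domain.ndim
    L_per_dim = tuple(int(v) for v in L_per_dim)
    if len(L_per_dim) != domain.ndim:
        raise InvalidDomainError("need one truncation level per dimension")
    feats = tuple(_build_dim_features(d, L) for d, L in zip(domain.dims, L_per_dim))
    return BasisSet(domain=domain, dim_features=feats, L_per_dim=L_per_dim)


def evaluate_basis(basis: BasisSet, u) -> np.ndarray:
    """phi(u): deterministic length-L feature vector."""
    return basis.evaluate(u)


@dataclass
class FunctionWeights:
    """Weights of one matrix-valued parameter function.

    ``W`` has shape ``(D2 * L, D1)`` with basis-major row layout: row
    ``l * D2 + j`` column ``i`` holds the weight of basis function ``l`` for
    entry ``(i, j)`` of ``M``.  This is the layout for which
    ``M(u) = W.T @ kron(phi(u), I_D2)`` and ``M(u) @ x = W.T @ kron(phi(u), x)``.
    """

    D1: int
    D2: int
    W: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[1] != self.D1 or self.W.shape[0] % self.D2:
            raise ValueError(
                f"weight matrix shape {self.W.shape} inconsistent with "
                f"D1={self.D1}, D2={self.D2}"
            )

    @property
    def L(self) -> int:
        return self.W.shape[0] // self.D2

    def copy(self) -> "FunctionWeights":
        return FunctionWeights(self.D1, self.D2, self.W.copy(), self.label)


def sample_function(basis: BasisSet, D1: int, D2: int, rng, label: str = "") -> FunctionWeights:
    """Draw i.i.d. N(0, 1) weights for a D1 x D2 matrix function (GP prior draw)."""
    if D1 < 1 or D2 < 1:
        raise ValueError("function dimensions must be >= 1")
    rng = np.random.default_rng(rng)
    W = rng.standard_normal((D2 * basis.L, D1))
    return FunctionWeights(D1=D1, D2=D2, W=W, label=label)


def evaluate_function(weights: FunctionWeights, basis: BasisSet, u) -> np.ndarray:
    """M(u) = W.T (phi(u) x I_D2), returned as a (D1, D2) matrix."""
    phi = basis.evaluate(u)
    if len(phi) != weights.L:
        raise ValueError(
            f"basis size {len(phi)} does not match weight layout L={weights.L}"
        )
    W3 = weights.W.reshape(weights.L, weights.D2, weights.D1)
    return np.einsum("l,lji->ij", phi, W3)


def project_function(func, basis: BasisSet, D1: int, D2: int, U_grid,
                     label: str = "") -> FunctionWeights:
    """Least-squares projection of an analytic matrix function onto the basis.

    Used to serialize analytically defined models (e.g. the ring-attractor
    ground truth) through the weight-based container format.  The residual of
    the projection on the grid measures the approximation error.
    """
    U_grid = np.asarray(U_grid, dtype=float)
    if U_grid.ndim == 1:
        U_grid = U_grid[:, None]
    Phi = basis.evaluate_many(U_grid)            # (n, L)
    targets = np.stack([np.asarray(func(u if len(u) > 1 else u[0]), dtype=float)
                        .reshape(D1, D2) for u in U_grid])  # (n, D1, D2)
    # solve Phi @ W3[l, j, i] = targets[n, i, j] for each (i, j)
    B = targets.transpose(0, 2, 1).reshape(len(U_grid), D2 * D1)
    sol, *_ = np.linalg.lstsq(Phi, B, rcond=None)
    W3 = sol.reshape(basis.L, D2, D1)
    return FunctionWeights(D1=D1, D2=D2, W=W3.reshape(basis.L * D2, D1), label=label)
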