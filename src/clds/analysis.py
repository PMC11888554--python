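"""Post-fit interpretation of a CLDS.

Because the model is linear at each condition, classical linear-systems
analyses apply pointwise in u: fixed points solve (I - A(u)) x* = b(u)
exactly, and the local stability structure is the spectrum of A(u).  The
*composite dynamics* marginalize the condition out of the dynamics given
latent position — x_{t+1} ~ E_{p(u|x)}[A(u) x + b(u)] — estimated by
pooling posterior-mode latents with their covariates and averaging within
latent-space bins.  Model tuning curves follow from the law of total
expectation: E[y_i | u] = C_i(u) E[x | u] (+ d_i(u)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kalman import posterior_mode
from .model import CLDSModel, TrialSet

__all__ = ["FixedPointCurve", "CompositeField", "fixed_points",
           "dynamics_spectrum", "composite_field", "tuning_curves",
           "empirical_tuning_curves"]


@dataclass
class FixedPointCurve:
    """Fixed points and local spectra along a condition grid."""

    u_grid: np.ndarray
    points: np.ndarray       # (n, D) solutions x*(u); NaN where singular
    eigvals: np.ndarray      # (n, D) complex, sorted by descending modulus
    eig_angles: np.ndarray   # (n, D) eigenvector angles (D=2), else NaN
    singular: np.ndarray     # (n,) flags where I - A(u) was singular


@dataclass
class CompositeField:
    """Binned estimate of the composite displacement field g(x) - x."""

    centers_x: np.ndarray    # bin centers, first latent dimension
    centers_y: np.ndarray    # bin centers, second latent dimension
    vectors: np.ndarray      # (nx, ny, 2) displacement; NaN where unoccupied
    occupancy: np.ndarray    # (nx, ny) pooled posterior-point counts


def _sorted_eig(A):
    w, V = np.linalg.eig(A)
    order = np.lexsort((-np.angle(w), -np.abs(w)))
    return w[order], V[:, order]


def fixed_points(model: CLDSModel, u_grid) -> FixedPointCurve:
    """Solve (I - A(u)) x* = b(u) on a condition grid.

    Singular systems (eigenvalue of A at exactly 1: a line attractor) are
    flagged per point rather than raised.
    """
    u_grid = np.asarray(u_grid, dtype=float)
    pts_u = u_grid[:, None] if u_grid.ndim == 1 else u_grid
    n = len(pts_u)
    D = model.D
    points = np.full((n, D), np.nan)
    eigvals = np.full((n, D), np.nan, dtype=complex)
    angles = np.full((n, D), np.nan)
    singular = np.zeros(n, dtype=bool)
    I = np.eye(D)
    for g, u in enumerate(pts_u):
        p = model.params_at(u)
        w, V = _sorted_eig(p.A)
        eigvals[g] = w
        if D == 2:
            angles[g] = np.arctan2(V[1].real, V[0].real)
        M = I - p.A
        if np.abs(np.linalg.eigvals(M)).min() < 1e-10:
            singular[g] = True
            continue
        x_star = np.linalg.solve(M, p.b)
        resid = np.linalg.norm(M @ x_star - p.b)
        if resid > 1e-8 * max(1.0, np.linalg.norm(p.b)):
            singular[g] = True
            continue
        points[g] = x_star
    return FixedPointCurve(u_grid=u_grid, points=points, eigvals=eigvals,
                           eig_angles=angles, singular=singular)


def dynamics_spectrum(model: CLDSModel, u_grid):
    """Eigenvalues (descending modulus, ties by argument) and eigenvector
    angles of A(u) on a condition grid; returns (eigvals, angles)."""
    curve = fixed_points(model, u_grid)
    return curve.eigvals, curve.eig_angles


def composite_field(model: CLDSModel, trialset: TrialSet,
                    n_bins_per_dim: int = 25, bounds=None) -> CompositeField:
    """Estimate the composite displacement field on a latent-space grid.

    Posterior-mode latents are pooled with their covariates across trials;
    within each occupied bin the field is the average over the pooled u of
    A(u) x_c + b(u) - x_c evaluated at the bin center x_c.  Supports D=2.
    """
    if model.D != 2:
        raise ValueError("composite field is defined for D=2 models")
    xs, us = [], []
    for tr in trialset:
        xs.append(posterior_mode(model, tr))
        us.append(tr.u)
    X = np.concatenate(xs)
    U = np.concatenate(us)
    if bounds is None:
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        pad = 1e-9 + 0.0 * lo
        lo, hi = lo - pad, hi + pad
    else:
        (lo0, hi0), (lo1, hi1) = bounds
        lo = np.array([lo0, lo1])
        hi = np.array([hi0, hi1])
    edges0 = np.linspace(lo[0], hi[0], n_bins_per_dim + 1)
    edges1 = np.linspace(lo[1], hi[1], n_bins_per_dim + 1)
    c0 = 0.5 * (edges0[:-1] + edges0[1:])
    c1 = 0.5 * (edges1[:-1] + edges1[1:])
    i0 = np.clip(np.digitize(X[:, 0], edges0) - 1, 0, n_bins_per_dim - 1)
    i1 = np.clip(np.digitize(X[:, 1], edges1) - 1, 0, n_bins_per_dim - 1)

    occupancy = np.zeros((n_bins_per_dim, n_bins_per_dim), dtype=int)
    vectors = np.full((n_bins_per_dim, n_bins_per_dim, 2), np.nan)
    sums = np.zeros((n_bins_per_dim, n_bins_per_dim, 2))
    for a, b_, u in zip(i0, i1, U):
        p = model.params_at(u)
        xc = np.array([c0[a], c1[b_]])
        sums[a, b_] += p.A @ xc + p.b - xc
        occupancy[a, b_] += 1
    occupied = occupancy > 0
    vectors[occupied] = sums[occupied] / occupancy[occupied, None]
    return CompositeField(centers_x=c0, centers_y=c1, vectors=vectors,
                          occupancy=occupancy)


def _bin_scalar_condition(U, n_bins, lo, hi):
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(U, edges) - 1, 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return idx, centers


def tuning_curves(model: CLDSModel, trialset: TrialSet, n_bins: int = 64):
    """Model tuning curves over a scalar condition.

    E[x | u] is estimated by averaging smoothed posterior means within
    condition bins; the curve for neuron i is C_i(u_c) E[x | u_c] + d_i(u_c)
    at bin centers.  Returns (centers, curves (n_bins, N), n_per_bin);
    empty bins hold NaN.
    """
    if trialset.domain.ndim != 1:
        raise ValueError("tuning curves require a scalar condition")
    dim = trialset.domain.dims[0]
    xs, us = [], []
    for tr in trialset:
        xs.append(posterior_mode(model, tr))
        us.append(tr.u[:, 0])
    X = np.concatenate(xs)
    U = np.concatenate(us)
    idx, centers = _bin_scalar_condition(U, n_bins, dim.lower, dim.upper)
    curves = np.full((n_bins, model.N), np.nan)
    counts = np.bincount(idx, minlength=n_bins)
    for b in range(n_bins):
        if counts[b] == 0:
            continue
        ex = X[idx == b].mean(axis=0)
        p = model.params_at(np.array([centers[b]]))
        curves[b] = p.C @ ex + p.d
    return centers, curves, counts


def empirical_tuning_curves(trialset: TrialSet, n_bins: int = 64):
    """Binned mean observed rate per neuron over a scalar condition."""
    if trialset.domain.ndim != 1:
        raise ValueError("tuning curves require a scalar condition")
    dim = trialset.domain.dims[0]
    Y = np.concatenate([tr.y for tr in trialset])
    U = np.concatenate([tr.u[:, 0] for tr in trialset])
    idx, centers = _bin_scalar_condition(U, n_bins, dim.lower, dim.upper)
    curves = np.full((n_bins, Y.shape[1]), np.nan)
    counts = np.bincount(idx, minlength=n_bins)
    for b in range(n_bins):
        if counts[b] > 0:
            curves[b] = Y[idx == b].mean(axis=0)
    return centers, curves, counts
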