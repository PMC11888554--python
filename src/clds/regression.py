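"""Conditionally linear regression: MAP weight estimation in the expanded
feature space.

The regression model is y_n = M(u_n) x_n + eps_n with eps_n ~ N(0, Sigma)
and a basis-weight expansion M(u) = W^T (phi(u) x I).  Writing
z_n = phi(u_n) x x_n, the MAP weights under the standard-normal weight prior
solve the Sylvester equation

    (sum_n z_n z_n^T) W + W Sigma = sum_n z_n y_n^T,

which is a penalized multi-output least squares whose ridge penalty is
whitened by the noise covariance.  Inside EM the sums are replaced by their
posterior expectations, so the solver works from accumulated moments and
never materializes the design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_sylvester

__all__ = ["RegressionProblem", "expand_features", "solve_map_weights"]


def expand_features(phi_u: np.ndarray, x: np.ndarray) -> np.ndarray:
    """z = phi(u) x x (Kronecker product, basis-major ordering)."""
    return np.kron(np.asarray(phi_u, dtype=float), np.asarray(x, dtype=float))


@dataclass
class RegressionProblem:
    """Moments of a conditionally linear regression.

    gram  : (p, p)  sum over data of (expected) z z^T
    cross : (p, D1) sum over data of (expected) z y^T
    sigma : (D1, D1) SPD noise covariance
    """

    gram: np.ndarray
    cross: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.gram = np.asarray(self.gram, dtype=float)
        self.cross = np.asarray(self.cross, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        p = self.gram.shape[0]
        if self.gram.shape != (p, p):
            raise ValueError("gram must be square")
        if self.cross.shape[0] != p:
            raise ValueError("cross moment row dimension mismatch")
        D1 = self.cross.shape[1]
        if self.sigma.shape != (D1, D1):
            raise ValueError("sigma dimension mismatch")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-9):
            raise ValueError("sigma must be symmetric")

    @classmethod
    def from_data(cls, Z: np.ndarray, Y: np.ndarray, sigma: np.ndarray):
        """Build moments from raw design rows Z (n, p) and targets Y (n, D1)."""
        Z = np.asarray(Z, dtype=float)
        Y = np.asarray(Y, dtype=float)
        return cls(gram=Z.T @ Z, cross=Z.T @ Y, sigma=sigma)


def solve_map_weights(problem: RegressionProblem) -> np.ndarray:
    """Solve gram @ W + W @ sigma = cross for the MAP weights.

    The gram matrix is PSD and sigma is required PD, so the two spectra
    cannot sum to zero and the Sylvester system is nonsingular.
    """
    sig_eigs = np.linalg.eigvalsh(problem.sigma)
    if sig_eigs.min() <= 0:
        raise ValueError("noise covariance must be positive definite")
    W = solve_sylvester(problem.gram, problem.sigma, problem.cross)
    resid = problem.gram @ W + W @ problem.sigma - problem.cross
    scale = max(np.linalg.norm(problem.cross), 1.0)
    if not np.all(np.isfinite(W)) or np.linalg.norm(resid) > 1e-6 * scale:
        raise RuntimeError("Sylvester solve failed to reach residual tolerance")
    return W
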