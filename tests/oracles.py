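"""Independent reference computations used to check the package.

Everything here is deliberately naive — dense joint-Gaussian algebra,
brute-force series summation, textbook constant-parameter EM — and shares
no code path with the implementation it checks.
"""

import numpy as np
from scipy.stats import multivariate_normal


def wrapped_se_kernel(delta, period, lengthscale, variance, n_terms=50):
    """Periodic squared-exponential kernel by direct wrapped summation,
    normalized so k(0) = variance."""
    num = sum(np.exp(-(delta + m * period) ** 2 / (2 * lengthscale ** 2))
              for m in range(-n_terms, n_terms + 1))
    den = sum(np.exp(-(m * period) ** 2 / (2 * lengthscale ** 2))
              for m in range(-n_terms, n_terms + 1))
    return variance * num / den


def joint_gaussian(params, m0, Q1, Q, R):
    """Dense joint distribution of (x_{1:T}, y_{1:T}) for a time-varying
    linear-Gaussian state-space model.

    params: list of (A_t, b_t, C_t, d_t) for t = 0..T-1 (A_t, b_t drive the
    transition t -> t+1).  Returns (mean_x (T*D,), mean_y (T*N,),
    cov blocks Sxx, Sxy, Syy).
    """
    T = len(params)
    D = len(m0)
    N = params[0][2].shape[0]
    mean_x = np.zeros((T, D))
    mean_x[0] = m0
    for t in range(T - 1):
        A, b, _, _ = params[t]
        mean_x[t + 1] = A @ mean_x[t] + b
    Sxx = np.zeros((T, T, D, D))
    Sxx[0, 0] = Q1
    for t in range(T - 1):
        A = params[t][0]
        for s in range(t + 1):
            Sxx[t + 1, s] = A @ Sxx[t, s]
            Sxx[s, t + 1] = Sxx[t + 1, s].T
        Sxx[t + 1, t + 1] = A @ Sxx[t, t] @ A.T + Q
    Cs = [p[2] for p in params]
    ds = [p[3] for p in params]
    mean_y = np.stack([Cs[t] @ mean_x[t] + ds[t] for t in range(T)])

    def blk(M):  # (T,T,a,b) -> (T*a, T*b)
        return M.transpose(0, 2, 1, 3).reshape(T * M.shape[2], T * M.shape[3])

    Sxy = np.zeros((T, T, D, N))
    Syy = np.zeros((T, T, N, N))
    for t in range(T):
        for s in range(T):
            Sxy[t, s] = Sxx[t, s] @ Cs[s].T
            Syy[t, s] = Cs[t] @ Sxx[t, s] @ Cs[s].T
        Syy[t, t] += R
    return (mean_x.ravel(), mean_y.ravel(),
            blk(Sxx), blk(Sxy), blk(Syy))


def condition_joint(params, m0, Q1, Q, R, Y):
    """Posterior of the stacked latents given stacked observations, plus the
    marginal log-likelihood of Y, by dense Gaussian conditioning."""
    mx, my, Sxx, Sxy, Syy = joint_gaussian(params, m0, Q1, Q, R)
    yv = np.asarray(Y, dtype=float).ravel()
    sol = np.linalg.solve(Syy, yv - my)
    post_mean = mx + Sxy @ sol
    post_cov = Sxx - Sxy @ np.linalg.solve(Syy, Sxy.T)
    loglik = multivariate_normal(mean=my, cov=Syy, allow_singular=False).logpdf(yv)
    return post_mean, post_cov, float(loglik)


def lds_em_reference(trials, D, A0, b0, C0, m0v, Q1_0, Q0, R0, n_iter,
                     learn_C=True):
    """Textbook maximum-likelihood EM for a constant-parameter
    linear-Gaussian state-space model with bias terms.

    trials: list of (T, N) observation arrays.  Returns the per-iteration
    parameter dictionaries (after each M-step).
    """
    A, b, C, mv = A0.copy(), b0.copy(), C0.copy(), m0v.copy()
    Q1, Q, R = Q1_0.copy(), Q0.copy(), R0.copy()
    N = trials[0].shape[1]
    d = np.zeros(N)
    history = []
    for _ in range(n_iter):
        # E-step: per trial smoothed moments via dense conditioning
        stats = []
        for Y in trials:
            T = Y.shape[0]
            params = [(A, b, C, d)] * T
            pm, pc, _ = condition_joint(params, mv, Q1, Q, R, Y)
            mu = pm.reshape(T, D)
            V = np.array([pc[t * D:(t + 1) * D, t * D:(t + 1) * D]
                          for t in range(T)])
            S = np.array([pc[(t + 1) * D:(t + 2) * D, t * D:(t + 1) * D]
                          + np.outer(mu[t + 1], mu[t]) for t in range(T - 1)])
            stats.append((Y, mu, V, S))
        # M-step: dynamics [A b] and emissions C (d fixed at 0) from pooled
        # moments
        Da = D + 1
        Gd = np.zeros((Da, Da)); Hd = np.zeros((Da, D))
        Ge = np.zeros((D, D)); He = np.zeros((D, N))
        K = len(trials)
        for Y, mu, V, S in stats:
            T = Y.shape[0]
            for t in range(T):
                second = V[t] + np.outer(mu[t], mu[t])
                Ge += second
                He += np.outer(mu[t], Y[t])
                if t + 1 < T:
                    G = np.zeros((Da, Da))
                    G[:D, :D] = second; G[:D, D] = mu[t]
                    G[D, :D] = mu[t]; G[D, D] = 1
                    Gd += G
                    Hd += np.vstack([S[t].T, mu[t + 1][None, :]])
        Bd = np.linalg.solve(Gd, Hd).T            # (D, D+1)
        A, b = Bd[:, :D], Bd[:, D]
        if learn_C:
            C = np.linalg.solve(Ge, He).T         # (N, D)
        mv = sum(mu[0] for _, mu, _, _ in stats) / K
        # covariances with the new parameters
        Q1 = sum(V[0] + np.outer(mu[0] - mv, mu[0] - mv)
                 for _, mu, V, _ in stats) / K
        nQ = np.zeros((D, D)); nR = np.zeros((N, N)); ntr = 0; nob = 0
        for Y, mu, V, S in stats:
            T = Y.shape[0]
            for t in range(T):
                second = V[t] + np.outer(mu[t], mu[t])
                r = Y[t] - C @ mu[t]
                nR += np.outer(r, r) + C @ V[t] @ C.T
                nob += 1
                if t + 1 < T:
                    second1 = V[t + 1] + np.outer(mu[t + 1], mu[t + 1])
                    Bfull = np.hstack([A, b[:, None]])
                    Gt = np.zeros((Da, Da))
                    Gt[:D, :D] = second; Gt[:D, D] = mu[t]
                    Gt[D, :D] = mu[t]; Gt[D, D] = 1
                    Mx = np.hstack([S[t], mu[t + 1][:, None]])
                    nQ += (second1 - Bfull @ Mx.T - Mx @ Bfull.T
                           + Bfull @ Gt @ Bfull.T)
                    ntr += 1
        Q = nQ / ntr
        R = nR / nob
        history.append({"A": A.copy(), "b": b.copy(), "C": C.copy(),
                        "m": mv.copy(), "Q1": Q1.copy(), "Q": Q.copy(),
                        "R": R.copy()})
    return history
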