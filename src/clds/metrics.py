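"""Evaluation metrics: data reconstruction and co-smoothing.

*Data reconstruction* maps the posterior-mode latent trajectory through the
emission model.  *Co-smoothing* hides one neuron, infers the latents from
the remaining neurons only, predicts the hidden neuron's rate and scores it
with the coefficient of determination R^2; it is the primary held-out
metric for latent-variable models of neural data.
"""

from __future__ import annotations

import numpy as np

from .kalman import posterior_mode
from .model import CLDSModel, ParamFunction, Trial, TrialSet

__all__ = ["reconstruct", "r_squared", "cosmoothing", "drop_neuron"]


def reconstruct(model: CLDSModel, trial: Trial) -> np.ndarray:
    """Mean emission y_hat_t = C(u_t) x_hat_t + d(u_t) along the posterior
    mode given the full observations."""
    xhat = posterior_mode(model, trial)
    params = model.params_along(trial.u)
    return np.stack([p.C @ x + p.d for p, x in zip(params, xhat)])


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size < 2:
        raise ValueError("R^2 needs at least two points")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for zero-variance targets")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def drop_neuron(model: CLDSModel, i: int) -> CLDSModel:
    """Model with neuron i removed from the emission side: row i of C and
    entry i of d deleted, row and column i of R deleted."""
    N = model.N
    keep = [j for j in range(N) if j != i]
    basis = model.basis

    def C_red(u, _keep=keep):
        return model.C(basis, u)[_keep, :]

    def d_red(u, _keep=keep):
        return model.d(basis, u)[_keep]

    return CLDSModel(
        D=model.D, N=N - 1,
        A=model.A, b=model.b,
        C=ParamFunction((N - 1, model.D), func=C_red, name="C"),
        d=ParamFunction((N - 1,), func=d_red, name="d"),
        m=model.m,
        Q1=model.Q1, Q=model.Q,
        R=model.R[np.ix_(keep, keep)],
        basis=basis, domain=model.domain,
        fixed=model.fixed | {"C", "d"},
    )


def cosmoothing(model: CLDSModel, test_trials: TrialSet, top_k: int = 5):
    """Held-out single-neuron prediction R^2.

    For each of the ``top_k`` neurons with highest test-set variance
    (ties broken by neuron index): delete the neuron from the emission
    model, smooth the latents from the remaining neurons, predict the
    hidden neuron's rate via its own emission row, and compute R^2 against
    the hidden data concatenated across test trials.

    Returns (per_neuron, mean) where per_neuron maps neuron index -> R^2.
    """
    if model.N < 2:
        raise ValueError("co-smoothing needs at least two neurons")
    Y = np.concatenate([tr.y for tr in test_trials])
    variances = Y.var(axis=0)
    order = np.lexsort((np.arange(model.N), -variances))
    selected = order[: min(top_k, model.N)]

    per_neuron = {}
    for i in selected:
        reduced = drop_neuron(model, int(i))
        keep = [j for j in range(model.N) if j != i]
        true_col, pred_col = [], []
        for tr in test_trials:
            sub = Trial(y=tr.y[:, keep], u=tr.u)
            xhat = posterior_mode(reduced, sub)
            params = model.params_along(tr.u)
            pred = np.array([p.C[i, :] @ x + p.d[i]
                             for p, x in zip(params, xhat)])
            true_col.append(tr.y[:, i])
            pred_col.append(pred)
        per_neuron[int(i)] = r_squared(np.concatenate(true_col),
                                       np.concatenate(pred_col))
    return per_neuron, float(np.mean(list(per_neuron.values())))
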