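"""EM machinery: sufficient statistics, M-steps, monotonicity, and the
classical time-invariant-LDS reduction."""

import numpy as np
import pytest

from clds import em as _em
from clds.basis import FunctionWeights, build_basis, constant_domain, periodic_domain
from clds.estimator import CLDS, fit_em, select_hyperparameters
from clds.model import CLDSModel, ParamFunction, Trial, TrialSet
from clds.regression import RegressionProblem, solve_map_weights
from conftest import random_small_model
from oracles import condition_joint, lds_em_reference


def _trialset_from(model, u_seqs, seed=0):
    rng = np.random.default_rng(seed)
    trials = [model.sample_trial(u, rng) for u in u_seqs]
    return TrialSet(trials=trials, domain=model.basis.domain)


def test_sufficient_stats_additive_over_identical_trials(rng):
    model = random_small_model(rng)
    u = rng.uniform(0, 2 * np.pi, size=10)
    tr = model.sample_trial(u, 3)
    single = TrialSet([tr], model.basis.domain)
    triple = TrialSet([tr, tr, tr], model.basis.domain)
    s1 = _em.e_step(model, single)
    s3 = _em.e_step(model, triple)
    for name in ("dyn_gram", "dyn_cross", "em_gram", "em_cross",
                 "init_gram", "init_cross"):
        assert np.allclose(getattr(s3, name), 3 * getattr(s1, name),
                           rtol=1e-10)
    assert s3.total_loglik == pytest.approx(3 * s1.total_loglik, rel=1e-10)


def test_noise_free_stats_equal_empirical_latent_moments(rng):
    model = random_small_model(rng)
    model.Q = 1e-12 * np.eye(model.D)
    model.R = 1e-12 * np.eye(model.N)
    model.Q1 = 1e-12 * np.eye(model.D)
    u = rng.uniform(0, 2 * np.pi, size=12)
    tr = model.sample_trial(u, 5)
    ts = TrialSet([tr], model.basis.domain)
    stats = _em.e_step(model, ts)
    # with a degenerate posterior the stats are plain moments of the truth
    Phi = model.basis.evaluate_many(tr.u)
    D = model.D
    dyn_gram = np.zeros_like(stats.dyn_gram)
    dyn_cross = np.zeros_like(stats.dyn_cross)
    for t in range(11):
        xt = np.concatenate([tr.x[t], [1.0]])
        dyn_gram += np.kron(np.outer(Phi[t], Phi[t]), np.outer(xt, xt))
        dyn_cross += np.kron(Phi[t][:, None], np.outer(xt, tr.x[t + 1]))
    assert np.allclose(stats.dyn_gram, dyn_gram, rtol=1e-4, atol=1e-6)
    assert np.allclose(stats.dyn_cross, dyn_cross, rtol=1e-4, atol=1e-6)


def test_scalar_two_step_stats_match_joint_oracle(rng):
    model = random_small_model(rng, D=1, N=1, L=3)
    u = np.array([0.4, 2.2])
    tr = model.sample_trial(u, 7)
    params = [(p.A, p.b, p.C, p.d) for p in model.params_along(u)]
    pm, pc, _ = condition_joint(params, model.params_at([u[0]]).m,
                                model.Q1, model.Q, model.R, tr.y)
    e0, e1 = pm
    v00, v01, v11 = pc[0, 0], pc[0, 1], pc[1, 1]
    Phi = model.basis.evaluate_many(tr.u)
    stats = _em.e_step(model, TrialSet([tr], model.basis.domain))
    G0 = np.array([[v00 + e0 ** 2, e0], [e0, 1.0]])
    assert np.allclose(stats.dyn_gram,
                       np.kron(np.outer(Phi[0], Phi[0]), G0), rtol=1e-8)
    cross0 = np.array([[v01 + e0 * e1], [e1]])
    assert np.allclose(stats.dyn_cross,
                       np.kron(Phi[0][:, None], cross0), rtol=1e-8)
    assert np.allclose(stats.init_cross, np.outer(Phi[0], [e0]), rtol=1e-8)


def test_zero_stats_give_zero_weights():
    L, D = 4, 2
    p = (D + 1) * L
    wA, wb = _em.m_step_dynamics(
        _em.SufficientStats(
            dyn_gram=np.zeros((p, p)), dyn_cross=np.zeros((p, D)),
            em_gram=None, em_cross=None,
            init_gram=np.zeros((L, L)), init_cross=np.zeros((L, D)),
            n_transitions=0, n_observations=0),
        Q=np.eye(D), D=D, L=L)
    assert np.allclose(wA.W, 0.0) and np.allclose(wb.W, 0.0)


def test_initial_state_update_is_shrunk_average(rng):
    # constant basis: m update is the ridge-shrunk mean of E[x_1]
    L, D, K = 1, 2, 5
    phi0 = 2.0  # constant feature value sqrt(sigma^2)
    x1s = rng.standard_normal((K, D))
    Q1 = np.eye(D)
    gram = K * phi0 ** 2 * np.eye(1)
    cross = phi0 * x1s.sum(axis=0)[None, :]
    stats = _em.SufficientStats(
        dyn_gram=np.zeros((2, 2)), dyn_cross=np.zeros((2, D)),
        em_gram=None, em_cross=None,
        init_gram=gram, init_cross=cross,
        n_transitions=0, n_observations=0)
    wm = _em.m_step_initial(stats, Q1, D)
    m_val = phi0 * wm.W[0]
    expected = x1s.mean(axis=0) * (K * phi0 ** 2) / (K * phi0 ** 2 + 1.0)
    assert np.allclose(m_val, expected, rtol=1e-10)


def _run_package_em(model, trialset, n_iter):
    """Drive the package's EM updates in the estimator's order, recording
    parameters after each iteration."""
    D, N, L = model.D, model.N, model.basis.L
    history = []
    u0 = trialset[0].u[0]
    for _ in range(n_iter):
        stats = _em.e_step(model, trialset)
        wA, wb = _em.m_step_dynamics(stats, model.Q, D, L)
        wC, _ = _em.m_step_emissions(stats, model.R, D, N, L, True, False)
        wm = _em.m_step_initial(stats, model.Q1, D)
        model.A = ParamFunction((D, D), weights=wA, name="A")
        model.b = ParamFunction((D,), weights=wb, name="b")
        model.C = ParamFunction((N, D), weights=wC, name="C")
        model.m = ParamFunction((D,), weights=wm, name="m")
        model.Q1, model.Q, model.R = _em.update_covariances(
            model, trialset, stats, floor=1e-12)
        p = model.params_at(u0)
        history.append({"A": p.A, "b": p.b, "C": p.C, "m": p.m,
                        "Q1": model.Q1, "Q": model.Q, "R": model.R})
    return history


def _constant_basis_model(rng, D, N, variance=1e8):
    basis = build_basis(constant_domain(variance=variance), 1)
    phi0 = np.sqrt(variance)
    A0 = 0.6 * np.eye(D) + 0.1 * rng.standard_normal((D, D))
    b0 = rng.standard_normal(D) * 0.3
    C0 = rng.standard_normal((N, D))
    m0 = rng.standard_normal(D) * 0.2
    as_w = lambda M, d2, lab: ParamFunction(
        M.shape if M.ndim > 1 else (M.shape[0],),
        weights=FunctionWeights(
            D1=M.shape[0], D2=d2,
            W=(M.reshape(M.shape[0], d2).T / phi0).reshape(d2, M.shape[0]),
            label=lab), name=lab)
    model = CLDSModel(
        D=D, N=N,
        A=as_w(A0, D, "A"), b=as_w(b0, 1, "b"), C=as_w(C0, D, "C"),
        d=ParamFunction.zero((N,), name="d"),
        m=as_w(m0, 1, "m"),
        Q1=np.eye(D), Q=0.3 * np.eye(D), R=0.5 * np.eye(N),
        basis=basis, fixed=frozenset({"d"}))
    return model, (A0, b0, C0, m0)


@pytest.mark.parametrize("seed", [0, 1])
def test_constant_basis_em_matches_textbook_lds_em(seed):
    """With a condition-independent basis and a diffuse weight prior, every
    EM update must coincide with classical linear-Gaussian EM."""
    rng = np.random.default_rng(seed)
    D, N = 2, 3
    model, (A0, b0, C0, m0) = _constant_basis_model(rng, D, N)
    u_seqs = [np.zeros(12) for _ in range(3)]
    ts = _trialset_from(model, u_seqs, seed=seed)
    ref = lds_em_reference([tr.y for tr in ts], D, A0, b0, C0, m0,
                           np.eye(D), 0.3 * np.eye(D), 0.5 * np.eye(N),
                           n_iter=4)
    ours = _run_package_em(model, ts, n_iter=4)
    for it in range(4):
        for key in ("A", "b", "C", "m", "Q1", "Q", "R"):
            assert np.allclose(ours[it][key], ref[it][key], rtol=1e-6,
                               atol=1e-8), (it, key)


def test_fit_objective_monotone_on_ring(small_ring):
    _, trialset, _ = small_ring
    est = CLDS(n_latents=2, domain=trialset.domain, n_basis=9, max_iter=25,
               tol=0.0, random_state=1)
    est.fit(trialset)
    obj = np.asarray(est.trace_.objectives)
    assert np.all(np.diff(obj) >= -1e-8 * np.abs(obj[:-1]))


def test_zero_iterations_return_prior_initialization(small_ring):
    _, trialset, _ = small_ring
    est1 = CLDS(domain=trialset.domain, n_basis=9, max_iter=0, random_state=3)
    est2 = CLDS(domain=trialset.domain, n_basis=9, max_iter=0, random_state=3)
    est1.fit(trialset)
    est2.fit(trialset)
    assert np.array_equal(est1.model_.A.weights.W, est2.model_.A.weights.W)
    assert est1.n_iter_ == 0
    assert len(est1.trace_.objectives) == 1
    # the initialization is an actual prior draw rescaled for stability
    est3 = CLDS(domain=trialset.domain, n_basis=9, max_iter=0, random_state=4)
    est3.fit(trialset)
    assert not np.array_equal(est1.model_.b.weights.W,
                              est3.model_.b.weights.W)


def test_hyperparameter_selection_single_point_and_tie_break(small_ring):
    _, trialset, _ = small_ring
    grid = [{"n_basis": 7, "lengthscale": 1.0}]
    best, table = select_hyperparameters(trialset, grid, seed=0,
                                         max_iter=3, top_k=2)
    assert best is grid[0]
    assert len(table) == 1
    dup = [{"n_basis": 7, "lengthscale": 1.0},
           {"n_basis": 7, "lengthscale": 1.0}]
    best2, table2 = select_hyperparameters(trialset, dup, seed=0,
                                           max_iter=3, top_k=2)
    assert best2 is dup[0]
    assert np.allclose(table2["cosmoothing_r2"].iloc[0],
                       table2["cosmoothing_r2"].iloc[1])
    with pytest.raises(ValueError):
        select_hyperparameters(trialset, [], seed=0)


def test_fit_em_wrapper_returns_model_and_trace(small_ring):
    _, trialset, _ = small_ring
    model, trace = fit_em(trialset, n_latents=2, n_basis=7, max_iter=2,
                          random_state=0)
    assert model.D == 2 and trace.n_iter <= 2
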