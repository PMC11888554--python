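"""Fourier-feature basis: kernel approximation, layout, prior sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clds.basis import (ConditionDomain, DomainDimension, InvalidDomainError,
                        OutOfDomainError, build_basis, constant_domain,
                        evaluate_basis, evaluate_function, periodic_domain,
                        project_function, sample_function)
from oracles import wrapped_se_kernel


@pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0])
def test_periodic_kernel_matches_wrapped_se_oracle(kappa):
    basis = build_basis(periodic_domain(0, 2 * np.pi, kappa, 1.0), 25)
    g = np.linspace(0, 2 * np.pi, 40, endpoint=False)
    K = basis.kernel(g, g)
    Ko = wrapped_se_kernel(g[:, None] - g[None, :], 2 * np.pi, kappa, 1.0)
    assert np.abs(K - Ko).max() < 1e-3


def test_constant_basis_limit_returns_prior_variance():
    # a single interval feature with infinite length-scale: k(u, u') = sigma^2
    basis = build_basis(constant_domain(-1, 1, variance=2.5), 1)
    g = np.linspace(-1, 1, 9)
    K = basis.kernel(g, g)
    assert np.allclose(K, 2.5, atol=1e-12)
    assert np.allclose(evaluate_basis(basis, [0.3]), [np.sqrt(2.5)])


def test_discrete_embedded_levels_follow_se_correlation():
    # correlation between embedded levels 0 and 1 at kappa = 0.5
    dom = ConditionDomain((DomainDimension(
        "discrete_embedded", 0.0, 1.0, 0.5, 1.0, levels=(0.0, 1.0)),))
    basis = build_basis(dom, 41)
    k01 = basis.kernel(np.array([0.0]), np.array([1.0]))[0, 0]
    k00 = basis.kernel(np.array([0.0]), np.array([0.0]))[0, 0]
    assert k01 / k00 == pytest.approx(np.exp(-1 / (2 * 0.5 ** 2)), rel=1e-4)


def test_interval_kernel_approximates_plain_se():
    dom = ConditionDomain((DomainDimension("interval", 0.0, 4.0, 0.5, 1.3),))
    basis = build_basis(dom, 41)
    g = np.linspace(0, 4, 25)
    K = basis.kernel(g, g)
    Ko = 1.3 * np.exp(-((g[:, None] - g[None, :]) ** 2) / (2 * 0.5 ** 2))
    assert np.abs(K - Ko).max() < 1e-3


def test_periodic_evaluation_wraps_and_is_deterministic():
    basis = build_basis(periodic_domain(), 9)
    u = np.array([1.234])
    v1 = evaluate_basis(basis, u)
    v2 = evaluate_basis(basis, u + 2 * np.pi)
    assert np.allclose(v1, v2, atol=1e-12)
    assert np.array_equal(v1, evaluate_basis(basis, u))
    assert len(v1) == basis.L == 9
    # self-consistency: phi(u).phi(u) equals the kernel diagonal
    assert v1 @ v1 == pytest.approx(basis.kernel(u, u)[0, 0], abs=1e-14)


def test_out_of_domain_and_invalid_hyperparameters_raise():
    dom = ConditionDomain((DomainDimension("interval", 0.0, 1.0, 0.3),))
    basis = build_basis(dom, 5)
    with pytest.raises(OutOfDomainError):
        evaluate_basis(basis, [1.5])
    dd = ConditionDomain((DomainDimension(
        "discrete_embedded", 0.0, 1.0, 0.3, levels=(0.0, 1.0)),))
    with pytest.raises(OutOfDomainError):
        evaluate_basis(build_basis(dd, 5), [0.37])
    with pytest.raises(InvalidDomainError):
        DomainDimension("interval", 0.0, 1.0, -1.0)
    with pytest.raises(InvalidDomainError):
        DomainDimension("interval", 0.0, 1.0, 1.0, variance=0.0)
    with pytest.raises(InvalidDomainError):
        DomainDimension("interval", 2.0, 1.0, 1.0)


def test_sample_function_layout_and_seeding(rng):
    basis = build_basis(periodic_domain(), 4)
    w1 = sample_function(basis, 2, 3, np.random.default_rng(5))
    w2 = sample_function(basis, 2, 3, np.random.default_rng(5))
    assert w1.W.shape == (12, 2)
    assert np.array_equal(w1.W, w2.W)


def test_sampled_function_variance_matches_kernel(rng):
    # Monte-Carlo prior variance of a scalar function at a fixed point
    basis = build_basis(periodic_domain(lengthscale=0.8), 15)
    u = np.array([2.0])
    k_uu = basis.kernel(u, u)[0, 0]
    n = 10_000
    phi = evaluate_basis(basis, u)
    vals = np.array([
        evaluate_function(sample_function(basis, 1, 1, rng), basis, u).item()
        for _ in range(200)
    ])
    # 200 full draws check the evaluation path; the 10^4-sample check uses
    # the weight-space representation directly (same distribution)
    W = rng.standard_normal((n, basis.L))
    samples = W @ phi
    var = samples.var(ddof=1)
    se = k_uu * np.sqrt(2.0 / (n - 1))
    assert abs(var - k_uu) < 3 * se
    assert abs(vals.var(ddof=1) - k_uu) < 4 * k_uu * np.sqrt(2.0 / 199)


def test_kronecker_identity_between_function_and_features(rng):
    basis = build_basis(periodic_domain(), 7)
    w = sample_function(basis, 3, 2, rng)
    u = np.array([0.77])
    phi = evaluate_basis(basis, u)
    X = rng.standard_normal((2, 4))
    lhs = evaluate_function(w, basis, u) @ X
    rhs = w.W.T @ np.kron(phi[:, None], X)
    assert np.allclose(lhs, rhs, atol=1e-12)


def test_zero_and_constant_weight_functions(rng):
    basis = build_basis(periodic_domain(), 5)
    from clds.basis import FunctionWeights
    w0 = FunctionWeights(D1=2, D2=2, W=np.zeros((10, 2)))
    assert np.allclose(evaluate_function(w0, basis, [1.0]), 0.0)
    cbasis = build_basis(constant_domain(variance=1.0), 1)
    wc = sample_function(cbasis, 2, 2, rng)
    M1 = evaluate_function(wc, cbasis, [-0.5])
    M2 = evaluate_function(wc, cbasis, [0.9])
    assert np.allclose(M1, M2, atol=1e-14)


def test_tensor_product_kernel_is_product_of_marginals():
    dims = (
        DomainDimension("periodic", 0.0, 2 * np.pi, 1.0, 1.5),
        DomainDimension("interval", 0.0, 1.0, 0.4, 0.8),
    )
    dom2 = ConditionDomain(dims)
    b2 = build_basis(dom2, (9, 7))
    assert b2.L == 63
    b_per = build_basis(ConditionDomain(dims[:1]), 9)
    b_int = build_basis(ConditionDomain(dims[1:]), 7)
    u = np.array([1.2, 0.3])
    v = np.array([4.0, 0.9])
    k2 = b2.kernel(u[None, :], v[None, :])[0, 0]
    k_marg = (b_per.kernel(u[:1], v[:1])[0, 0]
              * b_int.kernel(u[1:], v[1:])[0, 0])
    assert k2 == pytest.approx(k_marg, rel=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 2 * np.pi - 1e-9), min_size=2, max_size=8),
       st.floats(0.3, 3.0))
def test_gram_matrix_is_positive_semidefinite(points, kappa):
    basis = build_basis(periodic_domain(lengthscale=kappa), 11)
    G = basis.kernel(np.array(points), np.array(points))
    assert np.linalg.eigvalsh(G).min() >= -1e-10


def test_periodic_kernel_is_stationary():
    basis = build_basis(periodic_domain(lengthscale=0.7), 13)
    g = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    K = basis.kernel(g, g)
    # entries with equal wrapped distance must coincide
    d = np.minimum(np.abs(g[:, None] - g[None, :]),
                   2 * np.pi - np.abs(g[:, None] - g[None, :]))
    for dist in np.unique(np.round(d, 9)):
        vals = K[np.isclose(d, dist)]
        assert np.ptp(vals) < 1e-10


def test_projection_of_analytic_ring_dynamics_is_accurate():
    from clds.ring import RingConfig, make_ring_model
    model = make_ring_model(RingConfig())
    basis = build_basis(model.domain, 25)
    grid = np.linspace(0, 2 * np.pi, 128, endpoint=False)
    w = project_function(lambda th: model.A(None, [th]), basis, 2, 2, grid)
    errs = [np.abs(evaluate_function(w, basis, [th]) - model.A(None, [th])).max()
            for th in np.linspace(0, 2 * np.pi, 57)]
    assert max(errs) < 1e-3
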