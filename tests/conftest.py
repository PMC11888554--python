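import numpy as np
import pytest

from clds.basis import build_basis, periodic_domain, sample_function
from clds.model import CLDSModel, ParamFunction
from clds.ring import RingConfig, generate_dataset


def random_spd(rng, n, scale=1.0):
    M = rng.standard_normal((n, n))
    return scale * (M @ M.T / n + np.eye(n))


def random_small_model(rng, D=2, N=3, L=5, stable_scale=0.6):
    """Weight-parameterized CLDS on a periodic domain with tempered dynamics."""
    domain = periodic_domain(0.0, 2 * np.pi, lengthscale=1.0, variance=1.0)
    basis = build_basis(domain, L)
    wA = sample_function(basis, D, D, rng, label="A")
    wA.W *= stable_scale / np.sqrt(L)
    model = CLDSModel(
        D=D, N=N,
        A=ParamFunction((D, D), weights=wA, name="A"),
        b=ParamFunction((D,), weights=sample_function(basis, D, 1, rng, "b"), name="b"),
        C=ParamFunction((N, D), weights=sample_function(basis, N, D, rng, "C"), name="C"),
        d=ParamFunction((N,), weights=sample_function(basis, N, 1, rng, "d"), name="d"),
        m=ParamFunction((D,), weights=sample_function(basis, D, 1, rng, "m"), name="m"),
        Q1=random_spd(rng, D, 0.5),
        Q=random_spd(rng, D, 0.3),
        R=random_spd(rng, N, 0.4),
        basis=basis,
        fixed=frozenset(),
    )
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ring():
    """A small ring-attractor dataset shared by fast tests."""
    cfg = RingConfig(K=6, T=60, seed=7)
    trialset, truth = generate_dataset(cfg)
    return cfg, trialset, truth
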