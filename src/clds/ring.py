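"""Synthetic head-direction ring attractor.

The ground truth is itself a CLDS: with heading angle theta as the
condition, the latent dynamics form a leaky line attractor whose
orientation rotates with theta,

    A(theta) = (1 - eps) e2(theta) e2(theta)^T,   b(theta) = e1(theta),

where e1 = (cos theta, sin theta) points at the ring and e2 is the tangent.
The fixed point of the local linear system is exactly e1(theta) — the unit
ring — and the eigenvalues of A are {1 - eps, 0} for every heading.  Each
neuron reads out the e1-component of the latent through a raised-cosine
bump tuning curve centered on its preferred angle.  Heading follows a
wrapped Gaussian random walk.  Parameter functions are encoded analytically
(not via basis weights), so the ground truth carries no approximation error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import periodic_domain
from .model import CLDSModel, ParamFunction, Trial, TrialSet

__all__ = ["RingConfig", "make_ring_model", "simulate_heading",
           "generate_dataset"]

TWO_PI = 2.0 * np.pi


@dataclass
class RingConfig:
    """Study conditions for the synthetic head-direction experiment.

    Trial length, neuron count and the heading step size follow the
    simulated head-direction setup (T=100, 10 neurons, step s.d. 0.5 rad);
    the leak, noise magnitudes, trial count and bump sharpness are package
    defaults chosen to give a clearly attracting but noisy ring.
    """

    epsilon: float = 0.1          # leak of the line attractor, in (0, 1)
    n_neurons: int = 10
    T: int = 100
    K: int = 20
    heading_step_sd: float = 0.5  # radians per step
    obs_noise_sd: float = 0.1
    dyn_noise_sd: float = 0.05
    bump_sharpness: float = 2.0   # exponent of the raised-cosine tuning bump
    preferred_angles: np.ndarray | None = None
    lengthscale: float = 1.0      # kernel hyperparameters attached to the
    variance: float = 1.0         # domain for downstream fitting
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")
        if self.heading_step_sd < 0 or self.obs_noise_sd < 0 or self.dyn_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.preferred_angles is None:
            self.preferred_angles = np.arange(self.n_neurons) * TWO_PI / self.n_neurons
        self.preferred_angles = np.mod(np.asarray(self.preferred_angles, float), TWO_PI)
        if len(self.preferred_angles) != self.n_neurons:
            raise ValueError("need one preferred angle per neuron")


def e1(theta):
    return np.array([np.cos(theta), np.sin(theta)])


def e2(theta):
    return np.array([-np.sin(theta), np.cos(theta)])


def tuning_amplitudes(cfg: RingConfig, theta: float) -> np.ndarray:
    """Raised-cosine bump r_i(theta) = max(0, cos(theta - theta_i))^p."""
    return np.maximum(0.0, np.cos(theta - cfg.preferred_angles)) ** cfg.bump_sharpness


def make_ring_model(cfg: RingConfig) -> CLDSModel:
    """Analytic ground-truth CLDS (D=2) for the ring attractor."""
    eps = cfg.epsilon
    floor = 1e-8  # keep covariances PD even in the noise-free setting

    def A_fn(theta):
        v = e2(theta)
        return (1.0 - eps) * np.outer(v, v)

    def C_fn(theta):
        return np.outer(tuning_amplitudes(cfg, theta), e1(theta))

    N = cfg.n_neurons
    return CLDSModel(
        D=2, N=N,
        A=ParamFunction((2, 2), func=A_fn, name="A"),
        b=ParamFunction((2,), func=lambda th: e1(th), name="b"),
        C=ParamFunction((N, 2), func=C_fn, name="C"),
        d=ParamFunction.zero((N,), name="d"),
        m=ParamFunction.zero((2,), name="m"),
        Q1=np.eye(2),
        Q=max(cfg.dyn_noise_sd ** 2, floor) * np.eye(2),
        R=max(cfg.obs_noise_sd ** 2, floor) * np.eye(N),
        basis=None,
        domain=periodic_domain(0.0, TWO_PI, cfg.lengthscale, cfg.variance),
        fixed=frozenset({"d"}),
    )


def simulate_heading(T: int, step_sd: float, rng) -> np.ndarray:
    """Wrapped Gaussian random-walk heading: theta_t ~ N(theta_{t-1}, sd^2),
    theta_1 uniform on [0, 2*pi)."""
    rng = np.random.default_rng(rng)
    theta = np.empty(T)
    theta[0] = rng.uniform(0.0, TWO_PI)
    steps = rng.normal(0.0, step_sd, size=T - 1) if T > 1 else np.empty(0)
    theta[1:] = theta[0] + np.cumsum(steps)
    return np.mod(theta, TWO_PI)


def generate_dataset(cfg: RingConfig):
    """Simulate K trials; returns (TrialSet, ground-truth model).

    Each trial stores its true latent trajectory in ``Trial.x``.
    """
    model = make_ring_model(cfg)
    rng = np.random.default_rng(cfg.seed)
    trials = []
    for _ in range(cfg.K):
        theta = simulate_heading(cfg.T, cfg.heading_step_sd, rng)
        trials.append(model.sample_trial(theta, rng))
    ts = TrialSet(trials=trials, domain=model.domain,
                  metadata={"generator": "ring_attractor",
                            "epsilon": cfg.epsilon})
    return ts, model
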