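# clds — conditionally linear dynamical systems

`clds` models multi-trial neural population recordings with latent linear
dynamical systems whose parameters are smooth nonlinear functions of observed
experimental covariates (head direction, reach angle, task epoch, ...).
Conditioned on the covariate sequence the model is linear-Gaussian, so latent
inference is exact Kalman smoothing and learning is closed-form EM — yet as
the covariate moves, the family of local linear systems traces out genuinely
nonlinear dynamical structure such as ring attractors. The package is aimed
at systems/computational neuroscientists who want interpretable,
data-efficient models of condition-dependent population dynamics.

## Model

With observations `y_t ∈ R^N`, latents `x_t ∈ R^D` and covariates `u_t`:

```
x_1     ~  N(m(u_1), Q1)
x_{t+1} =  A(u_t) x_t + b(u_t) + ε_t,     ε_t ~ N(0, Q)
y_t     =  C(u_t) x_t + d(u_t) + ω_t,     ω_t ~ N(0, R)
```

Every parameter function M ∈ {A, b, C, d, m} has the finite basis expansion

```
M_ij(u) = Σ_{ℓ=1..L} w_ℓ^(ij) φ_ℓ(u),      w_ℓ^(ij) ~ iid N(0, 1),
```

where the fixed Fourier features φ_ℓ are scaled so that the implied kernel
`φ(u)·φ(u′)` approximates a squared-exponential GP kernel with variance σ²
and length-scale κ (its periodic wrap on angular covariates). Writing
`z = φ(u) ⊗ x`, MAP estimation of the weights given latent moments is
multi-output ridge regression whitened by the noise covariance Σ — the
solution of the Sylvester equation `(ZᵀZ) W + W Σ = ZᵀY` — so every EM
M-step is a single linear solve. Post-fit, each condition indexes an
ordinary linear system: fixed points solve `(I − A(u)) x* = b(u)` exactly,
stability is the spectrum of `A(u)`, tuning curves are `C_i(u) E[x|u]`, and
the condition-marginalized "composite" vector field visualizes the global
nonlinear flow.

## Worked example

Simulate the synthetic head-direction ring attractor (heading follows a
wrapped random walk; the latent system leaks onto a rotating line attractor
whose fixed point is the unit ring), fit a CLDS with the emission map frozen
to ground truth, and evaluate held-out neurons:

```python
import numpy as np
from clds import CLDS, RingConfig, generate_dataset, fixed_points, cosmoothing
from clds.ring import e1, tuning_amplitudes

cfg = RingConfig(K=20, T=100, seed=0)
trials, truth = generate_dataset(cfg)
perm = np.random.default_rng(0).permutation(cfg.K)
train, test = trials[perm[4:]], trials[perm[:4]]

est = CLDS(n_latents=2, domain=trials.domain, n_basis=13, max_iter=100,
           fixed_C=lambda th: np.outer(tuning_amplitudes(cfg, th), e1(th)),
           random_state=0)
est.fit(train)
print(f"EM converged after {est.n_iter_} iterations, loglik = {est.loglik_:.1f}")

per_neuron, mean_r2 = cosmoothing(est.model_, test, top_k=5)
print(f"co-smoothing R^2 (top-5 neurons): mean = {mean_r2:.3f}")

grid = np.linspace(0, 2 * np.pi, 8, endpoint=False)
fp = fixed_points(est.model_, grid)
print("fixed-point radii:", np.round(np.linalg.norm(fp.points, axis=1), 3))
print("leading |eigenvalue| of A(theta):", np.round(np.abs(fp.eigvals[:, 0]), 3))
```

Output:

```
EM converged after 77 iterations, loglik = 13794.0
co-smoothing R^2 (top-5 neurons): mean = 0.928
fixed-point radii: [0.993 0.991 1.014 1.    0.992 0.999 1.004 1.007]
leading |eigenvalue| of A(theta): [0.909 0.902 0.908 0.896 0.904 0.907 0.893 0.894]
```

Co-smoothing hides one neuron, infers latents from the rest, and scores the
hidden neuron's predicted rate with R² — here ≈ 0.93 per held-out neuron.
The recovered fixed points lie on the unit circle (radii ≈ 1) and the
leading eigenvalue of `A(θ)` sits at `1 − ε = 0.9` for every heading: the
fitted model has rediscovered the ring attractor from spike-rate data.

`CLDS` follows the scikit-learn estimator protocol (`get_params`,
`set_params`, `fit`, `predict`, `score`), so it composes with sklearn model
selection; `clds.select_hyperparameters` grid-searches {L, κ, σ} by held-out
co-smoothing on an 80/20 trial split.

## Command line

```
clds simulate --config run.yaml --out data.h5 [--model-out truth.h5]
clds fit      --config run.yaml --data data.h5 --out model.h5 [--trace-out trace.csv]
clds eval     --config run.yaml --model model.h5 --data data.h5 --out scores.csv
clds analyze  --model model.h5 --data data.h5 --out-prefix results/analysis
clds select   --config run.yaml --data data.h5 --out table.csv --n-basis 9 --n-basis 13 --lengthscale 0.5 --lengthscale 1.0
```

The YAML config has four strictly validated sections — `model`
(`n_latents`, `n_basis`, optional per-dimension `basis` list with `kind`
∈ {periodic, interval, discrete_embedded}, `lower`, `upper`, `lengthscale`,
`variance`, `levels`), `em` (`max_iter`, `tol`, `seed`), `data` (`path` or
`simulate` with the `RingConfig` fields), and `eval` (`top_k`,
`test_fraction`, `split_seed`). Trial sets and models are HDF5 containers
(`/trials/<k>/y|u|x`, domain and metadata as JSON attributes); long-format
CSV import (`trial, t, y0.., u0..` columns) is provided for user data.

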