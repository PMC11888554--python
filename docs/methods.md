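# Methods

## Model

A conditionally linear dynamical system (CLDS) is a latent linear-Gaussian
state-space model whose parameters are functions of an observed covariate
process `u_t` taking values in a condition space `U`:

```
x_1     ~  N(m(u_1), Q1)
x_{t+1} =  A(u_t) x_t + b(u_t) + ε_t,     ε_t ~ N(0, Q)       (dynamics)
y_t     =  C(u_t) x_t + d(u_t) + ω_t,     ω_t ~ N(0, R)       (emissions)
```

The key assumptions are (i) the covariates are fully observed at every time
step, (ii) noise is Gaussian and homoscedastic across conditions (only the
deterministic maps vary with `u`), and (iii) the parameter functions vary
smoothly over `U`. Conditioned on `u_{1:T}` the model is an ordinary
time-varying linear-Gaussian state-space model, which is what makes both
inference and interpretation exact.

## Approximate GP priors via Fourier features

Each entry of each parameter function carries a truncated basis expansion
`M_ij(u) = Σ_ℓ w_ℓ^(ij) φ_ℓ(u)` with standard-normal weights. The features
are chosen so the implied finite-rank kernel `k(u,u′) = φ(u)·φ(u′)`
approximates a squared-exponential (SE) kernel with variance σ² and
length-scale κ:

- **Periodic dimensions** use the real Fourier pairs
  `{1, cos(2πℓu/P), sin(2πℓu/P)}` scaled by the square roots of the cosine
  coefficients of the *wrapped* SE kernel (the periodic summation of the SE
  over the period `P`, normalized so `k(0) = σ²`). By Poisson summation the
  coefficients are proportional to `exp(−κ²(2πℓ/P)²/2)`, so the truncated
  kernel converges to the wrapped SE extremely fast: at `κ = 1`, `P = 2π`,
  `L = 25` the max-abs kernel error on a dense grid is below 1e−15.
- **Interval dimensions** reuse the same construction on a padded surrogate
  period. The padding per side is `max(0.25·width, 3κ)`: a fixed fractional
  pad alone is insufficient when κ is comparable to the interval width,
  since the wrap-around term `exp(−(P−Δ)²/2κ²)` would contaminate the
  kernel at large in-interval distances. With the κ-dependent pad the
  surrogate kernel matches the plain SE to ~1e−3 or better.
- **Discrete conditions** (e.g. a task-epoch indicator) are embedded on a
  continuous interval, so κ controls the correlation between levels:
  `k(0,1)/k(0,0) = exp(−1/(2κ²))` for unit-separated levels. Admissible
  levels are validated; other values are rejected.
- **Multi-dimensional conditions** take the tensor product of per-dimension
  features, i.e. a product kernel; the total basis size is the product of
  per-dimension truncation levels.
- `κ = ∞` (the `constant_domain` helper with `L = 1`) collapses the basis
  to a constant, recovering a time-invariant LDS; a linear-kernel prior is
  obtained by supplying identity features and is not specially coded.

σ² is absorbed into the feature scales so that weights are always unit
normal — the weight prior never needs per-function tuning. Weight matrices
are stored basis-major: `W ∈ R^{D2·L × D1}` with row `ℓ·D2 + j` holding
basis function ℓ for input coordinate j, which is the layout for which
`M(u) = Wᵀ(φ(u) ⊗ I)` and `M(u)x = Wᵀ(φ(u) ⊗ x)` hold under the standard
Kronecker ordering.

## Inference and learning

**E-step.** Per trial, a Kalman filter with per-step parameters
`F(u_t)` (Joseph-form covariance updates plus symmetrization each step)
accumulates the exact marginal log-likelihood from the innovation
densities; a Rauch–Tung–Striebel backward pass yields smoothed means,
covariances, and adjacent second moments `E[x_{t+1} x_tᵀ]`. Filter/smoother
moments and the log-likelihood are tested to 1e−8 against dense
joint-Gaussian conditioning on random small instances.

**M-steps.** In the expanded feature space `z = φ(u) ⊗ x`, the MAP weights
of each parameter function solve the Sylvester equation
`(Σ E[z zᵀ]) W + W Σ_noise = Σ E[z yᵀ]` (Bartels–Stewart via
`scipy.linalg.solve_sylvester`, operating on accumulated expected moments —
the design matrix is never materialized). The ridge identity in the
isotropic case and agreement with direct numerical maximization of the
penalized likelihood in the general case are both tested. `A` and `b` are
updated jointly by augmenting the latent with a constant 1 before feature
expansion, and likewise `C` and `d` when the output baseline is learned;
the identity matrix in the ridge special case has the weight-row dimension
`D2·L`, as required by the stationarity condition of the penalized
objective. Noise covariances `{Q1, Q, R}` are then updated from expected
residual outer products under the freshly updated functions. Because the
weight updates condition on the old covariances and the covariance updates
condition on the new weights, the procedure is expectation/conditional
maximization; each conditional step is an exact maximizer, so the penalized
marginal log-likelihood (log-likelihood plus `−½Σ‖W‖²_F` over learned
functions) is non-decreasing, which the tests assert at 1e−8 slack on
every iteration of every seeded run.

**Initialization.** Parameter functions start at draws from their GP
priors. One adjustment is applied: if the sampled dynamics map has spectral
radius above 0.95 anywhere on the training covariates, the dynamics weights
are rescaled once so it does not — raw prior draws are frequently explosive
and would make the first E-step numerically extreme without changing the
eventual fixed point of EM in practice. Initial covariances are `Q1 = I`,
`Q = 0.1·I`, and `R = diag(var(y))`.

**Defaults.** `max_iter = 200`, relative objective tolerance `1e−6`,
covariance eigenvalue floor `1e−6` (guards degeneracy on noise-free data).
`d(·)` is frozen at zero by default (`learn_d=True` enables it); `C` can be
frozen to a known matrix or callable (`fixed_C`), the standard device for
comparing recovered dynamics to ground truth without gauge ambiguity —
when `C` is learned, no gauge fixing is imposed and parameter-level
comparisons are not meaningful. `Q1` is learned by default but uses only
one datum per trial, so `learn_Q1=False` (freeze at `I`) is provided for
small trial counts. Hyperparameters {L, κ, σ} are selected by grid search
scored by held-out co-smoothing on a seeded 80/20 trial split (marginal
likelihood is reported alongside in the score table); ties break in grid
order.

## Evaluation

*Data reconstruction* maps the posterior-mode latents (the smoothed means,
since the posterior is Gaussian) through the emission model; `d(u)` is
included whenever it is active. *Co-smoothing* deletes one neuron from the
emission side entirely — its row of `C`, entry of `d`, and row/column of
`R` — smooths the latents from the remaining neurons, predicts the hidden
neuron's rate through its own emission row, and scores R² against the
hidden data concatenated over test trials (concatenation rather than
per-trial averaging keeps short trials from dominating). Neurons are
selected by highest test-set variance with index tie-break; a permutation
test in the suite verifies the hidden column cannot influence its own
prediction.

## Synthetic ring-attractor experiment

The end-to-end testbed is a head-direction ring attractor that is itself a
CLDS with the heading angle θ as condition. With `e1(θ) = (cos θ, sin θ)`
and `e2(θ)` its tangent, the generative parameters are
`A(θ) = (1−ε) e2 e2ᵀ` (a leaky line attractor along the tangent) and
`b(θ) = e1`, so the local fixed point is exactly `e1(θ)` — the unit ring —
and the eigenvalues of `A(θ)` are `{1−ε, 0}` everywhere. Neuron i reads out
the ring component through a raised-cosine bump,
`C_i(θ) = max(0, cos(θ − θ_i))² · e1(θ)ᵀ`, with preferred angles
equi-spaced; `d ≡ 0`, `m ≡ 0`, `Q1 = I`. Heading follows a wrapped Gaussian
random walk with per-step s.d. 0.5 rad, trials are length 100 with 10
neurons, and the ground-truth functions are encoded analytically so the
truth carries no basis-approximation error.

Values the generator needed that are free choices of this package:
leak `ε = 0.1`, observation noise s.d. 0.1, dynamics noise s.d. 0.05,
bump sharpness 2, and `K = 20` trials. They were fixed once to give a
clearly attracting but noisy ring in which recovery is nontrivial.

What the simulator does and does not emulate: it produces smooth firing
rates with Gaussian noise, homogeneous tuning widths, and a fully observed,
one-dimensional condition. Real recordings have spiking (non-Gaussian)
variability, heterogeneous and drifting tuning, and covariates measured
with error — passing the synthetic suite demonstrates correct inference
and recovery within the model class, not robustness to those departures.

A note on fixed-point recovery: `x*(u) = (I − A(u))⁻¹ b(u)` amplifies
parameter error along the line-attractor direction by `1/ε` (a factor 10 at
the default leak), so fixed-point accuracy is the most sensitive recovery
metric — mean A/b errors of a few percent translate into tangential
fixed-point deviations up to ~0.2 in poorly visited heading regions.

## Analysis conventions

Fixed points are exact linear solves with a per-point singularity flag
(an eigenvalue of `A(u)` at 1 — a line attractor — has no isolated fixed
point); the residual `‖(I−A)x* − b‖ ≤ 1e−8` is enforced on every returned
point. Spectra are sorted by descending modulus with argument tie-break.
The composite field pools posterior-mode latents with their covariates over
trials, bins latent space on an equal-width grid (default 25×25; 64
condition bins for tuning curves), and averages `A(u)x_c + b(u) − x_c` over
the pooled `u` within each bin, evaluated at the bin center `x_c` — a
gridded approximation of the condition-marginalized dynamics whose fidelity
degrades in bins visited under heterogeneous conditions; occupancy counts
are returned so sparsely supported bins can be discounted. Model tuning
curves average smoothed posterior means within condition bins and map the
result through the emission row at the bin center.

## Problem sizes

The test suite and the acceptance script run the full ring pipeline at
`K = 20, T = 100, N = 10` with `D = 2, L = 13, κ = 1, σ² = 1` and five
simulation/fit seeds; oracle-equivalence checks use 100 random instances
with `D ≤ 3, N ≤ 4, T ≤ 5`; monotonicity checks use ten seeded runs each on
ring and condition-independent data at reduced sizes (`K = 5, T = 50`).
These sizes were chosen so the entire suite completes in a few minutes on
one CPU while leaving every statistical margin wide.

## Known limitations

- Gaussian emissions only; the conditional-linear structure would support
  log-concave spike-count likelihoods via approximate EM, but no such
  emission model is implemented (the emission seam is the `CLDSModel`
  parameter-function container, not a pluggable likelihood).
- Covariates must be observed at every time step; there is no facility for
  missing or partially observed conditions, and no missing-data handling
  within a trial.
- When `C` is learned the latent basis is not identifiable (any invertible
  linear reparameterization trades off against `A`, `b`, `Q`); only
  prediction-level comparisons are meaningful in that regime.
- The `Q1` update pools one residual per trial and is noisy for small `K`.
- Hyperparameter selection refits the model per grid point; the grid is
  evaluated serially and can be slow for large grids.
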