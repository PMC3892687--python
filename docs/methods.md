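# Methods

`topaug` implements *topological augmentation*: an iterative workflow that
locates and repairs missing structure (state variables and reaction terms) in
deterministic kinetic models of biochemical systems. This note records the
model assumptions, the numerical choices, the design decisions that were
genuinely open, and what the bundled synthetic studies do and do not
demonstrate.

## The model class and the workflow

A model is a system of ODEs, dx/dt = f(x, u, θ, t), with states x
(concentrations), optional time-varying inputs u, parameters θ, an output map
h(x), and additive Gaussian measurement noise with per-point covariance S_k.
Structural (topological) uncertainty is represented by reformulating the ODEs
as Itô SDEs,

    dx = f(x, u, θ, t) dt + diag(σ) dW,

with one non-negative *system-noise* magnitude σ_i per state equation. The
σ_i quantify everything the drift fails to describe — intrinsic randomness
plus missing or wrong reaction terms. The workflow is:

1. build a minimal ODE model;
2. test its compatibility with the data (viability criterion, bias check);
3. reformulate as an SDE;
4. explore the joint parameter space (kinetics and σ) and characterize the
   viable region;
5. read off which σ_i can be made negligible over the viable space — a σ_i
   that cannot be eliminated points to the defective equation;
6. optionally add a diffusion-driven auxiliary state (zero drift, own σ)
   that either replaces a suspect parameter or multiplies a hypothesized
   term; its filtered trajectory over the viable ensemble traces the time
   course of the missing mechanism;
7. translate that trace into the simplest matching deterministic rate law,
   add it to the ODE model, and iterate. Candidate models accumulated along
   the way are ranked by Bayes factors.

## Filtering and the cost function

Stochastic trajectories cannot be compared to data by least squares — every
SDE simulation differs — so all parameter evaluation goes through a
continuous-discrete extended Kalman filter. Between observations the mean and
covariance follow

    dm/dt = f(m, u, θ, t),
    dP/dt = A P + P Aᵀ + diag(σ)²,   A = ∂f/∂x|_m,

and each observation applies the standard EKF update with H = ∂h/∂x|_m. The
cost is the innovation-form negative log-likelihood

    J(θ) = Σ_k ½ [ e_kᵀ Σ_k⁻¹ e_k + ln det(2π Σ_k) ],

a deterministic function of θ, which makes sampling-based exploration
possible. The relative sizes of S and σ set the filter's weights of trust:
S → 0 makes the filtered means track the data, σ → 0 makes them track the
ODE solution.

Numerical choices:

- Moment propagation uses fixed-substep classical RK4 (default 6 substeps
  per inter-observation interval; `EKFOptions.max_step` caps the step length
  — the glutamine study runs with `max_step=1` min). A fixed-step scheme was
  chosen over an adaptive integrator for speed (the samplers evaluate the
  cost tens of thousands of times); correctness is audited against an exact
  discrete Kalman recursion (matrix exponential + Van Loan discretization)
  on linear models, where 40 substeps reproduce cost and filtered means to
  1e-6 relative.
- Covariances are symmetrized after every step, updated in Joseph form, and
  negative eigenvalues (if the cheap diagonal check trips) are clipped to 0.
- Jacobians are analytic for all bundled models and central finite
  differences (relative step 1e-6) otherwise.
- Divergence (non-finite moments, covariance entries beyond 1e12 × data
  scale, or a failed Cholesky) is reported as cost +∞, never an exception:
  samplers must survive absurd parameter points.
- Bundled rate laws clamp their substrate at zero: uptake from an empty pool
  is zero, and the linearization stays away from the pole at Q = −K_m when a
  filtered mean dips below zero.
- The smoothing (backward) pass is not implemented; the workflow uses the
  filter only.

## Viability

For ODE models, the standardized squared-residual sum of a correct model is
χ² with N degrees of freedom, so a point is viable at level α when

    J(θ) ≤ ½(N + α√(2N)) + Σ_k ½ ln det(2π S_k)

(one-sided, upper bound; α = 3 by default). For SDE models this argument no
longer applies and viability is anchored to the best point found: J(θ) ≤
J_best + δ ln 10, with δ = 5 likelihood orders of magnitude by default.
Likelihood weights w_i ∝ exp(J_best − J_i) over the viable set are used for
all ensemble summaries. A sign test on innovation signs (optionally
one-sided, optionally windowed in time) is reported as a bias diagnostic; it
never vetoes viability.

## Parameter-space exploration

All sampling happens in log10 parameter space; parameters are positive.
`explore` runs, per seed: a Latin-hypercube scan of the box; a Nelder–Mead
descent from the best scan point (with an explicit initial simplex of 10% of
the box width — scipy's default simplex degenerates near zero coordinates);
several MH chains, each with an annealing prefix (plain Metropolis on
exp(−J)) followed by the flattened target exp(−max(J, cutoff)), under which
chains wander the viable region uniformly; and a final polish from the
overall best point. Every cost evaluation — including polish trails — is kept
in the returned sample. The flattened target alone turned out to be purely
diffusive below the cutoff and reliably missed the optimum that anchors the
relative cutoff; the descent phases fix that. Proposal scales adapt toward
25% acceptance; proposals reflect at the box boundary.

`characterize` clusters viable points (single linkage, cut at 1 log10 unit by
default), fits a covariance ellipsoid per cluster, and grows each radius by
25% per step while at least half of 200 uniform test draws inside remain
viable; newly found viable points are merged back into the sample, and a
better optimum re-anchors the relative cutoff.

`diagnose` decides eliminability of noise magnitudes. A σ-subset is
(jointly) eliminable when a stored viable point has all its members within
ε = 1 decade of the box floor. Because a random walk essentially never
diffuses into a viable low-noise corner even when one exists, `diagnose` can
probe candidates actively: clamp the subset to the floor at the best viable
points, re-optimize the free coordinates (multi-start Nelder–Mead including
a neutral box-center start), and merge any viable witness into the sample.
Witnesses are stored points, so re-evaluating their cost re-confirms
viability.

`infer_hidden` runs the filter at each viable point (or a seeded subsample)
and aggregates the auxiliary state into a likelihood-weighted mean ± weighted
standard error, SE = √(Σ w_i²(x_i − μ)²) with normalized weights.
`match_term` fits four one-covariate families — constant a, linear a·z,
saturating a/(b+z), switch a·1{z<b} — to the trace by weighted least squares
(weights 1/SE²) and ranks them by a small-sample-corrected information score
(AICc on the weighted residual sum). The ranking depends only on (covariate,
trace) pairs, so it is invariant to affine rescaling of the time grid.

## Model comparison

Marginal likelihoods are Monte-Carlo integrals of exp(−J) under uniform
priors on declared log10 boxes; the box choice is an explicit part of the
comparison configuration. Estimates are computed with log-sum-exp
stabilization, and the delta-method standard error is reported. Plain prior
sampling collapses for the larger (7–11 parameter) models — single draws
dominate and over-flexible models win spuriously — so a stratified mode
draws half the points uniformly inside the characterized viable-region
ellipsoids and reweights every draw by prior density over mixture density
(defensive importance sampling, unbiased by construction). The glutamine
ranking uses the stratified mode; the pharmacokinetic M-series works with
plain sampling over its 2-decade priors. Posteriors are p_i ∝ prior_i ·
marginal_i; with equal model priors the posterior ratio equals the Bayes
factor.

## The synthetic case studies

No measured data ship with the package; both studies are emulated by seeded
generators whose parameters are declared once in
`topaug/casestudies/constants.py`.

**Pharmacokinetics.** Truth: saturating uptake of an oral dose (Q₀ = 50 mg,
V_max = 10 mg/h, K_m = 3 mg, C_L = 5 l/h, V = 15 l), plasma concentration C
observed at 20 equally spaced times over 10 h with 10% proportional error.
K_m is small relative to the dose (deeply saturated uptake) so that
mass-action absorption is a *structurally* wrong approximation: with a
shallower saturation the initial linear model fits within five likelihood
orders of the SDE optimum and the study's diagnosis (neither σ eliminable
jointly under the linear drift) would be false. The M1–M8 family crosses
{linear, saturating} uptake with the four σ-subsets; "eliminated" σ are
removed from the model and the prior.

**Glutamine transport.** Truth: the regulated-MM model — constitutive
low-affinity uptake (V_max = 0.75 mM/min, K_m = 14 mM) plus a regulated
pool W·V₂Q/(K₂+Q) (V₂ = 0.8 mM/min, K₂ = 1 mM) whose activity W ∈ [0,1]
ramps at k_w = 0.04/min once external glutamine falls below K = 4 mM;
intracellular turnover D = 0.1/min. The culture's cell-to-medium volume
ratio is a fixed logistic input calibrated so depletion (the metabolic
shift) lands at t = 0. 23 extracellular points every 10 min and 14
intracellular points concentrated in the post-shift response window, 5%
proportional error floored at 0.1 mM (quantification limit). The activation
gate is smoothed (logistic in Q, width 0.05 mM) so trajectories and
Jacobians are well behaved; a hard gate and a capped (non-saturating)
activation law are available behind flags. The step-6 probe model
`mm_ext_W` keeps σ_Q and σ_C alongside the auxiliary state's σ_W: with W as
the only noise channel, transient misfit is forced through W and
compensation modes contaminate the inferred activation time course.

What these generators do **not** emulate: biological replicates, growth
feedback of intracellular glutamine on the cell count, glutamine synthesis
from other nitrogen sources after the shift, non-Gaussian measurement error,
and intrinsic copy-number noise. Consequences observed in this synthetic
world and documented here deliberately:

- The single-MM model's misfit to regulated-MM data concentrates in the
  *likelihood gap* (≥ 20 nll units), not in one-sided residuals: with
  proportional errors and free (V_max, K_m, D) the fitted MM balances its
  signed residuals, so pointwise sign tests on intracellular innovations
  have essentially no power even though the model ranking is decisive. A
  real study whose intracellular pool recovers after the shift (e.g. by
  synthesis from the new nitrogen source) would produce the one-sided
  underestimation that this generator cannot.
- The inferred auxiliary state's *baseline* is weakly identified (a constant
  offset in W trades against V_max when the affinities are similar); its
  time-variation is the meaningful signal.

## Problem sizes

Default study sizes used by the test suite and the acceptance script (chosen
as a practical single-CPU budget; all are plain function arguments):
exploration 3–6 chains × 250–300 steps with 64–96 scan points and ≤ 200
polish evaluations; ellipsoid expansion 80–150 draws per step; marginal
likelihoods 500–2000 draws per model; replicate sweeps 5 seeds; the linear
filter audit 100 random models; viability calibration 300–500 replicates.

## Known limitations

- Diagonal, state-independent diffusion only; no SDE schemes beyond
  Euler–Maruyama; no smoother; no SBML import.
- The simplified explorer is property-tested (coverage on analytic costs),
  not equivalent to the out-of-equilibrium sampler it abbreviates; very
  narrow or strongly curved viable regions may require larger budgets.
- Plain Monte-Carlo marginal likelihoods are only trustworthy for small
  models with informative priors; use the stratified mode otherwise.
- The term dictionary is deliberately minimal (four families, one
  covariate); committing a chosen term to a new model remains a human step.
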