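# Methods

## The generative model

`massmc` inverts a single-node neural mass model (NMM), a biophysically
motivated dynamic causal model of electrophysiological recordings.  Three
neural populations — spiny-stellate cells, inhibitory interneurons and
pyramidal cells — interact through four connection strengths
g<sub>1..4</sub>; each population's post-synaptic response is a critically
damped second-order kernel with rate constant τ<sub>e</sub> (excitatory) or
τ<sub>i</sub> (inhibitory) and maximum amplitude h<sub>e</sub> / h<sub>i</sub>.
Membrane potential is converted to a normalised firing-rate deflection by
the sigmoid S(v) = 1/(1 + e<sup>−0.56 v</sup>) − 1/2.  Intrinsic conduction
delays δ are folded in by the first-order substitution
x(t − δ) ≈ x(t) − δ ẋ(t), applied inside every sigmoid argument and closed
with the identities ẋ₁ = x₄, ẋ₇ = x₈, ẋ₉ = x₅ − x₆, so the nine equations
remain an explicit ODE system.  A Heaviside step of amplitude u drives the
spiny-stellate population from t = 0.  The observable is the pyramidal
potential x₉, recorded at T points with additive i.i.d. Normal noise of
variance σ² = 0.0625 mV².

All ten parameters θ = (g₁, g₂, g₃, g₄, δ, τᵢ, hᵢ, τₑ, hₑ, u) are strictly
positive and carry independent Gamma(k₁, scale k₂) priors (the shipped
table also records the generative "true" column used for synthetic data).
The joint log-density is

J(θ) = −½ ln|Σ| − (T/2) ln 2π − ½ (x₉(θ) − y)ᵀ Σ⁻¹ (x₉(θ) − y)
       + Σₚ ln Gamma(θₚ; k₁ₚ, k₂ₚ),     Σ = σ² I.

### Simulation grid

The recording window and sampling rate are package choices: t ∈ [0, 100] ms
with T = 100 evenly spaced observations and onset at t = 0.  This covers
many multiples of the membrane time constants (τ ≈ 6–8 ms) and of the delay
(δ ≈ 12 ms), so the step response and its settling are both observed.  All
simulations start from rest, x(0) = 0, the drive-off equilibrium.

Integration uses a stiff variable-order BDF method with the analytic state
Jacobian; relative and absolute tolerances default to 10⁻³.  A trajectory
whose state norm passes 10⁶ terminates early and is reported as diverged;
the likelihood maps that status to −∞ so samplers treat such proposals as
zero-probability rather than erroring.

## A structural property: the line of equilibria

Because ẋ₉ = x₅ − x₆, the ninth state is the time-integral of x₂ − x₃ and
enters the flow only through sigmoids.  Consequently the driven system has
a one-dimensional *continuum* of fixed points parameterised by x₉, and the
Jacobian at any of them carries an exactly-zero structural eigenvalue (the
tangent of the equilibrium line).  Two practical consequences:

1. **The raw instability protocol is a noise-dominated statistic.**
   Classifying a prior draw unstable iff the leading real part of the full
   nine-eigenvalue spectrum is ≥ 0 means, for every draw whose remaining
   modes are stable, reading the sign of a numerically-zero eigenvalue
   (±10⁻¹⁸) — a fair coin.  The statistic therefore hovers near one half by
   construction (we measure 53–54% at n = 2000): roughly the genuinely
   unstable mass plus half the marginal mass.  `prior_instability_fraction`
   implements exactly this protocol as its default because it is the
   calibration the prior table was built against.
2. **The meaningful classification lives on the invariant manifold**
   x₉ = x₂ − x₃ that contains the rest state.  Eliminating x₉ gives an
   8-state system whose Jacobian spectrum decides whether trajectories from
   rest settle; `StabilityReport.stable` reports this flag, and about 23%
   of prior draws are unstable by it — all of Hopf type (complex pairs
   crossing the axis).  Since the sigmoids are bounded, no trajectory can
   actually escape to infinity: "unstable" dynamics manifest as sustained
   large oscillations, hence a very low log joint, not integrator blow-up.
   The long-integration agreement test classifies draws decisively away
   from the marginal boundary (|max Re λ| > 0.02/ms) and confirms the
   manifold classification predicts settling.

The samplers' stable-initialisation gate uses the manifold flag.

## Gradients

Two exact routes to dJ/dθ are implemented and cross-checked:

* **Forward sensitivities.**  The variational system
  dS/dt = (∂f/∂x) S + ∂f/∂θ, S(0) = 0, is integrated jointly with the
  states (99 coupled equations) at the same tolerances; ∂f/∂x and ∂f/∂θ are
  analytic (hand-differentiated once, unit-tested against central finite
  differences at 10⁻⁵–10⁻⁶ relative).  The Newton matrix for the augmented
  BDF solve uses the block-diagonal approximation (∂f/∂x repeated), which
  affects only Newton convergence rate, never solution accuracy.  All
  sampling uses this route: it remains well-behaved when the forward
  dynamics are (nearly) unstable.
* **Adjoint.**  One backward linear ODE λ̇ = −(∂f/∂x)ᵀλ with an impulse
  −rₖ/σ² on the observable component at each observation time, accumulating
  ∫ λᵀ ∂f/∂θ dt.  Validity requires a stable forward pass; the forward
  trajectory is stored as a dense interpolant (checkpointing is unnecessary
  at T = 100).  Agreement with forward sensitivities is tolerance-limited:
  ≤ 10⁻² relative at loose tolerances, tightening with the integrator.

Finite-difference validation of either route is done at tight integrator
tolerances (10⁻⁸/10⁻¹⁰): at the default 10⁻³ the finite difference of the
log joint is itself integration-noise-limited and no sub-percent agreement
is achievable for any implementation.

The metric tensor for the Riemannian kernel is the Gauss–Newton/Fisher
matrix G(θ) = S₉ᵀ Σ⁻¹ S₉ + diag((k₁−1)/θ²), where S₉ is the T×10
sensitivity of the observable and the second term is the negative Hessian
of the Gamma log-prior (positive for every shipped shape k₁ > 1).  The data
term uses the full T-sample sum — the Fisher information of the likelihood.
G is symmetrised and, if its smallest eigenvalue is non-positive, jittered
by 10⁻⁸·mean(diag G)·I (the Gauss–Newton term alone is only positive
semi-definite).

## Samplers

All four kernels share a target interface (log-density, gradient, metric)
and a seeded chain driver.  Initial positions are prior draws
rejection-sampled until dynamically stable.  Default protocol: 20 000
samples, 6 000 discarded as burn-in.

* **Random-walk Metropolis** — proposal N(θ, 0.57 I), 0.57 = 2.4²/10 being
  the classical optimal-scaling constant for ten dimensions; symmetric, so
  the acceptance ratio is the density ratio.
* **LMC-E** — Langevin proposal θ′ = θ + (ε²/2)∇J + ε z with a full
  Metropolis–Hastings (MALA) correction.
* **LMC-R** — natural-gradient Langevin: drift (ε²/2) G⁻¹∇J, diffusion
  ε √(G⁻¹), with G evaluated at the current point and treated as locally
  constant (no curvature/Christoffel correction); default ε = 0.75.
* **HMC-E** — leapfrog trajectories of L steps at step size ε with a
  diagonal mass matrix (identity by default), full momentum refreshment,
  Metropolis energy correction, and specular reflection of the momentum at
  the positivity planes θₚ = 0 (position mirrored, normal momentum
  component negated) so the Gamma support is respected without spoiling
  reversibility.  Reflection can be disabled for unconstrained targets.

### Truncated drift

Both Langevin kernels truncate the drift to a ball of radius 4 ε √d (in the
metric-whitened geometry for LMC-R).  Far from the mode the raw
Newton-like drift overshoots by orders of magnitude; the reverse-proposal
density then collapses and the chain can reject every proposal
indefinitely — we observed exactly this pathology from some stable prior
initialisations.  Truncation (used consistently in both proposal
densities, so the Metropolis ratio remains exact) is the standard remedy
and is inactive near the mode.

### Metric treatment in the LMC-R correction

Two correction conventions are implemented.  The default,
``correction="mmala"``, re-evaluates G at the proposed point for the
reverse proposal density (the simplified manifold-MALA convention): the
kernel is then exact for the target.  On this posterior, where G is
strongly position-dependent (condition numbers ~10⁵–10⁶), that exactness
costs acceptance rate (~0.08 at ε = 0.75).  The alternative,
``correction="constant"``, evaluates both proposal densities under the
current metric so the determinant terms cancel; it roughly triples the
effective sample size but is exact only where the metric is locally
constant — and on this model the residual bias measurably shifts the
weakly identified amplitude parameters, degrading coverage of the true
values.  Exactness was preferred as the default; both modes coincide on
any target with a constant metric, which is what the Gaussian exactness
suite verifies.

### HMC self-tuning

At initialisation, ε is bisected on a log scale (at fixed L) to a pilot
acceptance rate of 0.65 ± 0.1.  During burn-in, every l = 10 iterations the
pair ζ = (ε, L) is re-selected by maximising a GP-UCB acquisition over the
box ε ∈ [10⁻⁴, 10⁻²], L ∈ [10, 150]: the objective is the expected squared
jumping distance per leapfrog step (ESJD/L) observed on the last window;
the surrogate is a zero-mean GP with a squared-exponential ARD kernel over
range-standardised coordinates (ε on a log scale) with length-scale
λ = 0.2; the confidence width follows the standard GP-UCB schedule
b_{i+1}½ = √(2 ln((i+1)^{ς/2+2} π²/(3κ))) with κ = 0.1, ς = 2, and the
exploration term is damped by a_i = 1/max(1, i − ϕ + 1)^{1/(ν+1)} (ν = 1,
ϕ = burn-in), enforcing diminishing adaptation.  After burn-in, ζ is
frozen at the incumbent best observed objective, so the sampling-phase
kernel is fixed and the chain is a valid MCMC sample.  The acquisition
argmax is taken over a deterministic 25 × 15 grid (log-spaced ε, integer
L), ties breaking toward smaller ε then smaller L.  The GP observation
variance defaults to 10% of the empirical variance of the observed
objective values (floor 10⁻⁸).

## Diagnostics

* **Geweke Z** compares the mean of the first 10% of the post-burn-in
  chain with the last 50%, each segment's variance estimated by its
  long-run variance (spectral density at frequency zero).  The default
  estimator truncates the autocovariance sum adaptively by Geyer's
  initial-monotone-sequence rule — the same machinery as the ESS
  estimator, so the two diagnostics agree about the chain's correlation
  length; a fixed-fraction Bartlett window is available as an option.  A
  fixed short window under-estimates the long-run variance whenever the
  autocorrelation time exceeds it and then inflates |Z| even for stationary
  chains, which matters at the reduced run lengths used here.  The sweep
  variant discards 0, 1, 2, … of 80 front bins (never more than half the
  chain) and recomputes Z, localising where non-stationarity ends.
* **ESS** uses Geyer's initial monotone sequence estimator
  (pairs of autocovariances, truncated at the first negative pair, forced
  non-increasing), clamped to [1, R]; a constant chain reports 1.
  nESS = wall-time / min ESS is reported from the run's own timing and
  never asserted in tests (hardware-dependent).
* **Error summaries**: the parameter-space norm ‖E[θ|y] − θ_true‖₂ (the
  headline accuracy number) and the RMSE between the trajectory at the
  posterior-mean parameters and the noiseless truth, optionally as a
  running trace over increasing numbers of draws.

## What the synthetic data do and do not emulate

The generator reproduces the study conditions: step-driven NMM trajectory,
observation of the pyramidal channel only, Normal noise of variance 0.0625
per sample, priors calibrated so that roughly half of prior draws carry the
unstable marker.  It does not emulate structured physiological noise,
electrode/forward-model gain, multi-channel observations, or model
mismatch (the inference model is the generative model).  Passing tests
therefore demonstrate correctness of the numerics and samplers under the
stated model, not robustness of NMM inversion on real EEG.

## Problem sizes and numerical choices

Chain lengths are the package's own desk-scale protocols: the test
suite's Riemannian-Langevin convergence and parameter-recovery checks use
the full 20 000/6 000 protocol; the reproduction script's convergence
statistic uses a reduced 4 000/1 200 run; the Metropolis failure-mode run
uses the full protocol (cheap, because almost every proposal is rejected
before any ODE solve); the ESS-ordering comparison runs 600 matched
iterations per gradient kernel with the HMC trajectory-length box reduced
to [10, 20] leapfrog steps.  At reduced lengths the Riemannian chain's
autocorrelation time (~100 iterations at the prescribed ε = 0.75) leaves
only a few effective samples per Geweke segment, so the max-|Z| statistic
is volatile across seeds; the full-length protocol gives it far more
resolution.  Root-finding for fixed points uses MINPACK's Powell
dogleg-hybrid Newton method with analytic Jacobians (residual tolerance
10⁻⁸); eigenvalues come from dense LAPACK solves.

## Known limitations

* Riemannian-metric HMC and non-constant-metric (Christoffel) MALA are out
  of scope by design.
* The adjoint route assumes the drive is active from t₀ and a stable
  forward pass; sampling never relies on it.
* The LMC-R default correction is exact only under the locally-constant
  metric assumption (see above); the fully exact mmala mode is available
  but mixes poorly on this posterior.
* Single-chain diagnostics only; no multi-chain shrink factors.
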