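# massmc

Gradient-based MCMC inversion of a single-node neural mass model (NMM) —
a dynamic causal model for electrophysiology.

## The problem

Neural mass models describe the average membrane potentials of interacting
neural populations (here: spiny-stellate cells, inhibitory interneurons and
pyramidal cells) through a nine-state nonlinear ODE system with ten
strictly positive parameters

θ = (g₁, g₂, g₃, g₄, δ, τᵢ, hᵢ, τₑ, hₑ, u):

connection strengths g₁..g₄, an intrinsic delay δ (folded in via the
first-order substitution x(t−δ) ≈ x(t) − δẋ(t)), membrane rate constants
τₑ, τᵢ and post-synaptic amplitudes hₑ, hᵢ, and a Heaviside step drive of
amplitude u.  The only observable is the pyramidal potential x₉(t),
recorded with additive Normal noise (variance 0.0625 mV² per sample).
Given a noisy recording y, the package samples the posterior of θ under
independent Gamma priors by evaluating the joint log-density

J(θ) = −½ ln|Σ| − (T/2) ln 2π − ½ (x₉(θ)−y)ᵀΣ⁻¹(x₉(θ)−y) + Σₚ ln Γ(θₚ; k₁ₚ, k₂ₚ)

and its gradient dJ/dθ = −(x₉(θ)−y)ᵀΣ⁻¹ ∂x₉/∂θ + (k₁−1)/θ − 1/k₂, where
the trajectory sensitivities ∂x/∂θ come from forward variational equations
(an adjoint route is also provided).  The priors are calibrated so that
roughly half of prior draws produce dynamically unstable models, which is
what makes the inversion hard: a useful sampler must steer away from
instability.

Four kernels are implemented and compared:

| kernel | proposal | gradient | metric |
|---|---|---|---|
| `mh` | random walk, N(θ, 0.57 I) | – | – |
| `lmc_e` | Langevin (MALA, truncated drift) | forward sensitivities | identity |
| `lmc_r` | natural-gradient Langevin, ε = 0.75 | forward sensitivities | Gauss–Newton/Fisher G(θ) |
| `hmc` | leapfrog trajectories, specular reflection at θ > 0 | forward sensitivities | diagonal mass |

HMC self-tunes its step size ε ∈ [10⁻⁴, 10⁻²] and trajectory length
L ∈ [10, 150] by maximising the expected squared jumping distance per
leapfrog step through a GP-UCB surrogate during burn-in, after an initial
bisection of ε to a 0.65 acceptance rate.

Single-chain diagnostics include the Geweke spectral Z-score (first 10%
vs last 50% of the post-burn-in chain, long-run variances by Geyer's
initial-monotone-sequence rule), a Geweke sweep over 80 bins, effective
sample size by the initial monotone sequence estimator, and parameter- and
prediction-space error norms against the known generative truth.

See `docs/methods.md` for the model equations, numerical choices, and a
discussion of the model's structural line of equilibria (and what that
implies for stability classification).

## Worked example

```python
import numpy as np
from massmc import nmm
from massmc.samplers import NMMPosterior, run_sampler
from massmc.diagnostics import ess_summary, geweke_z, error_summary

# synthetic recording from the shipped true-parameter column
rec = nmm.generate_dataset(seed=11)          # 100 points over 100 ms
post = NMMPosterior(rec)

# reduced Riemannian-metric Langevin run
chain = run_sampler("lmc_r", post, n_samples=4000, burn_in=1200, seed=2)
P = chain.posterior

ess = ess_summary(P)
zmax = max(abs(geweke_z(P[:, j]).z) for j in range(10))
err = error_summary(P, nmm.true_parameters(), rec)
print(f"acceptance {chain.acceptance_rate:.3f}  mean ESS {ess.mean:.1f}")
print(f"max |Geweke Z| {zmax:.2f}  l2 parameter error {err.l2_parameter:.2f}")
```

Output from this exact run:

```
acceptance 0.075  mean ESS 19.2
max |Geweke Z| 4.32  l2 parameter error 6.59
```

Read: about 8% of Langevin proposals are accepted at the prescribed
ε = 0.75; the 2800 retained draws are worth ≈ 19 independent samples per
parameter; a max |Z| above 2 flags that this short chain has not yet fully
converged (the full 20 000-sample protocol brings it down to ≈ 2 and
covers the true value for 8 of 10 parameters, missing only the two
weakly identified amplitudes — the expected failure mode for this model);
the posterior mean sits a distance ≈ 6.6 from the true parameter vector,
dominated by the inhibitory amplitude hᵢ.  A random-walk Metropolis chain
on the same data accepts ~0.05% of proposals and yields a mean ESS of a
few — no usable mixing — while LMC-R and self-tuned HMC both recover the
bulk of the parameters.

The same pipeline is scriptable from the shell:

```bash
massmc simulate --seed 11 --out recording.csv
massmc sample --kind lmc_r --n 4000 --burnin 1200 --seed 2 --out runs/
massmc diagnose runs/chain.csv
massmc stability-scan --n 2000 --seed 1
massmc gradcheck --seed 0 --n 3
```

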