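"""MCMC kernels: random-walk Metropolis, Langevin (Euclidean/Riemannian), HMC.

All kernels operate on a *target* object exposing

* ``dim`` — parameter dimension,
* ``logp(theta)`` — log joint density (``-inf`` off support / diverged),
* ``logp_grad(theta)`` — ``(logp, grad)``,
* ``logp_grad_metric(theta)`` — ``(logp, grad, G)`` with G symmetric
  positive definite,

so the same code drives both analytic toy targets (used to verify exactness)
and the neural-mass-model posterior, where one forward-sensitivity solve
yields value, gradient and Gauss-Newton metric simultaneously.

The Langevin kernels apply a full Metropolis-Hastings correction with the
asymmetric Gaussian proposal densities (MALA), so every kernel is exact for
its stationary distribution; the Riemannian variant preconditions drift and
diffusion with the inverse metric and re-evaluates G at the proposed point
for the reverse density.  HMC uses the leapfrog scheme with optional
specular reflection of the momentum at the positivity boundaries implied by
the Gamma priors.
"""

from __future__ import annotations

import time
from collections import OrderedDict
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_solve, solve_triangular

from . import nmm
from .gradients import forward_sensitivities, grad_log_joint, log_joint, metric_tensor
from .tuning import AcquisitionSettings, Tuner, TuningBounds, bisect_stepsize

__all__ = [
    "ChainState",
    "Chain",
    "NMMPosterior",
    "MHSettings",
    "LMCSettings",
    "HMCSettings",
    "mh_step",
    "lmc_e_step",
    "lmc_r_step",
    "leapfrog",
    "specular_reflect",
    "hmc_step",
    "run_sampler",
]


@dataclass
class ChainState:
    """Current position with cached density, gradient and metric."""

    theta: np.ndarray
    logp: float
    grad: np.ndarray | None = None
    metric: np.ndarray | None = None
    accepted: bool = True


class NMMPosterior:
    """The joint log-density of the neural mass model as a sampler target.

    Value-only evaluations integrate the 9 model states; gradient/metric
    evaluations integrate the augmented sensitivity system.  A small
    memoisation cache keyed on the parameter bytes avoids re-integrating
    when a kernel needs the same point twice (e.g. leapfrog endpoint
    followed by the acceptance test).
    """

    dim = nmm.N_PARAMS

    def __init__(self, rec, grid=None, rtol=1e-3, atol=1e-3, table=None,
                 cache_size: int = 16):
        self.rec = rec
        self.grid = grid or rec.grid
        self.rtol = rtol
        self.atol = atol
        self.table = table
        self.n_solves = 0          # value-only ODE integrations
        self.n_sens_solves = 0     # augmented sensitivity integrations
        self._cache: OrderedDict[bytes, tuple] = OrderedDict()
        self._cache_size = cache_size

    # -- internal ---------------------------------------------------------
    def _eval_full(self, theta: np.ndarray):
        key = theta.tobytes()
        if key in self._cache:
            self._cache.move_to_end(key)
            return self._cache[key]
        if np.any(theta <= 0) or not np.all(np.isfinite(theta)):
            out = (-np.inf, None, None)
        else:
            sens = forward_sensitivities(theta, self.grid, self.rtol, self.atol)
            self.n_sens_solves += 1
            if not sens.success:
                out = (-np.inf, None, None)
            else:
                lj = log_joint(theta, self.rec, self.grid, self.rtol, self.atol,
                               self.table, trajectory=sens)
                grad = grad_log_joint(theta, self.rec, sens, self.table)
                G, _ = metric_tensor(theta, sens, self.rec.noise_var, self.table)
                out = (lj.value, grad, G)
        self._cache[key] = out
        if len(self._cache) > self._cache_size:
            self._cache.popitem(last=False)
        return out

    # -- target protocol --------------------------------------------------
    def logp(self, theta) -> float:
        theta = np.asarray(theta, dtype=float)
        key = theta.tobytes()
        if key in self._cache:
            return self._cache[key][0]
        self.n_solves += 1
        return log_joint(theta, self.rec, self.grid, self.rtol, self.atol,
                         self.table).value

    def logp_grad(self, theta):
        theta = np.asarray(theta, dtype=float)
        lp, grad, _ = self._eval_full(theta)
        return lp, grad

    def logp_grad_metric(self, theta):
        theta = np.asarray(theta, dtype=float)
        return self._eval_full(theta)

    def initial_state(self, rng: np.random.Generator, max_tries: int = 10_000,
                      require_stable: bool = True) -> np.ndarray:
        """Rejection-sample the prior until a dynamically stable draw is found."""
        for _ in range(max_tries):
            theta = nmm.sample_prior(1, table=self.table, rng=rng)[0]
            if require_stable and not nmm.find_fixed_point(theta).stable:
                continue
            if np.isfinite(self.logp(theta)):
                return theta
        raise RuntimeError(f"no stable initial draw found in {max_tries} prior samples")


# ---------------------------------------------------------------------------
# settings


@dataclass(frozen=True)
class MHSettings:
    """Random-walk proposal covariance: scale * identity.

    The default 0.57 = 2.4^2 / d is the classical optimal-scaling rule for
    d = 10 parameters.
    """

    scale: float = 0.57


@dataclass(frozen=True)
class LMCSettings:
    eps: float = 0.75
    metric: bool = False  # True: Riemannian (natural-gradient) variant
    correction: str = "mmala"  # lmc_r MH correction: 'mmala' | 'constant'


@dataclass(frozen=True)
class HMCSettings:
    eps: float | None = None          # None: bisected at initialisation
    L: int = 10
    mass: np.ndarray | None = None    # diagonal of M; None = identity
    bounds: TuningBounds = field(default_factory=TuningBounds)
    tune: bool = True
    tune_interval: int = 10
    target_accept: float = 0.65
    pilot_iters: int = 25
    reflect: bool = True
    acquisition: AcquisitionSettings = field(default_factory=AcquisitionSettings)


# ---------------------------------------------------------------------------
# kernels


def mh_step(state: ChainState, target, rng: np.random.Generator,
            scale: float = 0.57) -> ChainState:
    """Random-walk Metropolis with a Normal(theta, scale * I) proposal.

    The proposal is symmetric, so the acceptance ratio is the posterior
    density ratio alone; proposals with -inf log joint are always rejected.
    """
    prop = state.theta + np.sqrt(scale) * rng.standard_normal(target.dim)
    lp = target.logp(prop)
    if np.log(rng.uniform()) < lp - state.logp:
        return ChainState(prop, lp, accepted=True)
    return replace(state, accepted=False)


def _mala_logq(x_to, mean, eps):
    d = x_to - mean
    return -0.5 * float(d @ d) / eps**2


def _truncate(drift: np.ndarray, cap: float) -> np.ndarray:
    """Truncated-drift rule: rescale the Langevin drift onto a ball.

    Unbounded drift far from the mode makes the reverse-proposal density
    collapse and the chain sticky; capping it (and using the capped drift
    consistently in both proposal densities) restores ergodicity without
    biasing the kernel.
    """
    nrm = float(np.linalg.norm(drift))
    if nrm <= cap:
        return drift
    return drift * (cap / nrm)


def _drift_cap(eps: float, dim: int) -> float:
    # a few noise standard deviations: inactive near the mode
    return 4.0 * eps * np.sqrt(dim)


def lmc_e_step(state: ChainState, target, rng: np.random.Generator,
               eps: float = 0.75) -> ChainState:
    """Euclidean-metric Langevin (truncated-drift MALA) step.

    Proposal theta' = theta + eps^2/2 * grad + eps * z (drift truncated to a
    ball of a few noise standard deviations), corrected with the full
    Metropolis-Hastings ratio for the asymmetric Gaussian proposal.
    """
    if state.grad is None:
        state.logp, state.grad = target.logp_grad(state.theta)
    cap = _drift_cap(eps, target.dim)
    mean_fwd = state.theta + _truncate(0.5 * eps**2 * state.grad, cap)
    prop = mean_fwd + eps * rng.standard_normal(target.dim)
    lp, grad_p = target.logp_grad(prop)
    if not np.isfinite(lp):
        return replace(state, accepted=False)
    mean_rev = prop + _truncate(0.5 * eps**2 * grad_p, cap)
    log_alpha = (lp - state.logp
                 + _mala_logq(state.theta, mean_rev, eps)
                 - _mala_logq(prop, mean_fwd, eps))
    if np.log(rng.uniform()) < log_alpha:
        return ChainState(prop, lp, grad=grad_p, accepted=True)
    return replace(state, accepted=False)


def _metric_logq(x_to, mean, eps, chol_G, log_det_G):
    """log N(x_to; mean, eps^2 G^{-1}) up to dimension-constant terms."""
    d = x_to - mean
    w = chol_G.T @ d  # d' G d = ||L' d||^2 for G = L L'
    return 0.5 * log_det_G - len(d) * np.log(eps) - 0.5 * float(w @ w) / eps**2


def lmc_r_step(state: ChainState, target, rng: np.random.Generator,
               eps: float = 0.75, correction: str = "mmala") -> ChainState:
    """Riemannian-metric Langevin step with a locally constant metric.

    The drift is the natural gradient G^{-1} grad J and the diffusion is
    preconditioned by sqrt(G^{-1}), with G evaluated at the current point
    and treated as constant over the move (no curvature correction).

    Two Metropolis-Hastings correction modes are provided:

    * ``"mmala"`` (default) — the reverse density re-evaluates G at the
      proposed point (simplified manifold-MALA), making the kernel exact
      for the target; when the metric varies strongly along the chain
      this costs acceptance rate, but it is the mode that leaves the
      posterior undistorted.
    * ``"constant"`` — both forward and reverse proposal densities use
      the current metric, so the determinant terms cancel.  Faster mixing,
      but exact only where the metric really is locally constant; on this
      model's posterior the residual bias measurably shifts weakly
      identified parameters.

    Falls back to a Euclidean step if the metric cannot be factorised.
    """
    if correction not in ("constant", "mmala"):
        raise ValueError("correction must be 'constant' or 'mmala'")
    if state.grad is None or state.metric is None:
        state.logp, state.grad, state.metric = target.logp_grad_metric(state.theta)
    try:
        L_cur = np.linalg.cholesky(state.metric)
    except np.linalg.LinAlgError:
        return lmc_e_step(state, target, rng, eps)
    cap = _drift_cap(eps, target.dim)

    def nat_drift(L, grad):
        # drift truncated in the whitened (metric) geometry
        w = _truncate(0.5 * eps**2 * solve_triangular(L, grad, lower=True), cap)
        return solve_triangular(L.T, w, lower=False)

    mean_fwd = state.theta + nat_drift(L_cur, state.grad)
    z = rng.standard_normal(target.dim)
    prop = mean_fwd + eps * solve_triangular(L_cur.T, z, lower=False)
    lp, grad_p, G_p = target.logp_grad_metric(prop)
    if not np.isfinite(lp):
        return replace(state, accepted=False)
    ldet_cur = 2.0 * float(np.sum(np.log(np.diag(L_cur))))
    if correction == "mmala":
        try:
            L_rev = np.linalg.cholesky(G_p)
        except np.linalg.LinAlgError:
            return replace(state, accepted=False)
        ldet_rev = 2.0 * float(np.sum(np.log(np.diag(L_rev))))
        mean_rev = prop + nat_drift(L_rev, grad_p)
    else:
        L_rev, ldet_rev = L_cur, ldet_cur
        mean_rev = prop + nat_drift(L_cur, grad_p)
    log_alpha = (lp - state.logp
                 + _metric_logq(state.theta, mean_rev, eps, L_rev, ldet_rev)
                 - _metric_logq(prop, mean_fwd, eps, L_cur, ldet_cur))
    if np.log(rng.uniform()) < log_alpha:
        return ChainState(prop, lp, grad=grad_p, metric=G_p, accepted=True)
    return replace(state, accepted=False)


def specular_reflect(rho: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Reflect the momentum off a constraint surface with unit normal n.

    rho' = rho - 2 (rho . n) n: the normal component is negated, tangential
    components and the norm are preserved.
    """
    normal = np.asarray(normal, dtype=float)
    nrm = np.linalg.norm(normal)
    if nrm == 0:
        raise ValueError("constraint normal must be non-zero")
    n = normal / nrm
    return rho - 2.0 * float(rho @ n) * n


def leapfrog(theta, rho, eps, L, M, grad_fn, reflect: bool = True):
    """Stoermer-Verlet integration of the separable Hamiltonian.

    Each step is half-kick / drift / half-kick with kinetic energy
    rho' M^{-1} rho / 2 and potential -J(theta).  If ``reflect`` is set, any
    coordinate driven below zero during the drift is mirrored back and its
    momentum component negated (specular reflection at the positivity
    planes), preserving the Hamiltonian and reversibility.

    ``grad_fn(theta)`` must return the gradient of J, or ``None``/non-finite
    to signal an invalid point, in which case the trajectory is abandoned.

    Returns ``(theta, rho, valid)``.
    """
    theta = np.asarray(theta, dtype=float).copy()
    rho = np.asarray(rho, dtype=float).copy()
    Minv = 1.0 / np.asarray(M, dtype=float)
    grad = grad_fn(theta)
    if grad is None or not np.all(np.isfinite(grad)):
        return theta, rho, False
    for _ in range(int(L)):
        rho = rho + 0.5 * eps * grad
        theta = theta + eps * Minv * rho
        if reflect:
            for _bounce in range(50):
                neg = theta < 0
                if not neg.any():
                    break
                theta[neg] = -theta[neg]
                rho[neg] = -rho[neg]
            else:
                return theta, rho, False
        grad = grad_fn(theta)
        if grad is None or not np.all(np.isfinite(grad)):
            return theta, rho, False
        rho = rho + 0.5 * eps * grad
    return theta, rho, True


def hmc_step(state: ChainState, target, rng: np.random.Generator,
             eps: float, L: int, mass: np.ndarray | None = None,
             reflect: bool = True) -> ChainState:
    """One Hamiltonian Monte Carlo transition.

    Momentum is fully refreshed from N(0, M); the proposal follows L
    leapfrog steps of size eps and is accepted with probability
    min(1, exp(H_old - H_new)).  Invalid trajectories (divergence or
    gradient failure) are rejected outright.
    """
    d = target.dim
    M = np.ones(d) if mass is None else np.asarray(mass, dtype=float)
    rho0 = np.sqrt(M) * rng.standard_normal(d)

    def grad_fn(th):
        lp, g = target.logp_grad(th)
        return g if np.isfinite(lp) else None

    theta_new, rho_new, valid = leapfrog(state.theta, rho0, eps, L, M, grad_fn,
                                         reflect=reflect)
    if not valid:
        return replace(state, accepted=False)
    lp_new, grad_new = target.logp_grad(theta_new)
    if not np.isfinite(lp_new):
        return replace(state, accepted=False)
    h_old = -state.logp + 0.5 * float(np.sum(rho0**2 / M))
    h_new = -lp_new + 0.5 * float(np.sum(rho_new**2 / M))
    if np.log(rng.uniform()) < h_old - h_new:
        return ChainState(theta_new, lp_new, grad=grad_new, accepted=True)
    return replace(state, accepted=False)


# ---------------------------------------------------------------------------
# chain driver


@dataclass
class Chain:
    """Ordered draws with per-iteration metadata."""

    draws: np.ndarray          # (n, d)
    log_joint: np.ndarray      # (n,)
    accepted: np.ndarray       # (n,) bool
    burn_in: int
    seed: int | None
    kind: str
    eps_trace: np.ndarray | None = None
    L_trace: np.ndarray | None = None
    wall_time: float = 0.0
    tuning_trace: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.draws.shape[0]

    @property
    def posterior(self) -> np.ndarray:
        return self.draws[self.burn_in:]

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted[1:])) if self.n_samples > 1 else 1.0


def _bisect_hmc_eps(target, state, settings: HMCSettings,
                    rng: np.random.Generator) -> float:
    M = settings.mass

    def accept_rate(eps):
        s = state
        acc = 0
        for _ in range(settings.pilot_iters):
            s = hmc_step(s, target, rng, eps, settings.L, M, settings.reflect)
            acc += s.accepted
        return acc / settings.pilot_iters

    eps, _ = bisect_stepsize(accept_rate, settings.bounds,
                             target_rate=settings.target_accept)
    return eps


def run_sampler(
    kind: str,
    target,
    n_samples: int = 20_000,
    burn_in: int = 6_000,
    seed: int | None = 0,
    settings=None,
    init=None,
) -> Chain:
    """Run a seeded single chain of the requested kernel.

    ``kind`` is one of ``mh``, ``lmc_e``, ``lmc_r``, ``hmc``.  The initial
    position is ``init`` if given, else ``target.initial_state(rng)`` (for
    the model posterior: a prior draw rejection-sampled to dynamical
    stability).  For HMC, the step size is bisected to the target acceptance
    rate at initialisation and (eps, L) are re-tuned every ``tune_interval``
    iterations during burn-in by GP-UCB on the ESJD objective, then frozen
    at the incumbent best for the sampling phase.
    """
    if kind not in ("mh", "lmc_e", "lmc_r", "hmc"):
        raise ValueError(f"unknown sampler kind: {kind}")
    if n_samples <= burn_in:
        raise ValueError("n_samples must exceed burn_in")
    rng = np.random.default_rng(seed)
    t_start = time.perf_counter()

    if init is None:
        init = target.initial_state(rng)
    theta0 = np.asarray(init, dtype=float)

    d = target.dim
    draws = np.empty((n_samples, d))
    logps = np.empty(n_samples)
    accepted = np.zeros(n_samples, dtype=bool)
    eps_trace = L_trace = None
    tuner = None

    if kind == "mh":
        settings = settings or MHSettings()
        state = ChainState(theta0, target.logp(theta0))
        step = lambda s: mh_step(s, target, rng, settings.scale)
    elif kind == "lmc_e":
        settings = settings or LMCSettings(metric=False)
        lp, g = target.logp_grad(theta0)
        state = ChainState(theta0, lp, grad=g)
        step = lambda s: lmc_e_step(s, target, rng, settings.eps)
    elif kind == "lmc_r":
        settings = settings or LMCSettings(metric=True)
        lp, g, G = target.logp_grad_metric(theta0)
        state = ChainState(theta0, lp, grad=g, metric=G)
        step = lambda s: lmc_r_step(s, target, rng, settings.eps,
                                    settings.correction)
    else:  # hmc
        settings = settings or HMCSettings()
        lp, g = target.logp_grad(theta0)
        state = ChainState(theta0, lp, grad=g)
        eps = settings.eps
        if eps is None:
            eps = _bisect_hmc_eps(target, state, settings, rng)
        L = settings.L
        eps_trace = np.empty(n_samples)
        L_trace = np.empty(n_samples, dtype=int)
        if settings.tune:
            acq = replace(settings.acquisition, phi=burn_in)
            tuner = Tuner(bounds=settings.bounds, settings=acq,
                          interval=settings.tune_interval)

    if not np.isfinite(state.logp):
        raise ValueError("initial state has -inf log joint")

    draws[0] = state.theta
    logps[0] = state.logp
    accepted[0] = True
    if kind == "hmc":
        eps_trace[0], L_trace[0] = eps, settings.L

    for i in range(1, n_samples):
        if kind == "hmc":
            state = hmc_step(state, target, rng, eps, L, settings.mass,
                             settings.reflect)
            eps_trace[i], L_trace[i] = eps, L
            if tuner is not None and i % settings.tune_interval == 0:
                window = draws[i - settings.tune_interval:i]
                if i <= burn_in:
                    eps, L = tuner.observe_and_propose(window, eps, L, i)
                elif i - settings.tune_interval <= burn_in:
                    best = tuner.incumbent()   # freeze after burn-in
                    if best is not None:
                        eps, L = best
        else:
            state = step(state)
        draws[i] = state.theta
        logps[i] = state.logp
        accepted[i] = state.accepted

    return Chain(
        draws=draws,
        log_joint=logps,
        accepted=accepted,
        burn_in=burn_in,
        seed=seed,
        kind=kind,
        eps_trace=eps_trace,
        L_trace=L_trace,
        wall_time=time.perf_counter() - t_start,
        tuning_trace=tuner.trace if tuner is not None else [],
    )
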