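"""Self-tuning of HMC's step size and trajectory length via GP-UCB.

The tuning objective is the expected squared jumping distance per leapfrog
step, g(zeta) = E||theta_{t+1} - theta_t||^2 / L, observed over short windows
of the chain (every l = 10 iterations by default).  A Gaussian-process
surrogate with a squared-exponential ARD kernel models g over the bounded
box zeta = (eps, L); the next setting maximises the upper confidence bound

    psi(zeta) = mu_i(zeta) + a_i * sqrt(b_{i+1}) * sigma_i(zeta)

where b follows the standard GP-UCB confidence schedule and the factor
a_i -> 0 enforces diminishing adaptation, so the kernel is asymptotically
fixed.  At initialisation the step size is bisected (at fixed L) to a target
acceptance rate of 0.65.

Coordinates are standardised to the unit square before kernel evaluation
(eps on a log scale), so the length-scale lambda = 0.2 is range-relative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TuningBounds",
    "AcquisitionSettings",
    "esjd",
    "GPSurrogate",
    "ucb_acquire",
    "bisect_stepsize",
    "Tuner",
]


@dataclass(frozen=True)
class TuningBounds:
    """Box constraints on the HMC hyper-parameters."""

    eps_min: float = 1e-4
    eps_max: float = 1e-2
    L_min: int = 10
    L_max: int = 150

    def __post_init__(self):
        if not 0 < self.eps_min < self.eps_max:
            raise ValueError("require 0 < eps_min < eps_max")
        if not 1 <= self.L_min <= self.L_max:
            raise ValueError("require 1 <= L_min <= L_max")

    def contains(self, eps: float, L: int) -> bool:
        return self.eps_min <= eps <= self.eps_max and self.L_min <= L <= self.L_max

    def standardise(self, eps, L) -> np.ndarray:
        """Map (eps, L) into the unit square, eps on a log scale."""
        le, lo, hi = np.log(eps), np.log(self.eps_min), np.log(self.eps_max)
        u = (le - lo) / (hi - lo)
        v = (np.asarray(L, float) - self.L_min) / max(self.L_max - self.L_min, 1)
        return np.stack(np.broadcast_arrays(u, v), axis=-1)


@dataclass(frozen=True)
class AcquisitionSettings:
    """GP-UCB constants: confidence level kappa, dimension constant sigma_v,
    burn-in phi (after which adaptation decays) and decay exponent nu."""

    kappa: float = 0.1
    varsigma: float = 2.0
    phi: int = 6000
    nu: float = 1.0
    lengthscale: float = 0.2

    def __post_init__(self):
        if not 0 < self.kappa < 1:
            raise ValueError("kappa must lie in (0, 1)")

    def a(self, i: int) -> float:
        """Diminishing-adaptation factor; 1 during burn-in, then decaying."""
        return 1.0 / max(1, i - self.phi + 1) ** (1.0 / (self.nu + 1.0))

    def b_sqrt(self, i: int) -> float:
        """Confidence width sqrt(b_{i+1}) = sqrt(2 log((i+1)^{vs/2+2} pi^2 / (3 kappa)))."""
        exponent = self.varsigma / 2.0 + 2.0
        return float(
            np.sqrt(2.0 * np.log((i + 1) ** exponent * np.pi**2 / (3.0 * self.kappa)))
        )


def esjd(window: np.ndarray, L: int) -> float:
    """Mean squared Euclidean jump between consecutive draws, per leapfrog step.

    ``window`` is an (m, d) array of m >= 2 consecutive draws.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if window.shape[0] < 2:
        raise ValueError("need at least two consecutive draws")
    jumps = np.diff(window, axis=0)
    return float(np.mean(np.sum(jumps**2, axis=1))) / L


class GPSurrogate:
    """Zero-mean GP over standardised (eps, L) with an SE-ARD kernel.

    Observation noise defaults to 10% of the empirical variance of the
    observed objective values (floored at 1e-8); a jitter is added if the
    Gram matrix is numerically singular.
    """

    def __init__(self, bounds: TuningBounds, lengthscale: float = 0.2,
                 sigma_mod2: float | None = None):
        self.bounds = bounds
        self.lengthscale = lengthscale
        self.sigma_mod2 = sigma_mod2
        self._Z: list[np.ndarray] = []   # standardised inputs
        self._g: list[float] = []

    @property
    def n_obs(self) -> int:
        return len(self._g)

    def add(self, eps: float, L: int, g: float) -> None:
        if g < 0:
            raise ValueError("ESJD objective is non-negative")
        self._Z.append(self.bounds.standardise(eps, L))
        self._g.append(float(g))

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        d2 = ((A[:, None, :] - B[None, :, :]) / self.lengthscale) ** 2
        return np.exp(-0.5 * d2.sum(axis=-1))

    def _noise(self) -> float:
        if self.sigma_mod2 is not None:
            return self.sigma_mod2
        if len(self._g) < 2:
            return 1e-8
        return max(0.1 * float(np.var(self._g)), 1e-8)

    def posterior(self, eps, L) -> tuple[np.ndarray, np.ndarray]:
        """GP posterior mean and variance at query points (vectorised)."""
        Zq = np.atleast_2d(self.bounds.standardise(eps, L))
        kqq = np.ones(len(Zq))
        if self.n_obs == 0:
            return np.zeros(len(Zq)), kqq
        Z = np.vstack(self._Z)
        g = np.asarray(self._g)
        K = self._kernel(Z, Z) + self._noise() * np.eye(self.n_obs)
        try:
            cf = np.linalg.cholesky(K)
        except np.linalg.LinAlgError:
            cf = np.linalg.cholesky(K + 1e-8 * np.eye(self.n_obs))
        kq = self._kernel(Zq, Z)
        alpha = np.linalg.solve(cf.T, np.linalg.solve(cf, g))
        mean = kq @ alpha
        v = np.linalg.solve(cf, kq.T)
        var = np.maximum(kqq - np.sum(v**2, axis=0), 0.0)
        return mean, var


def ucb_acquire(
    model: GPSurrogate,
    settings: AcquisitionSettings,
    i: int,
    bounds: TuningBounds | None = None,
    n_eps: int = 25,
    n_L: int = 15,
) -> tuple[float, int]:
    """Argmax of the UCB acquisition over a deterministic grid on the box.

    The grid is 25 log-spaced step sizes by 15 integer trajectory lengths;
    ties break toward smaller eps, then smaller L.
    """
    bounds = bounds or model.bounds
    eps_grid = np.geomspace(bounds.eps_min, bounds.eps_max, n_eps)
    L_grid = np.unique(np.linspace(bounds.L_min, bounds.L_max, n_L).round().astype(int))
    E, Lg = np.meshgrid(eps_grid, L_grid, indexing="ij")
    mean, var = model.posterior(E.ravel(), Lg.ravel())
    psi = mean + settings.a(i) * settings.b_sqrt(i) * np.sqrt(var)
    best = int(np.argmax(psi))  # first max: smallest eps, then smallest L
    return float(E.ravel()[best]), int(Lg.ravel()[best])


def bisect_stepsize(
    accept_rate_fn,
    bounds: TuningBounds,
    target_rate: float = 0.65,
    tol: float = 0.1,
    max_iter: int = 12,
) -> tuple[float, bool]:
    """Bisect eps on a log scale toward a pilot acceptance rate of 0.65.

    ``accept_rate_fn(eps)`` estimates the acceptance rate from a short pilot
    run.  Acceptance is assumed monotone non-increasing in eps; if even the
    boundary values cannot bracket the target the nearer bound is returned
    with ``converged=False``.
    """
    lo, hi = np.log(bounds.eps_min), np.log(bounds.eps_max)
    r_lo = accept_rate_fn(bounds.eps_min)
    if r_lo < target_rate - tol:
        return bounds.eps_min, False
    if abs(r_lo - target_rate) <= tol:
        return bounds.eps_min, True
    r_hi = accept_rate_fn(bounds.eps_max)
    if r_hi > target_rate + tol:
        return bounds.eps_max, False
    if abs(r_hi - target_rate) <= tol:
        return bounds.eps_max, True
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = accept_rate_fn(float(np.exp(mid)))
        if abs(r - target_rate) <= tol:
            return float(np.exp(mid)), True
        if r > target_rate:
            lo = mid
        else:
            hi = mid
    return float(np.exp(0.5 * (lo + hi))), False


@dataclass
class Tuner:
    """Orchestrates ESJD observation and UCB acquisition along a chain."""

    bounds: TuningBounds = field(default_factory=TuningBounds)
    settings: AcquisitionSettings = field(default_factory=AcquisitionSettings)
    interval: int = 10
    trace: list = field(default_factory=list)

    def __post_init__(self):
        self.model = GPSurrogate(self.bounds, lengthscale=self.settings.lengthscale)

    def observe_and_propose(
        self, window: np.ndarray, eps: float, L: int, iteration: int
    ) -> tuple[float, int]:
        """Record the window's ESJD at (eps, L) and return the next setting."""
        g = esjd(window, L)
        self.model.add(eps, L, g)
        nxt = ucb_acquire(self.model, self.settings, iteration, self.bounds)
        mean, var = self.model.posterior(*nxt)
        self.trace.append(
            {
                "iteration": iteration,
                "eps": eps,
                "L": L,
                "esjd": g,
                "next_eps": nxt[0],
                "next_L": nxt[1],
                "gp_mean": float(mean[0]),
                "gp_var": float(var[0]),
            }
        )
        return nxt

    def incumbent(self) -> tuple[float, int] | None:
        """Best observed setting (maximal raw objective), for post-burn-in freezing."""
        if self.model.n_obs == 0:
            return None
        k = int(np.argmax(self.model._g))
        # recover original coordinates from the trace
        return self.trace[k]["eps"], self.trace[k]["L"]
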