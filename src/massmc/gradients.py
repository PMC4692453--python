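"""Log joint density, its gradients, and the Gauss-Newton/Fisher metric.

The target of inference is the joint log-density of a noisy pyramidal trace
``y`` and the parameters ``theta``::

    J(theta) = -1/2 ln|Sigma| - T/2 ln(2 pi)
               - 1/2 (x9(theta) - y)' Sigma^{-1} (x9(theta) - y)
               + sum_p ln Gamma(theta_p; k1_p, scale=k2_p)

with Sigma = noise_var * I.  Two exact routes to dJ/dtheta are provided:

* forward sensitivities — the variational system dS/dt = (df/dx) S + df/dtheta
  integrated jointly with the states (robust even near instability, and the
  route used for all sampling), and
* the adjoint method — one backward linear ODE whose solution is contracted
  against df/dtheta (cheaper per gradient, valid for stable trajectories).

The metric tensor used by the Riemannian-metric Langevin kernel is the
Gauss-Newton approximation of the negative log-joint Hessian:
``G = S9' Sigma^{-1} S9 + diag((k1 - 1) / theta^2)`` where ``S9`` is the
T x 10 sensitivity of the observable.  The Gamma-prior curvature follows
from differentiating the log prior twice; it is positive for every shape
k1 > 1, which all shipped priors satisfy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import gamma as gamma_dist

from .nmm import (
    N_PARAMS,
    N_STATES,
    SimulationGrid,
    SyntheticRecording,
    jacobian_theta,
    jacobian_x,
    prior_shapes_scales,
    vector_field,
)

__all__ = [
    "LogJointResult",
    "log_prior",
    "grad_log_prior",
    "log_joint",
    "SensitivityResult",
    "forward_sensitivities",
    "grad_log_joint",
    "adjoint_gradient",
    "metric_tensor",
]

_BLOWUP = 1e6


@dataclass
class LogJointResult:
    value: float
    residual: np.ndarray | None
    misfit: float
    norm_const: float
    log_prior: float
    diverged: bool = False


def log_prior(theta, table=None) -> float:
    """Sum of independent Gamma log-densities; -inf off the support."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0) or not np.all(np.isfinite(theta)):
        return -np.inf
    k1, k2 = prior_shapes_scales(table)
    return float(np.sum(gamma_dist.logpdf(theta, a=k1, scale=k2)))


def grad_log_prior(theta, table=None) -> np.ndarray:
    """d/dtheta of the Gamma log prior: (k1 - 1)/theta - 1/k2."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("theta outside the Gamma support")
    k1, k2 = prior_shapes_scales(table)
    return (k1 - 1.0) / theta - 1.0 / k2


def _gaussian_terms(residual: np.ndarray, noise_var: float) -> tuple[float, float]:
    T = len(residual)
    norm_const = -0.5 * T * np.log(noise_var) - 0.5 * T * np.log(2.0 * np.pi)
    misfit = -0.5 * float(residual @ residual) / noise_var
    return misfit, norm_const


def log_joint(
    theta,
    rec: SyntheticRecording,
    grid: SimulationGrid | None = None,
    rtol: float = 1e-3,
    atol: float = 1e-3,
    table=None,
    trajectory=None,
) -> LogJointResult:
    """Evaluate J(theta) for a recording; -inf for diverged or invalid theta.

    ``trajectory`` may pass in a pre-computed simulation at ``theta`` to
    avoid re-integrating (used by the samplers, which obtain the states as a
    by-product of the sensitivity solve).
    """
    from .nmm import simulate  # local import to keep module load cheap

    theta = np.asarray(theta, dtype=float)
    lp = log_prior(theta, table)
    if not np.isfinite(lp):
        return LogJointResult(-np.inf, None, 0.0, 0.0, lp, diverged=False)
    grid = grid or rec.grid
    traj = simulate(theta, grid, rtol=rtol, atol=atol) if trajectory is None else trajectory
    if not traj.success:
        return LogJointResult(-np.inf, None, 0.0, 0.0, lp, diverged=True)
    residual = traj.x9 - rec.y
    misfit, norm_const = _gaussian_terms(residual, rec.noise_var)
    return LogJointResult(misfit + norm_const + lp, residual, misfit, norm_const, lp)


@dataclass
class SensitivityResult:
    """States and parameter sensitivities on the observation grid."""

    t: np.ndarray
    x: np.ndarray          # (T, 9)
    sens: np.ndarray       # (T, 9, 10)
    success: bool
    message: str = ""

    @property
    def x9(self) -> np.ndarray:
        return self.x[:, 8]

    @property
    def s9(self) -> np.ndarray:
        """Sensitivity of the observable: (T, 10)."""
        return self.sens[:, 8, :]


def forward_sensitivities(
    theta,
    grid: SimulationGrid | None = None,
    rtol: float = 1e-3,
    atol: float = 1e-3,
    method: str = "BDF",
) -> SensitivityResult:
    """Integrate states and sensitivities jointly from S(0) = 0.

    The augmented 99-dimensional system stacks the 9 states with the 9 x 10
    sensitivity matrix; both are advanced by the same stiff integrator at the
    same tolerances.  Divergence is reported via ``success=False``.
    """
    grid = grid or SimulationGrid()
    theta = np.asarray(theta, dtype=float)
    times = grid.times
    T = grid.n_points

    def rhs(t, z, input_on):
        x = z[:9]
        S = z[9:].reshape(N_STATES, N_PARAMS)
        Jx = jacobian_x(x, theta)
        dz = np.empty_like(z)
        dz[:9] = vector_field(x, theta, input_on=input_on)
        with np.errstate(over="ignore", invalid="ignore"):
            # overflow here signals exponentially growing sensitivities;
            # the terminal blow-up event aborts the solve cleanly
            dz[9:] = (Jx @ S + jacobian_theta(x, theta, input_on=input_on)).ravel()
        return dz

    def jac(t, z, input_on):
        # Newton matrix for the augmented system; the exact block
        # d(Sdot)/dx (second derivatives of f) is omitted — this only
        # affects Newton convergence rate, not solution accuracy.
        x = z[:9]
        Jx = jacobian_x(x, theta)
        Jfull = np.zeros((99, 99))
        Jfull[:9, :9] = Jx
        for p in range(N_PARAMS):
            idx = slice(9 + p, 99, N_PARAMS)
            Jfull[idx, idx] = Jx
        return Jfull

    def event(t, z, *args):
        # sensitivities diverge exponentially for unstable draws even when
        # the (sigmoid-bounded) states stay finite — watch the whole vector
        m = np.max(np.abs(z))
        return _BLOWUP - (m if np.isfinite(m) else 2 * _BLOWUP)

    event.terminal = True

    x_out = np.zeros((T, 9))
    s_out = np.zeros((T, N_STATES, N_PARAMS))

    def run_leg(t_span, t_eval, z0, input_on):
        return solve_ivp(
            rhs,
            t_span,
            z0,
            args=(input_on,),
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            jac=(lambda t, z, flag: jac(t, z, flag)) if method in ("BDF", "Radau") else None,
            events=event,
        )

    z0 = np.zeros(99)
    if grid.onset > grid.t0:
        pre = times[times < grid.onset]
        post = times[times >= grid.onset]
        sol = run_leg((grid.t0, grid.onset), pre, z0, False)
        if not sol.success or sol.status == 1:
            return SensitivityResult(times, x_out, s_out, False, sol.message)
        for k in range(len(pre)):
            x_out[k] = sol.y[:9, k]
            s_out[k] = sol.y[9:, k].reshape(N_STATES, N_PARAMS)
        z0 = sol.y[:, -1].copy()
        sol = run_leg((grid.onset, grid.t_end), post, z0, True)
        if not sol.success or sol.status == 1 or sol.y.shape[1] != len(post):
            return SensitivityResult(times, x_out, s_out, False, sol.message)
        off = len(pre)
        for k in range(len(post)):
            x_out[off + k] = sol.y[:9, k]
            s_out[off + k] = sol.y[9:, k].reshape(N_STATES, N_PARAMS)
    else:
        sol = run_leg((grid.t0, grid.t_end), times, z0, True)
        if not sol.success or sol.status == 1 or sol.y.shape[1] != T:
            return SensitivityResult(times, x_out, s_out, False, sol.message)
        for k in range(T):
            x_out[k] = sol.y[:9, k]
            s_out[k] = sol.y[9:, k].reshape(N_STATES, N_PARAMS)
    if not np.all(np.isfinite(x_out)) or not np.all(np.isfinite(s_out)):
        return SensitivityResult(times, x_out, s_out, False, "non-finite values")
    return SensitivityResult(times, x_out, s_out, True, "ok")


def grad_log_joint(
    theta,
    rec: SyntheticRecording,
    sens: SensitivityResult,
    table=None,
) -> np.ndarray:
    """Gradient of J via forward sensitivities.

    dJ/dtheta = -(x9 - y)' Sigma^{-1} (dx9/dtheta) + (k1-1)/theta - 1/k2
    """
    theta = np.asarray(theta, dtype=float)
    residual = sens.x9 - rec.y
    data_term = -(residual @ sens.s9) / rec.noise_var
    return data_term + grad_log_prior(theta, table)


def adjoint_gradient(
    theta,
    rec: SyntheticRecording,
    grid: SimulationGrid | None = None,
    rtol: float = 1e-3,
    atol: float = 1e-3,
    table=None,
) -> np.ndarray:
    """Gradient of J via the adjoint (backward) linear ODE.

    The misfit j(t) = -1/(2 sigma^2) (x9(t) - y_t)^2 sampled at the T
    observation times acts as a sequence of impulse sources for the adjoint
    state: integrating ``lambda' = -(df/dx)' lambda`` backwards in time, the
    adjoint picks up a jump ``d j_k / dx = -(x9(t_k)-y_k)/sigma^2 * e9`` at
    each observation, and the gradient accumulates
    ``int lambda(t)' df/dtheta dt`` plus the prior term.  Only valid for a
    stable (non-divergent) forward trajectory.
    """
    from .nmm import simulate

    grid = grid or rec.grid
    theta = np.asarray(theta, dtype=float)
    traj = simulate(theta, grid, rtol=rtol, atol=atol)
    if not traj.success:
        raise RuntimeError("adjoint gradient requires a non-divergent forward pass")

    # dense forward interpolant for the backward pass
    dense = solve_ivp(
        lambda t, y: vector_field(y, theta, input_on=True),
        (grid.t0, grid.t_end),
        np.zeros(9),
        method="BDF",
        dense_output=True,
        rtol=rtol,
        atol=atol,
        jac=lambda t, y: jacobian_x(y, theta),
    )
    if not dense.success:
        raise RuntimeError("dense forward solve failed")
    if grid.onset > grid.t0:
        raise NotImplementedError("adjoint path assumes the drive is on from t0")

    times = grid.times
    residual = traj.x9 - rec.y
    inv_var = 1.0 / rec.noise_var

    # augmented backward system: z = [lambda (9), accumulated gradient (10)]
    def back_rhs(t, z):
        lam = z[:9]
        x = dense.sol(t)
        dlam = -jacobian_x(x, theta).T @ lam
        dgrad = lam @ jacobian_theta(x, theta, input_on=True)
        return np.concatenate([dlam, dgrad])

    z = np.zeros(19)
    grad_data = np.zeros(N_PARAMS)
    # sweep observation times from last to first; each contributes an
    # adjoint jump of dj/dx = -residual/sigma^2 on the x9 component
    for k in range(len(times) - 1, -1, -1):
        z[8] += -residual[k] * inv_var
        if k == 0:
            break
        sol = solve_ivp(
            back_rhs,
            (times[k], times[k - 1]),
            z,
            method="BDF",
            rtol=min(rtol, 1e-6),
            atol=min(atol, 1e-8),
        )
        if not sol.success:
            raise RuntimeError("backward adjoint solve failed")
        z = sol.y[:, -1]
    # S(0)=0 so the boundary term at t0 vanishes; the accumulated integral
    # already carries the sign of dJ/dtheta
    grad_data = -z[9:]
    return grad_data + grad_log_prior(theta, table)


def metric_tensor(
    theta,
    sens: SensitivityResult,
    noise_var: float = 0.0625,
    table=None,
    jitter_scale: float = 1e-8,
):
    """Gauss-Newton + prior-curvature metric G(theta), guarded to be SPD.

    Returns (G, info) where info records the condition number and any jitter
    applied.  The data term sums s_t s_t' / noise_var over observation times
    (s_t = sensitivity row of the observable); the prior adds
    (k1 - 1)/theta^2 on the diagonal.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("theta outside the Gamma support")
    k1, _ = prior_shapes_scales(table)
    if np.any(k1 <= 1):
        raise ValueError("prior curvature non-positive for shape <= 1")
    S9 = sens.s9
    G = S9.T @ S9 / noise_var + np.diag((k1 - 1.0) / theta**2)
    G = 0.5 * (G + G.T)
    eigs = np.linalg.eigvalsh(G)
    jitter = 0.0
    if eigs[0] <= 0:
        jitter = jitter_scale * float(np.mean(np.diag(G)))
        G = G + jitter * np.eye(N_PARAMS)
        eigs = np.linalg.eigvalsh(G)
    info = {"condition_number": float(eigs[-1] / max(eigs[0], 1e-300)), "jitter": jitter}
    return G, info
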