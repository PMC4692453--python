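"""Single-chain convergence and efficiency diagnostics.

Geweke's spectral diagnostic compares the mean of an early chain segment
(first 10% post burn-in) with a late segment (last 50%) through a Z-score
whose segment variances come from the spectral density at frequency zero,
so autocorrelation within each segment is accounted for.  The sweep variant
repeats the test while discarding progressively more of the chain front
(80 bins, never more than half the chain), which localises where
non-stationarity ends.

Effective sample size uses Geyer's initial monotone sequence estimator:
autocovariances are summed in adjacent pairs, truncated at the first
negative pair and forced non-increasing, giving a consistent, conservative
estimate of the integrated autocorrelation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "spectral_density_zero",
    "GewekeResult",
    "geweke_z",
    "geweke_sweep",
    "ess_imse",
    "ESSResult",
    "ess_summary",
    "ErrorSummary",
    "error_summary",
]


def _autocovariances(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased (1/n) autocovariances up to max_lag via FFT."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[: max_lag + 1].real / n
    return acov


def _ims_longrun_variance(acov: np.ndarray, n: int) -> float:
    """Geyer initial-monotone-sequence estimate of the long-run variance.

    Sums autocovariances in adjacent pairs, truncating at the first
    negative pair and enforcing monotone non-increase — an adaptive,
    consistent truncation that tracks the chain's own correlation length.
    """
    g0 = acov[0]
    sigma2 = -g0
    prev = np.inf
    for m in range((n - 1) // 2 + 1):
        i, j = 2 * m, 2 * m + 1
        pair = acov[i] + (acov[j] if j < len(acov) else 0.0)
        if pair <= 0:
            break
        pair = min(pair, prev)
        sigma2 += 2.0 * pair
        prev = pair
    return max(sigma2, g0 * 1e-12)


def spectral_density_zero(x: np.ndarray, max_lag_frac: float | None = None) -> float:
    """Long-run variance of the chain: the spectral density at frequency
    zero times 2*pi, i.e. the asymptotic variance of the segment mean times
    the segment length.

    With ``max_lag_frac=None`` (default) the autocovariance sum is
    truncated adaptively by Geyer's initial-monotone-sequence rule — the
    same machinery as the ESS estimator, so the two diagnostics are
    mutually consistent and remain honest when the autocorrelation time is
    long relative to the segment.  A float value instead applies a Bartlett
    (triangular) window truncated at that fraction of the segment length.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("segment too short")
    if max_lag_frac is None:
        return _ims_longrun_variance(_autocovariances(x, n - 1), n)
    M = max(1, int(np.floor(max_lag_frac * n)))
    acov = _autocovariances(x, M)
    w = 1.0 - np.arange(1, M + 1) / (M + 1)
    return float(acov[0] + 2.0 * np.sum(w * acov[1:]))


@dataclass
class GewekeResult:
    z: float
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    defined: bool = True


def geweke_z(chain_column, c_a: float = 0.10, c_b: float = 0.50,
             max_lag_frac: float | None = None) -> GewekeResult:
    """Geweke convergence Z-score for one parameter chain (post burn-in).

    Z = (mean_A - mean_B) / sqrt(S_A(0)/n_A + S_B(0)/n_B) over the disjoint
    prefix (fraction ``c_a``) and suffix (fraction ``c_b``) segments.
    A zero-variance segment yields ``defined=False`` rather than NaN.
    """
    x = np.asarray(chain_column, dtype=float)
    n = len(x)
    if not (0 < c_a and 0 < c_b and c_a + c_b < 1):
        raise ValueError("need c_a, c_b > 0 and c_a + c_b < 1")
    if n < 100:
        raise ValueError("post-burn-in chain too short for a Geweke test")
    na, nb = int(np.floor(c_a * n)), int(np.floor(c_b * n))
    a, b = x[:na], x[n - nb:]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return GewekeResult(np.nan, a.mean(), b.mean(), 0.0, 0.0, defined=False)
    va = spectral_density_zero(a, max_lag_frac)
    vb = spectral_density_zero(b, max_lag_frac)
    denom = np.sqrt(va / na + vb / nb)
    if denom == 0:
        return GewekeResult(np.nan, a.mean(), b.mean(), va, vb, defined=False)
    return GewekeResult(float((a.mean() - b.mean()) / denom),
                        float(a.mean()), float(b.mean()), va, vb)


def geweke_sweep(chain: np.ndarray, n_bins: int = 80, c_a: float = 0.10,
                 c_b: float = 0.50) -> np.ndarray:
    """Z-scores after discarding 0, 1, 2, ... front bins (at most half).

    ``chain`` is (n, d) post burn-in; returns (n_kept_offsets, d) where the
    sweep stops before more than half the chain would be discarded.
    """
    chain = np.atleast_2d(np.asarray(chain, dtype=float))
    n, d = chain.shape
    if n < 2 * n_bins:
        raise ValueError("chain too short for the requested number of bins")
    bin_len = n // n_bins
    out = []
    for k in range(n_bins // 2 + 1):
        start = k * bin_len
        if n - start < n // 2:
            break
        seg = chain[start:]
        out.append([geweke_z(seg[:, j], c_a, c_b).z for j in range(d)])
    return np.asarray(out)


def ess_imse(chain_column) -> float:
    """Effective sample size by the initial monotone sequence estimator.

    ESS = R / (1 + 2 sum_q gamma_q) with the autocorrelation sum truncated
    at the first negative adjacent pair and the pair sums forced
    non-increasing.  Clamped to [1, R]; a constant chain returns 1.
    """
    x = np.asarray(chain_column, dtype=float)
    R = len(x)
    if R < 10:
        raise ValueError("chain too short for ESS estimation")
    if np.ptp(x) == 0:
        return 1.0
    acov = _autocovariances(x, R - 1)
    sigma2 = _ims_longrun_variance(acov, R)
    ess = R * acov[0] / sigma2
    return float(np.clip(ess, 1.0, R))


@dataclass
class ESSResult:
    per_parameter: np.ndarray
    mean: float
    min: float
    wall_time_minutes: float | None = None

    @property
    def ness(self) -> float | None:
        """Worst-case time-normalised ESS: minutes per effective sample."""
        if self.wall_time_minutes is None:
            return None
        return self.wall_time_minutes / self.min


def ess_summary(chain: np.ndarray, wall_time_minutes: float | None = None) -> ESSResult:
    """Per-parameter, mean and min ESS for an (n, d) post-burn-in chain."""
    chain = np.atleast_2d(np.asarray(chain, dtype=float))
    ess = np.array([ess_imse(chain[:, j]) for j in range(chain.shape[1])])
    return ESSResult(ess, float(ess.mean()), float(ess.min()), wall_time_minutes)


@dataclass
class ErrorSummary:
    l2_parameter: float
    prediction_rmse: float
    running_rmse: np.ndarray | None = None


def error_summary(posterior_draws: np.ndarray, theta_true, rec=None,
                  grid=None, running: bool = False,
                  running_stride: int = 50) -> ErrorSummary:
    """Posterior-accuracy summaries against the known generative truth.

    * ``l2_parameter``: ||posterior mean - theta_true||_2 in parameter space.
    * ``prediction_rmse``: RMSE between the trajectory simulated at the
      posterior-mean parameters and the noiseless truth (requires ``rec``).
    * ``running_rmse``: the same RMSE with the posterior mean accumulated
      over increasing numbers of draws (evaluated every ``running_stride``
      draws) — the convergence trace of the prediction error.
    """
    from .nmm import simulate

    draws = np.atleast_2d(np.asarray(posterior_draws, dtype=float))
    theta_true = np.asarray(theta_true, dtype=float)
    post_mean = draws.mean(axis=0)
    l2 = float(np.linalg.norm(post_mean - theta_true))

    rmse = np.nan
    run = None
    if rec is not None:
        grid = grid or rec.grid

        def pred_rmse(theta):
            traj = simulate(theta, grid)
            if not traj.success:
                return np.nan
            return float(np.sqrt(np.mean((traj.x9 - rec.clean) ** 2)))

        rmse = pred_rmse(post_mean)
        if running:
            cum = np.cumsum(draws, axis=0)
            ks = np.arange(running_stride, len(draws) + 1, running_stride)
            run = np.array([pred_rmse(cum[k - 1] / k) for k in ks])
    return ErrorSummary(l2, rmse, run)
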