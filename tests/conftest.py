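"""Shared fixtures: synthetic recordings and analytic toy targets."""

from __future__ import annotations

import numpy as np
import pytest

from massmc import nmm
from massmc.samplers import NMMPosterior


class GaussianTarget:
    """Multivariate Normal log-density target with optional fixed metric."""

    def __init__(self, cov, metric=None):
        self.cov = np.atleast_2d(np.asarray(cov, dtype=float))
        self.prec = np.linalg.inv(self.cov)
        self.dim = self.cov.shape[0]
        self._metric = self.prec if metric is None else np.asarray(metric, float)

    def logp(self, theta):
        theta = np.atleast_1d(theta)
        return -0.5 * float(theta @ self.prec @ theta)

    def logp_grad(self, theta):
        theta = np.atleast_1d(theta)
        return self.logp(theta), -self.prec @ theta

    def logp_grad_metric(self, theta):
        lp, g = self.logp_grad(theta)
        return lp, g, self._metric.copy()

    def initial_state(self, rng):
        return rng.standard_normal(self.dim)


class FlatTarget:
    """Constant density: every Metropolis proposal is accepted."""

    dim = 3

    def logp(self, theta):
        return 0.0

    def logp_grad(self, theta):
        return 0.0, np.zeros(self.dim)

    def initial_state(self, rng):
        return np.zeros(self.dim)


class HalfLineTarget:
    """1-D standard Normal restricted to theta > 0 (for -inf rejection)."""

    dim = 1

    def logp(self, theta):
        theta = np.atleast_1d(theta)
        if theta[0] <= 0:
            return -np.inf
        return -0.5 * float(theta @ theta)

    def logp_grad(self, theta):
        return self.logp(theta), -np.atleast_1d(theta)

    def initial_state(self, rng):
        return np.array([1.0])


@pytest.fixture(scope="session")
def true_theta():
    return nmm.true_parameters()


@pytest.fixture(scope="session")
def recording():
    """Reference synthetic recording on the default 100-point grid."""
    return nmm.generate_dataset(seed=11)


@pytest.fixture(scope="session")
def posterior(recording):
    return NMMPosterior(recording)


@pytest.fixture(scope="session")
def stable_prior_draws():
    """A handful of dynamically stable prior draws (shared across tests)."""
    rng = np.random.default_rng(123)
    draws = []
    while len(draws) < 8:
        theta = nmm.sample_prior(1, rng=rng)[0]
        if nmm.find_fixed_point(theta).stable:
            draws.append(theta)
    return np.array(draws)
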