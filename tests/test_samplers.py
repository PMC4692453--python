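"""Correctness of the four MCMC kernels and the leapfrog integrator."""

import numpy as np
import pytest

from conftest import FlatTarget, GaussianTarget, HalfLineTarget
from massmc.samplers import (
    Chain,
    ChainState,
    HMCSettings,
    LMCSettings,
    MHSettings,
    hmc_step,
    leapfrog,
    lmc_e_step,
    lmc_r_step,
    mh_step,
    run_sampler,
    specular_reflect,
)
from massmc.tuning import TuningBounds


def _mc_se(x):
    return x.std() / np.sqrt(len(x))


class TestMHStep:
    def test_flat_target_accepts_everything(self):
        target = FlatTarget()
        rng = np.random.default_rng(0)
        state = ChainState(np.zeros(3), 0.0)
        for _ in range(50):
            state = mh_step(state, target, rng)
            assert state.accepted

    def test_minus_inf_proposal_always_rejected(self):
        target = HalfLineTarget()
        rng = np.random.default_rng(0)
        state = ChainState(np.array([0.05]), target.logp(np.array([0.05])))
        rejected_neg = 0
        tried_neg = 0
        for _ in range(400):
            new = mh_step(state, target, rng, scale=4.0)
            # any accepted move must stay inside the support
            assert new.theta[0] > 0
            state = new
        # chain remained in support throughout
        assert np.isfinite(state.logp)


class TestLeapfrog:
    def _harmonic_grad(self, theta):
        return -theta  # J = -theta^2/2

    def test_reversibility(self):
        rng = np.random.default_rng(3)
        theta, rho = rng.normal(size=2), rng.normal(size=2)
        M = np.ones(2)
        th1, r1, ok = leapfrog(theta, rho, 0.1, 25, M, self._harmonic_grad,
                               reflect=False)
        th2, r2, ok2 = leapfrog(th1, -r1, 0.1, 25, M, self._harmonic_grad,
                                reflect=False)
        assert ok and ok2
        np.testing.assert_allclose(th2, theta, atol=1e-10)
        np.testing.assert_allclose(-r2, rho, atol=1e-10)

    def test_one_step_map_is_volume_preserving(self):
        """On H = theta^2/2 + rho^2/2 one leapfrog step is the linear map
        K(eps/2) D(eps) K(eps/2); its determinant is exactly 1."""
        eps = 0.3
        K = np.array([[1.0, 0.0], [-eps / 2.0, 1.0]])  # half kick: rho += eps/2 * (-theta)
        D = np.array([[1.0, eps], [0.0, 1.0]])          # drift: theta += eps * rho
        A = K @ D @ K
        assert np.linalg.det(A) == pytest.approx(1.0, abs=1e-14)
        # our integrator realises exactly this map
        z0 = np.array([0.7, -0.4])
        th, r, ok = leapfrog(z0[:1], z0[1:], eps, 1, np.ones(1),
                             self._harmonic_grad, reflect=False)
        expected = A @ z0
        assert th[0] == pytest.approx(expected[0], abs=1e-14)
        assert r[0] == pytest.approx(expected[1], abs=1e-14)

    def test_energy_error_scales_quadratically(self):
        errs = []
        for eps in (0.1, 0.05):
            th, r = np.array([1.0]), np.array([0.0])
            worst = 0.0
            for _ in range(int(round(2 * np.pi / eps))):  # one period
                th, r, _ = leapfrog(th, r, eps, 1, np.ones(1),
                                    self._harmonic_grad, reflect=False)
                worst = max(worst, abs(0.5 * float(th @ th + r @ r) - 0.5))
            errs.append(worst)
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.25)

    def test_reflection_keeps_positivity(self):
        grad = lambda th: np.zeros(1)
        th, r, ok = leapfrog(np.array([0.05]), np.array([-1.0]), 0.2, 5,
                             np.ones(1), grad, reflect=True)
        assert ok
        assert th[0] > 0


class TestSpecularReflect:
    def test_norm_preserved_and_involution(self):
        rng = np.random.default_rng(0)
        rho = rng.normal(size=10)
        n = rng.normal(size=10)
        n /= np.linalg.norm(n)
        r1 = specular_reflect(rho, n)
        assert np.linalg.norm(r1) == pytest.approx(np.linalg.norm(rho))
        np.testing.assert_allclose(specular_reflect(r1, n), rho, atol=1e-12)

    def test_normal_incidence_and_zero_normal(self):
        n = np.zeros(10)
        n[2] = 1.0
        np.testing.assert_allclose(specular_reflect(n.copy(), n), -n)
        with pytest.raises(ValueError):
            specular_reflect(np.ones(10), np.zeros(10))


class TestKernelExactness:
    """All kernels leave a known Gaussian target invariant."""

    @pytest.mark.parametrize("kind,settings", [
        ("mh", MHSettings(scale=1.0)),
        ("lmc_e", LMCSettings(eps=0.9)),
        ("lmc_r", LMCSettings(eps=1.2, metric=True)),
        ("hmc", HMCSettings(eps=0.45, L=8, tune=False, reflect=False)),
    ])
    def test_recovers_correlated_gaussian_moments(self, kind, settings):
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        target = GaussianTarget(cov)
        chain = run_sampler(kind, target, n_samples=20_000, burn_in=2_000,
                            seed=17, settings=settings)
        post = chain.posterior
        from massmc.diagnostics import ess_imse

        for j in range(2):
            ess = ess_imse(post[:, j])
            se_mean = post[:, j].std() / np.sqrt(ess)
            assert abs(post[:, j].mean()) < 3 * se_mean + 0.02
            se_var = post[:, j].var() * np.sqrt(2.0 / ess)
            assert abs(post[:, j].var() - 1.0) < 3 * se_var + 0.02
        c = np.corrcoef(post.T)[0, 1]
        assert c == pytest.approx(0.9, abs=0.05)

    def test_hmc_acceptance_rises_as_step_shrinks(self):
        target = GaussianTarget(np.eye(2))
        rates = []
        for eps in (1.2, 0.6, 0.15):
            chain = run_sampler("hmc", target, n_samples=800, burn_in=100,
                                seed=3, settings=HMCSettings(eps=eps, L=5,
                                                             tune=False,
                                                             reflect=False))
            rates.append(chain.acceptance_rate)
        assert rates[0] < rates[1] < rates[2]
        assert rates[2] > 0.98


class TestLangevinReductions:
    def test_lmc_e_with_zero_gradient_is_random_walk(self):
        target = FlatTarget()
        rng = np.random.default_rng(9)
        state = ChainState(np.zeros(3), 0.0, grad=np.zeros(3))
        eps = 0.5
        new = lmc_e_step(state, target, rng, eps)
        # drift-free: jump is exactly eps * z for the consumed z
        rng2 = np.random.default_rng(9)
        z = rng2.standard_normal(3)
        np.testing.assert_allclose(new.theta, eps * z)

    def test_lmc_r_with_identity_metric_equals_lmc_e(self):
        cov = np.array([[2.0, 0.3], [0.3, 0.5]])
        t_e = GaussianTarget(cov)
        t_r = GaussianTarget(cov, metric=np.eye(2))
        ch_e = run_sampler("lmc_e", t_e, 3000, 500, seed=21,
                           settings=LMCSettings(eps=0.4),
                           init=np.zeros(2))
        ch_r = run_sampler("lmc_r", t_r, 3000, 500, seed=21,
                           settings=LMCSettings(eps=0.4, metric=True),
                           init=np.zeros(2))
        np.testing.assert_allclose(ch_r.draws, ch_e.draws, atol=1e-12)

    def test_lmc_r_scalar_metric_rescales_step(self):
        cov = np.array([[1.5, 0.0], [0.0, 0.8]])
        c = 4.0
        t_r = GaussianTarget(cov, metric=c * np.eye(2))
        t_e = GaussianTarget(cov)
        eps = 0.6
        ch_r = run_sampler("lmc_r", t_r, 2000, 200, seed=8,
                           settings=LMCSettings(eps=eps, metric=True),
                           init=np.zeros(2))
        ch_e = run_sampler("lmc_e", t_e, 2000, 200, seed=8,
                           settings=LMCSettings(eps=eps / np.sqrt(c)),
                           init=np.zeros(2))
        np.testing.assert_allclose(ch_r.draws, ch_e.draws, atol=1e-10)

    def test_default_step_size_is_paper_value(self):
        assert LMCSettings().eps == 0.75


class TestRunSampler:
    def test_degenerate_run_returns_initial_state(self):
        target = GaussianTarget(np.eye(2))
        chain = run_sampler("mh", target, n_samples=1, burn_in=0, seed=0,
                            init=np.array([0.3, -0.2]))
        np.testing.assert_array_equal(chain.draws[0], [0.3, -0.2])

    def test_same_seed_gives_bit_identical_chains(self):
        target = GaussianTarget(np.eye(3))
        a = run_sampler("lmc_e", target, 500, 100, seed=13,
                        settings=LMCSettings(eps=0.5))
        b = run_sampler("lmc_e", target, 500, 100, seed=13,
                        settings=LMCSettings(eps=0.5))
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.accepted, b.accepted)

    def test_protocol_defaults(self):
        import inspect

        sig = inspect.signature(run_sampler)
        assert sig.parameters["n_samples"].default == 20_000
        assert sig.parameters["burn_in"].default == 6_000

    def test_chain_never_holds_minus_inf_after_start(self):
        target = HalfLineTarget()
        chain = run_sampler("mh", target, 500, 0, seed=1,
                            settings=MHSettings(scale=4.0),
                            init=np.array([0.5]))
        assert np.all(np.isfinite(chain.log_joint))

    def test_rejects_bad_kind_and_lengths(self):
        target = GaussianTarget(np.eye(2))
        with pytest.raises(ValueError):
            run_sampler("nuts", target, 100, 10)
        with pytest.raises(ValueError):
            run_sampler("mh", target, 100, 100)
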