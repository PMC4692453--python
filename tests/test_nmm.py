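"""Model definition, simulation, stability and prior sampling."""

import numpy as np
import pytest
from scipy import stats

from massmc import nmm


class TestSigmoid:
    def test_zero_and_oddness(self):
        assert nmm.sigmoid(0.0) == 0.0
        v = np.linspace(-40, 40, 41)
        np.testing.assert_allclose(nmm.sigmoid(v) + nmm.sigmoid(-v), 0.0, atol=1e-15)

    def test_bounds_and_value(self):
        v = np.array([-1e4, -10, 10, 1e4])
        s = nmm.sigmoid(v)
        assert np.all(s >= -0.5) and np.all(s <= 0.5)  # saturates in float
        assert np.all(np.abs(nmm.sigmoid(np.linspace(-30, 30, 7))) < 0.5)
        assert nmm.sigmoid(10.0) == pytest.approx(1.0 / (1.0 + np.exp(-5.6)) - 0.5)

    def test_derivative_matches_finite_difference(self):
        for v in (-3.0, 0.0, 1.7):
            fd = (nmm.sigmoid(v + 1e-6) - nmm.sigmoid(v - 1e-6)) / 2e-6
            assert nmm.dsigmoid(v) == pytest.approx(fd, rel=1e-6)
        assert nmm.dsigmoid(0.0) == pytest.approx(0.14)


class TestVectorField:
    def test_origin_fixed_point_drive_off(self, true_theta):
        f = nmm.vector_field(np.zeros(9), true_theta, input_on=False)
        np.testing.assert_array_equal(f, np.zeros(9))

    def test_drive_enters_only_spiny_stellate_equation(self, true_theta):
        f = nmm.vector_field(np.zeros(9), true_theta, input_on=True)
        g1, g2, g3, g4, delta, ti, hi, te, he, u = true_theta
        assert f[3] == pytest.approx(he * u / te)
        mask = np.ones(9, dtype=bool)
        mask[3] = False
        np.testing.assert_array_equal(f[mask], np.zeros(8))

    def test_delay_free_limit_matches_instantaneous_arguments(self, true_theta):
        rng = np.random.default_rng(0)
        x = rng.normal(size=9)
        th = true_theta.copy()
        th[4] = 0.0  # delta = 0
        f = nmm.vector_field(x, th, input_on=True)
        g1, g2, g3, g4, _, ti, hi, te, he, u = th
        s = nmm.sigmoid
        assert f[4] == pytest.approx(g2 * he * s(x[0]) / te - x[1] / te**2 - 2 * x[4] / te)
        assert f[7] == pytest.approx(g3 * he * s(x[8]) / te - x[6] / te**2 - 2 * x[7] / te)


class TestJacobians:
    @pytest.mark.parametrize("seed", range(5))
    def test_state_jacobian_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(scale=2.0, size=9)
        theta = nmm.sample_prior(1, rng=rng)[0]
        J = nmm.jacobian_x(x, theta)
        Jfd = np.empty((9, 9))
        h = 1e-6
        for j in range(9):
            e = np.zeros(9)
            e[j] = h
            Jfd[:, j] = (nmm.vector_field(x + e, theta) - nmm.vector_field(x - e, theta)) / (2 * h)
        np.testing.assert_allclose(J, Jfd, rtol=1e-5, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_parameter_jacobian_matches_finite_differences(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(scale=2.0, size=9)
        theta = nmm.sample_prior(1, rng=rng)[0]
        Jt = nmm.jacobian_theta(x, theta)
        Jfd = np.empty((9, 10))
        for p in range(10):
            h = 1e-6 * max(theta[p], 1.0)
            e = np.zeros(10)
            e[p] = h
            Jfd[:, p] = (nmm.vector_field(x, theta + e) - nmm.vector_field(x, theta - e)) / (2 * h)
        np.testing.assert_allclose(Jt, Jfd, rtol=1e-5, atol=1e-6)

    def test_linear_rows_are_state_independent(self, true_theta):
        rng = np.random.default_rng(1)
        J1 = nmm.jacobian_x(rng.normal(size=9), true_theta)
        J2 = nmm.jacobian_x(rng.normal(size=9), true_theta)
        for row in (0, 1, 2, 6, 8):
            np.testing.assert_array_equal(J1[row], J2[row])

    def test_sigmoid_slope_enters_pyramidal_coupling(self, true_theta):
        th = true_theta.copy()
        th[4] = 0.0  # delta = 0 isolates the instantaneous coupling
        J = nmm.jacobian_x(np.zeros(9), th)
        g1, g2, g3, g4, _, ti, hi, te, he, u = th
        assert J[3, 8] == pytest.approx(he * g1 * 0.14 / te)


class TestSimulate:
    def test_zero_drive_stays_at_origin(self, true_theta):
        th = true_theta.copy()
        th[9] = 1e-300  # effectively no drive
        traj = nmm.simulate(th)
        assert traj.success
        np.testing.assert_allclose(traj.x, 0.0, atol=1e-9)

    def test_tolerance_refinement_converges(self, true_theta):
        coarse = nmm.simulate(true_theta, rtol=1e-3, atol=1e-3)
        fine = nmm.simulate(true_theta, rtol=5e-4, atol=5e-4)
        ref = nmm.simulate(true_theta, rtol=1e-9, atol=1e-11)
        err_coarse = np.max(np.abs(coarse.x9 - ref.x9))
        err_fine = np.max(np.abs(fine.x9 - ref.x9))
        assert err_coarse < 5e-2
        assert err_fine <= err_coarse * 1.5  # refinement does not degrade

    def test_true_parameters_give_damped_step_response(self, true_theta):
        traj = nmm.simulate(true_theta)
        assert traj.success
        # early transient oscillates, late trace settles near a new level
        early = np.ptp(traj.x9[:50])
        late = np.ptp(traj.x9[-10:])
        assert early > 10 * late
        assert abs(traj.x9[-1]) > 0.1  # settles away from zero

    def test_delay_continuity(self, true_theta):
        th0 = true_theta.copy()
        th0[4] = 1e-8
        base = nmm.simulate(th0, rtol=1e-6, atol=1e-8)
        diffs = []
        for delta in (0.5, 0.05):
            th = true_theta.copy()
            th[4] = delta
            traj = nmm.simulate(th, rtol=1e-6, atol=1e-8)
            diffs.append(np.max(np.abs(traj.x9 - base.x9)))
        assert diffs[1] < diffs[0]
        assert diffs[1] < 0.05


class TestFixedPointStability:
    def test_residual_below_tolerance(self, stable_prior_draws):
        rep = nmm.find_fixed_point(stable_prior_draws[0])
        assert rep.converged
        assert rep.residual_norm <= 1e-8

    def test_structural_zero_eigenvalue_present(self, true_theta):
        # the equilibrium continuum induces one eigenvalue at exactly zero
        rep = nmm.find_fixed_point(true_theta)
        assert np.min(np.abs(rep.eigenvalues)) < 1e-10
        assert len(rep.eigenvalues) == 9
        assert len(rep.eigenvalues_reduced) == 8

    def test_true_model_is_stable(self, true_theta):
        rep = nmm.find_fixed_point(true_theta)
        assert rep.stable
        assert np.max(rep.eigenvalues_reduced.real) < 0

    def test_classification_predicts_long_run_settling(self):
        """Manifold eigenvalue classification vs a long-integration oracle.

        Draws decisively away from the marginal boundary must settle to the
        manifold fixed point iff classified stable.
        """
        rng = np.random.default_rng(7)
        checked = agree = 0
        while checked < 10:
            theta = nmm.sample_prior(1, rng=rng)[0]
            rep = nmm.find_fixed_point(theta)
            rate = abs(np.max(rep.eigenvalues_reduced.real))
            if rate < 0.02:
                continue
            t_end = max(200.0, 10.0 / rate)
            traj = nmm.simulate(theta, nmm.SimulationGrid(0, t_end, 100),
                                rtol=1e-6, atol=1e-8)
            settled = traj.success and np.max(
                np.abs(traj.x[-5:] - rep.manifold_fixed_point)) < 0.05
            checked += 1
            agree += rep.stable == settled
        assert agree >= 9


class TestPriorSampling:
    def test_moments_match_gamma_closed_forms(self):
        n = 100_000
        draws = nmm.sample_prior(n, rng=0)
        shapes, scales = nmm.prior_shapes_scales()
        # g1 mean and delta variance against k1*k2 and k1*k2^2
        mean_g1 = draws[:, 0].mean()
        se_g1 = draws[:, 0].std() / np.sqrt(n)
        assert abs(mean_g1 - shapes[0] * scales[0]) < 3 * se_g1
        var_d = draws[:, 4].var()
        se_var = np.sqrt(2.0 / (n - 1)) * var_d  # normal-ish approx
        assert abs(var_d - shapes[4] * scales[4] ** 2) < 3 * se_var

    def test_all_draws_strictly_positive_and_reproducible(self):
        a = nmm.sample_prior(1000, rng=42)
        b = nmm.sample_prior(1000, rng=42)
        assert np.all(a > 0)
        np.testing.assert_array_equal(a, b)


class TestGenerateDataset:
    def test_zero_noise_returns_clean_trace(self):
        rec = nmm.generate_dataset(noise_var=0.0, seed=0)
        np.testing.assert_array_equal(rec.y, rec.clean)

    def test_noise_variance_calibration(self):
        grid = nmm.SimulationGrid(0, 100, 5000)
        rec1 = nmm.generate_dataset(grid=grid, seed=1)
        rec2 = nmm.generate_dataset(grid=grid, seed=2)
        noise = np.concatenate([rec1.y - rec1.clean, rec2.y - rec2.clean])
        n = len(noise)
        se = 0.0625 * np.sqrt(2.0 / (n - 1))
        assert abs(noise.var() - 0.0625) < 3 * se

    def test_seeded_reproducibility_bit_identical(self):
        a = nmm.generate_dataset(seed=5)
        b = nmm.generate_dataset(seed=5)
        np.testing.assert_array_equal(a.y, b.y)

    def test_refuses_negative_noise(self):
        with pytest.raises(ValueError):
            nmm.generate_dataset(noise_var=-1.0)


class TestPriorTableIO:
    def test_default_table_shape_and_order(self):
        df = nmm.default_prior_table()
        assert list(df["parameter"]) == list(nmm.PARAM_NAMES)
        assert (df["shape"] > 1).all()  # prior curvature positive everywhere

    def test_round_trip(self, tmp_path):
        path = tmp_path / "priors.csv"
        nmm.save_prior_table(nmm.default_prior_table(), path)
        df = nmm.load_prior_table(path)
        np.testing.assert_allclose(df["scale"], nmm.default_prior_table()["scale"])

    def test_rejects_malformed_table(self, tmp_path):
        path = tmp_path / "bad.csv"
        df = nmm.default_prior_table().copy()
        df.loc["g1", "shape"] = -1.0
        df.reset_index(drop=True).to_csv(path, index=False)
        with pytest.raises(ValueError):
            nmm.load_prior_table(path)
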