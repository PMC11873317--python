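"""Simulator, benchmark definitions, initial sampling and splitting."""

import numpy as np
import pytest

from sdecoeff.sde import (BrownianDraws, CoefficientField, InitialDistribution,
                          PathEnsemble, SDEProblem, SimulationDivergedError,
                          TimeGrid, euler_maruyama_simulate,
                          make_benchmark_problem, sample_initial,
                          split_train_test)


class TestTimeGrid:
    def test_regular_grid_properties(self):
        g = TimeGrid.regular(0.0, 5.0, 400)
        assert g.n_times == 400
        assert g.dt == pytest.approx(5.0 / 399)

    def test_rejects_non_equidistant(self):
        with pytest.raises(ValueError, match="equidistant"):
            TimeGrid(np.array([0.0, 0.1, 0.3]))

    def test_rejects_decreasing_and_short(self):
        with pytest.raises(ValueError):
            TimeGrid(np.array([0.0, -0.1]))
        with pytest.raises(ValueError):
            TimeGrid(np.array([0.0]))


class TestEulerMaruyama:
    def test_zero_dynamics_constant_paths(self, toy_grid):
        prob = SDEProblem(
            CoefficientField(lambda t, x: 0.0 * x, lambda t, x: 0.0 * x),
            InitialDistribution.point(3.0), toy_grid)
        ens = euler_maruyama_simulate(prob, 4, noise=0)
        assert np.all(ens.array == 3.0)

    def test_deterministic_euler_recursion(self):
        grid = TimeGrid.regular(0.0, 1.0, 11)  # dt = 0.1
        prob = SDEProblem(
            CoefficientField(lambda t, x: -2.0 * x, lambda t, x: 0.0 * x),
            InitialDistribution.point(1.0), grid)
        ens = euler_maruyama_simulate(prob, 1, noise=0)
        assert ens.array[0, 1] == pytest.approx(0.8, abs=1e-15)
        assert ens.array[0, 2] == pytest.approx(0.64, abs=1e-15)

    def test_drift_free_matches_forward_euler_bitwise(self, toy_grid):
        # diffusion == 0: stochastic simulator must equal the ODE recursion exactly
        prob = SDEProblem(
            CoefficientField(lambda t, x: np.sin(x) - 0.5 * x,
                             lambda t, x: 0.0 * x),
            InitialDistribution.point(0.7), toy_grid)
        ens = euler_maruyama_simulate(prob, 1, noise=5)
        x = np.array([0.7])
        for k in range(toy_grid.n_times - 1):
            x = x + (np.sin(x) - 0.5 * x) * toy_grid.dt
            assert ens.array[0, k + 1] == x[0]

    def test_ou_moments_match_closed_form(self):
        lam = sig = 2.0
        prob = make_benchmark_problem(
            "OU", grid=TimeGrid.regular(0.0, 1.0, 201),
            initial=InitialDistribution.point(1.0))
        ens = euler_maruyama_simulate(prob, 5000, noise=42)
        xt = ens.array[:, -1]
        mean_true = np.exp(-lam)
        var_true = sig ** 2 * (1 - np.exp(-2 * lam)) / (2 * lam)
        se_mean = np.sqrt(var_true / 5000)
        se_var = var_true * np.sqrt(2.0 / (5000 - 1))
        assert abs(xt.mean() - mean_true) < 4 * se_mean
        assert abs(xt.var(ddof=1) - var_true) < 4 * se_var

    def test_constant_diffusion_increment_variance(self):
        sigma = 1.5
        grid = TimeGrid.regular(0.0, 1.0, 11)
        prob = SDEProblem(
            CoefficientField(lambda t, x: 0.0 * x,
                             lambda t, x: sigma * np.ones_like(x)),
            InitialDistribution.point(0.0), grid)
        ens = euler_maruyama_simulate(prob, 10_000, noise=9)
        incs = np.diff(ens.array, axis=1)
        target = sigma ** 2 * grid.dt
        se = target * np.sqrt(2.0 / (10_000 - 1))
        assert np.all(np.abs(incs.var(axis=0, ddof=1) - target) < 5 * se)

    def test_cir_guard_no_nan_at_paper_scale(self):
        prob = make_benchmark_problem("CIR")
        ens = euler_maruyama_simulate(prob, 5000, noise=3)
        assert np.all(np.isfinite(ens.array))

    def test_divergence_raises_with_step_index(self):
        grid = TimeGrid.regular(0.0, 10.0, 11)
        prob = SDEProblem(
            CoefficientField(lambda t, x: x ** 3, lambda t, x: 0.0 * x),
            InitialDistribution.point(5.0), grid)
        with pytest.raises(SimulationDivergedError):
            euler_maruyama_simulate(prob, 1, noise=0)

    def test_same_seed_identical_ensembles(self, ou_problem_small):
        a = euler_maruyama_simulate(ou_problem_small, 50, noise=5)
        b = euler_maruyama_simulate(ou_problem_small, 50, noise=5)
        assert np.array_equal(a.array, b.array)

    def test_noise_shape_mismatch_rejected(self, ou_problem_small):
        draws = BrownianDraws.sample(10, ou_problem_small.grid, 0)
        with pytest.raises(ValueError, match="shape"):
            euler_maruyama_simulate(ou_problem_small, 20, noise=draws,
                                    initial_values=np.zeros(20))


class TestBenchmarks:
    def test_ou_coefficients(self):
        p = make_benchmark_problem("OU")
        assert p.coefficients.drift(0.0, 1.0) == pytest.approx(-2.0)
        assert p.coefficients.diffusion(0.0, 5.0) == pytest.approx(2.0)

    def test_cir_coefficients(self):
        p = make_benchmark_problem("CIR")
        assert p.coefficients.drift(0.0, 4.0) == pytest.approx(0.0)
        assert p.coefficients.diffusion(0.0, 4.0) == pytest.approx(4.0)
        # guard: sqrt evaluated at max(x, 0)
        assert p.coefficients.diffusion(0.0, -1.0) == pytest.approx(0.0)

    def test_sin1_coefficients(self):
        p = make_benchmark_problem("SIN1")
        assert p.coefficients.drift(0.0, 0.0) == pytest.approx(0.0)
        x = 1.3
        assert p.coefficients.drift(0.0, x) == pytest.approx(
            15.0 * np.sin(x / (2 * np.pi)) - 2.0 * x)
        assert p.coefficients.diffusion(0.0, -2.0) == pytest.approx(3.0)

    def test_sin2_constant_diffusion(self, rng):
        p = make_benchmark_problem("SIN2")
        ts, xs = rng.uniform(0, 2, 20), rng.uniform(-5, 5, 20)
        assert np.allclose(p.coefficients.diffusion(ts, xs), 1.0)
        assert p.coefficients.drift(0.5, 0.7) == pytest.approx(
            -15.0 * np.sin(0.7) + np.sin(0.5) / (2 * np.pi) - 2.0 * 0.7)

    def test_unknown_name_and_bad_params(self):
        with pytest.raises(ValueError, match="unknown"):
            make_benchmark_problem("GBM")
        with pytest.raises(ValueError, match="positive"):
            make_benchmark_problem("OU", params={"lambda": -1.0, "sigma": 2.0})
        with pytest.raises(ValueError, match="requires"):
            make_benchmark_problem("OU", params={"lambda": 1.0})


class TestInitialSampling:
    def test_point_mass(self):
        spec = InitialDistribution.point(2.0)
        assert np.array_equal(sample_initial(spec, 3, 0), [2.0, 2.0, 2.0])

    def test_normal_mean_within_clt_bound(self):
        draws = sample_initial(InitialDistribution.normal(0.0, 3.0), 10 ** 5, 1)
        assert abs(draws.mean()) < 4 * 3.0 / np.sqrt(10 ** 5)

    def test_exponential_mean(self):
        draws = sample_initial(InitialDistribution.exponential(0.5), 10 ** 5, 2)
        se = 2.0 / np.sqrt(10 ** 5)
        assert abs(draws.mean() - 2.0) < 4 * se

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            InitialDistribution.normal(0.0, -1.0)
        with pytest.raises(ValueError):
            InitialDistribution.exponential(0.0)


class TestSplit:
    def test_paper_scale_split(self, ou_problem_small):
        ens = euler_maruyama_simulate(ou_problem_small, 5000, noise=0)
        tr, te = split_train_test(ens, 0.2, seed=1)
        assert tr.n_paths == 4000 and te.n_paths == 1000

    def test_split_is_partition(self, ou_small):
        tr, te = split_train_test(ou_small, 0.2, seed=3)
        joined = np.vstack([tr.array, te.array])
        # every original path appears exactly once across the two parts
        order = np.lexsort(joined.T)
        orig = np.lexsort(ou_small.array.T)
        assert np.array_equal(joined[order], ou_small.array[orig])

    def test_split_deterministic(self, ou_small):
        a = split_train_test(ou_small, 0.2, seed=9)
        b = split_train_test(ou_small, 0.2, seed=9)
        assert np.array_equal(a[0].array, b[0].array)
        assert np.array_equal(a[1].array, b[1].array)

    def test_small_split(self, toy_grid, rng):
        ens = PathEnsemble(rng.normal(size=(5, 5)), toy_grid)
        tr, te = split_train_test(ens, 0.2, seed=0)
        assert tr.n_paths == 4 and te.n_paths == 1

    def test_degenerate_fraction(self, toy_grid, rng):
        ens = PathEnsemble(rng.normal(size=(3, 5)), toy_grid)
        with pytest.raises(ValueError):
            split_train_test(ens, 1e-9, seed=0)
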