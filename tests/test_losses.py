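"""Loss formulations: hand-computed values, oracle checks, invariants."""

import numpy as np
import pytest
from scipy.optimize import linprog

from sdecoeff.autodiff import Tensor
from sdecoeff.losses import (LossConfig, TransitionBatch, autocorrelation_loss,
                             em_neg2_log_pseudolik, ensemble_acf, hybrid_loss,
                             lag_autocorrelation, lt_neg2_log_pseudolik,
                             moment_loss, pseudolik_loss,
                             wasserstein1_empirical, wasserstein_loss)
from sdecoeff.network import build_network, fit_scaler
from sdecoeff.sde import (BrownianDraws, CoefficientField, PathEnsemble,
                          TimeGrid, euler_maruyama_simulate,
                          make_benchmark_problem)

from conftest import make_ensemble

UNIT_DIFFUSION = CoefficientField(lambda t, x: 0.0 * x,
                                  lambda t, x: np.ones_like(x))
OU_FIELD = CoefficientField(lambda t, x: -2.0 * x, lambda t, x: np.ones_like(x))


def w1_linear_program(u, v):
    """Exhaustive optimal-transport LP between two empirical measures."""
    n, m = len(u), len(v)
    cost = np.abs(np.subtract.outer(u, v)).ravel()
    a_eq = []
    for i in range(n):
        row = np.zeros((n, m)); row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(m):
        row = np.zeros((n, m)); row[:, j] = 1
        a_eq.append(row.ravel())
    b_eq = np.concatenate([np.full(n, 1.0 / n), np.full(m, 1.0 / m)])
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=b_eq, method="highs")
    assert res.success
    return res.fun


class TestMomentLoss:
    def test_identical_ensembles_zero(self, rng, toy_grid):
        e = PathEnsemble(rng.normal(size=(6, 5)), toy_grid)
        assert moment_loss(e, e) == 0.0

    def test_hand_example_single_active_timepoint(self):
        # column {0,2} vs {1,1}: means agree, sample variances 2 vs 0 -> 4
        obs = make_ensemble([[0.0, 5.0], [2.0, 5.0]])
        sim = make_ensemble([[1.0, 5.0], [1.0, 5.0]])
        assert moment_loss(obs, sim) == pytest.approx(4.0)

    def test_constant_shift_only_moves_means(self, rng):
        obs = make_ensemble(rng.normal(size=(8, 4)))
        sim = make_ensemble(obs.array + 0.7)
        assert moment_loss(obs, sim) == pytest.approx(4 * 0.7 ** 2)

    def test_grid_mismatch_rejected(self, rng):
        a = make_ensemble(rng.normal(size=(4, 3)))
        b = make_ensemble(rng.normal(size=(4, 3)), t1=2.0)
        with pytest.raises(ValueError, match="grids"):
            moment_loss(a, b)


class TestWasserstein:
    def test_point_masses(self):
        assert wasserstein1_empirical([0.0], [1.0]) == pytest.approx(1.0)

    def test_sorted_coupling_closed_form(self):
        assert wasserstein1_empirical([0.0, 2.0], [1.0, 3.0]) == pytest.approx(1.0)

    def test_identical_samples_zero(self, rng):
        u = rng.normal(size=9)
        assert wasserstein1_empirical(u, u.copy()) == 0.0

    @pytest.mark.parametrize("sizes", [(5, 5), (5, 7), (3, 8)])
    def test_matches_linear_program(self, rng, sizes):
        n, m = sizes
        for _ in range(20):
            u, v = rng.normal(size=n), rng.normal(size=m)
            assert wasserstein1_empirical(u, v) == pytest.approx(
                w1_linear_program(u, v), abs=1e-8)

    def test_metric_axioms_small(self, rng):
        for _ in range(20):
            a, b, c = (rng.normal(size=5) for _ in range(3))
            dab = wasserstein1_empirical(a, b)
            assert dab == pytest.approx(wasserstein1_empirical(b, a), abs=1e-12)
            assert dab <= (wasserstein1_empirical(a, c)
                           + wasserstein1_empirical(c, b) + 1e-12)

    def test_differentiable_through_sorting(self, rng):
        v0 = rng.normal(size=6)
        v = Tensor(v0, requires_grad=True)
        out = wasserstein1_empirical(rng.normal(size=4), v)
        out.backward()
        assert np.all(np.isfinite(v.grad)) and np.any(v.grad != 0)

    def test_loss_constant_shift(self, rng):
        obs = make_ensemble(rng.normal(size=(10, 4)))
        sim = make_ensemble(obs.array + 1.0)
        assert wasserstein_loss(obs, sim) == pytest.approx(2.0)

    def test_loss_single_shifted_timepoint(self, rng):
        obs = make_ensemble(rng.normal(size=(10, 3)))
        shifted = obs.array.copy()
        shifted[:, 1] += 3.0
        sim = make_ensemble(shifted)
        assert wasserstein_loss(obs, sim) == pytest.approx(1.0 + 3.0)

    def test_loss_zero_iff_identical_marginals(self, rng):
        obs = make_ensemble(rng.normal(size=(10, 4)))
        perm = obs.array.copy()
        for k in range(4):  # same marginals, different path pairing
            perm[:, k] = np.random.default_rng(k).permutation(perm[:, k])
        assert wasserstein_loss(obs, make_ensemble(perm)) == pytest.approx(0.0)
        assert wasserstein_loss(obs, make_ensemble(perm + 0.1)) > 0


class TestAutocorrelation:
    def test_linear_path_perfect_correlation(self):
        assert lag_autocorrelation(np.arange(10.0), 3) == pytest.approx(1.0)

    def test_alternating_path(self):
        alt = np.array([1.0, -1.0] * 5)
        assert lag_autocorrelation(alt, 1) == pytest.approx(-1.0)
        assert lag_autocorrelation(alt, 2) == pytest.approx(1.0)

    def test_constant_path_raises(self):
        with pytest.raises(ValueError, match="constant"):
            lag_autocorrelation(np.ones(10), 1)

    def test_loss_from_linear_vs_alternating(self):
        lin = make_ensemble(np.tile(np.arange(8.0), (3, 1)))
        alt = make_ensemble(np.tile(np.array([1.0, -1.0] * 4), (3, 1)))
        # rho_1 = 1 vs -1 -> (1 - (-1))^2 = 4
        assert autocorrelation_loss(lin, alt, K=1) == pytest.approx(4.0)

    def test_loss_symmetric(self, rng):
        a = make_ensemble(rng.normal(size=(5, 10)))
        b = make_ensemble(rng.normal(size=(5, 10)))
        assert autocorrelation_loss(a, b, 3) == pytest.approx(
            autocorrelation_loss(b, a, 3))

    def test_identical_zero(self, rng):
        a = make_ensemble(rng.normal(size=(5, 10)))
        assert autocorrelation_loss(a, a, 3) == pytest.approx(0.0)

    def test_k_too_large_rejected(self, rng):
        a = make_ensemble(rng.normal(size=(5, 6)))
        with pytest.raises(ValueError, match="too large"):
            autocorrelation_loss(a, a, K=4)

    def test_constant_paths_skipped_with_warning(self, rng):
        vals = rng.normal(size=(4, 10))
        vals[0] = 1.0  # one constant path: excluded from the ensemble mean
        a = make_ensemble(vals)
        expected = ensemble_acf(vals[1:], 2)
        assert np.allclose(ensemble_acf(vals, 2), expected)
        all_const = make_ensemble(np.ones((3, 10)))
        with pytest.warns(UserWarning, match="constant"):
            assert autocorrelation_loss(all_const, a, 2) >= 0.0


class TestPseudoLikelihoods:
    def test_em_zero_residual_unit_scale(self):
        batch = TransitionBatch(t=[0.0], x=[1.0], dt=[1.0], x_next=[1.0])
        val = em_neg2_log_pseudolik(batch, UNIT_DIFFUSION)
        assert val[0] == pytest.approx(np.log(2 * np.pi), abs=1e-9)

    def test_em_hand_value(self):
        batch = TransitionBatch(t=[0.0], x=[1.0], dt=[0.1], x_next=[1.2])
        field = CoefficientField(lambda t, x: np.ones_like(x),
                                 lambda t, x: np.ones_like(x))
        assert em_neg2_log_pseudolik(batch, field)[0] == pytest.approx(
            np.log(2 * np.pi * 0.1) + 0.1, abs=1e-9)

    def test_em_b2dt_unit(self):
        # b=2, dt=0.25 -> b^2 dt = 1; zero residual leaves only log(2 pi)
        field = CoefficientField(lambda t, x: 0.3 * np.ones_like(x),
                                 lambda t, x: 2.0 * np.ones_like(x))
        batch = TransitionBatch(t=[0.0], x=[0.5], dt=[0.25],
                                x_next=[0.5 + 0.3 * 0.25])
        assert em_neg2_log_pseudolik(batch, field)[0] == pytest.approx(
            np.log(2 * np.pi), abs=1e-9)

    def test_lt_state_constant_drift_zero(self):
        field = CoefficientField(lambda t, x: np.ones_like(x),
                                 lambda t, x: np.ones_like(x))
        batch = TransitionBatch(t=[0.0], x=[2.0], dt=[1.0], x_next=[3.0])
        assert lt_neg2_log_pseudolik(batch, field)[0] == pytest.approx(0.0, abs=1e-9)

    def test_lt_ou_hand_values(self):
        batch = TransitionBatch(t=[0.0], x=[1.0], dt=[0.1], x_next=[0.82])
        assert lt_neg2_log_pseudolik(batch, OU_FIELD)[0] == pytest.approx(
            np.log(0.1), abs=1e-7)
        batch2 = TransitionBatch(t=[0.0], x=[1.0], dt=[0.1], x_next=[0.9])
        assert lt_neg2_log_pseudolik(batch2, OU_FIELD)[0] == pytest.approx(
            np.log(0.1) + 0.064, abs=1e-7)

    def test_lt_minus_em_is_log2pi_for_state_constant_drift(self, rng):
        # drift depends on t only -> d_x a = 0 -> difference is the constant
        field = CoefficientField(lambda t, x: np.sin(t) * np.ones_like(x),
                                 lambda t, x: 0.5 + 0.0 * x)
        batch = TransitionBatch(t=rng.uniform(0, 2, 1000),
                                x=rng.normal(size=1000),
                                dt=rng.uniform(0.01, 0.5, 1000),
                                x_next=rng.normal(size=1000))
        diff = (lt_neg2_log_pseudolik(batch, field)
                - em_neg2_log_pseudolik(batch, field))
        assert np.allclose(diff, -np.log(2 * np.pi), atol=1e-9)

    def test_network_lt_uses_exact_tangent(self, rng):
        net = build_network(seed=4)
        batch = TransitionBatch(t=rng.uniform(0, 1, 32), x=rng.normal(size=32),
                                dt=np.full(32, 0.05), x_next=rng.normal(size=32))
        out = lt_neg2_log_pseudolik(batch, net)
        out.sum().backward()
        assert all(np.all(np.isfinite(p.grad)) for p in net.parameters
                   if p.grad is not None)

    def test_pseudolik_loss_averages(self, rng):
        ens = make_ensemble(rng.normal(size=(2, 3)))
        per = em_neg2_log_pseudolik(TransitionBatch.from_ensemble(ens), OU_FIELD)
        assert pseudolik_loss(ens, OU_FIELD, "em") == pytest.approx(per.mean())

    def test_batched_evaluations_average_to_full(self, rng):
        ens = make_ensemble(rng.normal(size=(4, 6)))
        full = pseudolik_loss(ens, OU_FIELD, "em")
        n = 4 * 5
        parts = [pseudolik_loss(ens, OU_FIELD, "em", batch=idx)
                 for idx in np.split(np.arange(n), 4)]
        assert np.mean(parts) == pytest.approx(full, rel=1e-10)

    def test_true_coefficients_beat_zero_drift_on_ou(self):
        prob = make_benchmark_problem(
            "OU", grid=TimeGrid.regular(0.0, 2.0, 50))
        data = euler_maruyama_simulate(prob, 100, noise=8)
        true_field = CoefficientField(lambda t, x: -2.0 * x,
                                      lambda t, x: 2.0 * np.ones_like(x))
        null_field = CoefficientField(lambda t, x: 0.0 * x,
                                      lambda t, x: 2.0 * np.ones_like(x))
        assert (pseudolik_loss(data, true_field, "em")
                < pseudolik_loss(data, null_field, "em"))


class TestHybrid:
    def test_single_term_scaling(self, rng):
        ens = make_ensemble(rng.normal(size=(6, 5)))
        cfg = LossConfig(terms=("lt",), eta=10.0)
        assert hybrid_loss(ens, OU_FIELD, cfg) == pytest.approx(
            10.0 * pseudolik_loss(ens, OU_FIELD, "lt"))

    def test_additivity_of_terms(self, ou_small):
        net = build_network(seed=1)
        sdata = fit_scaler(ou_small).transform_ensemble(ou_small)
        cfg = LossConfig(terms=("moment", "em"), m=50)
        noise = BrownianDraws.sample(50, sdata.grid, 3)
        total = hybrid_loss(sdata, net, cfg, noise, initial_seed=5)
        from sdecoeff.losses import simulate_for_loss
        sim = simulate_for_loss(sdata, net, 50, noise, initial_seed=5)
        sim_detached = PathEnsemble(sim.array.copy(), sim.grid)
        expected = (moment_loss(sdata, sim_detached)
                    + 10.0 * pseudolik_loss(sdata, net, "em").item())
        assert total.item() == pytest.approx(expected, rel=1e-9)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            LossConfig(terms=())
        with pytest.raises(ValueError):
            LossConfig(terms=("em", "lt"))
        with pytest.raises(ValueError):
            LossConfig(terms=("momentum",))

    def test_gradients_finite_all_terms(self, ou_small):
        net = build_network(seed=2)
        sdata = fit_scaler(ou_small).transform_ensemble(ou_small)
        cfg = LossConfig(terms=("moment", "wasserstein", "autocorr", "lt"),
                         m=30, K=3, batch_size=256)
        noise = BrownianDraws.sample(30, sdata.grid, 1)
        loss = hybrid_loss(sdata, net, cfg, noise,
                           batch=np.arange(256), initial_seed=2)
        loss.backward()
        for p in net.parameters:
            assert p.grad is not None and np.all(np.isfinite(p.grad))
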