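"""Neural-ODE core: initialisation, loss, simulation, gradients, training."""

import numpy as np
import pytest

from bloomdyn.ude import (EnsembleResult, NetworkSpec, TrainingConfig,
                          UDEModel, init_network, lda_loss,
                          select_representative, simulate_ude, train_ensemble,
                          train_ude, _lda_loss_grad, _mlp_forward,
                          _rk4_backward, _rk4_forward)


class TestInitNetwork:
    def test_parameter_count_matches_independent_formula(self):
        spec = NetworkSpec()
        # independent count: sum over layers of (w_in * w_out + w_out)
        widths = [8, 16, 16, 16, 16, 5]
        expected = sum(widths[i] * widths[i + 1] + widths[i + 1]
                       for i in range(len(widths) - 1))
        assert expected == 1045
        model = init_network(spec)
        total = sum(W.size + b.size for W, b in model.params)
        assert total == spec.n_params == expected

    def test_same_seed_identical_weights(self):
        a = init_network(NetworkSpec(seed=42))
        b = init_network(NetworkSpec(seed=42))
        for (Wa, ba), (Wb, bb) in zip(a.params, b.params):
            np.testing.assert_array_equal(Wa, Wb)
            np.testing.assert_array_equal(ba, bb)

    def test_different_seeds_differ(self):
        a = init_network(NetworkSpec(seed=1))
        b = init_network(NetworkSpec(seed=2))
        assert any(not np.array_equal(Wa, Wb)
                   for (Wa, _), (Wb, _) in zip(a.params, b.params))

    def test_invalid_widths_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(widths=(7, 16, 5))
        with pytest.raises(ValueError):
            NetworkSpec(widths=(8, 16, 4))


class TestLdaLoss:
    def test_zero_at_equality(self):
        x = np.random.default_rng(0).normal(size=(7, 5))
        assert lda_loss(x, x) == pytest.approx(0.0, abs=1e-14)

    def test_colinear_vectors_have_zero_angle_term(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(4, 5))
        y = 2.0 * m
        norms = np.linalg.norm(m, axis=1)
        expected = 0.2 * np.mean((norms - 2 * norms) ** 2)
        assert lda_loss(m, y) == pytest.approx(expected, rel=1e-12)

    def test_orthogonal_unit_vectors_cost_the_angle_weight(self):
        m = np.array([[1.0, 0, 0, 0, 0]])
        y = np.array([[0.0, 1.0, 0, 0, 0]])
        assert lda_loss(m, y) == pytest.approx(0.8, abs=1e-14)

    def test_zero_vector_contributes_no_angle_term(self):
        m = np.zeros((1, 5))
        y = np.array([[0.0, 2.0, 0, 0, 0]])
        assert lda_loss(m, y) == pytest.approx(0.2 * 4.0, abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            lda_loss(np.zeros((3, 5)), np.zeros((4, 5)))

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m = rng.normal(size=(6, 5))
            y = rng.normal(size=(6, 5))
            assert lda_loss(m, y) >= 0.0

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(5, 5))
        y = rng.normal(size=(5, 5))
        loss, grad = _lda_loss_grad(m, y, 0.2, 0.8)
        eps = 1e-7
        for idx in [(0, 0), (2, 3), (4, 4)]:
            mp = m.copy(); mp[idx] += eps
            mm = m.copy(); mm[idx] -= eps
            fd = (lda_loss(mp, y) - lda_loss(mm, y)) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestSimulateUde:
    def test_zero_final_layer_gives_constant_trajectory(self, standardized_clean):
        _, _, drivers = standardized_clean
        model = init_network(NetworkSpec(seed=0), drivers)
        W, b = model.params[-1]
        model.params[-1] = (np.zeros_like(W), np.zeros_like(b))
        x0 = np.array([0.5, -1.0, 0.2, 0.0, 1.0])
        traj = simulate_ude(model, x0, np.arange(1.0, 100.0), drivers)
        np.testing.assert_allclose(traj, np.tile(x0, (99, 1)), atol=1e-9)

    def test_first_point_equals_x0_exactly(self, standardized_clean):
        _, _, drivers = standardized_clean
        model = init_network(NetworkSpec(seed=5), drivers)
        x0 = np.zeros(5)
        traj = simulate_ude(model, x0, np.array([1.0, 50.0, 100.0]), drivers)
        np.testing.assert_array_equal(traj[0], x0)

    def test_agrees_with_independent_fixed_step_integrator(self, standardized_clean):
        _, _, drivers = standardized_clean
        model = init_network(NetworkSpec(seed=2), drivers)
        t_grid = np.arange(1.0, 200.0)
        traj = simulate_ude(model, np.zeros(5), t_grid, drivers, rtol=1e-8)
        # brute-force RK4 oracle at half-day steps, written independently
        h = 0.5
        x = np.zeros(5)
        oracle = [x]
        t = 1.0
        for _ in range(int((199 - 1) / h) - 1):
            def f(tt, xx):
                return model.rhs(xx[None], drivers(tt)[None])[0]
            k1 = f(t, x)
            k2 = f(t + h / 2, x + h / 2 * k1)
            k3 = f(t + h / 2, x + h / 2 * k2)
            k4 = f(t + h, x + h * k3)
            x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            if abs(t - round(t)) < 1e-9:
                oracle.append(x)
        oracle = np.array(oracle)
        np.testing.assert_allclose(traj[: len(oracle)], oracle, atol=1e-4)

    def test_outside_driver_domain_rejected(self, standardized_clean):
        _, _, drivers = standardized_clean
        model = init_network(NetworkSpec(seed=0), drivers)
        with pytest.raises(ValueError):
            simulate_ude(model, np.zeros(5), np.array([0.2, 10.0]), drivers)


class TestRk4Gradient:
    def test_backprop_matches_finite_difference_through_solver(self, standardized_clean):
        """End-to-end gradient of a trajectory loss w.r.t. all weights."""
        _, _, drivers = standardized_clean
        spec = NetworkSpec(widths=(8, 6, 5), seed=9, rate_scale=0.05)
        model = init_network(spec, drivers)
        h = 1.0
        n_steps = 30
        d_half = drivers(1.0 + 0.5 * h * np.arange(2 * n_steps + 1))
        x0 = np.array([0.1, -0.2, 0.3, 0.0, -0.1])
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(n_steps + 1, 5))

        def loss_of(params):
            X, _, ok = _rk4_forward(params, spec.rate_scale, x0, d_half, h)
            assert ok
            return lda_loss(X, Y)

        X, caches, ok = _rk4_forward(model.params, spec.rate_scale, x0, d_half, h)
        _, gM = _lda_loss_grad(X, Y, 0.2, 0.8)
        grads = _rk4_backward(model.params, spec.rate_scale, caches, gM, h)

        eps = 1e-6
        for layer, coord in [(0, (2, 3)), (1, (4, 5)), (1, (0, 0))]:
            Wp = [(W.copy(), b.copy()) for W, b in model.params]
            Wp[layer][0][coord] += eps
            up = loss_of(Wp)
            Wm = [(W.copy(), b.copy()) for W, b in model.params]
            Wm[layer][0][coord] -= eps
            down = loss_of(Wm)
            fd = (up - down) / (2 * eps)
            assert grads[layer][0][coord] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestTrainUde:
    def test_zero_iterations_returns_initialised_model(self, standardized_clean):
        _, std, drivers = standardized_clean
        spec = NetworkSpec(widths=(8, 16, 16, 5), seed=0)
        cfg = TrainingConfig(iterations=0, seed=0)
        trained = train_ude(std, drivers, spec, cfg)
        fresh = init_network(spec)
        for (Wt, bt), (Wf, bf) in zip(trained.params, fresh.params):
            np.testing.assert_array_equal(Wt, Wf)
        assert trained.loss_history == []

    def test_loss_history_finite_and_decreasing_overall(self, standardized_clean):
        _, std, drivers = standardized_clean
        spec = NetworkSpec(widths=(8, 16, 16, 5), seed=1)
        cfg = TrainingConfig(iterations=40, seed=1)
        model = train_ude(std, drivers, spec, cfg)
        hist = np.asarray(model.loss_history)
        assert len(hist) == 40
        assert np.all(np.isfinite(hist))
        assert hist[-1] <= hist[0]

    def test_noiseless_recovery_battery(self, standardized_clean, preset,
                                        truth_trajectory, day_grid):
        """Multi-start training on clean data recovers the true trajectory.

        The trajectory loss is multi-modal (single-peak local minima
        exist), which is why the method trains batteries of networks; the
        best of a three-seed battery must track the truth closely.
        """
        _, std, drivers = standardized_clean
        best = np.inf
        for seed in (0, 1, 2):
            spec = NetworkSpec(widths=(8, 16, 16, 5), seed=seed)
            cfg = TrainingConfig(iterations=500, seed=seed)
            model = train_ude(std, drivers, spec, cfg)
            traj = simulate_ude(model, model.x0, day_grid, drivers)
            best = min(best, float(np.mean((traj - truth_trajectory) ** 2)))
        assert best <= 0.05

    def test_x0_rule_uses_early_observations(self, standardized_clean):
        from bloomdyn.preprocessing import STATE_VARS
        _, std, drivers = standardized_clean
        cfg = TrainingConfig(iterations=0, seed=0)
        model = train_ude(std, drivers, NetworkSpec(widths=(8, 16, 16, 5)), cfg)
        early = std[std["day_of_year"] <= 30]
        np.testing.assert_allclose(
            model.x0, early[STATE_VARS].to_numpy().mean(axis=0), atol=1e-12)


@pytest.fixture(scope="module")
def small_ensemble(standardized_clean):
    _, std, drivers = standardized_clean
    spec = NetworkSpec(widths=(8, 16, 16, 5), seed=0)
    cfg = TrainingConfig(iterations=30, seed=0)
    return train_ensemble(std, drivers, spec, cfg, n_members=3,
                          t_grid=np.arange(1.0, 366.0, 5.0))


class TestEnsemble:
    def test_mean_is_pointwise_average(self, small_ensemble):
        np.testing.assert_allclose(
            small_ensemble.mean_trajectory,
            small_ensemble.member_trajectories.mean(axis=0), atol=1e-12)

    def test_single_member_mean_equals_member(self, standardized_clean):
        _, std, drivers = standardized_clean
        spec = NetworkSpec(widths=(8, 16, 16, 5), seed=3)
        cfg = TrainingConfig(iterations=10, seed=3)
        ens = train_ensemble(std, drivers, spec, cfg, n_members=1,
                             t_grid=np.arange(1.0, 366.0, 10.0))
        np.testing.assert_array_equal(ens.mean_trajectory,
                                      ens.member_trajectories[0])
        assert ens.member_mse[0] == 0.0

    def test_members_differ(self, small_ensemble):
        assert small_ensemble.member_mse.max() > 0
        assert np.all(np.isfinite(small_ensemble.member_mse))

    def test_representative_is_brute_force_argmin(self, small_ensemble):
        rep = select_representative(small_ensemble)
        mses = [np.mean((T - small_ensemble.mean_trajectory) ** 2)
                for T in small_ensemble.member_trajectories]
        assert rep is small_ensemble.members[int(np.argmin(mses))]

    def test_representative_of_identical_members(self, small_ensemble):
        traj = small_ensemble.member_trajectories[0]
        ens = EnsembleResult(
            members=list("abc"), t_grid=small_ensemble.t_grid,
            member_trajectories=np.stack([traj, traj, traj]),
            mean_trajectory=traj, member_mse=np.zeros(3))
        assert select_representative(ens) == "a"   # lowest index on ties


class TestCheckpoint:
    def test_json_round_trip(self, standardized_clean, tmp_path):
        _, std, drivers = standardized_clean
        spec = NetworkSpec(widths=(8, 16, 16, 5), seed=4)
        cfg = TrainingConfig(iterations=5, seed=4)
        model = train_ude(std, drivers, spec, cfg)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = UDEModel.from_json(path, drivers=drivers)
        X = np.random.default_rng(0).normal(size=(4, 5))
        D = np.random.default_rng(1).normal(size=(4, 3))
        np.testing.assert_allclose(loaded.rhs(X, D), model.rhs(X, D), atol=1e-12)
        np.testing.assert_allclose(loaded.x0, model.x0)
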