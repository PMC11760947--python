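"""Basis library, derivative harvesting, and sparse equation fitting."""

import itertools

import numpy as np
import pytest

from bloomdyn.sindy import (DerivativeSample, build_library, evaluate_library,
                            fit_sparse, parse_equations, sample_derivatives,
                            to_equations, tune_sparsity)
from bloomdyn.ude import NetworkSpec, init_network, simulate_ude


def _enumerate_monomials(n, order):
    """Independent oracle: count distinct monomials of degree <= order."""
    count = 1                                  # the constant
    for deg in range(1, order + 1):
        count += len(list(itertools.combinations_with_replacement(range(n), deg)))
    return count


class TestBuildLibrary:
    def test_default_library_has_45_named_functions(self):
        lib = build_library(5, 3, 2)
        assert len(lib) == 45
        assert len(set(lib.names)) == 45

    @pytest.mark.parametrize("n_state, n_driver, expected", [
        (1, 0, 3), (3, 0, 10), (2, 1, 10),
    ])
    def test_small_libraries(self, n_state, n_driver, expected):
        assert len(build_library(n_state, n_driver, 2)) == expected

    def test_count_formula_against_enumeration(self):
        for n in range(1, 11):
            lib = build_library(n, 0, 2)
            assert len(lib) == 1 + n + n * (n + 1) // 2
            assert len(lib) == _enumerate_monomials(n, 2)

    def test_unsupported_order_rejected(self):
        with pytest.raises(ValueError):
            build_library(5, 3, 3)

    def test_deterministic_ordering(self):
        lib = build_library(5, 3, 2)
        assert lib.names[0] == "1"
        assert lib.names[1:9] == ["Chl-a", "DIN", "DIP", "totN", "totP",
                                  "Temp", "Sal", "Kd"]
        assert lib.names[9] == "Chl-a^2"
        assert lib.names[17] == "Chl-a*DIN"


class TestEvaluateLibrary:
    def test_zero_input_hits_only_the_constant(self):
        lib = build_library()
        out = evaluate_library(lib, np.zeros(5), np.zeros(3))
        expected = np.zeros(45)
        expected[0] = 1.0
        np.testing.assert_array_equal(out, expected)

    def test_single_variable_monomials(self):
        lib = build_library()
        out = evaluate_library(lib, np.array([2.0, 0, 0, 0, 0]), np.zeros(3))
        names = lib.names
        assert out[names.index("Chl-a")] == 2.0
        assert out[names.index("Chl-a^2")] == 4.0
        assert out[names.index("Chl-a*DIN")] == 0.0

    def test_matches_brute_force_symbolic_expansion(self):
        lib = build_library()
        rng = np.random.default_rng(0)
        z = rng.normal(size=8)
        out = evaluate_library(lib, z[:5], z[5:])
        for k, term in enumerate(lib.terms):
            expected = 1.0
            for i in term:                     # independent product evaluation
                expected *= z[i]
            assert out[k] == pytest.approx(expected, abs=1e-12)


class TestSampleDerivatives:
    def test_zero_output_network_yields_zero_derivatives(self, standardized_clean):
        _, _, drivers = standardized_clean
        model = init_network(NetworkSpec(widths=(8, 16, 16, 5), seed=0), drivers)
        W, b = model.params[-1]
        model.params[-1] = (np.zeros_like(W), np.zeros_like(b))
        model.x0 = np.array([0.4, 0.1, -0.2, 0.0, 0.3])
        t_grid = np.arange(1.0, 100.0)
        sample = sample_derivatives(model, drivers, t_grid, seed=0)
        np.testing.assert_allclose(sample.Xdot, 0.0, atol=1e-12)
        base = sample.base()
        np.testing.assert_allclose(base.X, np.tile(model.x0, (99, 1)), atol=1e-9)

    def test_row_count_and_base_block(self, standardized_clean):
        _, _, drivers = standardized_clean
        model = init_network(NetworkSpec(widths=(8, 16, 16, 5), seed=1), drivers)
        model.x0 = np.zeros(5)
        t_grid = np.arange(1.0, 51.0)
        sample = sample_derivatives(model, drivers, t_grid,
                                    state_jitter=0.1, n_repeats=3, seed=2)
        assert len(sample.X) == 50 * 4
        assert sample.n_base == 50
        np.testing.assert_array_equal(sample.base().X, sample.X[:50])

    def test_derivatives_match_finite_differences_of_simulation(
            self, standardized_clean):
        _, _, drivers = standardized_clean
        model = init_network(NetworkSpec(widths=(8, 16, 16, 5), seed=3), drivers)
        model.x0 = np.zeros(5)
        t_dense = np.arange(1.0, 100.0, 0.5)
        traj = simulate_ude(model, model.x0, t_dense, drivers, rtol=1e-9)
        sample = sample_derivatives(model, drivers, np.arange(2.0, 99.0),
                                    n_repeats=0, seed=0)
        # central-difference oracle on the dense simulation
        fd = (traj[2:] - traj[:-2]) / 1.0
        fd_days = t_dense[1:-1]
        keep = np.isin(fd_days, sample.t)
        np.testing.assert_allclose(sample.Xdot, fd[keep], atol=1e-3)


class TestFitSparse:
    def test_zero_penalty_equals_ordinary_least_squares(self, analytic_sample,
                                                        preset):
        lib = preset.library
        model = fit_sparse(analytic_sample, lib, 0.0)
        theta = evaluate_library(lib, analytic_sample.Z)
        for eq in range(5):
            ols = np.linalg.lstsq(theta, analytic_sample.Xdot[:, eq], rcond=None)[0]
            ols[np.abs(ols) < 1e-8] = 0.0
            np.testing.assert_allclose(model.coef[eq], ols, atol=1e-8)

    def test_exact_support_recovery_from_analytic_derivatives(
            self, analytic_sample, preset):
        model = fit_sparse(analytic_sample, preset.library, 1e-6)
        assert np.array_equal(model.coef != 0, preset.support)
        assert np.max(np.abs(model.coef - preset.coef)) < 1e-6

    def test_zero_derivatives_give_empty_model(self, analytic_sample, preset):
        sample = DerivativeSample(t=analytic_sample.t, X=analytic_sample.X,
                                  D=analytic_sample.D,
                                  Xdot=np.zeros_like(analytic_sample.Xdot),
                                  n_base=analytic_sample.n_base)
        model = fit_sparse(sample, preset.library, 1e-5)
        assert np.all(model.coef == 0)
        np.testing.assert_allclose(model.rss, 0.0, atol=1e-20)

    def test_rss_nonincreasing_as_penalty_decreases(self, analytic_sample, preset):
        penalties = np.logspace(-3, -7, 6)
        rss = [fit_sparse(analytic_sample, preset.library, p).rss.sum()
               for p in penalties]
        assert all(b <= a + 1e-9 for a, b in zip(rss, rss[1:]))


class TestTuneSparsity:
    def test_single_value_grid(self, analytic_sample, preset):
        assert tune_sparsity(analytic_sample, preset.library, [3e-4]) == 3e-4

    def test_kappa_zero_prefers_smallest_penalty(self, analytic_sample, preset):
        grid = [1e-6, 1e-5, 1e-4]
        assert tune_sparsity(analytic_sample, preset.library, grid, kappa=0.0) == 1e-6

    def test_selected_penalty_lies_in_exact_recovery_range(
            self, analytic_sample, preset):
        grid = np.logspace(-7, -3, 10)
        chosen = tune_sparsity(analytic_sample, preset.library, grid)
        # brute-force scan oracle for the exact-recovery range
        good = []
        for p in grid:
            m = fit_sparse(analytic_sample, preset.library, p)
            if (np.array_equal(m.coef != 0, preset.support)
                    and np.max(np.abs(m.coef - preset.coef)) < 1e-6):
                good.append(p)
        assert good, "no penalty in the grid recovers the truth"
        assert chosen in good


class TestEquationText:
    def test_all_zero_model_prints_zero_lines(self, preset):
        from bloomdyn.sindy import SparseModel
        model = SparseModel(coef=np.zeros((5, 45)), penalty=0.0,
                            rss=np.zeros(5),
                            library_names=tuple(preset.library.names))
        text = to_equations(model, preset.library)
        assert text.splitlines() == [
            "dChl-a/dt = 0", "dDIN/dt = 0", "dDIP/dt = 0",
            "dtotN/dt = 0", "dtotP/dt = 0"]

    def test_single_constant_term(self, preset):
        from bloomdyn.sindy import SparseModel
        coef = np.zeros((5, 45))
        coef[0, 0] = 0.5
        model = SparseModel(coef=coef, penalty=0.0, rss=np.zeros(5))
        text = to_equations(model, preset.library)
        assert text.splitlines()[0] == "dChl-a/dt = 0.5"

    def test_round_trip_reproduces_coefficients(self, analytic_sample, preset):
        model = fit_sparse(analytic_sample, preset.library, 1e-6)
        text = to_equations(model, preset.library)
        back = parse_equations(text, preset.library)
        np.testing.assert_allclose(back, model.coef, rtol=1e-4, atol=1e-9)
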