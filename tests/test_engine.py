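import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import medbo as mb
from medbo.engine import SurrogateModel, _sample_simplex
from medbo.medium import orient_objectives


class TestChebyshevScalarization:
    def test_symmetric_point(self):
        val = mb.chebyshev_scalarize(np.ones(3), np.full(3, 1 / 3), rho=0.05)
        assert val == pytest.approx(1 / 3 + 0.05)

    def test_zero_rho_reduces_to_weighted_min(self):
        y = np.array([0.2, 0.9])
        w = np.array([0.7, 0.3])
        assert mb.chebyshev_scalarize(y, w, rho=1e-300) == pytest.approx(
            min(0.7 * 0.2, 0.3 * 0.9)
        )

    @given(
        y=st.lists(st.floats(-5, 5), min_size=2, max_size=4),
        w=st.lists(st.floats(0.01, 1), min_size=2, max_size=4),
        rho=st.floats(0.001, 0.5),
    )
    def test_matches_direct_formula(self, y, w, rho):
        k = min(len(y), len(w))
        y, w = np.array(y[:k]), np.array(w[:k])
        wn = w / w.sum()
        expected = min(wn * y) + rho * sum(wn * y)
        assert mb.chebyshev_scalarize(y, w, rho) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_weights_rejected(self):
        with pytest.raises(ValueError):
            mb.chebyshev_scalarize(np.ones(2), np.zeros(2), 0.05)
        with pytest.raises(ValueError):
            mb.chebyshev_scalarize(np.ones(2), np.array([-1.0, 2.0]), 0.05)

    def test_matrix_rows(self):
        Y = np.array([[1.0, 1.0], [0.0, 2.0]])
        w = np.array([0.5, 0.5])
        out = mb.chebyshev_scalarize(Y, w, 0.1)
        assert out.shape == (2,)
        assert out[0] == pytest.approx(0.5 + 0.1 * 1.0)

    def test_simplex_sampler_is_a_distribution(self):
        rng = np.random.default_rng(0)
        draws = np.array([_sample_simplex(rng, 3) for _ in range(200)])
        assert np.allclose(draws.sum(axis=1), 1.0)
        assert np.all(draws >= 0)


class TestInitRandomMedia:
    def test_deterministic_for_fixed_seed(self, chain_medium):
        spec, _ = chain_medium
        a = mb.init_random_media(spec, 20, seed=42)
        b = mb.init_random_media(spec, 20, seed=42)
        assert np.array_equal(a, b)
        c = mb.init_random_media(spec, 20, seed=43)
        assert not np.array_equal(a, c)

    def test_within_box(self, chain_medium):
        spec, _ = chain_medium
        X = mb.init_random_media(spec, 50, seed=0)
        assert X.shape == (50, 2)
        assert np.all(X >= 0) and np.all(X <= spec.box_upper)

    def test_equality_constraint_projection(self, chain_medium):
        spec, _ = chain_medium
        con = mb.LinearConstraint(coefficients={"X0": 1.0, "X1": -2.0}, rhs=0.0)
        X = mb.init_random_media(spec, 30, constraints=[con], seed=1)
        assert np.allclose(X[:, 0] - 2 * X[:, 1], 0.0, atol=1e-9 * spec.box_upper[0])


def _function_dataset(xs, ys, objective="production"):
    """Wrap scalar samples of a 1-d function as a dataset for the surrogate."""
    ds = mb.SampleDataset(["X0"], np.array([1.0]), (objective, "cost"))
    results = [
        mb.ObjectiveVector(
            f_growth=float(y) if objective == "growth" else 0.0,
            f_prod=float(y) if objective == "production" else 0.0,
            f_cost=float(x),
            feasible=True,
        )
        for x, y in zip(xs, ys)
    ]
    ds.append(np.asarray(xs, float)[:, None], results, 0)
    return ds


class TestSurrogate:
    def test_interpolates_linear_data(self):
        xs = np.linspace(0, 1, 12)
        ys = 2.0 + 3.0 * xs
        surr = mb.fit_surrogate(_function_dataset(xs, ys))
        mu, _ = surr.predict(xs[:, None])
        target = (ys - ys.min()) / (ys.max() - ys.min())  # min-max oriented
        assert np.allclose(mu[:, 0], target, atol=1e-4)

    def test_posterior_mean_within_three_sigma_at_training_points(self, small_run):
        dataset, _ = small_run
        surr = mb.fit_surrogate(dataset)
        Y, _ = dataset.oriented()
        mu, sd = surr.predict(dataset.X_unit)
        assert np.all(np.abs(mu - Y) <= 3 * sd + 1e-6)

    def test_variance_shrinks_at_data(self):
        xs = np.linspace(0.2, 0.5, 10)
        surr = mb.fit_surrogate(_function_dataset(xs, np.sin(xs * 6)))
        _, sd_at = surr.predict(np.array([[0.35]]))
        _, sd_far = surr.predict(np.array([[0.99]]))
        assert sd_at[0, 0] <= sd_far[0, 0]

    def test_sine_regression_matches_linear_algebra_oracle(self):
        rng = np.random.default_rng(3)
        xs = np.sort(rng.uniform(0, 1, 20))
        ys = np.sin(2 * np.pi * xs)
        ds = _function_dataset(xs, ys)
        surr = mb.fit_surrogate(ds)
        gp = surr.gps[0]

        xq = np.linspace(0, 1, 100)[:, None]
        mu, _ = surr.predict(xq)

        # independent posterior-mean computation from the fitted kernel
        Y, _ = ds.oriented()
        y = Y[:, 0]
        K = gp.kernel_(xs[:, None]) + gp.alpha * np.eye(20)
        ks = gp.kernel_(xq, xs[:, None])
        mu_oracle = y.mean() + ks @ np.linalg.solve(K, y - y.mean())
        assert np.allclose(mu[:, 0], mu_oracle, atol=1e-6)

        # and the fit is an accurate regression of the function itself
        lo, hi = ys.min(), ys.max()
        pred_raw = mu[:, 0] * (hi - lo) + lo
        rmse = np.sqrt(np.mean((pred_raw - np.sin(2 * np.pi * xq[:, 0])) ** 2))
        assert rmse < 0.05

    def test_fantasy_conditioning_pins_the_added_point(self, small_run):
        dataset, _ = small_run
        surr = mb.fit_surrogate(dataset)
        x_new = np.array([[0.31, 0.77]])
        mu, _ = surr.predict(x_new)
        cond = surr.conditioned(x_new, mu)
        mu2, sd2 = cond.predict(x_new)
        assert np.allclose(mu2, mu, atol=1e-4)

    def test_needs_two_samples(self, chain_medium):
        spec, _ = chain_medium
        ds = mb.SampleDataset(spec.decision_names, spec.box_upper, ("growth", "cost"))
        with pytest.raises(ValueError):
            mb.fit_surrogate(ds)


class TestProposeBatch:
    def test_batch_size_respected(self, small_run):
        dataset, config = small_run
        surr = mb.fit_surrogate(dataset)
        from dataclasses import replace

        X = mb.propose_batch(surr, dataset, replace(config, batch_size=5))
        assert X.shape == (5, 2)
        assert np.all(X >= 0) and np.all(X <= 1)

    def test_constraint_pinning_a_coordinate(self, small_run):
        dataset, config = small_run
        surr = mb.fit_surrogate(dataset)
        from dataclasses import replace

        # physical-unit constraint X0 = 0 pins the first unit coordinate
        con = mb.LinearConstraint(coefficients={"X0": 1.0}, rhs=0.0)
        cfg = replace(config, batch_size=3, constraints=(con,))
        X = mb.propose_batch(surr, dataset, cfg)
        assert np.all(X[:, 0] <= 1e-6)


class TestRunLoop:
    def test_budget_accounting(self, small_run):
        dataset, config = small_run
        assert len(dataset) == config.n_init + config.n_iter * config.batch_size
        assert (dataset.iteration_label == 0).sum() == config.n_init
        for it in range(1, config.n_iter + 1):
            assert (dataset.iteration_label == it).sum() == config.batch_size

    def test_deterministic_replay(self, chain_model, chain_medium, growth_objective, small_run):
        model, _ = chain_model
        spec, prices = chain_medium
        dataset, config = small_run
        again = mb.run(model, spec, prices, growth_objective, ("growth", "cost"), config)
        assert np.array_equal(dataset.X_raw, again.X_raw)
        pd.testing.assert_frame_equal(dataset.Y_raw, again.Y_raw)

    def test_hypervolume_nondecreasing_over_iterations(self, small_run):
        dataset, config = small_run
        Y = orient_objectives(dataset.Y_raw, dataset.objectives)
        # orient cost to positive scale for a fixed reference point
        Y = np.column_stack([Y[:, 0], Y[:, 1] - Y[:, 1].min()])
        hvs = []
        for it in range(config.n_iter + 1):
            sub = Y[dataset.iteration_label <= it]
            hvs.append(mb.dominated_hypervolume(sub))
        assert all(b >= a - 1e-12 for a, b in zip(hvs, hvs[1:]))

    def test_objective_validation(self, chain_model, chain_medium, growth_objective):
        model, _ = chain_model
        spec, prices = chain_medium
        cfg = mb.OptimizationConfig(n_init=2, n_iter=1, batch_size=1, seed=0)
        with pytest.raises(ValueError, match="2 or 3"):
            mb.run(model, spec, prices, growth_objective, ("growth",), cfg)
        with pytest.raises(ValueError, match="production"):
            mb.run(model, spec, prices, growth_objective, ("growth", "production"), cfg)

    def test_one_dimensional_front_recovery(self, chain_spec):
        """With one tunable nutrient the Pareto set is the pre-saturation
        segment u0 in [0, knee]; a short loop should recover nearly all of
        the grid oracle's dominated hypervolume."""
        model, _ = mb.make_toy_gem(chain_spec)
        comps = (
            mb.MediumComponent(name="X0", reaction_id="IMP_X0", role="decision",
                               box_upper=4.0, unit="flux"),
            mb.MediumComponent(name="X1", reaction_id="IMP_X1", role="fixed",
                               baseline_value=4.0, unit="flux"),
        )
        spec = mb.MediumSpec(components=comps)
        prices = mb.PriceTable(prices={"X0": 1.0})
        obj = mb.make_combined_objective(model, 1.0)
        oracle_front, _, oracle_Y = mb.brute_force_pareto(
            model, spec, prices, obj, grid_per_dim=81
        )
        cfg = mb.OptimizationConfig(n_init=6, n_iter=10, batch_size=1, seed=5)
        ds = mb.run(model, spec, prices, obj, ("growth", "cost"), cfg)
        Y = orient_objectives(ds.Y_raw, ds.objectives)
        shift = -oracle_Y[:, 1].min()  # common cost reference
        hv_bo = mb.dominated_hypervolume(Y + np.array([0.0, shift]))
        hv_oracle = mb.dominated_hypervolume(
            oracle_front.Y_members + np.array([0.0, shift])
        )
        assert hv_bo >= 0.95 * hv_oracle


class TestRestartFromPareto:
    def test_padding_arithmetic(self, small_run, chain_medium):
        dataset, _ = small_run
        spec, _ = chain_medium
        cfg = mb.OptimizationConfig(n_init=30, n_iter=1, batch_size=1, seed=2)
        X0 = mb.restart_from_pareto(dataset, spec, cfg)
        n_front = len(mb.extract_front(dataset))
        assert X0.shape == (max(30, n_front), 2)
        assert np.allclose(X0[:n_front], mb.extract_front(dataset).X_members)

    def test_keeps_all_when_front_exceeds_n_init(self, small_run, chain_medium):
        dataset, _ = small_run
        spec, _ = chain_medium
        n_front = len(mb.extract_front(dataset))
        assert n_front > 2
        cfg = mb.OptimizationConfig(n_init=2, n_iter=1, batch_size=1, seed=2)
        X0 = mb.restart_from_pareto(dataset, spec, cfg)
        assert X0.shape[0] == n_front

    def test_chained_runs_do_not_lose_front_quality(
        self, chain_model, chain_medium, growth_objective, small_run
    ):
        model, _ = chain_model
        spec, prices = chain_medium
        first, config = small_run
        X0 = mb.restart_from_pareto(first, spec, config)
        second = mb.run(
            model, spec, prices, growth_objective, ("growth", "cost"), config,
            initial_X=X0,
        )
        ref_shift = max(
            first.Y_raw["cost"].max(), second.Y_raw["cost"].max()
        )

        def hv(ds):
            Y = orient_objectives(ds.Y_raw, ds.objectives)
            return mb.dominated_hypervolume(
                np.column_stack([Y[:, 0], Y[:, 1] + ref_shift])
            )

        assert hv(second) >= hv(first) - 1e-9
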