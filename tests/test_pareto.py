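import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import medbo as mb
from conftest import brute_force_mask
from medbo.medium import orient_objectives


class TestParetoMask:
    def test_singleton_is_nondominated(self):
        assert mb.pareto_mask(np.array([[1.0, 2.0]])).tolist() == [True]

    def test_hand_checked_dominance(self):
        Y = np.array([[1, 0], [0, 1], [0.5, 0.5], [0.4, 0.4]])
        assert mb.pareto_mask(Y).tolist() == [True, True, True, False]

    def test_duplicates_all_retained(self):
        Y = np.array([[1.0, 1.0], [1.0, 1.0], [0.5, 0.5]])
        assert mb.pareto_mask(Y).tolist() == [True, True, False]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mb.pareto_mask(np.empty((0, 2)))

    @given(seed=st.integers(0, 10_000))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        k = int(rng.integers(2, 4))
        Y = rng.normal(size=(n, k)).round(2)  # rounding forces ties
        assert np.array_equal(mb.pareto_mask(Y), brute_force_mask(Y))

    @given(seed=st.integers(0, 1000), scale=st.floats(0.01, 100))
    def test_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        Y = rng.normal(size=(30, 3))
        Z = Y.copy()
        Z[:, 1] *= scale
        assert np.array_equal(mb.pareto_mask(Y), mb.pareto_mask(Z))

    def test_front_invariants_hold(self, small_run):
        dataset, _ = small_run
        front = mb.extract_front(dataset)
        # mutual non-domination among members
        assert np.all(mb.pareto_mask(front.Y_members))
        # every non-member dominated by some member
        Y = orient_objectives(dataset.Y_raw, dataset.objectives)
        members = set(front.member_indices.tolist())
        for i in range(len(dataset)):
            if i in members:
                continue
            dominated = np.any(
                np.all(front.Y_members >= Y[i], axis=1)
                & np.any(front.Y_members > Y[i], axis=1)
            )
            assert dominated


class TestBestRatioTrace:
    def test_running_maximum(self):
        idx, ratio, trace = mb.best_ratio_trace([1, 3, 2], [1, 1, 1])
        assert trace.tolist() == [1, 3, 3]

    def test_monotone_input_is_its_own_trace(self):
        _, ratio, trace = mb.best_ratio_trace([1, 2, 3], [1, 1, 1])
        assert np.array_equal(ratio, trace)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        num = rng.uniform(0, 2, 100)
        den = rng.uniform(0.1, 2, 100)
        _, ratio, trace = mb.best_ratio_trace(num, den)
        best, expected = -np.inf, []
        for n, d in zip(num, den):
            best = max(best, n / d)
            expected.append(best)
        assert np.allclose(trace, expected)

    def test_zero_denominators_excluded(self):
        idx, ratio, _ = mb.best_ratio_trace([1, 2, 3], [0, 1, 1])
        assert idx.tolist() == [1, 2]
        with pytest.raises(ValueError):
            mb.best_ratio_trace([1, 2], [0, 0])


class TestFilterLowGrowth:
    def test_zero_threshold_keeps_everything(self, small_run):
        dataset, _ = small_run
        assert len(mb.filter_low_growth(dataset, 0.0)) == len(dataset)

    def test_standard_cut(self, chain_medium):
        spec, _ = chain_medium
        ds = mb.SampleDataset(spec.decision_names, spec.box_upper, ("growth", "cost"))
        ds.append(
            np.array([[0.1, 0.1], [1.0, 1.0]]),
            [
                mb.ObjectiveVector(0.0005, 0, 0.1, feasible=True),
                mb.ObjectiveVector(0.5, 0, 1.0, feasible=True),
            ],
            0,
        )
        kept = mb.filter_low_growth(ds, 0.001)
        assert kept.tolist() == [1]
        assert len(ds) == 2  # underlying dataset untouched

    @given(seed=st.integers(0, 500))
    def test_commutes_with_pareto_above_threshold(self, seed):
        rng = np.random.default_rng(seed)
        growth = rng.uniform(0, 1, 40)
        cost = rng.uniform(0.1, 2, 40)
        Y = np.column_stack([growth, -cost])
        thr = 0.3
        mask_then_filter = np.flatnonzero(mb.pareto_mask(Y) & (growth >= thr))
        keep = growth >= thr
        sub_mask = mb.pareto_mask(Y[keep])
        filter_then_mask = np.flatnonzero(keep)[sub_mask]
        # every front member above the threshold stays a member after filtering
        assert set(mask_then_filter) <= set(filter_then_mask)


class TestPcaMedia:
    def test_line_data_is_rank_one(self):
        t = np.linspace(0, 1, 30)
        X = np.column_stack([t, 2 * t]) + 1e-9 * np.random.default_rng(0).normal(size=(30, 2))
        _, _, evr = mb.pca_media(X, scale=False)
        assert evr[0] >= 0.999

    def test_rotation_invariant_spectrum(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3)) @ np.diag([3.0, 1.0, 0.3])
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        _, _, evr1 = mb.pca_media(X, scale=False)
        _, _, evr2 = mb.pca_media(X @ R.T, scale=False)
        assert np.allclose(evr1, evr2, atol=1e-10)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(50, 13))
        _, _, evr = mb.pca_media(X, scale=True)
        Z = (X - X.mean(0)) / X.std(0)
        s = np.linalg.svd(Z, compute_uv=False)
        assert np.allclose(evr, s**2 / (s**2).sum(), atol=1e-10)

    def test_constant_column_named_in_error(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match=r"\[0\]"):
            mb.pca_media(X)


class TestComponentDistributions:
    def _front(self, X, box):
        return mb.ParetoFront(
            member_indices=np.arange(len(X)),
            Y_members=np.zeros((len(X), 2)),
            X_members=np.asarray(X, float),
        )

    def test_identical_compositions_have_zero_iqr(self):
        front = self._front([[1.0, 2.0]] * 5, None)
        df = mb.component_distributions(front, ["a", "b"], np.array([4.0, 4.0]))
        assert np.allclose(df["iqr"], 0.0)
        assert df["tight"].all()

    def test_component_pinned_at_box_upper(self):
        X = np.column_stack([np.full(6, 4.0), np.linspace(0, 4, 6)])
        df = mb.component_distributions(self._front(X, None), ["a", "b"], np.array([4.0, 4.0]))
        assert df.loc[df.component == "a", "median"].item() == 1.0
        assert df.loc[df.component == "a", "iqr"].item() == 0.0

    def test_quartiles_match_sorting_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 4, size=(25, 1))
        df = mb.component_distributions(self._front(X, None), ["a"], np.array([4.0]))
        xs = np.sort(X[:, 0] / 4.0)

        def interp_quantile(q):
            # linear interpolation between order statistics (numpy default)
            pos = q * (len(xs) - 1)
            lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
            hi = min(lo + 1, len(xs) - 1)
            return xs[lo] * (1 - frac) + xs[hi] * frac

        for col, q in [("min", 0.0), ("q1", 0.25), ("median", 0.5), ("q3", 0.75), ("max", 1.0)]:
            assert df[col].item() == pytest.approx(interp_quantile(q), abs=1e-12)


class TestPerturbPareto:
    def _toy_front(self):
        Y = np.array([[1.0, 0.0], [0.6, 0.6], [0.0, 1.0]])
        X = np.array([[0.0, 4.0], [2.0, 2.0], [4.0, 0.0]])
        return mb.ParetoFront(member_indices=np.arange(3), Y_members=Y, X_members=X)

    def test_tiny_sigma_converges_to_center(self, chain_model, chain_medium, growth_objective):
        model, _ = chain_model
        spec, prices = chain_medium

        def evaluator(Xp):
            rows = []
            for x in Xp:
                ov = mb.evaluate_objectives(model, spec, x, prices, growth_objective)
                rows.append({"growth": ov.f_growth, "cost": ov.f_cost})
            return orient_objectives(pd.DataFrame(rows), ("growth", "cost"))

        center_X = np.array([[2.0, 4.0]])
        center_Y = evaluator(center_X)
        front = mb.ParetoFront(
            member_indices=np.array([0]), Y_members=center_Y, X_members=center_X
        )
        results = mb.perturb_pareto(
            front, np.array([4.0, 4.0]), sigmas=[1e-6], n_per_center=20,
            evaluator=evaluator, seed=0,
        )
        assert np.allclose(results[0].perturbed_Y, center_Y, atol=1e-4)

    def test_all_dominated_draws_classified_inward(self):
        front = self._toy_front()

        def evaluator(Xp):
            return np.full((len(Xp), 2), 0.1)  # strictly inside the envelope

        results = mb.perturb_pareto(
            front, np.array([4.0, 4.0]), sigmas=[0.1], n_per_center=10,
            evaluator=evaluator, seed=1,
        )
        for r in results:
            assert r.inward_fraction == 1.0

    def test_classification_consistent_with_union_mask(self):
        front = self._toy_front()
        rng = np.random.default_rng(4)

        def evaluator(Xp):
            return rng.uniform(0, 1.2, size=(len(Xp), 2))

        results = mb.perturb_pareto(
            front, np.array([4.0, 4.0]), sigmas=[0.2], n_per_center=15,
            evaluator=evaluator, seed=2,
        )
        for r in results:
            for y, cls in zip(r.perturbed_Y, r.classification):
                union = np.vstack([front.Y_members, y[None, :]])
                nondominated = mb.pareto_mask(union)[-1]
                assert (cls == "outside-envelope") == bool(nondominated)

    def test_perturbations_clipped_to_box(self):
        front = self._toy_front()
        results = mb.perturb_pareto(
            front, np.array([4.0, 4.0]), sigmas=[2.0], n_per_center=50,
            evaluator=lambda X: np.zeros((len(X), 2)), seed=3,
        )
        for r in results:
            assert np.all(r.perturbed_X >= 0) and np.all(r.perturbed_X <= 4.0)

    def test_input_validation(self):
        front = self._toy_front()
        with pytest.raises(ValueError):
            mb.perturb_pareto(front, np.ones(2), [-0.1], 5, lambda X: X, 0)


class TestDominatedHypervolume:
    def test_known_rectangles(self):
        assert mb.dominated_hypervolume(np.array([[0.5, 0.5]])) == pytest.approx(0.25)
        Y = np.array([[1.0, 0.25], [0.5, 0.5], [0.25, 1.0]])
        # union of three rectangles
        expected = 1.0 * 0.25 + 0.5 * 0.25 + 0.25 * 0.5
        assert mb.dominated_hypervolume(Y) == pytest.approx(expected)

    def test_unit_cube_point_3d(self):
        assert mb.dominated_hypervolume(np.array([[1.0, 1.0, 1.0]])) == pytest.approx(1.0)

    @given(seed=st.integers(0, 300))
    def test_matches_monte_carlo(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 4))
        Y = rng.uniform(0, 1, size=(5, k))
        hv = mb.dominated_hypervolume(Y)
        pts = rng.uniform(0, 1, size=(20_000, k))
        inside = np.any(np.all(pts[:, None, :] <= Y[None, :, :], axis=2), axis=1)
        assert hv == pytest.approx(inside.mean(), abs=0.02)

    def test_dominated_points_add_nothing(self):
        base = np.array([[0.8, 0.8]])
        more = np.array([[0.8, 0.8], [0.5, 0.5]])
        assert mb.dominated_hypervolume(base) == mb.dominated_hypervolume(more)
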