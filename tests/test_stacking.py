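"""IPCW-Brier stacking: censoring KM, weights, CV, bands."""

import itertools

import numpy as np
import pytest

import reslife as rl
from reslife.stacking import (
    _fit_submodel,
    _ipcw_weights,
    default_grid,
    ipcw_brier,
    optimize_weights,
)


def toy_censored_data(n=40, seed=0, censor_scale=6.0):
    rng = np.random.default_rng(seed)
    t = rng.exponential(2.0, n)
    c = rng.exponential(censor_scale, n)
    return np.minimum(t, c), (t <= c).astype(int)


class TestCensoringKM:
    def test_hand_computed_product_limit(self):
        G = rl.censoring_km([1.0, 2.0, 3.0], [1, 0, 1])
        assert G(1.9) == 1.0
        assert G(2.0) == pytest.approx(0.5)
        assert G(3.0) == pytest.approx(0.5)
        assert G.left(2.0) == 1.0

    def test_all_events_give_unit_curve(self):
        G = rl.censoring_km([1.0, 2.0, 3.0], [1, 1, 1])
        assert np.all(np.asarray(G(np.array([0.5, 2.0, 5.0]))) == 1.0)

    def test_all_censored_gives_empirical_survival(self):
        G = rl.censoring_km([1.0, 2.0, 4.0], [0, 0, 0])
        np.testing.assert_allclose(
            np.asarray(G(np.array([0.5, 1.0, 2.0, 4.0]))),
            [1.0, 2 / 3, 1 / 3, 0.0],
        )


class TestIPCWBrier:
    def test_perfect_prediction_scores_zero(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        delta = np.ones(4, dtype=int)
        grid = rl.EvaluationGrid(np.array([1.5, 2.5]))
        G = rl.censoring_km(v, delta)
        pred = (v[:, None] > grid.points[None, :]).astype(float)
        assert ipcw_brier(pred, v, delta, grid, G) == 0.0

    def test_constant_half_prediction_uncensored(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        delta = np.ones(4, dtype=int)
        grid = rl.EvaluationGrid(np.array([0.5, 2.5, 3.5]))
        G = rl.censoring_km(v, delta)
        pred = np.full((4, 3), 0.5)
        assert ipcw_brier(pred, v, delta, grid, G) == pytest.approx(0.25 * 12)

    def test_three_subject_censored_case_by_hand(self):
        # V = (1, 2, 3), subject 2 censored; grid point t = 2.5
        # G: censoring event at 2 with 2 at risk => G(t)=0.5 for t>=2
        # weights at t=2.5: subj1 event before t -> 1/G(1-)=1;
        # subj2 censored before t -> 0; subj3 at risk -> 1/G(2.5)=2
        v = np.array([1.0, 2.0, 3.0])
        delta = np.array([1, 0, 1])
        grid = rl.EvaluationGrid(np.array([2.5]))
        G = rl.censoring_km(v, delta)
        pred = np.array([[0.2], [0.9], [0.7]])
        expected = 1.0 * (0.0 - 0.2) ** 2 + 0.0 + 2.0 * (1.0 - 0.7) ** 2
        assert ipcw_brier(pred, v, delta, grid, G) == pytest.approx(expected)

    def test_degenerate_censoring_survival_raises(self):
        v = np.array([1.0, 2.0, 3.0])
        delta = np.array([1, 0, 1])
        grid = rl.EvaluationGrid(np.array([2.5]))
        # explicit censoring curve that vanishes before the grid point while
        # subject 3 is still at risk there
        G = rl.CensoringSurvival(np.array([2.0]), np.array([0.0]))
        pred = np.full((3, 1), 0.5)
        with pytest.raises(rl.stacking.WeightDegeneracyError):
            ipcw_brier(pred, v, delta, grid, G)


class TestCVPredictions:
    def test_fold_assignment_deterministic_in_seed(self):
        v, delta = toy_censored_data(n=60, seed=3)
        grid = default_grid(v)
        p1 = rl.cv_predictions(v, delta, ("exponential", "weibull"), grid=grid, seed=5)
        p2 = rl.cv_predictions(v, delta, ("exponential", "weibull"), grid=grid, seed=5)
        p3 = rl.cv_predictions(v, delta, ("exponential", "weibull"), grid=grid, seed=6)
        np.testing.assert_array_equal(p1, p2)
        assert not np.array_equal(p1, p3)

    def test_replicated_rows_match_full_fit(self):
        base_v = np.array([0.5, 1.0, 1.5, 2.0, 3.0])
        base_d = np.array([1, 1, 0, 1, 1])
        v = np.tile(base_v, 40)
        delta = np.tile(base_d, 40)
        grid = default_grid(v)
        pred = rl.cv_predictions(v, delta, ("exponential",), grid=grid, seed=0)
        full = _fit_submodel("exponential", v, delta)
        expected = np.asarray(full.residual_survival(grid.points))
        # random stratified folds perturb the multiset composition of the
        # replicated rows slightly, so agreement is near- but not to
        # optimizer tolerance
        np.testing.assert_allclose(
            pred[:, 0, :], np.broadcast_to(expected, pred[:, 0, :].shape),
            atol=0.02)

    def test_leave_one_out_on_tiny_data(self):
        v = np.array([0.5, 1.0, 2.0, 3.5, 4.0, 5.0])
        delta = np.ones(6, dtype=int)
        grid = rl.EvaluationGrid(np.array([1.5, 3.0]))
        pred = rl.cv_predictions(v, delta, ("exponential",), grid=grid,
                                 n_folds=6, seed=1)
        # subject i's prediction must equal the fit without subject i
        for i in range(6):
            rest = np.delete(v, i)
            fit = _fit_submodel("exponential", rest, np.ones(5, dtype=int))
            np.testing.assert_allclose(
                pred[i, 0, :], np.asarray(fit.residual_survival(grid.points)),
                atol=1e-6)

    def test_predictions_lie_in_unit_interval(self, small_weibull_residual_data):
        v, delta = small_weibull_residual_data
        pred = rl.cv_predictions(v, delta, rl.DEFAULT_MODELS, seed=2)
        assert np.all((pred >= 0.0) & (pred <= 1.0))


class TestOptimizeWeights:
    def test_single_model_gets_unit_weight(self):
        v, delta = toy_censored_data(seed=2)
        grid = default_grid(v)
        G = rl.censoring_km(v, delta)
        pred = np.random.default_rng(0).uniform(0, 1, (v.size, 1, len(grid)))
        w = optimize_weights(pred, v, delta, grid, G)
        np.testing.assert_allclose(w.alpha, [1.0])

    def test_pointwise_dominant_model_takes_all_weight(self):
        v = np.linspace(0.5, 5.0, 20)
        delta = np.ones(20, dtype=int)
        grid = rl.EvaluationGrid(np.array([1.0, 2.5, 4.0]))
        G = rl.censoring_km(v, delta)
        z = (v[:, None] > grid.points[None, :]).astype(float)
        good = np.clip(z + 0.02 * (0.5 - z), 0, 1)
        bad = np.clip(z + 0.5 * (0.5 - z), 0, 1)
        pred = np.stack([bad, good], axis=1)
        w = optimize_weights(pred, v, delta, grid, G)
        np.testing.assert_allclose(w.alpha, [0.0, 1.0], atol=1e-8)

    def test_matches_dense_simplex_grid_search(self):
        v, delta = toy_censored_data(n=20, seed=9)
        grid = default_grid(v, 4)
        G = rl.censoring_km(v, delta)
        rng = np.random.default_rng(4)
        pred = np.sort(rng.uniform(0, 1, (20, 3, 4)), axis=2)[:, :, ::-1].copy()
        w = optimize_weights(pred, v, delta, grid, G)
        opt = ipcw_brier(
            np.clip(np.einsum("k,nks->ns", w.alpha, pred), 0, 1),
            v, delta, grid, G)
        best = np.inf
        for i, j in itertools.product(range(101), range(101)):
            if i + j > 100:
                continue
            a = np.array([i, j, 100 - i - j]) / 100.0
            val = ipcw_brier(
                np.clip(np.einsum("k,nks->ns", a, pred), 0, 1),
                v, delta, grid, G)
            best = min(best, val)
        assert opt <= best + 1e-6

    def test_simplex_invariants_and_vertex_optimality(self):
        for seed in range(5):
            v, delta = toy_censored_data(n=30, seed=seed)
            grid = default_grid(v, 5)
            G = rl.censoring_km(v, delta)
            rng = np.random.default_rng(100 + seed)
            pred = np.sort(rng.uniform(0, 1, (30, 4, 5)), axis=2)[:, :, ::-1].copy()
            w = optimize_weights(pred, v, delta, grid, G)
            assert np.all(w.alpha >= -1e-12)
            assert abs(w.alpha.sum() - 1.0) <= 1e-8
            opt = ipcw_brier(np.clip(np.einsum("k,nks->ns", w.alpha, pred), 0, 1),
                             v, delta, grid, G)
            for k in range(4):
                vertex = ipcw_brier(pred[:, k, :], v, delta, grid, G)
                assert opt <= vertex + 1e-9
            uniform = ipcw_brier(np.clip(pred.mean(axis=1), 0, 1),
                                 v, delta, grid, G)
            assert opt <= uniform + 1e-9


class TestStackedFit:
    def test_unit_weight_recovers_submodel(self, small_weibull_residual_data):
        v, delta = small_weibull_residual_data
        fit = rl.stack_fit(v, delta, models=("weibull", "gamma"), seed=0)
        forced = rl.StackedFit(
            labels=fit.labels, submodels=fit.submodels,
            weights=rl.WeightVector(np.array([1.0, 0.0])),
            grid=fit.grid, objective_value=np.nan)
        t = np.linspace(0, 3, 30)
        np.testing.assert_allclose(
            rl.stack_survival(forced, t, "underlying"),
            np.asarray(fit.submodels[0].underlying_survival(t)), atol=1e-12)

    def test_identical_submodels_are_weight_invariant(self, small_weibull_residual_data):
        v, delta = small_weibull_residual_data
        sub = _fit_submodel("weibull", v, delta)
        grid = default_grid(v)
        t = np.linspace(0, 4, 20)
        for alpha in ([0.2, 0.8], [0.5, 0.5]):
            fit = rl.StackedFit(labels=("weibull", "weibull2"),
                                submodels=(sub, sub),
                                weights=rl.WeightVector(np.array(alpha)),
                                grid=grid, objective_value=0.0)
            np.testing.assert_allclose(
                rl.stack_survival(fit, t, "residual"),
                np.asarray(sub.residual_survival(t)), atol=1e-12)

    def test_stacked_curves_monotone_in_unit_interval(self, small_weibull_residual_data):
        v, delta = small_weibull_residual_data
        fit = rl.stack_fit(v, delta, seed=11)
        assert abs(fit.weights.alpha.sum() - 1.0) < 1e-8
        t = np.linspace(0.0, float(v.max()) * 1.5, 200)
        for scale in ("residual", "underlying"):
            s = rl.stack_survival(fit, t, scale)
            assert np.all((s >= 0.0) & (s <= 1.0))
            assert np.all(np.diff(s) <= 1e-9)
        assert rl.stack_survival(fit, 0.0, "underlying") == pytest.approx(1.0, abs=1e-8)


class TestBootstrap:
    def test_bands_ordered_and_deterministic(self):
        v, delta = toy_censored_data(n=50, seed=12)
        tgrid = np.linspace(0, 4, 9)
        out1 = rl.bootstrap_bands(v, delta, models=("exponential", "weibull"),
                                  B=6, time_grid=tgrid, seed=3)
        out2 = rl.bootstrap_bands(v, delta, models=("exponential", "weibull"),
                                  B=6, time_grid=tgrid, seed=3)
        _, lo, hi = out1
        assert np.all(lo <= hi + 1e-12)
        np.testing.assert_array_equal(out1[1], out2[1])
        np.testing.assert_array_equal(out1[2], out2[2])

    def test_band_width_shrinks_with_sample_size(self):
        tgrid = np.linspace(0.2, 3.0, 8)
        widths = {}
        for n in (80, 640):
            v, delta = toy_censored_data(n=n, seed=21)
            _, lo, hi = rl.bootstrap_bands(
                v, delta, models=("exponential",), B=10, time_grid=tgrid, seed=5)
            widths[n] = np.median(hi - lo)
        assert widths[640] < widths[80]

    def test_b_below_two_rejected(self):
        v, delta = toy_censored_data()
        with pytest.raises(ValueError):
            rl.bootstrap_bands(v, delta, B=1)
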