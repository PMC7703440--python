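"""GLM / BRT / IDW fitting rules, gates, and predictions."""

from itertools import combinations

import numpy as np
import pytest
from scipy.special import expit

import sdmbias as sb
from sdmbias.errors import ConfigurationError, UnavailablePredictionError
from sdmbias.sampling import DetectionMatrix
from sdmbias.sdm import (
    SDMTrainingSet,
    _fit_glm_candidate,
    _idw_predict,
    build_training_set,
    fit_brt,
    fit_glm,
    fit_idw,
)

PRED5 = None  # filled per-fixture


def make_train(x, y, cells=None, names=None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    names = tuple(names or [f"v{i}" for i in range(x.shape[1])])
    means = x.mean(axis=0)
    sds = np.where(x.std(axis=0) == 0, 1.0, x.std(axis=0))
    if cells is None:
        cells = np.zeros(y.size, dtype=int)
    return SDMTrainingSet(y=y, x=(x - means) / sds,
                          cells=np.asarray(cells, dtype=int),
                          predictor_names=names, means=means, sds=sds)


def random_train(rng, n=None, signal=0.0):
    n = n or int(rng.integers(60, 220))
    x = rng.standard_normal((n, 5))
    eta = rng.normal(-1.2, 0.8) + signal * x[:, 0]
    y = (rng.random(n) < expit(eta)).astype(float)
    return make_train(x, y)


class TestBuildTrainingSet:
    def test_rows_share_cell_predictors(self, quick_env, small_grid):
        mat = DetectionMatrix(matrix=np.array([[1], [0], [1]], dtype=np.uint8),
                              species=np.array([4]),
                              event_cells=np.array([2, 2, 5]))
        names = quick_env.names[:5]
        train = build_training_set(mat, quick_env, 4, names)
        assert train.y.tolist() == [1.0, 0.0, 1.0]
        assert np.array_equal(train.x[0], train.x[1])
        assert not np.array_equal(train.x[0], train.x[2])

    def test_wrong_predictor_count(self, quick_env):
        mat = DetectionMatrix(matrix=np.zeros((2, 1), dtype=np.uint8),
                              species=np.array([0]),
                              event_cells=np.array([0, 1]))
        with pytest.raises(ConfigurationError):
            build_training_set(mat, quick_env, 0, quick_env.names[:4])
        with pytest.raises(ConfigurationError):
            build_training_set(mat, quick_env, 0,
                               quick_env.names[:4] + ["nope"])

    def test_standardised_columns(self, quick_env):
        rng = np.random.default_rng(0)
        cells = rng.integers(0, quick_env.grid.n_cells, 50)
        mat = DetectionMatrix(
            matrix=rng.integers(0, 2, (50, 1)).astype(np.uint8),
            species=np.array([0]), event_cells=cells)
        train = build_training_set(mat, quick_env, 0, quick_env.names[:5])
        assert np.allclose(train.x.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(train.x.std(axis=0), 1, atol=1e-12)


class TestFitGate:
    def test_five_presences_always_skipped(self, small_grid):
        rng = np.random.default_rng(1)
        for n_ones in (0, 1, 5):
            y = np.zeros(60)
            y[:n_ones] = 1
            train = make_train(rng.standard_normal((60, 5)), y,
                               cells=rng.integers(0, 36, 60))
            for fit in (fit_glm(train), fit_brt(train, seed=0),
                        fit_idw(train, small_grid)):
                assert fit.status == "skipped_insufficient_presences"
                with pytest.raises(UnavailablePredictionError):
                    fit.predict_surface(None, small_grid)


class TestChecklistGLM:
    def test_term_budget_from_printed_rule(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((1025, 5))
        y = np.zeros(1025)
        y[:25] = 1
        fit = fit_glm(make_train(x, y))
        assert fit.model_description["term_budget"] == 2
        assert len(fit.model_description["terms"]) <= 2

    def test_budget_and_hierarchy_never_violated(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            train = random_train(rng, signal=rng.uniform(0, 2))
            fit = fit_glm(train)
            if fit.status != "fitted":
                continue
            terms = fit.model_description["terms"]
            ones = int(train.y.sum())
            budget = min(ones, train.y.size - ones) // 10
            assert len(terms) <= budget
            for t in terms:
                if t.endswith("^2"):
                    assert t[:-2] in terms

    def test_budget_zero_gives_intercept_only(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((60, 5))
        y = np.zeros(60)
        y[:8] = 1  # 8 ones -> budget 0, but gate passed
        fit = fit_glm(make_train(x, y))
        assert fit.status == "fitted"
        assert fit.model_description["terms"] == []

    def test_stepwise_close_to_exhaustive(self):
        # exhaustive search over hierarchy-respecting models with <= 2 terms
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.standard_normal((200, 5))
            y = (rng.random(200) < expit(-1 + 1.5 * x[:, 1])).astype(float)
            y[:12] = 1  # ensure budget >= 2 is possible
            train = make_train(x, y)
            fit = fit_glm(train)
            budget = min(min(int(train.y.sum()),
                             200 - int(train.y.sum())) // 10, 10)
            names = train.predictor_names
            cands = [()]
            cands += [(n,) for n in names]
            if budget >= 2:
                cands += [tuple(c) for c in combinations(names, 2)]
                cands += [(n, f"{n}^2") for n in names]
            best = min(_fit_glm_candidate(train.y, train.x, names,
                                          tuple(sorted(t))).aic
                       for t in cands if len(t) <= budget)
            assert fit.model_description["aic"] <= best + 2.0

    def test_true_model_recovery_and_holdout_auc(self, quick_env):
        rng = np.random.default_rng(6)
        grid = quick_env.grid
        n = 2000
        x = rng.standard_normal((n, 5))
        eta = -0.5 + 1.5 * x[:, 0] - 1.5 * x[:, 2]
        y = (rng.random(n) < expit(eta)).astype(float)
        train = make_train(x[:1500], y[:1500])
        fit = fit_glm(train)
        terms = fit.model_description["terms"]
        assert "v0" in terms and "v2" in terms
        coefs = fit.model_description["coefficients"]
        held_eta = coefs["intercept"] + sum(
            coefs[t] * (make_train(x, y).x[1500:, int(t[1])] ** 2
                        if t.endswith("^2")
                        else make_train(x, y).x[1500:, int(t[1])])
            for t in terms)
        assert sb.auc(expit(held_eta), y[1500:].astype(int)) > 0.8

    def test_separation_falls_back_to_penalised(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((80, 5))
        y = (x[:, 0] > 0).astype(float)  # perfectly separable
        fit = fit_glm(make_train(x, y))
        assert fit.status == "fitted"
        assert fit.model_description["penalized_fallback"]

    def test_intercept_only_predicts_constant(self, quick_env):
        rng = np.random.default_rng(8)
        cells = rng.integers(0, quick_env.grid.n_cells, 70)
        x = quick_env.matrix(quick_env.names[:5])[cells]
        y = np.zeros(70)
        y[:8] = 1
        train = build_training_set(
            DetectionMatrix(matrix=y.reshape(-1, 1).astype(np.uint8),
                            species=np.array([0]), event_cells=cells),
            quick_env, 0, quick_env.names[:5])
        fit = fit_glm(train)
        scores = fit.predict_surface(quick_env, quick_env.grid)
        assert np.allclose(scores, scores[0])

    def test_glm_scores_match_linear_predictor(self, quick_env):
        rng = np.random.default_rng(9)
        grid = quick_env.grid
        cells = rng.integers(0, grid.n_cells, 300)
        xall = quick_env.matrix(quick_env.names[:5])
        eta_true = 2.0 * (xall[:, 0] - xall[:, 0].mean()) / xall[:, 0].std()
        y = (rng.random(300) < expit(eta_true[cells])).astype(float)
        train = build_training_set(
            DetectionMatrix(matrix=y.reshape(-1, 1).astype(np.uint8),
                            species=np.array([0]), event_cells=cells),
            quick_env, 0, quick_env.names[:5])
        fit = fit_glm(train)
        scores = fit.predict_surface(quick_env, grid)
        coefs = fit.model_description["coefficients"]
        xc = train.cell_design(quick_env)
        eta = np.full(grid.n_cells, coefs["intercept"])
        for t in fit.model_description["terms"]:
            j = train.predictor_names.index(t[:-2] if t.endswith("^2") else t)
            col = xc[:, j] ** 2 if t.endswith("^2") else xc[:, j]
            eta = eta + coefs[t] * col
        # description coefficients are rounded to 6 decimals
        assert np.allclose(scores, expit(eta), atol=1e-4)


BRT_FAST = dict(min_trees=30, max_trees=300, chunk=50, stop_margin=60)


class TestBoostedTrees:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((150, 5))
        y = (rng.random(150) < expit(-0.5 + 1.5 * x[:, 0])).astype(float)
        train = make_train(x, y)
        f1 = fit_brt(train, seed=3, **BRT_FAST)
        f2 = fit_brt(train, seed=3, **BRT_FAST)
        assert f1.model_description == f2.model_description

    def test_tree_count_within_cap(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((150, 5))
        y = (rng.random(150) < expit(-0.5 + 2 * x[:, 0])).astype(float)
        fit = fit_brt(make_train(x, y), seed=0, **BRT_FAST)
        assert fit.status == "fitted"
        assert 30 <= fit.model_description["n_trees"] <= 300
        assert fit.model_description["tree_complexity"] in (2, 5)

    def test_pure_noise_status_recorded_not_raised(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((120, 5))
        y = (rng.random(120) < 0.3).astype(float)
        # demand far more trees than noise can support at the rate floor
        fit = fit_brt(make_train(x, y), seed=0, min_trees=250, max_trees=300,
                      chunk=50, stop_margin=50,
                      learning_rate_start=0.01, learning_rate_floor=0.005)
        assert fit.status in ("fitted", "failed")

    def test_prediction_surface_bounds(self, quick_env):
        rng = np.random.default_rng(13)
        grid = quick_env.grid
        cells = rng.integers(0, grid.n_cells, 150)
        x = quick_env.matrix(quick_env.names[:5])[cells]
        y = (rng.random(150) < expit(x[:, 0])).astype(float)
        train = build_training_set(
            DetectionMatrix(matrix=y.reshape(-1, 1).astype(np.uint8),
                            species=np.array([0]), event_cells=cells),
            quick_env, 0, quick_env.names[:5])
        fit = fit_brt(train, seed=1, **BRT_FAST)
        if fit.status == "fitted":
            s = fit.predict_surface(quick_env, grid)
            assert np.all((s >= 0) & (s <= 1))


class TestInverseDistance:
    def test_exact_cell_average(self, small_grid):
        train = make_train(np.zeros((8, 5)), np.ones(8),
                           cells=np.full(8, 11))
        fit = fit_idw(train, small_grid)
        scores = fit.predict_surface(None, small_grid)
        assert scores[11] == pytest.approx(1.0)

    def test_single_event_predicts_everywhere(self, small_grid):
        # below the fit gate; exercise the interpolator directly
        pred = _idw_predict(np.array([4]), np.array([1.0]),
                            np.arange(small_grid.n_cells), 2.0, 5,
                            small_grid.pairwise_distance)
        assert np.allclose(pred, 1.0)

    def test_predictions_are_convex_combinations(self, small_grid):
        rng = np.random.default_rng(14)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            cells = rng.integers(0, small_grid.n_cells, n)
            y = rng.random(n)
            power = float(rng.integers(1, 5))
            m = [5, 10, None][int(rng.integers(0, 3))]
            pred = _idw_predict(cells, y, np.arange(small_grid.n_cells),
                                power, m, small_grid.pairwise_distance)
            assert pred.min() >= y.min() - 1e-12
            assert pred.max() <= y.max() + 1e-12

    def test_tuning_choices_reported(self, small_grid):
        rng = np.random.default_rng(15)
        cells = rng.integers(0, small_grid.n_cells, 120)
        xy = small_grid.centroid_xy[cells]
        y = (rng.random(120) < expit((xy[:, 0] - 30) / 10)).astype(float)
        fit = fit_idw(make_train(np.zeros((120, 5)), y, cells=cells),
                      small_grid)
        assert fit.status == "fitted"
        assert fit.model_description["power"] in (1, 2, 3, 4)
        assert fit.model_description["n_neighbors"] in (5, 10, 25, "all")

    def test_summary_mentions_method_and_status(self, small_grid):
        train = make_train(np.zeros((8, 5)), np.ones(8),
                           cells=np.full(8, 3))
        text = fit_idw(train, small_grid).summary()
        assert "IDW" in text and "fitted" in text
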