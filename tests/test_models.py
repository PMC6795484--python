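"""Tuning protocol: repeated stratified CV, grid refinement, refit, persistence."""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.model_selection import RepeatedStratifiedKFold

from odcert import CVConfig, ModelSpec, TrainedModel, cross_validate, refine_grid, train_final, tune
from odcert.errors import ConfigurationError, ValidationError
from odcert.models import best_point

CV_SMALL = CVConfig(k=5, repeats=2, seed=0)


def separable_toy(n_pos=15, n_neg=60):
    """Positives carry an 'overdose' indicator column; negatives never do."""
    rng = np.random.default_rng(7)
    n = n_pos + n_neg
    X = rng.integers(0, 2, size=(n, 6)).astype(float)
    y = np.array([True] * n_pos + [False] * n_neg)
    X[:, 0] = y.astype(float)
    return sp.csr_matrix(X), y


class TestCrossValidate:
    def test_separable_data_scores_perfect_f(self):
        X, y = separable_toy()
        res = cross_validate(X, y, ModelSpec("linear_svm", {"cost": [0.1, 1.0]}), CV_SMALL)
        assert set(res.values()) == {1.0}

    def test_single_class_labels_rejected(self):
        X, _ = separable_toy()
        with pytest.raises(ConfigurationError):
            cross_validate(X, np.zeros(X.shape[0], dtype=bool), ModelSpec("linear_svm"), CV_SMALL)

    def test_too_few_positives_for_k_advises_smaller_k(self):
        X, y = separable_toy(n_pos=3, n_neg=40)
        with pytest.raises(ConfigurationError, match="smaller k"):
            cross_validate(X, y, ModelSpec("linear_svm"), CVConfig(k=10, repeats=1, seed=0))

    def test_deterministic_given_seed(self):
        X, y = separable_toy()
        # noise column so folds actually matter
        spec = ModelSpec("random_forest", {"n_trees": [20], "max_depth": [4]})
        a = cross_validate(X, y, spec, CV_SMALL)
        b = cross_validate(X, y, spec, CV_SMALL)
        assert a == b

    def test_stratification_keeps_positive_counts_balanced(self):
        _, y = separable_toy(n_pos=23, n_neg=200)
        splitter = RepeatedStratifiedKFold(n_splits=10, n_repeats=3, random_state=1)
        for _, test_idx in splitter.split(np.zeros(len(y)), y):
            n_pos_fold = int(y[test_idx].sum())
            assert abs(n_pos_fold - 23 / 10) < 1


class TestModelSpec:
    def test_unknown_grid_key_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec("linear_svm", {"max_depth": [3]})

    def test_unknown_family_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec("naive_bayes")


class TestRefineGrid:
    def _results(self, spec, best):
        return {
            tuple(sorted({k: v for k, v in zip(spec.grid, point)}.items())): (
                1.0 if point == best else 0.5
            )
            for point in __import__("itertools").product(*spec.grid.values())
        }

    def test_edge_best_extends_outward(self):
        spec = ModelSpec("linear_svm", {"cost": [0.01, 0.1, 1.0]})
        res = self._results(spec, (1.0,))
        new = refine_grid(res, spec)
        values = sorted(new.grid["cost"])
        assert min(values) == pytest.approx(1 / np.sqrt(10), rel=1e-6)
        assert max(values) == pytest.approx(10.0)
        assert 1.0 in values
        # the old best is now interior
        assert values[0] < 1.0 < values[-1]

    def test_interior_best_with_small_improvement_terminates(self):
        spec = ModelSpec("linear_svm", {"cost": [0.1, 1.0, 10.0]})
        res = self._results(spec, (1.0,))
        new = refine_grid(res, spec, prev_best_score=1.0 - 1e-5, tol=1e-3)
        assert new.grid == spec.grid

    def test_interior_best_with_large_improvement_zooms_in(self):
        spec = ModelSpec("linear_svm", {"cost": [0.1, 1.0, 10.0]})
        res = self._results(spec, (1.0,))
        new = refine_grid(res, spec, prev_best_score=0.5, tol=1e-3)
        assert new.grid != spec.grid
        assert 1.0 in new.grid["cost"]
        assert min(new.grid["cost"]) > 0.1 and max(new.grid["cost"]) < 10.0

    def test_single_point_grid_widens(self):
        spec = ModelSpec("linear_svm", {"cost": [1.0]})
        res = self._results(spec, (1.0,))
        new = refine_grid(res, spec)
        assert len(new.grid["cost"]) == 3 and 1.0 in new.grid["cost"]

    def test_integer_parameter_refines_by_half_gap(self):
        spec = ModelSpec("random_forest", {"n_trees": [100, 300]})
        res = self._results(spec, (100,))
        new = refine_grid(res, spec)
        assert 100 in new.grid["n_trees"]
        assert all(v >= 1 for v in new.grid["n_trees"])

    def test_tie_breaks_prefer_simpler_model(self):
        spec = ModelSpec("linear_svm", {"cost": [0.01, 0.1, 1.0]})
        res = {tuple(sorted({"cost": c}.items())): 1.0 for c in spec.grid["cost"]}
        params, _ = best_point(res, spec)
        assert params["cost"] == 0.01


class TestTrainFinalAndPredict:
    def test_training_set_f_is_one_on_separable_toy(self):
        from odcert import confusion, metrics

        X, y = separable_toy()
        model = train_final(X, y, "linear_svm", {"cost": 1.0})
        rep = metrics(confusion(y, model.predict(X)))
        assert rep.f_score == 1.0

    def test_empty_matrix_gives_empty_predictions(self):
        X, y = separable_toy()
        model = train_final(X, y, "linear_svm", {"cost": 1.0})
        assert model.predict(sp.csr_matrix((0, X.shape[1]))).tolist() == []

    def test_all_zero_row_matches_decision_function_sign(self):
        X, y = separable_toy()
        model = train_final(X, y, "linear_svm", {"cost": 1.0})
        row = sp.csr_matrix((1, X.shape[1]))
        pred = model.predict(row)[0]
        assert pred == (model.decision_scores(row)[0] > 0)

    def test_persistence_round_trip_identical_predictions(self, tmp_path):
        X, y = separable_toy(n_pos=25, n_neg=100)
        model = train_final(X, y, "random_forest", {"n_trees": 30, "max_depth": 5})
        path = tmp_path / "model.joblib"
        model.save(path)
        reloaded = TrainedModel.load(path)
        rng = np.random.default_rng(5)
        X_new = sp.csr_matrix(rng.integers(0, 2, size=(1000, X.shape[1])).astype(float))
        assert (model.predict(X_new) == reloaded.predict(X_new)).all()

    def test_dimension_mismatch_names_both_sizes(self):
        from odcert import VectorizerConfig, fit_vocabulary

        vocab = fit_vocabulary(["HEROIN OVERDOSE"], VectorizerConfig(min_count=1, ngram_max=1))
        X, y = separable_toy()
        model = train_final(X, y, "linear_svm", {"cost": 1.0}, vocabulary=vocab)
        with pytest.raises(ValidationError, match="6.*2|2.*6"):
            model.predict(X)


class TestTune:
    @pytest.mark.parametrize("family,grid", [
        ("linear_svm", {"cost": [0.01, 1.0]}),
        ("random_forest", {"n_trees": [20], "max_depth": [4, 8]}),
        ("mlp", {"hidden_layer_sizes": [(8,)], "alpha": [1e-4, 1e-2]}),
    ])
    def test_all_families_reach_high_f_on_planted_signal(self, family, grid):
        # the MLP's stochastic optimizer needs corpus-scale sample counts
        X, y = separable_toy(n_pos=100, n_neg=900)
        params, score, history = tune(X, y, ModelSpec(family, grid), CV_SMALL, max_rounds=2)
        assert score >= 0.9
        assert set(params) == set(grid)

    def test_svm_cost_selection_stable_across_seeds(self):
        X, y = separable_toy(n_pos=20, n_neg=120)
        chosen = set()
        for seed in (0, 1, 2):
            params, _, _ = tune(
                X, y, ModelSpec("linear_svm", {"cost": [0.01, 0.1, 1.0, 10.0]}),
                CVConfig(k=5, repeats=2, seed=seed), max_rounds=1,
            )
            chosen.add(params["cost"])
        assert len(chosen) == 1

    def test_tuning_trajectory_deterministic(self):
        X, y = separable_toy(n_pos=20, n_neg=120)
        spec = ModelSpec("linear_svm", {"cost": [0.01, 0.1, 1.0]})
        a = tune(X, y, spec, CV_SMALL, max_rounds=3)
        b = tune(X, y, spec, CV_SMALL, max_rounds=3)
        assert a == b
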