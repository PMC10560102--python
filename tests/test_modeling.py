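"""Learner registry, grid search, cross-validation and persistence."""
import numpy as np
import pandas as pd
import pytest

from logbbpred.errors import ModelFormatError, SchemaError, UnknownLearnerError
from logbbpred.featurization import DescriptorTable
from logbbpred.modeling import (
    MODEL_FORMAT_VERSION,
    CVRecord,
    LearnerSpec,
    cross_validate,
    default_grids,
    grid_search,
    load_model,
    predict,
    save_model,
    train,
)


def linear_frame(rng, n=60, p=3):
    frame = pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"x{j}" for j in range(p)]
    )
    y = 2.0 * frame["x0"].to_numpy() + 1.0
    return DescriptorTable(data=frame), y


def nonlinear_frame(rng, n=300):
    frame = pd.DataFrame(rng.uniform(-3, 3, size=(n, 2)), columns=["x1", "x2"])
    y = np.sin(frame["x1"].to_numpy()) + frame["x2"].to_numpy() ** 2
    return DescriptorTable(data=frame), y


class TestTrainPredict:
    def test_mlr_fits_linear_data_exactly(self, rng):
        table, y = linear_frame(rng)
        model = train(LearnerSpec(name="mlr"), table, y, seed=0)
        assert np.allclose(predict(model, table), y, atol=1e-6)

    def test_knn1_memorizes_training_targets(self, rng):
        table, y = linear_frame(rng)
        model = train(LearnerSpec(name="knn"), table, y, params={"n_neighbors": 1}, seed=0)
        assert np.allclose(predict(model, table), y, atol=1e-12)

    @pytest.mark.parametrize("learner", ["lightgbm", "rf", "xgboost", "ann"])
    def test_same_seed_identical_predictions(self, rng, learner):
        table, y = nonlinear_frame(rng, n=120)
        preds = [
            predict(train(LearnerSpec(name=learner), table, y, seed=3), table)
            for _ in range(2)
        ]
        assert np.array_equal(preds[0], preds[1])

    def test_unknown_learner_rejected(self):
        with pytest.raises(UnknownLearnerError):
            LearnerSpec(name="deep_transformer")

    def test_non_finite_inputs_rejected(self, rng):
        table, y = linear_frame(rng)
        table.data.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            train(LearnerSpec(name="mlr"), table, y)

    def test_column_order_and_extras_irrelevant(self, rng):
        table, y = linear_frame(rng)
        model = train(LearnerSpec(name="mlr"), table, y, seed=0)
        base = predict(model, table)
        permuted = DescriptorTable(data=table.data[["x2", "x0", "x1"]])
        assert np.array_equal(predict(model, permuted), base)
        extra = table.data.copy()
        extra["irrelevant"] = 99.0
        assert np.array_equal(predict(model, DescriptorTable(data=extra)), base)

    def test_missing_feature_column_is_schema_error(self, rng):
        table, y = linear_frame(rng)
        model = train(LearnerSpec(name="mlr"), table, y, seed=0)
        with pytest.raises(SchemaError, match="x2"):
            predict(model, DescriptorTable(data=table.data[["x0", "x1"]]))


class TestCrossValidate:
    def test_noiseless_linear_mlr_is_perfect(self, rng):
        table, y = linear_frame(rng, n=100)
        record = cross_validate(LearnerSpec(name="mlr"), table, y, k=10, seed=0)
        assert record.mean_r2 == pytest.approx(1.0, abs=1e-9)
        assert record.mean_mse == pytest.approx(0.0, abs=1e-9)

    def test_pure_noise_r2_not_positive(self):
        r2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            frame = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("abc"))
            y = rng.standard_normal(100)  # independent of X
            rec = cross_validate(LearnerSpec(name="mlr"), DescriptorTable(data=frame), y, k=5, seed=seed)
            r2s.append(rec.mean_r2)
        assert np.mean(r2s) <= 0.0 + 0.05

    def test_folds_partition_the_index_set(self, rng):
        table, y = linear_frame(rng, n=57)
        record = cross_validate(LearnerSpec(name="mlr"), table, y, k=10, seed=4)
        all_test = np.concatenate(record.fold_test_indices)
        assert sorted(all_test.tolist()) == list(range(57))

    def test_bad_k_rejected(self, rng):
        table, y = linear_frame(rng, n=20)
        with pytest.raises(ValueError):
            cross_validate(LearnerSpec(name="mlr"), table, y, k=1)
        with pytest.raises(ValueError):
            cross_validate(LearnerSpec(name="mlr"), table, y, k=21)

    def test_means_are_arithmetic_means(self):
        rec = CVRecord(k=2, seed=0, fold_r2=[0.4, 0.8], fold_mse=[1.0, 3.0], fold_test_indices=[])
        assert rec.mean_r2 == pytest.approx(0.6)
        assert rec.mean_mse == pytest.approx(2.0)

    def test_boosted_trees_beat_mlr_on_nonlinear_signal(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            table, y = nonlinear_frame(rng)
            lgbm = cross_validate(
                LearnerSpec(name="lightgbm"), table, y, k=5, seed=seed,
                params={"min_child_samples": 5},
            )
            mlr = cross_validate(LearnerSpec(name="mlr"), table, y, k=5, seed=seed)
            wins += lgbm.mean_r2 > mlr.mean_r2
        assert wins == 5


class TestGridSearch:
    def test_single_point_grid_returned(self, rng):
        table, y = linear_frame(rng)
        spec = LearnerSpec(name="knn", param_grid={"n_neighbors": [3]})
        best_params, model, _ = grid_search(spec, table, y, k=5, seed=0)
        assert best_params == {"n_neighbors": 3}
        assert model.learner == "knn"

    def test_degenerate_setting_loses(self, rng):
        table, y = nonlinear_frame(rng, n=200)
        spec = LearnerSpec(
            name="lightgbm",
            param_grid={"n_estimators": [1, 200]},
            fixed_params={"min_child_samples": 5},
        )
        best_params, _, _ = grid_search(spec, table, y, k=5, seed=0)
        assert best_params["n_estimators"] == 200

    def test_winner_not_worse_than_any_grid_point(self, rng):
        table, y = nonlinear_frame(rng, n=150)
        spec = LearnerSpec(name="knn", param_grid={"n_neighbors": [1, 3, 7, 15]})
        _, model, best_record = grid_search(spec, table, y, k=5, seed=1)
        for k_neigh in [1, 3, 7, 15]:
            rec = cross_validate(
                LearnerSpec(name="knn"), table, y, k=5, seed=1, params={"n_neighbors": k_neigh}
            )
            assert best_record.mean_r2 >= rec.mean_r2 - 1e-12

    def test_enumeration_deterministic(self, rng):
        table, y = nonlinear_frame(rng, n=100)
        spec = LearnerSpec(name="knn", param_grid={"n_neighbors": [3, 5], "weights": ["uniform", "distance"]})
        first = grid_search(spec, table, y, k=5, seed=2)[0]
        second = grid_search(spec, table, y, k=5, seed=2)[0]
        assert first == second


class TestPersistence:
    def test_round_trip(self, rng, tmp_path):
        table, y = linear_frame(rng)
        model = train(LearnerSpec(name="mlr"), table, y, seed=0)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.feature_names == model.feature_names
        assert np.array_equal(predict(loaded, table), predict(model, table))

    def test_version_mismatch_refused(self, rng, tmp_path):
        import joblib

        path = tmp_path / "bad.joblib"
        joblib.dump({"format_version": MODEL_FORMAT_VERSION + 1}, path)
        with pytest.raises(ModelFormatError):
            load_model(path)


def test_default_grids_cover_all_learners():
    grids = default_grids()
    for name in ("lightgbm", "rf", "knn", "mlr", "svm", "adaboost", "xgboost", "ann"):
        assert name in grids
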