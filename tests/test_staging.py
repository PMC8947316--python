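import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from somnentropy import (
    FEATURE_COLUMNS,
    TrainConfig,
    assemble_feature_table,
    cohen_kappa,
    confusion_matrix,
    evaluate,
    make_subject_folds,
    make_task,
    train_and_predict,
)
from somnentropy.entropy import ENTROPY_FEATURES
from somnentropy.staging import feature_importance

from _oracles import kappa_naive

FAST_CFG = TrainConfig(n_bo_init=0, n_bo_iter=0, max_rounds=150)


class TestKappa:
    def test_hand_computed_confusion(self):
        cm = np.array([[20, 5], [10, 15]])
        assert cohen_kappa(cm) == pytest.approx(0.4, abs=1e-12)

    def test_perfect_agreement(self):
        task = make_task(3)
        acc, kap, _ = evaluate(["W", "NREM", "REM"] * 5, ["W", "NREM", "REM"] * 5, task)
        assert acc == 1.0 and kap == pytest.approx(1.0)

    def test_constant_predictor_on_balanced_truth_is_chance(self):
        task = make_task(3)
        truth = ["W", "NREM", "REM"] * 10
        pred = ["NREM"] * 30
        acc, kap, _ = evaluate(pred, truth, task)
        assert kap == pytest.approx(0.0, abs=1e-12)

    def test_matches_definition_and_sklearn_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            q = rng.integers(2, 6)
            cm = rng.integers(0, 30, size=(q, q))
            cm[0, 0] += 1  # non-degenerate
            assert cohen_kappa(cm) == pytest.approx(kappa_naive(cm), abs=1e-12)
        for _ in range(20):
            y1 = rng.integers(0, 4, 200)
            y2 = rng.integers(0, 4, 200)
            cm = confusion_matrix(y1.astype(str), y2.astype(str), [str(i) for i in range(4)])
            assert cohen_kappa(cm) == pytest.approx(
                cohen_kappa_score(y1, y2), abs=1e-12
            )


class TestTasks:
    def test_label_maps(self):
        stages = ["W", "N1", "N2", "N3", "REM"]
        assert list(make_task(5).map_labels(stages)) == stages
        assert list(make_task(4).map_labels(stages)) == ["W", "LS", "LS", "DS", "REM"]
        assert list(make_task(3).map_labels(stages)) == ["W", "NREM", "NREM", "NREM", "REM"]

    def test_unknown_task_size_rejected(self):
        with pytest.raises(ValueError):
            make_task(2)


class TestSubjectFolds:
    def test_sixteen_subjects_eight_folds_of_two(self):
        subjects = [f"s{i:02d}" for i in range(16)]
        folds = make_subject_folds(subjects, k=8, seed=1)
        assert len(folds) == 8
        tests = [s for f in folds for s in f["test"]]
        assert sorted(tests) == sorted(subjects)  # disjoint and exhaustive
        for f in folds:
            assert len(f["test"]) == 2 and len(f["val"]) == 2
            assert not set(f["train"]) & set(f["test"])
            assert not set(f["train"]) & set(f["val"])
            assert not set(f["val"]) & set(f["test"])

    def test_deterministic_under_seed(self):
        subjects = [f"s{i}" for i in range(16)]
        assert make_subject_folds(subjects, seed=3) == make_subject_folds(subjects, seed=3)

    def test_fold_count_shrinks_with_few_subjects(self):
        with pytest.warns(UserWarning, match="shrinking"):
            folds = make_subject_folds([f"s{i}" for i in range(8)], k=8, seed=0)
        assert len(folds) == 4


class TestFeatureTable:
    def test_23_feature_columns_and_retention_filter(self, strong_cohort):
        from somnentropy import EpochScheme, build_epochs

        beats, hyp = strong_cohort[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eps = build_epochs(hyp, beats, EpochScheme(window_len=300))
        table = assemble_feature_table(eps)
        feats = [c for c in FEATURE_COLUMNS if c in table.columns]
        assert len(feats) == 23
        assert len(table) == sum(e.retained for e in eps)
        assert set(table["stage"]) <= {"W", "N1", "N2", "N3", "REM"}

    def test_linear_only_ablation_drops_entropy_columns(self, strong_cohort):
        from somnentropy import EpochScheme, build_epochs

        beats, hyp = strong_cohort[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eps = build_epochs(hyp, beats, EpochScheme(window_len=300))
        table = assemble_feature_table(eps, linear_only=True)
        assert not set(ENTROPY_FEATURES) & set(table.columns)
        assert len([c for c in FEATURE_COLUMNS if c in table.columns]) == 17


class TestTrainAndPredict:
    def test_predictions_within_task_classes_and_strong_separation(self, strong_table300):
        table = strong_table300
        folds = make_subject_folds(table["subject_id"].unique(), k=8, seed=0)
        task = make_task(3)
        res = train_and_predict(table, task, folds, FAST_CFG, seed=0)
        for r in res:
            assert set(r.pred) <= set(task.classes)
        assert np.mean([r.kappa for r in res]) > 0.5

    def test_early_stopping_halts_before_round_cap(self, strong_table300):
        import xgboost as xgb
        from somnentropy.staging import _fit_booster, _prepare_fold

        table = strong_table300
        folds = make_subject_folds(table["subject_id"].unique(), k=8, seed=0)
        feats = [c for c in FEATURE_COLUMNS if c in table.columns]
        data = _prepare_fold(table, make_task(3), folds[0], feats)
        X_tr, y_tr, _ = data["train"]
        X_va, y_va, _ = data["val"]
        cfg = TrainConfig(max_rounds=2000, early_stopping_rounds=20)
        bst = _fit_booster(
            cfg.base_params,
            xgb.DMatrix(X_tr, label=y_tr, weight=data["weights"], feature_names=feats),
            xgb.DMatrix(X_va, label=y_va, feature_names=feats),
            cfg,
            len(data["classes"]),
            seed=0,
        )
        assert bst.best_iteration < 2000 - 1

    def test_nan_features_are_imputed_from_training_fold(self, strong_table300):
        table = strong_table300.copy()
        table.loc[table.index[:50], "sampen"] = np.nan
        folds = make_subject_folds(table["subject_id"].unique(), k=8, seed=0)
        res = train_and_predict(table, make_task(3), folds, FAST_CFG, seed=0)
        assert all(np.isfinite(r.acc) for r in res)

    def test_deterministic_under_seed(self, strong_table300):
        folds = make_subject_folds(strong_table300["subject_id"].unique(), k=8, seed=0)
        a = train_and_predict(strong_table300, make_task(3), folds, FAST_CFG, seed=4)
        b = train_and_predict(strong_table300, make_task(3), folds, FAST_CFG, seed=4)
        assert [r.kappa for r in a] == [r.kappa for r in b]
        assert all(np.array_equal(x.pred, y.pred) for x, y in zip(a, b))


class TestFeatureImportance:
    def test_discriminative_feature_outranks_pure_noise(self):
        # stage depends only on 'mrr'; every other column is noise
        rng = np.random.default_rng(0)
        n = 900
        mrr = rng.uniform(0.7, 1.2, n)
        stage = np.where(mrr > 1.05, "N3", np.where(mrr > 0.85, "N2", "W"))
        data = {c: rng.standard_normal(n) for c in FEATURE_COLUMNS}
        data["mrr"] = mrr
        table = pd.DataFrame(data)
        table["subject_id"] = [f"s{i % 8}" for i in range(n)]
        table["stage"] = stage
        table["epoch_start_s"] = np.arange(n) * 30.0
        folds = make_subject_folds(table["subject_id"].unique(), k=4, seed=0)
        res = train_and_predict(
            table, make_task(3), folds, FAST_CFG, seed=0, compute_importance=True
        )
        imp = res[0].importance
        assert (imp.to_numpy() >= 0).all()
        assert imp.index[0] == "mrr"

    def test_importance_deterministic(self, strong_table300):
        folds = make_subject_folds(strong_table300["subject_id"].unique(), k=8, seed=0)
        a = train_and_predict(
            strong_table300, make_task(3), folds[:1], FAST_CFG, seed=1, compute_importance=True
        )[0].importance
        b = train_and_predict(
            strong_table300, make_task(3), folds[:1], FAST_CFG, seed=1, compute_importance=True
        )[0].importance
        pd.testing.assert_frame_equal(a, b)


class TestBayesianTuning:
    def test_tuned_model_trains_and_predicts(self, strong_table300):
        folds = make_subject_folds(strong_table300["subject_id"].unique(), k=8, seed=0)
        cfg = TrainConfig(n_bo_init=3, n_bo_iter=2, max_rounds=60)
        res = train_and_predict(strong_table300, make_task(3), folds[:1], cfg, seed=0)
        assert set(res[0].best_params) == {
            "max_depth", "eta", "subsample", "colsample_bytree", "alpha", "lambda",
        }
        assert 2 <= res[0].best_params["max_depth"] <= 10
        assert 0.01 <= res[0].best_params["eta"] <= 0.3


class TestRunExperiment:
    def test_grid_structure_and_scheme_comparison(self):
        from somnentropy import CohortSpec, generate_cohort
        from somnentropy.staging import run_experiment

        cohort = generate_cohort(
            CohortSpec(n_subjects=4, night_duration=1.5 * 3600.0, seed=21)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_experiment(
                cohort,
                schemes=(270, 300),
                tasks=(3,),
                ablations=(False, True),
                seed=0,
                cfg=TrainConfig(n_bo_init=0, n_bo_iter=0, max_rounds=80),
                k_folds=2,
            )
        cells = out["cells"]
        assert set(cells) == {
            ("270", 3, False), ("270", 3, True),
            ("300", 3, False), ("300", 3, True),
        }
        for cv in cells.values():
            assert len(cv.fold_acc) == 2
            assert 0.0 <= cv.acc_mean <= 1.0
            assert -1.0 <= cv.kappa_mean <= 1.0
        assert all(0.0 <= p <= 1.0 for p in out["comparisons"].values())
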