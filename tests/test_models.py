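"""Splitting, training, evaluation metrics, and the comparison grid."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from anxeeg.features import LabeledFeatureTable
from anxeeg.io import ConfigurationError, InputError
from anxeeg.models import (
    ClassifierSpec,
    cohen_kappa,
    decision_scores,
    default_specs,
    evaluate,
    holdout_split,
    make_classifier,
    rank_auc,
    run_single,
    train,
)


def blob_table(n_per_class=50, separation=6.0, n_features=4, seed=0):
    """Two well-separated Gaussian blobs: linearly separable sanity data."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    b = rng.normal(separation, 1.0, size=(n_per_class, n_features))
    features = pd.DataFrame(np.vstack([a, b]), columns=[f"f{i}" for i in range(n_features)])
    labels = np.array([False] * n_per_class + [True] * n_per_class)
    provenance = pd.DataFrame(
        {"subject_id": "S00", "trial_id": "0", "epoch_index": range(2 * n_per_class), "synthetic": False}
    )
    return LabeledFeatureTable(features, labels, provenance)


class TestHoldoutSplit:
    def test_stratified_80_20_arithmetic(self):
        table = blob_table(50)
        train_t, test_t = holdout_split(table, 0.8, seed=0)
        assert train_t.n_rows == 80 and test_t.n_rows == 20
        assert train_t.class_counts() == (40, 40)
        assert test_t.class_counts() == (10, 10)

    def test_same_seed_same_split(self):
        table = blob_table(30)
        a_train, a_test = holdout_split(table, seed=5)
        b_train, b_test = holdout_split(table, seed=5)
        pd.testing.assert_frame_equal(a_train.features, b_train.features)
        pd.testing.assert_frame_equal(a_test.features, b_test.features)

    def test_partition_of_input(self):
        table = blob_table(25)
        train_t, test_t = holdout_split(table, seed=1)
        joined = pd.concat([train_t.features, test_t.features])
        assert len(joined) == table.n_rows
        merged = joined.sort_values(list(joined.columns)).reset_index(drop=True)
        original = table.features.sort_values(list(joined.columns)).reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, original)

    def test_tiny_class_rejected(self):
        table = blob_table(50).subset(np.arange(51))  # 50 non-anxious, 1 anxious
        with pytest.raises(InputError):
            holdout_split(table)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            holdout_split(blob_table(10), train_fraction=1.5)


class TestCohenKappa:
    def test_identical_lists_give_one(self):
        assert cohen_kappa([0, 1, 1, 0], [0, 1, 1, 0]) == 1.0

    def test_hand_example_half(self):
        # p_o = 0.75, p_e = 0.5 ⇒ κ = 0.5
        assert cohen_kappa([1, 1, 0, 0], [1, 0, 0, 0]) == pytest.approx(0.5)

    def test_chance_level_gives_zero(self):
        actual = [0, 0, 1, 1]
        predicted = [0, 1, 0, 1]  # independent, 50/50 marginals, agreement 0.5
        assert cohen_kappa(actual, predicted) == pytest.approx(0.0)

    def test_matches_sklearn_on_random_labelings(self, rng):
        for _ in range(25):
            a = rng.integers(0, 2, size=40)
            p = rng.integers(0, 2, size=40)
            if len(np.unique(np.concatenate([a, p]))) < 2:
                continue
            assert cohen_kappa(a, p) == pytest.approx(cohen_kappa_score(a, p), abs=1e-12)

    def test_degenerate_single_class_returns_one(self):
        assert cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            cohen_kappa([0, 1], [0, 1, 1])


class TestRankAuc:
    def test_matches_sklearn(self, rng):
        for _ in range(25):
            y = rng.integers(0, 2, size=50).astype(bool)
            if y.all() or not y.any():
                continue
            s = rng.normal(size=50)
            assert rank_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_score_negation_flips_auc(self, rng):
        y = np.array([True] * 20 + [False] * 30)
        s = rng.normal(size=50)
        assert rank_auc(y, s) == pytest.approx(1.0 - rank_auc(y, -s))

    def test_single_class_is_none(self):
        assert rank_auc(np.array([True, True]), np.array([0.1, 0.2])) is None


class TestTrainEvaluate:
    def test_one_nearest_neighbor_memorizes_training_set(self):
        table = blob_table(20, separation=1.0)
        model = train(ClassifierSpec("knn"), table)
        predictions = model.predict(table.features.to_numpy())
        assert np.array_equal(predictions.astype(bool), table.labels)

    def test_rf_deterministic_under_fixed_seed(self):
        table = blob_table(30, separation=1.5)
        a = train(ClassifierSpec("rf", {"n_estimators": 50}), table, seed=3)
        b = train(ClassifierSpec("rf", {"n_estimators": 50}), table, seed=3)
        X = table.features.to_numpy()
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    @pytest.mark.parametrize("name", [s.name for s in default_specs()])
    def test_every_classifier_separates_blobs(self, name):
        """Linearly separable data: each of the six models exceeds 0.95 test accuracy."""
        table = blob_table(60, separation=6.0, seed=2)
        hp = {"n_estimators": 50} if name in ("rf", "adaboost", "gradient_boost") else {}
        report = run_single(table, ClassifierSpec(name, hp), seed=0, use_smote=False)
        assert report.accuracy > 0.95
        assert report.auc > 0.95

    def test_report_identities(self):
        table = blob_table(40, separation=6.0)
        report = run_single(table, ClassifierSpec("lda"), seed=1, use_smote=False)
        assert report.recall_micro == report.accuracy
        assert report.confusion.sum() == report.n_test
        correct = report.confusion[0, 0] + report.confusion[1, 1]
        assert report.accuracy == pytest.approx(correct / report.n_test)
        assert -1.0 <= report.kappa <= 1.0
        assert 0.0 <= report.auc <= 1.0

    def test_scaler_fitted_on_train_only(self):
        """No test leakage: the pipeline's scaler parameters equal train statistics."""
        table = blob_table(40)
        train_t, _ = holdout_split(table, seed=0)
        model = train(ClassifierSpec("lda"), train_t)
        scaler = model.named_steps["scaler"]
        np.testing.assert_allclose(scaler.mean_, train_t.features.to_numpy().mean(axis=0))

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ConfigurationError):
            ClassifierSpec("mlp")

    def test_decision_scores_exist_for_all_models(self):
        table = blob_table(20, separation=2.0)
        for spec in default_specs():
            hp = {"n_estimators": 20} if spec.name in ("rf", "adaboost", "gradient_boost") else {}
            model = train(ClassifierSpec(spec.name, hp), table)
            scores = decision_scores(model, table.features.to_numpy())
            assert scores.shape == (table.n_rows,)
            assert np.isfinite(scores).all()


class TestComparisonGrid:
    def test_rf_outranks_simple_classifiers_at_large_effect(self):
        """On a strongly separable synthetic cohort, RF accuracy ≥ each of
        KNN/LDA/SVM on the same split in ≥ 70% of seeds."""
        from anxeeg.features import extract_features
        from anxeeg.labeling import label_dataset
        from anxeeg.pipeline import PipelineConfig, preprocess_dataset
        from anxeeg.simulate import SimulationConfig, generate_dataset

        wins = 0
        seeds = range(5)
        for seed in seeds:
            config = SimulationConfig(
                n_subjects=6, trial_seconds=10.0, effect_size=2.0,
                anxious_fraction=0.65, seed=seed,
            )
            dataset = generate_dataset(config)
            epochs = preprocess_dataset(dataset, PipelineConfig(seed=seed, simulation=config))
            labels = label_dataset(epochs, dataset.annotations, "hama")
            table = extract_features(epochs, method="psd", labels=labels)
            accs = {
                name: run_single(table, ClassifierSpec(name), seed=seed, use_smote=True).accuracy
                for name in ("rf", "knn", "lda", "svm")
            }
            wins += all(accs["rf"] >= accs[c] for c in ("knn", "lda", "svm"))
        assert wins / len(seeds) >= 0.70
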