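"""Classifier benchmark: six models, holdout evaluation, agreement metrics.

The comparison covers KNN (k=1), LDA (1 component), RBF-kernel SVM,
random forest (500 trees), AdaBoost (100 tree estimators) and gradient
boosting (100 tree estimators), each behind a per-feature z-score
standardizer fitted on the training split only. Evaluation is a stratified
80/20 holdout with accuracy, micro-averaged recall (identical to accuracy
by the micro-averaging identity), support-weighted precision, a 2×2
confusion matrix, rank-statistic ROC AUC, and Cohen's kappa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import precision_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from anxeeg.balance import smote
from anxeeg.features import LabeledFeatureTable
from anxeeg.io import ConfigurationError, InputError

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("knn", "lda", "svm", "rf", "adaboost", "gradient_boost")


@dataclass(frozen=True)
class ClassifierSpec:
    """One benchmark entry: algorithm name plus hyperparameter overrides.

    Defaults match the benchmark configuration: knn n_neighbors=1, rf
    n_estimators=500, adaboost/gradient_boost n_estimators=100, lda
    n_components=1, svm RBF kernel.
    """

    name: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ConfigurationError(
                f"unknown classifier {self.name!r}; expected one of {CLASSIFIER_NAMES}"
            )


def default_specs() -> list[ClassifierSpec]:
    return [ClassifierSpec(name) for name in CLASSIFIER_NAMES]


def make_classifier(spec: ClassifierSpec, seed: int = 0, ensemble_variant: str = "boosting"):
    """Build the sklearn estimator for a spec, wrapped in a train-fitted scaler.

    ``ensemble_variant='bagging'`` substitutes bagged trees for the two
    boosting ensembles (sensitivity analysis of the boosting reading of
    "AdaBoost bagging"/"gradient bagging").
    """
    hp = dict(spec.hyperparameters)
    if spec.name == "knn":
        clf = KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 1), **hp)
    elif spec.name == "lda":
        clf = LinearDiscriminantAnalysis(n_components=hp.pop("n_components", 1), **hp)
    elif spec.name == "svm":
        clf = SVC(kernel=hp.pop("kernel", "rbf"), random_state=seed, **hp)
    elif spec.name == "rf":
        clf = RandomForestClassifier(n_estimators=hp.pop("n_estimators", 500), random_state=seed, **hp)
    elif spec.name == "adaboost":
        n = hp.pop("n_estimators", 100)
        if ensemble_variant == "bagging":
            clf = BaggingClassifier(DecisionTreeClassifier(), n_estimators=n, random_state=seed, **hp)
        else:
            clf = AdaBoostClassifier(n_estimators=n, random_state=seed, **hp)
    elif spec.name == "gradient_boost":
        n = hp.pop("n_estimators", 100)
        if ensemble_variant == "bagging":
            clf = BaggingClassifier(DecisionTreeClassifier(), n_estimators=n, random_state=seed, **hp)
        else:
            clf = GradientBoostingClassifier(n_estimators=n, random_state=seed, **hp)
    else:  # unreachable; ClassifierSpec validates
        raise ConfigurationError(spec.name)
    return Pipeline([("scaler", StandardScaler()), ("clf", clf)])


@dataclass(frozen=True)
class EvaluationReport:
    """Holdout metrics for one fitted classifier."""

    classifier: ClassifierSpec
    accuracy: float
    recall_micro: float
    precision_weighted: float
    confusion: np.ndarray  # rows = actual [non-anxious, anxious], cols = predicted
    auc: float | None
    kappa: float
    split_seed: int
    n_test: int

    def to_dict(self) -> dict[str, Any]:
        return {
            "classifier": self.classifier.name,
            "accuracy": self.accuracy,
            "recall_micro": self.recall_micro,
            "precision_weighted": self.precision_weighted,
            "confusion": np.asarray(self.confusion).tolist(),
            "auc": self.auc,
            "kappa": self.kappa,
            "split_seed": self.split_seed,
            "n_test": self.n_test,
        }


def holdout_split(
    table: LabeledFeatureTable, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledFeatureTable, LabeledFeatureTable]:
    """Stratified random split into disjoint train/test tables."""
    if not 0 < train_fraction < 1:
        raise ConfigurationError(f"train_fraction must be in (0, 1), got {train_fraction}")
    counts = np.bincount(table.labels.astype(int), minlength=2)
    if counts.min() < 2:
        raise InputError(f"need ≥ 2 rows per class to split, got counts {counts.tolist()}")
    idx = np.arange(table.n_rows)
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=table.labels, random_state=seed
    )
    return table.subset(np.sort(train_idx)), table.subset(np.sort(test_idx))


def train(spec: ClassifierSpec, train_table: LabeledFeatureTable, seed: int = 0, ensemble_variant: str = "boosting"):
    """Fit the classifier (with its scaler) on the training table."""
    if train_table.n_rows == 0:
        raise InputError("empty training table")
    if len(set(train_table.labels.tolist())) < 2:
        raise InputError("training table must contain both classes")
    model = make_classifier(spec, seed=seed, ensemble_variant=ensemble_variant)
    model.fit(train_table.features.to_numpy(), train_table.labels.astype(int))
    return model


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous score for the anxious class, for ROC ranking."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def rank_auc(actual: np.ndarray, scores: np.ndarray) -> float | None:
    """ROC AUC as the Mann–Whitney rank statistic.

    P(score of a random positive > score of a random negative), with ties
    counted half. ``None`` when the test set has a single class.
    """
    actual = np.asarray(actual, dtype=bool)
    pos = np.asarray(scores, dtype=float)[actual]
    neg = np.asarray(scores, dtype=float)[~actual]
    if pos.size == 0 or neg.size == 0:
        logger.warning("single-class test set: AUC undefined")
        return None
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def cohen_kappa(actual, predicted) -> float:
    """Chance-corrected agreement κ = (p_o − p_e) / (1 − p_e).

    ``p_o`` is observed agreement, ``p_e`` chance agreement from the two
    raters' marginals. When both raters emit a single identical class
    (p_e = 1), κ is returned as 1 by convention, with a warning.
    """
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise InputError(f"label lists differ in length: {actual.shape} vs {predicted.shape}")
    if actual.size == 0:
        raise InputError("cannot compute kappa of empty label lists")
    classes = np.unique(np.concatenate([actual, predicted]))
    p_o = float(np.mean(actual == predicted))
    p_e = float(
        sum(np.mean(actual == c) * np.mean(predicted == c) for c in classes)
    )
    if p_e >= 1.0 - 1e-15:
        logger.warning("degenerate single-class agreement: kappa set to 1 by convention")
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def evaluate(model, test_table: LabeledFeatureTable, spec: ClassifierSpec, split_seed: int = 0) -> EvaluationReport:
    """Score a fitted model on a held-out table."""
    if test_table.n_rows == 0:
        raise InputError("empty test table")
    X = test_table.features.to_numpy()
    actual = test_table.labels.astype(int)
    predicted = np.asarray(model.predict(X), dtype=int)

    accuracy = float(np.mean(predicted == actual))
    confusion = np.zeros((2, 2), dtype=int)
    for a, p in zip(actual, predicted):
        confusion[a, p] += 1
    precision = float(precision_score(actual, predicted, average="weighted", zero_division=0))
    auc = rank_auc(actual.astype(bool), decision_scores(model, X))
    return EvaluationReport(
        classifier=spec,
        accuracy=accuracy,
        recall_micro=accuracy,  # micro-averaged recall ≡ accuracy
        precision_weighted=precision,
        confusion=confusion,
        auc=auc,
        kappa=cohen_kappa(actual, predicted),
        split_seed=split_seed,
        n_test=test_table.n_rows,
    )


def run_single(
    table: LabeledFeatureTable,
    spec: ClassifierSpec,
    seed: int = 0,
    use_smote: bool = True,
    smote_before_split: bool = False,
    smote_k: int = 5,
    train_fraction: float = 0.8,
    ensemble_variant: str = "boosting",
) -> EvaluationReport:
    """Split → (optionally) balance → train → evaluate, one classifier.

    By default SMOTE is applied to the training split only, so no
    synthetic interpolations of test rows leak into training;
    ``smote_before_split`` reproduces the leakier oversample-then-split
    variant.
    """
    if use_smote and smote_before_split:
        table = smote(table, k=smote_k, seed=seed)
    train_table, test_table = holdout_split(table, train_fraction=train_fraction, seed=seed)
    if use_smote and not smote_before_split:
        train_table = smote(train_table, k=smote_k, seed=seed)
    model = train(spec, train_table, seed=seed, ensemble_variant=ensemble_variant)
    return evaluate(model, test_table, spec, split_seed=seed)


def run_comparison(
    features_dwt: LabeledFeatureTable,
    features_psd: LabeledFeatureTable,
    labels_sam: np.ndarray,
    labels_hama: np.ndarray,
    specs: list[ClassifierSpec] | None = None,
    seed: int = 0,
    smote_k: int = 5,
    smote_before_split: bool = False,
) -> list[dict[str, Any]]:
    """The full benchmark grid: 6 classifiers × {dwt, psd} × {sam, hama} × {smote, none}.

    Returns one record per cell (48 with the default specs) carrying the
    grid coordinates and the evaluation metrics.
    """
    specs = specs if specs is not None else default_specs()
    feature_sets = {"dwt": features_dwt, "psd": features_psd}
    labelings = {"sam": labels_sam, "hama": labels_hama}
    records = []
    for feat_name, base_table in feature_sets.items():
        for label_name, labels in labelings.items():
            table = base_table.with_labels(labels)
            for use_smote in (True, False):
                for spec in specs:
                    report = run_single(
                        table,
                        spec,
                        seed=seed,
                        use_smote=use_smote,
                        smote_before_split=smote_before_split,
                        smote_k=smote_k,
                    )
                    records.append(
                        {
                            "features": feat_name,
                            "labeling": label_name,
                            "smote": use_smote,
                            **report.to_dict(),
                        }
                    )
    return records
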