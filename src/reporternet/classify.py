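"""Cross-validated classification of a candidate-gene panel.

The harness, fold assignment and metrics are native; classifier backends
plug in through a fit/predict contract (any sklearn-style estimator
factory). Fold assignment is stratified and a pure function of
(labels, n_folds, seed), so reports are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ClassificationReport:
    classifier_name: str
    accuracy: float
    f1: float
    recall: float
    fold_scores: pd.DataFrame  # per-fold accuracy/f1/recall
    n_folds: int
    seed: int


def stratified_folds(labels, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Within each class, members are shuffled with a seed derived from
    (seed, class) and dealt round-robin, so every fold contains both classes
    whenever each class has >= n_folds members.
    """
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    assign = np.empty(labels.size, dtype=int)
    for ci, cls in enumerate(np.unique(labels)):
        idx = np.flatnonzero(labels == cls)
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), ci)))
        rng.shuffle(idx)
        assign[idx] = np.arange(idx.size) % n_folds
    return assign


def confusion_metrics(y_true, y_pred, positive) -> dict[str, float]:
    """Accuracy, recall and F1 from 2x2 confusion counts, positive class fixed."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true == positive) & (y_pred == positive)).sum())
    fn = int(((y_true == positive) & (y_pred != positive)).sum())
    fp = int(((y_true != positive) & (y_pred == positive)).sum())
    tn = int(((y_true != positive) & (y_pred != positive)).sum())
    n = tp + fn + fp + tn
    accuracy = (tp + tn) / n if n else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"accuracy": accuracy, "f1": f1, "recall": recall}


def default_classifiers(seed: int = 0) -> dict[str, Callable]:
    """Factories for the shipped backends (sklearn + gradient-boosting libs)."""
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.tree import DecisionTreeClassifier

    backends: dict[str, Callable] = {
        "knn": lambda: KNeighborsClassifier(n_neighbors=5),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=100, random_state=seed
        ),
        "gradient_boosting": lambda: GradientBoostingClassifier(random_state=seed),
        "mlp": lambda: MLPClassifier(
            hidden_layer_sizes=(32,), max_iter=500, random_state=seed
        ),
    }
    try:
        from xgboost import XGBClassifier

        backends["xgb"] = lambda: XGBClassifier(
            n_estimators=100, random_state=seed, verbosity=0, eval_metric="logloss"
        )
    except ImportError:  # pragma: no cover
        pass
    try:
        from lightgbm import LGBMClassifier

        backends["lgbm"] = lambda: LGBMClassifier(
            n_estimators=100, random_state=seed, verbosity=-1
        )
    except ImportError:  # pragma: no cover
        pass
    return backends


def evaluate_panel(
    X: pd.DataFrame,
    labels: pd.Series,
    classifiers: dict[str, Callable] | None = None,
    n_folds: int = 5,
    seed: int = 0,
    positive: str = "case",
) -> list[ClassificationReport]:
    """Stratified k-fold evaluation of a gene panel.

    Parameters
    ----------
    X
        samples x genes feature matrix (panel-restricted expression,
        samples as rows).
    labels
        binary labels per sample; ``positive`` names the positive class
        for recall/F1 ("case" for diagnosis, "dead" for survival status).

    Per-classifier aggregate metrics are unweighted means of fold scores.
    """
    labels = labels.reindex(X.index)
    y = labels.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need both classes to evaluate")
    min_count = int(counts.min())
    if min_count < n_folds:
        logger.warning(
            "smallest class has %d members; reducing folds from %d", min_count, n_folds
        )
        n_folds = max(2, min_count)
    assign = stratified_folds(y, n_folds, seed)
    Xv = X.to_numpy(dtype=float)

    if classifiers is None:
        classifiers = default_classifiers(seed=seed)
    # map to integer codes for backends that require numeric targets
    code = {c: i for i, c in enumerate(classes)}
    y_code = np.array([code[v] for v in y])

    reports = []
    for name in classifiers:
        per_fold = []
        for fold in range(n_folds):
            test = assign == fold
            clf = classifiers[name]()
            clf.fit(Xv[~test], y_code[~test])
            pred = np.asarray(clf.predict(Xv[test]))
            per_fold.append(confusion_metrics(y_code[test], pred, code.get(positive, 1)))
        fold_df = pd.DataFrame(per_fold)
        reports.append(
            ClassificationReport(
                classifier_name=name,
                accuracy=float(fold_df["accuracy"].mean()),
                f1=float(fold_df["f1"].mean()),
                recall=float(fold_df["recall"].mean()),
                fold_scores=fold_df,
                n_folds=n_folds,
                seed=seed,
            )
        )
    return reports


def reports_to_frame(reports: list[ClassificationReport]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "classifier": [r.classifier_name for r in reports],
            "accuracy": [r.accuracy for r in reports],
            "f1": [r.f1 for r in reports],
            "recall": [r.recall for r in reports],
            "n_folds": [r.n_folds for r in reports],
        }
    ).set_index("classifier")
    return df.sort_values("accuracy", ascending=False, kind="stable")
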