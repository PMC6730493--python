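"""Diagnosis classifiers and the balanced-accuracy metric.

Two classifier families are supported, in a two-class (CVID vs
Non-CVID) and a three-class (CVID / other PADs / HC) formulation:

* random forest with 500 trees (default split criterion);
* soft-margin linear SVM with C = 1, one-vs-one for multiclass.

Performance is reported as balanced accuracy — the mean of per-class
recalls, which for two classes reduces to (TP/P + TN/N)/2 — because the
CVID class is heavily outnumbered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

DIAGNOSES = ("CVID", "otherPAD", "HC")

FEATURE_SETS = {
    "percentages_clusters": ("percentages_clusters",),
    "percentages_metaclusters": ("percentages_metaclusters",),
    "percentages_clusters_to_metaclusters": ("percentages_clusters_to_metaclusters",),
    "Clusters": ("percentages_clusters", "MFI_cluster"),
    "Meta_clusters": ("percentages_metaclusters", "MFI_metacluster"),
    "total": (
        "percentages_clusters",
        "percentages_metaclusters",
        "percentages_clusters_to_metaclusters",
        "MFI_cluster",
        "MFI_metacluster",
    ),
    "manual": None,  # externally provided manual-gating feature table
}


@dataclass
class ModelConfig:
    classifier: str = "svm"  # "rf" or "svm"
    n_classes: int = 2
    feature_set: str = "total"
    with_selection: bool = False
    panel: str = "combined"
    seed: int = 0
    # fixed by convention: rf -> 500 trees; svm -> linear kernel, C = 1
    n_trees: int = field(default=500, repr=False)
    svm_c: float = field(default=1.0, repr=False)

    def __post_init__(self) -> None:
        if self.classifier not in ("rf", "svm"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")


def make_labels(meta: pd.DataFrame, n_classes: int) -> pd.Series:
    """Map diagnoses to classification labels.

    Three classes keep {CVID, otherPAD, HC}; two classes pool other PADs
    and healthy controls into a joint NonCVID class.
    """
    diag = meta["diagnosis"]
    unknown = set(diag) - set(DIAGNOSES)
    if unknown:
        raise ValueError(f"unknown diagnoses: {sorted(unknown)}")
    if n_classes == 3:
        return diag.copy()
    if n_classes == 2:
        return diag.map(lambda d: "CVID" if d == "CVID" else "NonCVID")
    raise ValueError("n_classes must be 2 or 3")


def build_classifier(config: ModelConfig):
    if config.classifier == "rf":
        return RandomForestClassifier(
            n_estimators=config.n_trees, random_state=config.seed
        )
    return SVC(kernel="linear", C=config.svm_c, random_state=config.seed)


def fit_predict(
    X_train: pd.DataFrame,
    y_train,
    X_test: pd.DataFrame,
    config: ModelConfig,
):
    """Fit the configured classifier and predict the test samples.

    Returns (fitted model, predicted labels).  Deterministic for a
    fixed seed.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain at least two classes")
    if not X_train.columns.equals(X_test.columns):
        raise ValueError("train/test feature columns are not aligned")
    model = build_classifier(config)
    model.fit(X_train.to_numpy(), y_train)
    preds = model.predict(X_test.to_numpy())
    return model, preds


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean per-class recall over the classes present in ``y_true``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    recalls = []
    for c in np.unique(y_true):
        mask = y_true == c
        recalls.append(np.mean(y_pred[mask] == c))
    return float(np.mean(recalls))


def importances(model, feature_names) -> pd.Series:
    """Descending feature-importance ranking of a fitted model.

    SVM: per feature, the maximum absolute hyperplane coefficient over
    the one-vs-one class pairs.  Random forest: mean impurity decrease.
    Ties break by feature name.
    """
    if isinstance(model, RandomForestClassifier):
        if not hasattr(model, "estimators_"):
            raise AttributeError("model is not fitted")
        scores = model.feature_importances_
    elif isinstance(model, SVC):
        if not hasattr(model, "coef_"):
            raise AttributeError("model is not fitted")
        scores = np.abs(np.atleast_2d(model.coef_)).max(axis=0)
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    s = pd.Series(np.asarray(scores, dtype=float), index=list(feature_names))
    return s.iloc[np.lexsort((s.index, -s.values))]
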