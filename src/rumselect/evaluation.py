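"""Cross-validated classification accuracy of an attribute subset.

A selected subset is scored by stratified k-fold cross-validation with two
standard classifiers: a linear-kernel support-vector machine and a
k-nearest-neighbor classifier (k = 3 by default).  Stratification keeps
every fold's class proportions stable, which matters on the small,
imbalanced benchmark tables this method targets.  Accuracies are reported
in percent to two decimals.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .data_model import DecisionTable, SelectionConfig, ValidationError

__all__ = ["EvalResult", "evaluate"]

# hyperparameters beyond "linear" and "k neighbors" are plain defaults
_CLASSIFIER_META = {
    "svm": {"kernel": "linear", "C": 1.0},
    "knn": {"metric": "euclidean", "weights": "uniform"},
}


@dataclasses.dataclass
class EvalResult:
    """CV accuracies (percent) of one attribute subset."""

    subset: tuple[str, ...]
    accuracy_svm: float
    accuracy_knn: float
    folds: int
    seed: int
    classifier_meta: dict = dataclasses.field(
        default_factory=lambda: dict(_CLASSIFIER_META)
    )

    def to_dict(self) -> dict:
        return {
            "subset": list(self.subset),
            "accuracy_svm": self.accuracy_svm,
            "accuracy_knn": self.accuracy_knn,
            "folds": self.folds,
            "seed": self.seed,
            "classifier_meta": self.classifier_meta,
        }


def evaluate(
    table: DecisionTable, subset: Sequence[str], config: SelectionConfig
) -> EvalResult:
    """Stratified k-fold CV accuracy of linear SVM and kNN on a subset.

    The table is restricted to the subset's columns; folds are shuffled
    and seeded by ``config.rng_seed`` so repeated calls are identical.
    If the rarest class has fewer members than the requested fold count,
    the folds are reduced to that count (with a warning) so every fold
    sees every class.
    """
    if len(subset) == 0:
        raise ValidationError("cannot evaluate an empty attribute subset")
    table.validate()
    idx = table.column_indices(subset)
    X = table.values[:, idx]
    y = table.class_codes()

    folds = config.cv_folds
    min_class = int(np.bincount(y).min())
    if min_class < folds:
        folds = max(2, min_class)
        warnings.warn(
            f"smallest class has {min_class} member(s); "
            f"reducing folds from {config.cv_folds} to {folds}",
            RuntimeWarning,
            stacklevel=2,
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.rng_seed)
    svm = SVC(kernel="linear", C=1.0)
    knn = KNeighborsClassifier(n_neighbors=config.knn_k)
    acc_svm = cross_val_score(svm, X, y, cv=cv, scoring="accuracy").mean() * 100.0
    acc_knn = cross_val_score(knn, X, y, cv=cv, scoring="accuracy").mean() * 100.0
    return EvalResult(
        subset=tuple(subset),
        accuracy_svm=round(float(acc_svm), 2),
        accuracy_knn=round(float(acc_knn), 2),
        folds=folds,
        seed=config.rng_seed,
    )
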