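"""NT-vs-HT classification from synchrony features with leave-one-out CV.

Feature vectors are the per-subject band-max synchrony values (COH, PDC,
DTF, ffDTF, dDTF — directed measures in the ABP->PPG direction) for
normotensive and hypertensive subjects only.  Evaluation is leave-one-out:
each subject is predicted by a model trained on all others, with feature
standardization refit inside every training fold so no statistics leak
from the held-out subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .connectivity import SubjectSummary

__all__ = [
    "FeatureTable",
    "ClassifierSpec",
    "ClassificationReport",
    "build_features",
    "loocv",
    "nn_classifier_spec",
    "baseline_classifier_specs",
    "DEFAULT_MEASURES",
]

DEFAULT_MEASURES = ("COH", "PDC", "DTF", "ffDTF", "dDTF")
_LABELS = {"NT": 0, "HT": 1}


@dataclass
class FeatureTable:
    """Subjects x features matrix with binary NT/HT labels."""

    X: pd.DataFrame
    y: np.ndarray
    subject_ids: list[str]

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n(self) -> int:
        return len(self.subject_ids)


def build_features(
    summaries: Sequence[SubjectSummary],
    measures: Sequence[str] = DEFAULT_MEASURES,
    direction: str = "abp_to_ppg",
) -> FeatureTable:
    """Assemble the NT/HT feature table; prehypertensive subjects excluded.

    Raw band-max values are stored; standardization happens inside the
    cross-validation folds at evaluation time.
    """
    rows, labels, ids = [], [], []
    for s in summaries:
        if s.group not in _LABELS:
            continue
        row = {}
        for m in measures:
            key = m if m in ("COH", "pCOH") else f"{m}_{direction}"
            if key not in s.band_max or not np.isfinite(s.band_max[key]):
                raise KeyError(
                    f"subject {s.subject_id!r} missing measure {key!r}"
                )
            row[m] = s.band_max[key]
        rows.append(row)
        labels.append(_LABELS[s.group])
        ids.append(s.subject_id)
    X = pd.DataFrame(rows, columns=list(measures))
    return FeatureTable(X=X, y=np.asarray(labels, dtype=int), subject_ids=ids)


@dataclass(frozen=True)
class ClassifierSpec:
    """Named factory producing a fresh estimator for a given seed."""

    name: str
    factory: Callable[[int], BaseEstimator]

    def build(self, seed: int) -> BaseEstimator:
        return self.factory(seed)


class DiagLinearDiscriminant(BaseEstimator, ClassifierMixin):
    """Linear discriminant with pooled *diagonal* covariance.

    Equivalent to Gaussian naive Bayes with a shared per-feature variance;
    coincides with full LDA when features are uncorrelated.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.means_ = np.array([X[y == c].mean(axis=0) for c in self.classes_])
        resid = np.concatenate([X[y == c] - X[y == c].mean(axis=0) for c in self.classes_])
        self.var_ = resid.var(axis=0) + 1e-12
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        return self

    def _scores(self, X):
        X = np.asarray(X, dtype=float)
        scores = []
        for mu, prior in zip(self.means_, self.priors_):
            # linear in x: quadratic term is class-independent with pooled cov
            s = X @ (mu / self.var_) - 0.5 * np.sum(mu**2 / self.var_) + np.log(prior)
            scores.append(s)
        return np.column_stack(scores)

    def decision_function(self, X):
        s = self._scores(X)
        return s[:, 1] - s[:, 0]

    def predict(self, X):
        return self.classes_[np.argmax(self._scores(X), axis=1)]


def nn_classifier_spec(
    hidden_units: int = 10, max_iter: int = 1000, alpha: float = 1e-3
) -> ClassifierSpec:
    """Feed-forward network: one sigmoidal hidden layer, cross-entropy loss.

    "Two-layer" in the input/hidden/output counting convention; trained
    with L-BFGS, deterministic given the seed.
    """

    def factory(seed: int) -> BaseEstimator:
        return MLPClassifier(
            hidden_layer_sizes=(hidden_units,),
            activation="logistic",
            solver="lbfgs",
            alpha=alpha,
            max_iter=max_iter,
            random_state=seed,
        )

    return ClassifierSpec(name="nn", factory=factory)


def baseline_classifier_specs() -> list[ClassifierSpec]:
    """Representative fixed-hyperparameter baselines."""
    return [
        ClassifierSpec("linear", lambda seed: LinearDiscriminantAnalysis()),
        ClassifierSpec("diaglinear", lambda seed: DiagLinearDiscriminant()),
        ClassifierSpec(
            "quadratic", lambda seed: QuadraticDiscriminantAnalysis(reg_param=1e-3)
        ),
        ClassifierSpec("knn", lambda seed: KNeighborsClassifier(n_neighbors=5)),
        ClassifierSpec(
            "tree",
            lambda seed: DecisionTreeClassifier(max_depth=4, random_state=seed),
        ),
        ClassifierSpec("naive_bayes", lambda seed: GaussianNB()),
        ClassifierSpec("svm", lambda seed: SVC(kernel="rbf", C=1.0, gamma="scale")),
    ]


@dataclass
class ClassificationReport:
    """Leave-one-out outcome for one classifier on one feature set."""

    classifier: str
    features: tuple[str, ...]
    accuracy: float
    confusion: np.ndarray  # rows true, cols predicted, order [NT, HT]
    roc_points: np.ndarray  # (k, 2) columns FPR, TPR
    n: int
    failed_folds: int
    seed: int


def _held_out_score(model, x_row: np.ndarray) -> float:
    if hasattr(model, "predict_proba"):
        return float(model.predict_proba(x_row)[0, -1])
    return float(model.decision_function(x_row)[0])


def loocv(table: FeatureTable, spec: ClassifierSpec, seed: int = 0) -> ClassificationReport:
    """Leave-one-out cross-validation with fold-local standardization."""
    n = table.n
    classes, counts = np.unique(table.y, return_counts=True)
    if classes.size != 2 or np.min(counts) < 2:
        raise ValueError("need at least two subjects in each of two classes")
    X = table.X.to_numpy(dtype=float)
    y = table.y
    preds = np.full(n, -1, dtype=int)
    scores = np.full(n, np.nan)
    ok = np.ones(n, dtype=bool)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = Pipeline(
            [("scale", StandardScaler()), ("clf", spec.build(seed))]
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[mask], y[mask])
            preds[i] = int(model.predict(X[i : i + 1])[0])
            scores[i] = _held_out_score(model, X[i : i + 1])
        except Exception:  # convergence or degenerate-fold failure
            ok[i] = False
    failed = int(np.count_nonzero(~ok))
    if failed > 0.05 * n:
        raise RuntimeError(
            f"{failed}/{n} leave-one-out folds failed for {spec.name}"
        )
    used = ok
    accuracy = float(np.mean(preds[used] == y[used]))
    conf = confusion_matrix(y[used], preds[used], labels=[0, 1])
    finite = used & np.isfinite(scores)
    if np.unique(y[finite]).size == 2:
        fpr, tpr, _ = roc_curve(y[finite], scores[finite])
        roc_points = np.column_stack([fpr, tpr])
    else:
        roc_points = np.zeros((0, 2))
    return ClassificationReport(
        classifier=spec.name,
        features=tuple(table.feature_names),
        accuracy=accuracy,
        confusion=conf,
        roc_points=roc_points,
        n=int(np.count_nonzero(used)),
        failed_folds=failed,
        seed=seed,
    )
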