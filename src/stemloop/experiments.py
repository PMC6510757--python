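"""Classification experiments: dataset assembly, Random-Forest training,
evaluation, feature importances, and cross-application of trained models.

The protocol mirrors the recognition experiments for retrotransposon 3'
ends: a Random Forest (2000 trees by default) separates a positive class
from a negative class (typically dinucleotide-shuffled counterparts),
evaluated by stratified k-fold cross-validation with ROC-AUC plus
threshold metrics, and interrogated through normalized impurity (Gini)
feature importances, of which the 10 highest-ranked are summarized.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_curve,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from .encode import FeatureVector


class DatasetError(ValueError):
    """Raised for degenerate or inconsistent datasets."""


@dataclass(frozen=True)
class ExperimentSpec:
    """Configuration of one classification experiment."""

    name: str
    scheme: str
    class1_source: str = "class1"
    class2_source: str = "class2"
    n_trees: int = 2000
    cv_folds: int = 5
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.class1_source == self.class2_source:
            raise ValueError("class sources must be disjoint")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.n_trees < 1 or self.cv_folds < 2:
            raise ValueError("need n_trees >= 1 and cv_folds >= 2")


@dataclass
class LabeledDataset:
    X: np.ndarray
    y: np.ndarray
    ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    scheme: str


@dataclass
class ExperimentReport:
    """Metrics, curves and ranked feature importances for one experiment."""

    name: str
    scheme: str
    n_instances: int
    auc_mean: float
    auc_std: float
    accuracy_mean: float
    accuracy_std: float
    precision_mean: float
    precision_std: float
    recall_mean: float
    recall_std: float
    fold_aucs: list[float]
    roc_curve: list[tuple[float, float]]
    pr_curve: list[tuple[float, float]]
    confusion: list[list[int]]
    feature_importances: list[tuple[str, float]]
    top10: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "scheme": self.scheme,
            "n_instances": self.n_instances,
            "metrics": {
                "auc": {"mean": self.auc_mean, "std": self.auc_std},
                "accuracy": {"mean": self.accuracy_mean, "std": self.accuracy_std},
                "precision": {"mean": self.precision_mean, "std": self.precision_std},
                "recall": {"mean": self.recall_mean, "std": self.recall_std},
            },
            "fold_aucs": self.fold_aucs,
            "roc_curve": [list(p) for p in self.roc_curve],
            "pr_curve": [list(p) for p in self.pr_curve],
            "confusion": self.confusion,
            "feature_importances": [[n, v] for n, v in self.feature_importances],
            "top10": self.top10,
        }


@dataclass
class TrainedModel:
    """A fitted forest plus the feature contract it was trained under."""

    estimator: RandomForestClassifier
    scheme: str
    feature_names: tuple[str, ...]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return obj


def build_dataset(
    positives: Sequence[FeatureVector],
    negatives: Sequence[FeatureVector],
    positive_ids: Optional[Sequence[str]] = None,
    negative_ids: Optional[Sequence[str]] = None,
) -> LabeledDataset:
    """Row-stack feature vectors into a labeled matrix (1 = class 1).

    All vectors must share one scheme and an identical feature-name order;
    the first divergent feature is named on mismatch.
    """
    if not positives or not negatives:
        raise DatasetError("both classes must be non-empty")
    ref = positives[0]
    for vec in list(positives) + list(negatives):
        if vec.scheme != ref.scheme:
            raise DatasetError(
                f"scheme mismatch: {vec.scheme!r} vs {ref.scheme!r}"
            )
        if vec.names != ref.names:
            divergent = next(
                (a for a, b in zip(ref.names, vec.names) if a != b),
                "<length mismatch>",
            )
            raise DatasetError(f"feature order mismatch at {divergent!r}")
    X = np.vstack([v.values for v in positives] + [v.values for v in negatives])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))]).astype(int)
    if positive_ids is None:
        positive_ids = [f"pos{i}" for i in range(len(positives))]
    if negative_ids is None:
        negative_ids = [f"neg{i}" for i in range(len(negatives))]
    return LabeledDataset(
        X=X,
        y=y,
        ids=tuple(positive_ids) + tuple(negative_ids),
        feature_names=ref.names,
        scheme=ref.scheme,
    )


def _forest(spec: ExperimentSpec, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=spec.n_trees, random_state=seed, n_jobs=1
    )


def run_experiment(spec: ExperimentSpec, dataset: LabeledDataset) -> ExperimentReport:
    """Stratified k-fold cross-validation plus a final all-data fit.

    Per-fold ROC-AUC and threshold metrics are computed on held-out folds;
    ROC/PR curves come from the pooled out-of-fold probabilities; feature
    importances from the final model.  Fully reproducible given spec.seed.
    """
    counts = Counter(dataset.y.tolist())
    if len(counts) < 2:
        raise DatasetError("dataset contains a single class")
    if min(counts.values()) < 2 * spec.cv_folds:
        raise DatasetError(
            f"need >= 2 instances per class per fold "
            f"(have {dict(counts)} for {spec.cv_folds} folds); "
            "add data or reduce cv_folds"
        )
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    aucs, accs, precs, recs = [], [], [], []
    pooled_proba = np.zeros(len(dataset.y))
    for fold, (train_idx, test_idx) in enumerate(skf.split(dataset.X, dataset.y)):
        clf = _forest(spec, spec.seed + fold + 1)
        clf.fit(dataset.X[train_idx], dataset.y[train_idx])
        proba = clf.predict_proba(dataset.X[test_idx])[:, list(clf.classes_).index(1)]
        pooled_proba[test_idx] = proba
        pred = (proba >= spec.threshold).astype(int)
        y_test = dataset.y[test_idx]
        aucs.append(roc_auc_score(y_test, proba))
        accs.append(accuracy_score(y_test, pred))
        precs.append(precision_score(y_test, pred, zero_division=0))
        recs.append(recall_score(y_test, pred, zero_division=0))

    fpr, tpr, _ = roc_curve(dataset.y, pooled_proba)
    prec_c, rec_c, _ = precision_recall_curve(dataset.y, pooled_proba)
    pooled_pred = (pooled_proba >= spec.threshold).astype(int)
    conf = confusion_matrix(dataset.y, pooled_pred, labels=[0, 1])

    final = _forest(spec, spec.seed)
    final.fit(dataset.X, dataset.y)
    importances = final.feature_importances_
    total = importances.sum()
    if total > 0:
        importances = importances / total
    ranked = sorted(
        zip(dataset.feature_names, importances.tolist()),
        key=lambda nv: (-nv[1], nv[0]),
    )
    return ExperimentReport(
        name=spec.name,
        scheme=dataset.scheme,
        n_instances=len(dataset.y),
        auc_mean=float(np.mean(aucs)),
        auc_std=float(np.std(aucs)),
        accuracy_mean=float(np.mean(accs)),
        accuracy_std=float(np.std(accs)),
        precision_mean=float(np.mean(precs)),
        precision_std=float(np.std(precs)),
        recall_mean=float(np.mean(recs)),
        recall_std=float(np.std(recs)),
        fold_aucs=[float(a) for a in aucs],
        roc_curve=list(zip(fpr.tolist(), tpr.tolist())),
        pr_curve=list(zip(rec_c.tolist(), prec_c.tolist())),
        confusion=conf.tolist(),
        feature_importances=ranked,
        top10=[name for name, _ in ranked[:10]],
    )


def train_full(spec: ExperimentSpec, dataset: LabeledDataset) -> TrainedModel:
    """Fit one forest on the entire dataset (for cross-application)."""
    clf = _forest(spec, spec.seed)
    clf.fit(dataset.X, dataset.y)
    return TrainedModel(
        estimator=clf, scheme=dataset.scheme, feature_names=dataset.feature_names
    )


def cross_apply(
    model: TrainedModel,
    foreign: Sequence[FeatureVector],
    threshold: float = 0.5,
    return_probabilities: bool = False,
):
    """Fraction of foreign instances called positive at ``threshold``."""
    if not foreign:
        raise DatasetError("empty foreign set")
    for vec in foreign:
        if vec.scheme != model.scheme:
            raise DatasetError(
                f"scheme mismatch: model={model.scheme!r}, data={vec.scheme!r}"
            )
        if vec.names != model.feature_names:
            raise DatasetError("foreign vectors do not match training feature order")
    X = np.vstack([v.values for v in foreign])
    pos_col = list(model.estimator.classes_).index(1)
    proba = model.estimator.predict_proba(X)[:, pos_col]
    fraction = float(np.mean(proba >= threshold))
    if return_probabilities:
        return fraction, proba
    return fraction


def summarize_importances(reports: Sequence[ExperimentReport]):
    """Tally how often each property and each position appear in top-10 lists.

    Only meaningful for structure-based reports, whose feature names are
    ``position:property``.  Returns two lists of (label, count) sorted by
    descending count then label.
    """
    from .encode import SCHEME_STRUCTURE

    prop_tally: Counter = Counter()
    pos_tally: Counter = Counter()
    for report in reports:
        if report.scheme != SCHEME_STRUCTURE:
            raise DatasetError(
                f"importance summary requires structure_sl reports, got {report.scheme!r}"
            )
        for name in report.top10:
            position, sep, prop = name.partition(":")
            if not sep or not position or not prop:
                raise DatasetError(f"malformed feature name {name!r}")
            prop_tally[prop] += 1
            pos_tally[position] += 1
    order = lambda c: sorted(c.items(), key=lambda kv: (-kv[1], kv[0]))
    return order(prop_tally), order(pos_tally)
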