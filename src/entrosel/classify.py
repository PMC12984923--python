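"""Binary region classification: kNN (primary), linear SVM (comparison),
standardization, stratified k-fold cross-validation, confusion-matrix metrics
and ROC/AUC.

The kNN is implemented directly (Euclidean distance, majority vote,
nearest-index-first tie-breaking) because the ROC score for k = 1 is a
distance margin — nearest other-class distance minus nearest same-class
distance — which off-the-shelf classifiers do not expose.  The SVM delegates
to scikit-learn (linear kernel, box constraint 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import InvalidArgumentError, InvalidInputError

POSITIVE_LABEL = 1  # tumor


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "knn"  # "knn" or "svm"
    n_neighbors: int = 1
    box_constraint: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "svm"):
            raise InvalidArgumentError("kind must be 'knn' or 'svm'")
        if self.n_neighbors < 1 or self.box_constraint <= 0:
            raise InvalidArgumentError("invalid classifier parameters")


@dataclass
class ConfusionMatrix:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvaluationReport:
    confusion: ConfusionMatrix
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class_recall: dict = field(default_factory=dict)
    roc_points: list = field(default_factory=list)
    auc: float = float("nan")
    fold_accuracies: list = field(default_factory=list)
    seed: int | None = None


def standardize(train: np.ndarray, apply: np.ndarray | None = None):
    """Z-score columns with train statistics; zero-SD columns map to zeros.

    Returns (train_z, apply_z, scaler) where scaler is (mean, sd, degenerate).
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise InvalidInputError("need a 2-D train matrix with >= 2 rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    degenerate = sd == 0
    safe_sd = np.where(degenerate, 1.0, sd)
    train_z = (train - mean) / safe_sd
    train_z[:, degenerate] = 0.0
    apply_z = None
    if apply is not None:
        apply = np.asarray(apply, dtype=float)
        apply_z = (apply - mean) / safe_sd
        apply_z[:, degenerate] = 0.0
    return train_z, apply_z, (mean, sd, degenerate)


def knn_predict(train_x, train_y, query_x, k: int = 1):
    """k-nearest-neighbor labels and positive-class margin scores.

    Distances are Euclidean; votes are resolved by majority with the tie at
    even k falling back to the nearest neighbour's label; equal distances
    break toward the lower training index.  The returned score is
    d(nearest negative) - d(nearest positive): larger means more
    positive-like, giving a non-degenerate ROC sweep even at k = 1.
    """
    train_x = np.asarray(train_x, dtype=float)
    train_y = np.asarray(train_y)
    query_x = np.asarray(query_x, dtype=float)
    if train_x.shape[0] == 0:
        raise InvalidInputError("empty training set")
    if k > train_x.shape[0]:
        raise InvalidArgumentError("k exceeds the number of training rows")
    d = cdist(query_x, train_x, "euclidean")
    order = np.argsort(d, axis=1, kind="stable")  # stable => lower index first on ties
    labels = np.empty(query_x.shape[0], dtype=train_y.dtype)
    scores = np.empty(query_x.shape[0])
    classes = np.unique(train_y)
    for i in range(query_x.shape[0]):
        nn = order[i, :k]
        votes = train_y[nn]
        counts = {c: int((votes == c).sum()) for c in classes}
        best = max(counts.values())
        winners = [c for c in classes if counts[c] == best]
        labels[i] = votes[0] if len(winners) > 1 else winners[0]
        pos = d[i, train_y == POSITIVE_LABEL]
        neg = d[i, train_y != POSITIVE_LABEL]
        d_pos = pos.min() if pos.size else np.inf
        d_neg = neg.min() if neg.size else np.inf
        scores[i] = d_neg - d_pos
    return labels, scores


def svm_train_predict(train_x, train_y, query_x, spec: ClassifierSpec | None = None):
    """Soft-margin linear SVM (C = box constraint); returns labels + decision values."""
    spec = spec or ClassifierSpec(kind="svm")
    train_y = np.asarray(train_y)
    if np.unique(train_y).size < 2:
        raise InvalidInputError("SVM training requires both classes")
    clf = SVC(kernel="linear", C=spec.box_constraint)
    clf.fit(np.asarray(train_x, dtype=float), train_y)
    query_x = np.asarray(query_x, dtype=float)
    return clf.predict(query_x), clf.decision_function(query_x)


def confusion_counts(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InvalidInputError("label vectors must have equal length")
    pos = POSITIVE_LABEL
    return ConfusionMatrix(
        tp=int(((y_true == pos) & (y_pred == pos)).sum()),
        tn=int(((y_true != pos) & (y_pred != pos)).sum()),
        fp=int(((y_true != pos) & (y_pred == pos)).sum()),
        fn=int(((y_true == pos) & (y_pred != pos)).sum()),
    )


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def confusion_metrics(y_true, y_pred) -> EvaluationReport:
    """Accuracy plus macro-averaged precision/recall/F1 over the two classes.

    Each class is treated as positive in turn and the per-class values are
    averaged with equal weight.
    """
    cm = confusion_counts(y_true, y_pred)
    if cm.total == 0:
        raise InvalidInputError("no samples to evaluate")
    accuracy = (cm.tp + cm.tn) / cm.total
    p_pos, r_pos, f_pos = _prf(cm.tp, cm.fp, cm.fn)
    p_neg, r_neg, f_neg = _prf(cm.tn, cm.fn, cm.fp)  # negative class as positive
    return EvaluationReport(
        confusion=cm,
        accuracy=accuracy,
        precision=(p_pos + p_neg) / 2,
        recall=(r_pos + r_neg) / 2,
        f1=(f_pos + f_neg) / 2,
        per_class_recall={"positive": r_pos, "negative": r_neg},
    )


def roc_auc(scores, labels):
    """ROC points via a threshold sweep + trapezoidal AUC.

    Equivalent to the pairwise rank statistic: the probability that a
    positive sample outscores a negative one, counting ties as 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == POSITIVE_LABEL
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("ROC requires both classes")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], pos[order]
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    i = 0
    n = scores.size
    while i < n:
        j = i
        while j < n and s[j] == s[i]:  # process score ties as one threshold
            j += 1
        tp += int(y[i:j].sum())
        fp += (j - i) - int(y[i:j].sum())
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
        i = j
    auc = float(np.trapezoid(tpr, fpr))
    points = list(zip(fpr, tpr))
    return points, auc


def cross_validate(features, labels, spec: ClassifierSpec | None = None,
                   folds: int = 10, seed: int = 0) -> EvaluationReport:
    """Stratified k-fold CV with in-fold standardization.

    Every sample is predicted exactly once; the pooled confusion matrix,
    macro metrics, per-fold accuracies and the pooled-score ROC/AUC are
    reported.
    """
    spec = spec or ClassifierSpec()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if folds < 2:
        raise InvalidArgumentError("folds must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise InvalidInputError("every class needs at least `folds` members")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(labels)
    pooled_scores = np.empty(labels.size)
    fold_acc = []
    for train_idx, test_idx in skf.split(features, labels):
        tr_x, te_x = features[train_idx], features[test_idx]
        if spec.standardize:
            tr_x, te_x, _ = standardize(tr_x, te_x)
        if spec.kind == "knn":
            pred, sc = knn_predict(tr_x, labels[train_idx], te_x, spec.n_neighbors)
        else:
            pred, sc = svm_train_predict(tr_x, labels[train_idx], te_x, spec)
        y_pred[test_idx] = pred
        pooled_scores[test_idx] = sc
        fold_acc.append(float((pred == labels[test_idx]).mean()))
    report = confusion_metrics(labels, y_pred)
    report.fold_accuracies = fold_acc
    report.roc_points, report.auc = roc_auc(pooled_scores, labels)
    report.seed = seed
    return report
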