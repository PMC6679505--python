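"""Linear max-margin classification and k-fold evaluation.

The classifier is the liblinear L2-regularized, L2-loss support vector
classifier (dual form, one-vs-rest, penalty C = 1 by default) - the standard
choice for the very high-dimensional, sparse histogram features the cascade
produces.  Evaluation follows the aggregated-confusion-matrix protocol:
stratified k-fold splits, the filter banks and the classifier refit on each
training portion, the k per-fold confusion matrices summed, and per-class
indicators computed from the aggregate:

    Acc = (TP+TN)/(TP+FP+TN+FN),  Sen = TP/(TP+FN),  Ppv = TP/(TP+FP),
    Spe = TN/(TN+FP),             F1  = 2*Ppv*Sen/(Ppv+Sen)

all expressed in percent.  Macro averages are unweighted class means;
overall accuracy is 100 * trace / total.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from sklearn.svm import LinearSVC
import scipy.sparse

from ccanet_ecg.network import NetworkParams, fit as fit_network, transform_many
from ccanet_ecg.preprocess import normalize_beats

METRIC_NAMES = ("acc", "sen", "ppv", "spe", "f1")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the convention of the printed report tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Aggregated counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_labels: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_labels)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{k} class labels")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_predictions(cls, y_true, y_pred, class_labels) -> "ConfusionMatrix":
        index = {lab: i for i, lab in enumerate(class_labels)}
        counts = np.zeros((len(class_labels),) * 2, dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(counts, list(class_labels))

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if list(other.class_labels) != list(self.class_labels):
            raise ValueError("class labels differ")
        return ConfusionMatrix(self.counts + other.counts,
                               list(self.class_labels))


@dataclass
class MetricsReport:
    """Per-class and averaged indicators, in percent (NaN = undefined)."""

    class_labels: list
    per_class: dict = field(default_factory=dict)  # label -> {metric: float}
    averages: dict = field(default_factory=dict)   # metric -> float
    overall_accuracy: float = float("nan")
    total: int = 0

    def rounded(self, ndigits: int = 2) -> dict:
        """Nested plain-dict view rounded half-up, for reports."""
        rd = lambda v: (None if np.isnan(v) else round_half_up(v, ndigits))
        return {
            "per_class": {str(lab): {m: rd(v) for m, v in row.items()}
                          for lab, row in self.per_class.items()},
            "averages": {m: rd(v) for m, v in self.averages.items()},
            "overall_accuracy": rd(self.overall_accuracy),
            "total": self.total,
        }

    def to_text(self, ndigits: int = 2) -> str:
        r = self.rounded(ndigits)
        fmt = lambda v: "undef" if v is None else f"{v:g}"
        lines = ["class\t" + "\t".join(m.capitalize() for m in METRIC_NAMES)]
        for lab in map(str, self.class_labels):
            row = r["per_class"][lab]
            lines.append(lab + "\t" + "\t".join(fmt(row[m]) for m in METRIC_NAMES))
        lines.append("average\t" + "\t".join(
            fmt(r["averages"][m]) for m in METRIC_NAMES))
        lines.append(f"overall_accuracy\t{fmt(r['overall_accuracy'])}")
        lines.append(f"total\t{self.total}")
        return "\n".join(lines)


def confusion_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class Acc/Sen/Ppv/Spe/F1 (percent), macro averages, and OA.

    A metric whose denominator is zero is reported as NaN ("undefined", not
    0) and excluded from its macro average with a warning.
    """
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    report = MetricsReport(class_labels=list(cm.class_labels), total=total)
    per_metric: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    for i, lab in enumerate(cm.class_labels):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        row: dict[str, float] = {}
        row["acc"] = 100.0 * (tp + tn) / total
        row["sen"] = _ratio(tp, tp + fn, "Sen", lab)
        row["ppv"] = _ratio(tp, tp + fp, "Ppv", lab)
        row["spe"] = _ratio(tn, tn + fp, "Spe", lab)
        if np.isnan(row["sen"]) or np.isnan(row["ppv"]) \
                or row["sen"] + row["ppv"] == 0:
            warnings.warn(f"F1 undefined for class {lab!r}")
            row["f1"] = float("nan")
        else:
            row["f1"] = 2.0 * row["ppv"] * row["sen"] / (row["ppv"] + row["sen"])
        report.per_class[lab] = row
        for m in METRIC_NAMES:
            if not np.isnan(row[m]):
                per_metric[m].append(row[m])
    for m, vals in per_metric.items():
        if len(vals) < cm.n_classes:
            warnings.warn(f"{cm.n_classes - len(vals)} undefined {m} value(s) "
                          "excluded from the macro average")
        report.averages[m] = float(np.mean(vals)) if vals else float("nan")
    report.overall_accuracy = 100.0 * np.trace(counts) / total
    return report


def _ratio(num: int, den: int, name: str, label) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined for class {label!r} (0/0)")
        return float("nan")
    return 100.0 * num / den


# ---------------------------------------------------------------------------
# classifier

@dataclass
class LinearModel:
    """One-vs-rest linear max-margin model over feature vectors."""

    clf: LinearSVC
    class_labels: list

    def predict(self, features) -> np.ndarray:
        return self.clf.predict(_as_features(features))

    @property
    def C(self) -> float:
        return self.clf.C


def _as_features(features):
    if scipy.sparse.issparse(features):
        return features.astype(np.float64)
    return scipy.sparse.csr_matrix(np.asarray(features, dtype=np.float64))


def train_linear(features, labels, C: float = 1.0, seed: int = 0
                 ) -> LinearModel:
    """Fit the liblinear L2-regularized L2-loss dual SVC (one-vs-rest)."""
    if C <= 0:
        raise ValueError(f"penalty C must be > 0, got {C}")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    clf = LinearSVC(C=C, loss="squared_hinge", penalty="l2", dual=True,
                    random_state=seed, max_iter=5000)
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(_as_features(features), labels)
    return LinearModel(clf, list(classes))


# ---------------------------------------------------------------------------
# k-fold evaluation

def kfold_evaluate(beats_by_lead, labels, params: NetworkParams, k: int = 5,
                   C: float = 1.0, seed: int = 0) -> ConfusionMatrix:
    """Stratified k-fold evaluation with per-fold refitting.

    ``beats_by_lead`` holds raw beat vectors (n_leads, N, beat_length); each
    fold normalizes nothing anew (normalization is per beat, hence
    leakage-free) but refits the filter banks *and* the classifier on its
    training portion only.  The k fold confusion matrices are summed.
    """
    beats = np.asarray(beats_by_lead, dtype=float)
    if beats.ndim != 3:
        raise ValueError("beats_by_lead must be (n_leads, N, beat_length)")
    labels = np.asarray(labels)
    n = beats.shape[1]
    if labels.shape[0] != n:
        raise ValueError("labels length must match beat count")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of beats ({n})")
    classes, class_counts = np.unique(labels, return_counts=True)
    if np.any(class_counts < k):
        warnings.warn(
            "some classes have fewer members than folds; their folds may be "
            "empty: " + ", ".join(
                f"{c!r}:{int(cnt)}" for c, cnt in zip(classes, class_counts)
                if cnt < k))
    if beats.shape[2] != params.m * params.n:
        raise ValueError(
            f"beat length {beats.shape[2]} does not match matrix "
            f"{params.m}x{params.n}")
    matrices = normalize_beats(beats).reshape(
        beats.shape[0], n, params.m, params.n)

    fold_of = _stratified_folds(labels, classes, k, seed)
    aggregate = ConfusionMatrix(np.zeros((classes.size,) * 2, dtype=np.int64),
                                list(classes))
    for f in range(k):
        test_idx = np.flatnonzero(fold_of == f)
        train_idx = np.flatnonzero(fold_of != f)
        if test_idx.size == 0:
            continue
        model = fit_network(matrices[:, train_idx], params)
        f_train = transform_many(model, matrices[:, train_idx])
        f_test = transform_many(model, matrices[:, test_idx])
        clf = train_linear(f_train, labels[train_idx], C=C, seed=seed)
        pred = clf.predict(f_test)
        aggregate = aggregate + ConfusionMatrix.from_predictions(
            labels[test_idx], pred, list(classes))
    return aggregate


def _stratified_folds(labels, classes, k: int, seed: int) -> np.ndarray:
    """Seeded stratified fold assignment: per class, shuffle then deal
    round-robin into k folds (classes smaller than k simply miss some
    folds; fold offsets are rotated per class to balance fold sizes)."""
    rng = np.random.default_rng(seed)
    fold_of = np.empty(labels.shape[0], dtype=int)
    for j, c in enumerate(classes):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        fold_of[idx] = (np.arange(idx.size) + j) % k
    return fold_of


# ---------------------------------------------------------------------------
# persistence

def save_confusion_csv(cm: ConfusionMatrix, path: str, comment: str = "") -> None:
    with open(path, "w", newline="") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        w = csv.writer(fh)
        w.writerow(["true\\pred"] + [str(c) for c in cm.class_labels])
        for lab, row in zip(cm.class_labels, cm.counts):
            w.writerow([str(lab)] + [int(v) for v in row])


def load_confusion_csv(path: str) -> ConfusionMatrix:
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)
                if r and not r[0].startswith("#")]
    labels = rows[0][1:]
    counts = np.array([[int(v) for v in r[1:]] for r in rows[1:]],
                      dtype=np.int64)
    if [r[0] for r in rows[1:]] != labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    return ConfusionMatrix(counts, labels)
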