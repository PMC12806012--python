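"""Classification metrics, stratified fold plans and metric reports.

ROC AUC is computed as the Mann-Whitney pair-counting statistic (rank
form, 0.5 credit for ties); AUPRC as the step-interpolated area under
precision-recall; MCC from the 2x2 confusion matrix at a threshold chosen
by Youden's J (sensitivity + specificity - 1) on *validation* scores, so
test labels never touch threshold selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

METRIC_NAMES = ("roc_auc", "auprc", "accuracy", "mcc")


def _check_two_class(labels: np.ndarray) -> tuple[int, int]:
    pos = int(labels.sum())
    neg = labels.size - pos
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def roc_auc(scores, labels) -> float:
    """Mann-Whitney ROC AUC with 0.5 tie credit."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    pos, neg = _check_two_class(labels)
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - pos * (pos + 1) / 2) / (pos * neg))


def auprc(scores, labels) -> float:
    """Step-interpolated area under the precision-recall curve.

    Equals the average-precision sum AP = sum_i (R_i - R_{i-1}) P_i over
    descending score thresholds (tied scores grouped).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    pos, _ = _check_two_class(labels)
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # last index of each tied-score group
    boundary = np.nonzero(np.diff(s))[0]
    idx = np.concatenate([boundary, [s.size - 1]])
    precision = tp[idx] / (tp[idx] + fp[idx])
    recall = tp[idx] / pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def confusion_at_threshold(scores, labels, t: float) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) with prediction rule score >= t."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    pred = scores >= t
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fp, fn, tn


def mcc_at_threshold(scores, labels, t: float) -> float:
    """Matthews correlation coefficient at score >= t; 0 if a marginal is zero."""
    tp, fp, fn, tn = confusion_at_threshold(scores, labels, t)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def accuracy_at_threshold(scores, labels, t: float) -> float:
    tp, fp, fn, tn = confusion_at_threshold(scores, labels, t)
    return (tp + tn) / (tp + fp + fn + tn)


def youden_threshold(scores, labels) -> float:
    """Threshold maximising J = sensitivity + specificity - 1.

    Candidates are the midpoints between adjacent sorted unique scores
    (ties toward the smaller threshold). With a single unique score there
    is no separating cut and that score is returned (J = 0).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    _check_two_class(labels)
    uniq = np.unique(scores)
    if uniq.size == 1:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        tp, fp, fn, tn = confusion_at_threshold(scores, labels, t)
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldPlan:
    """Label-stratified partition of pair indices into k folds."""

    k: int
    assignments: np.ndarray  # pair index -> fold id
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignments == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignments != fold)[0]


def stratified_folds(labels, k: int = 10, seed: int = 0) -> FoldPlan:
    """Deterministic stratified k-fold assignment over pair labels."""
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels, dtype=np.int64)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} pairs; need >= k={k} for stratification"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(labels.size, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-fold metrics with mean/std aggregates and an outlier-dropped view.

    ``per_fold[f]`` maps metric name -> value (plus "threshold" and
    "accuracy_at_half"); aggregates are recomputable from per_fold.
    """

    per_fold: dict[int, dict[str, float]]
    primary_metric: str = "roc_auc"
    meta: dict = field(default_factory=dict)

    def fold_values(self, metric: str) -> np.ndarray:
        return np.array([self.per_fold[f][metric] for f in sorted(self.per_fold)])

    def aggregate(self) -> dict[str, tuple[float, float]]:
        return {
            m: (float(self.fold_values(m).mean()), float(self.fold_values(m).std()))
            for m in METRIC_NAMES
        }

    def outlier_fold(self, metric: str | None = None) -> int:
        vals = self.fold_values(metric or self.primary_metric)
        folds = sorted(self.per_fold)
        return folds[int(np.argmax(np.abs(vals - vals.mean())))]

    def aggregate_outlier_removed(self, metric: str | None = None):
        """Aggregates after dropping the fold most deviant on `metric`."""
        drop = self.outlier_fold(metric)
        keep = [f for f in sorted(self.per_fold) if f != drop]
        out = {}
        for m in METRIC_NAMES:
            vals = np.array([self.per_fold[f][m] for f in keep])
            out[m] = (float(vals.mean()), float(vals.std()))
        return drop, out

    def to_dict(self) -> dict:
        drop, removed = self.aggregate_outlier_removed()
        return {
            "per_fold": {str(f): dict(v) for f, v in self.per_fold.items()},
            "aggregate": {m: {"mean": a, "std": s} for m, (a, s) in self.aggregate().items()},
            "aggregate_outlier_removed": {
                m: {"mean": a, "std": s} for m, (a, s) in removed.items()
            },
            "outlier_fold": drop,
            "meta": dict(self.meta),
        }

    def summary(self) -> str:
        lines = []
        title = self.meta.get("variant", "model")
        lines.append(f"Cross-validation report ({title}, k={len(self.per_fold)})")
        header = f"{'fold':>4} " + " ".join(f"{m:>9}" for m in METRIC_NAMES) + f" {'thresh':>8}"
        lines.append(header)
        for f in sorted(self.per_fold):
            row = self.per_fold[f]
            lines.append(
                f"{f:>4} "
                + " ".join(f"{row[m]:>9.4f}" for m in METRIC_NAMES)
                + f" {row['threshold']:>8.4f}"
            )
        agg = self.aggregate()
        lines.append(
            "mean " + " ".join(f"{agg[m][0]:>9.4f}" for m in METRIC_NAMES)
        )
        lines.append(
            " std " + " ".join(f"{agg[m][1]:>9.4f}" for m in METRIC_NAMES)
        )
        drop, removed = self.aggregate_outlier_removed()
        lines.append(
            f"mean(-fold {drop}) "
            + " ".join(f"{removed[m][0]:>8.4f}" for m in METRIC_NAMES)
        )
        return "\n".join(lines)


def fold_metrics(test_scores, test_labels, threshold: float) -> dict[str, float]:
    """Full metric row for one fold at a pre-fitted threshold."""
    return {
        "roc_auc": roc_auc(test_scores, test_labels),
        "auprc": auprc(test_scores, test_labels),
        "accuracy": accuracy_at_threshold(test_scores, test_labels, threshold),
        "accuracy_at_half": accuracy_at_threshold(test_scores, test_labels, 0.5),
        "mcc": mcc_at_threshold(test_scores, test_labels, threshold),
        "threshold": float(threshold),
    }


def paired_fold_ttest(report_a: MetricsReport, report_b: MetricsReport,
                      metric: str = "roc_auc") -> tuple[float, float]:
    """Paired t-test on per-fold metric differences (a - b): (t, p)."""
    a = report_a.fold_values(metric)
    b = report_b.fold_values(metric)
    if a.size != b.size:
        raise ValueError("reports have different fold counts")
    t, p = scipy.stats.ttest_rel(a, b)
    return float(t), float(p)
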