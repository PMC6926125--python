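"""Five-fold cross-validation and the six binary-classification metrics.

From confusion counts TP, FP, TN, FN:

    Acc  = (TN + TP) / (TN + TP + FN + FP)
    Sens = TP / (TP + FN)
    Spec = TN / (TN + FP)
    Prec = TP / (TP + FP)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

AUC is the rank statistic: the fraction of (positive, negative) score
pairs ranked correctly, ties counted one half.  Any metric with a zero
denominator is defined as 0 and flagged as degenerate.

Cross-validation divides the data into k (default five) equal subsets —
stratified by label by default — and each fold serves once as the test
set while the rest train.  Feature selection and the classifier are
re-fitted inside each training fold by default so no test information
leaks into the ranking; a global-selection mode fits the selection once on
the full dataset before splitting.  The final report is the mean of the per-fold
metrics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from .pairmodel import PairRecord, predict, train_predictor
from .selection import rank_features, select_top_k

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CVResult",
    "compute_metrics",
    "auc_score",
    "kfold_split",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @staticmethod
    def from_predictions(y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return ConfusionCounts(
            TP=int(((y_true == 1) & (y_pred == 1)).sum()),
            FP=int(((y_true == 0) & (y_pred == 1)).sum()),
            TN=int(((y_true == 0) & (y_pred == 0)).sum()),
            FN=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass
class MetricsReport:
    """The six evaluation statistics plus the counts they derive from.

    ``degenerate`` lists the metrics whose denominator was zero (reported
    as 0 by convention).  ``auc`` is None when no scores were supplied.
    """

    acc: float
    sens: float
    spec: float
    prec: float
    mcc: float
    auc: Optional[float]
    counts: ConfusionCounts
    degenerate: tuple = ()

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "sens": self.sens,
            "spec": self.spec,
            "prec": self.prec,
            "mcc": self.mcc,
            "auc": self.auc,
            "counts": {"TP": self.counts.TP, "FP": self.counts.FP, "TN": self.counts.TN, "FN": self.counts.FN},
            "degenerate": list(self.degenerate),
        }


def _ratio(num: int, den: int, name: str, flags: list) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(
    counts: ConfusionCounts,
    scores: Optional[Sequence[Tuple[float, int]]] = None,
) -> MetricsReport:
    """Acc/Sens/Spec/Prec/MCC from confusion counts; AUC from (score, truth)
    pairs when provided."""
    if counts.total == 0:
        raise ValueError("all confusion counts are zero; metrics undefined")
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    flags: list = []
    acc = (tn + tp) / counts.total
    sens = _ratio(tp, tp + fn, "sens", flags)
    spec = _ratio(tn, tn + fp, "spec", flags)
    prec = _ratio(tp, tp + fp, "prec", flags)
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom_sq)
    auc = None
    if scores is not None:
        auc = auc_score(scores)
    return MetricsReport(acc, sens, spec, prec, mcc, auc, counts, tuple(flags))


def auc_score(scores: Sequence[Tuple[float, int]]) -> float:
    """Area under the ROC curve as the Mann-Whitney rank statistic.

    Equals the fraction of (positive, negative) pairs whose positive member
    scores higher, ties counted one half.  Requires both classes present.
    """
    s = np.array([p for p, _ in scores], dtype=np.float64)
    y = np.array([t for _, t in scores], dtype=np.int64)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def kfold_split(
    n: int,
    k: int = 5,
    seed: int = 0,
    stratify_labels: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Assign each of n records to one of k folds; sizes differ by <= 1.

    With ``stratify_labels`` the per-fold class counts differ from perfect
    balance by at most one record.  Deterministic given the seed.
    """
    if n < k:
        raise ValueError(f"cannot split {n} records into {k} folds")
    assignments = np.empty(n, dtype=np.int64)
    if stratify_labels is not None:
        classes, counts = np.unique(np.asarray(stratify_labels), return_counts=True)
        for c, cnt in zip(classes, counts):
            if cnt < k:
                raise ValueError(
                    f"cannot stratify {k} folds: class {c} has only {cnt} record(s), "
                    f"so some fold would lack it"
                )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n), np.asarray(stratify_labels))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n))
    for fold, (_, test_idx) in enumerate(split_iter):
        assignments[test_idx] = fold
    return assignments


@dataclass
class CVResult:
    """Per-fold metric reports, their mean, and the fold assignment used."""

    per_fold: List[MetricsReport]
    mean: MetricsReport
    fold_assignments: np.ndarray

    def to_dict(self) -> dict:
        return {
            "folds": len(self.per_fold),
            "per_fold": [m.to_dict() for m in self.per_fold],
            "mean": self.mean.to_dict(),
            "fold_assignments": [int(f) for f in self.fold_assignments],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", newline="\n") as fh:
                fh.write(text + "\n")
        return text


def _mean_report(per_fold: List[MetricsReport]) -> MetricsReport:
    counts = ConfusionCounts(
        TP=sum(m.counts.TP for m in per_fold),
        FP=sum(m.counts.FP for m in per_fold),
        TN=sum(m.counts.TN for m in per_fold),
        FN=sum(m.counts.FN for m in per_fold),
    )
    aucs = [m.auc for m in per_fold if m.auc is not None]
    return MetricsReport(
        acc=float(np.mean([m.acc for m in per_fold])),
        sens=float(np.mean([m.sens for m in per_fold])),
        spec=float(np.mean([m.spec for m in per_fold])),
        prec=float(np.mean([m.prec for m in per_fold])),
        mcc=float(np.mean([m.mcc for m in per_fold])),
        auc=float(np.mean(aucs)) if aucs else None,
        counts=counts,
        degenerate=tuple(sorted({f for m in per_fold for f in m.degenerate})),
    )


def cross_validate(
    records: Sequence[PairRecord],
    folds: int = 5,
    top_k: int = 50,
    n_trees: int = 500,
    selection_trees: int = 500,
    seed: int = 0,
    stratified: bool = True,
    refit_selection_per_fold: bool = True,
    weighted_importance: bool = True,
) -> CVResult:
    """k-fold cross-validation of selection + random-forest classification.

    Each training fold re-fits the feature ranking and the classifier from
    scratch (``refit_selection_per_fold=False`` ranks once on the full
    dataset instead).  Train and test partitions are disjoint by
    construction; a fold missing one of the classes is an error naming the
    fold.
    """
    records = list(records)
    labels = np.array([r.label for r in records])
    if any(l is None for l in labels):
        raise ValueError("cross-validation requires labelled records")
    labels = labels.astype(int)
    assignments = kfold_split(
        len(records), folds, seed, stratify_labels=labels if stratified else None
    )
    X = np.vstack([r.features for r in records])

    global_mask = None
    if not refit_selection_per_fold:
        report, _ = rank_features(
            X, labels, n_trees=selection_trees, seed=seed, weighted=weighted_importance
        )
        global_mask = select_top_k(report, top_k)

    per_fold = []
    for fold in range(folds):
        test_idx = np.where(assignments == fold)[0]
        train_idx = np.where(assignments != fold)[0]
        assert not set(test_idx) & set(train_idx)
        for part, idx in (("training", train_idx), ("test", test_idx)):
            present = set(labels[idx].tolist())
            if present != {0, 1}:
                raise ValueError(
                    f"fold {fold}: {part} split lacks a class (labels present: {sorted(present)})"
                )
        if global_mask is None:
            report, _ = rank_features(
                X[train_idx],
                labels[train_idx],
                n_trees=selection_trees,
                seed=seed + fold,
                weighted=weighted_importance,
            )
            mask = select_top_k(report, top_k)
        else:
            mask = global_mask
        predictor = train_predictor(
            [records[i] for i in train_idx], mask, n_trees=n_trees, seed=seed + fold
        )
        outcome = predict(predictor, [records[i] for i in test_idx])
        y_true = labels[test_idx]
        y_pred = [lab for _, lab in outcome]
        scores = [(p, int(t)) for (p, _), t in zip(outcome, y_true)]
        per_fold.append(
            compute_metrics(ConfusionCounts.from_predictions(y_true, y_pred), scores)
        )
    return CVResult(per_fold=per_fold, mean=_mean_report(per_fold), fold_assignments=assignments)
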