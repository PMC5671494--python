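"""Model evaluation: confusion metrics, ROC/AUC, threshold sweeps, k-fold CV.

Conventions:

* ACC, SEN (sensitivity), SPC (specificity) are reported as percents from
  the usual confusion-count ratios; MCC is the Matthews correlation
  coefficient with the convention MCC = 0 when any denominator factor is 0.
* AUC is the Mann-Whitney probability that a uniformly chosen positive
  outscores a uniformly chosen negative, ties counted one half. It equals
  the trapezoidal area under the ROC curve.
* Cross-validation uses stratified folds (per-class round-robin after a
  seeded shuffle); held-out scores from all folds are pooled and metrics
  computed once on the pool. Any learned feature weighting (AAP) is
  retrained within each fold on the training folds only, so no information
  from the held-out fold leaks into the features.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .dataio import EpitopeDataset, Peptide
from .models import (
    RFConfig,
    SVMConfig,
    TrainedModel,
    decision_scores,
    train_rf,
    train_svm,
)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    threshold: float
    ACC: float  # percent
    SEN: float | None  # percent; None when no positives evaluated
    SPC: float | None  # percent; None when no negatives evaluated
    MCC: float
    AUC: float | None = None


@dataclass
class CVReport:
    k: int
    seed: int
    fold_scores: list[np.ndarray]
    fold_labels: list[np.ndarray]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    auc: float
    best_threshold: float
    pooled_metrics: MetricsReport
    sweep: list[MetricsReport] = field(default_factory=list)


def confusion(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> ConfusionCounts:
    """Count TP/FP/TN/FN with the inclusive rule: predicted positive iff
    score >= threshold."""
    if len(scores) != len(labels):
        raise ValueError("scores and labels must be aligned")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = s >= threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        FP=int(np.sum(pred & (y == 0))),
        TN=int(np.sum(~pred & (y == 0))),
        FN=int(np.sum(~pred & (y == 1))),
    )


def metrics(counts: ConfusionCounts, threshold: float = float("nan")) -> MetricsReport:
    """ACC/SEN/SPC as percents, MCC in [-1, 1] (0 on zero denominator)."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    total = counts.total
    if total == 0:
        raise ValueError("no evaluated peptides")
    acc = (tp + tn) / total * 100.0
    sen = tp / (tp + fn) * 100.0 if (tp + fn) > 0 else None
    spc = tn / (tn + fp) * 100.0 if (tn + fp) > 0 else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ((tp * tn) - (fp * fn)) / np.sqrt(denom) if denom > 0 else 0.0
    return MetricsReport(threshold=threshold, ACC=acc, SEN=sen, SPC=spc, MCC=float(mcc))


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, np.ndarray]:
    """AUC (Mann-Whitney, ties half) plus ROC points (FPR, TPR).

    The AUC is computed from midranks: with n+ positives of rank-sum R+,
    AUC = (R+ - n+(n+ + 1)/2) / (n+ n-), identical to pairwise counting
    with ties scored one half and to the trapezoidal ROC area.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires at least one peptide of each class")
    ranks = rankdata(s)  # midranks
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y, s)
    return float(auc), np.column_stack([fpr, tpr])


def threshold_sweep(
    scores: Sequence[float],
    labels: Sequence[int],
    grid: Sequence[float] | str = "auto",
) -> tuple[list[MetricsReport], float]:
    """Metrics at each threshold; returns the sweep and the MCC-argmax
    threshold, ties broken toward higher specificity (then the higher
    threshold)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("threshold_sweep requires both classes present")
    if isinstance(grid, str):
        if grid != "auto":
            raise ValueError(f"unknown grid spec {grid!r}")
        distinct = np.unique(s)
        mids = (distinct[:-1] + distinct[1:]) / 2
        lo = distinct[0] - 1.0
        hi = distinct[-1] + 1.0
        thresholds = np.concatenate([[lo], distinct, mids, [hi]])
        thresholds = np.unique(thresholds)
    else:
        thresholds = np.asarray(list(grid), dtype=float)
        if thresholds.size == 0:
            raise ValueError("empty threshold grid")
    sweep = [metrics(confusion(s, y, t), threshold=float(t)) for t in thresholds]
    best = max(sweep, key=lambda m: (m.MCC, m.SPC if m.SPC is not None else -1, m.threshold))
    return sweep, best.threshold


def stratified_kfold(
    dataset: EpitopeDataset, k: int, seed: int
) -> list[tuple[list[int], list[int]]]:
    """Index folds over ``dataset.all_peptides()`` order: per-class
    round-robin assignment after a seeded shuffle. Returns (train_idx,
    test_idx) per fold; per-class fold sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    n_pos = dataset.n_pos
    n_all = n_pos + dataset.n_neg
    if n_pos < k or dataset.n_neg < k:
        raise ValueError(f"each class needs at least k={k} members")
    rng = random.Random(seed)
    pos_idx = list(range(n_pos))
    neg_idx = list(range(n_pos, n_all))
    rng.shuffle(pos_idx)
    rng.shuffle(neg_idx)
    fold_of = {}
    for j, i in enumerate(pos_idx):
        fold_of[i] = j % k
    for j, i in enumerate(neg_idx):
        fold_of[i] = j % k
    folds = []
    for f in range(k):
        test = sorted(i for i in range(n_all) if fold_of[i] == f)
        train = sorted(i for i in range(n_all) if fold_of[i] != f)
        folds.append((train, test))
    return folds


def _trainer(
    family: str, feature_kind: str, config: SVMConfig | RFConfig | None
) -> Callable[[EpitopeDataset], TrainedModel]:
    if family == "SVM":
        return lambda ds: train_svm(ds, feature_kind, config)
    if family == "RF":
        return lambda ds: train_rf(ds, feature_kind, config)
    raise ValueError(f"unknown model family {family!r}")


def kfold_cv(
    dataset: EpitopeDataset,
    feature_kind: str = "DPC",
    family: str = "SVM",
    config: SVMConfig | RFConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation with pooled held-out scoring.

    Each fold trains the full pipeline (AAP weights included, when used) on
    the k-1 training folds only and scores the held-out fold; held-out
    scores are pooled across folds, and AUC, a threshold sweep, and the
    operating-point metrics are computed once on the pool.
    """
    peptides = dataset.all_peptides()
    labels = np.array(dataset.labels())
    folds = stratified_kfold(dataset, k, seed)
    fit = _trainer(family, feature_kind, config)

    fold_scores: list[np.ndarray] = []
    fold_labels: list[np.ndarray] = []
    pooled_scores = np.empty(len(peptides))
    for train_idx, test_idx in folds:
        tr_pos = [peptides[i] for i in train_idx if labels[i] == 1]
        tr_neg = [peptides[i] for i in train_idx if labels[i] == 0]
        model = fit(EpitopeDataset(tr_pos, tr_neg))
        held_out = [peptides[i] for i in test_idx]
        scores = decision_scores(model, held_out)
        pooled_scores[test_idx] = scores
        fold_scores.append(scores)
        fold_labels.append(labels[test_idx])

    auc, _ = roc_auc(pooled_scores, labels)
    sweep, best_thr = threshold_sweep(pooled_scores, labels)
    report = metrics(confusion(pooled_scores, labels, best_thr), threshold=best_thr)
    report.AUC = auc
    return CVReport(
        k=k,
        seed=seed,
        fold_scores=fold_scores,
        fold_labels=fold_labels,
        pooled_scores=pooled_scores,
        pooled_labels=labels,
        auc=auc,
        best_threshold=best_thr,
        pooled_metrics=report,
        sweep=sweep,
    )


def write_cv_report(report: CVReport, path: str | Path) -> None:
    """CV report as TSV: per-threshold metric rows plus a summary block."""
    def fmt(v):
        return "NA" if v is None else f"{v:.4g}"

    with open(path, "w", newline="") as fh:
        fh.write(f"# k\t{report.k}\n# seed\t{report.seed}\n")
        fh.write(f"# AUC\t{report.auc:.4f}\n")
        fh.write(f"# best_threshold\t{report.best_threshold:.6g}\n")
        m = report.pooled_metrics
        fh.write(
            f"# pooled@best\tACC={fmt(m.ACC)}\tSEN={fmt(m.SEN)}\t"
            f"SPC={fmt(m.SPC)}\tMCC={fmt(m.MCC)}\n"
        )
        fh.write("threshold\tACC\tSEN\tSPC\tMCC\n")
        for row in report.sweep:
            fh.write(
                f"{row.threshold:.6g}\t{fmt(row.ACC)}\t{fmt(row.SEN)}\t"
                f"{fmt(row.SPC)}\t{fmt(row.MCC)}\n"
            )


def write_roc_points(points: np.ndarray, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("FPR\tTPR\n")
        for fpr, tpr in points:
            fh.write(f"{fpr:.6g}\t{tpr:.6g}\n")
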