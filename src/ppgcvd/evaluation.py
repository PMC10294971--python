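"""Confusion-matrix metrics and the reduction x classifier evaluation grid.

CVD is the positive class throughout.  The metric suite:

    PI   = (TP + TN - FN - FP) / (TP + TN) * 100
    Sens = TP / (TP + FN) * 100
    Spec = TN / (TN + FP) * 100
    Acc  = (TP + TN) / (TP + TN + FP + FN) * 100
    GDR  = (TP + TN - FP) / (TP + TN + FN) * 100
    Err  = (FP + FN) / (TP + TN + FP + FN) * 100

Accuracy and error rate are computed with exact rational arithmetic before
the percent conversion, so ``accuracy + error_rate == 100`` holds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold, StratifiedKFold

from . import classifiers as clf
from . import dimred
from .signal_io import SegmentMatrix
from .synth import CVD, NORMAL

__all__ = [
    "ConfusionCounts", "MetricsReport", "FoldPlan",
    "confusion", "metrics", "run_grid", "GridResult",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricsReport:
    """The six derived metrics, in percent; NaN marks an undefined metric."""

    pi: float
    sensitivity: float
    specificity: float
    accuracy: float
    gdr: float
    error_rate: float

    def as_dict(self) -> dict:
        return {
            "pi": self.pi, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "accuracy": self.accuracy,
            "gdr": self.gdr, "error_rate": self.error_rate,
        }


@dataclass(frozen=True)
class FoldPlan:
    n_folds: int = 10
    train_fraction: float = 0.9
    stratified: bool = True
    #: split at the subject level instead of the segment level
    subject_level: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if abs(self.train_fraction - (1.0 - 1.0 / self.n_folds)) > 1e-9:
            warnings.warn(
                "train_fraction is not 1 - 1/n_folds; k-fold splitting uses "
                "1/n_folds test shares"
            )


def confusion(true_labels, pred_labels) -> ConfusionCounts:
    """Counts with CVD as the positive class."""
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    bad = (set(np.unique(t)) | set(np.unique(p))) - {CVD, NORMAL}
    if bad:
        raise ValueError(f"non-binary labels: {sorted(bad)}")
    return ConfusionCounts(
        tp=int(np.sum((t == CVD) & (p == CVD))),
        tn=int(np.sum((t == NORMAL) & (p == NORMAL))),
        fp=int(np.sum((t == NORMAL) & (p == CVD))),
        fn=int(np.sum((t == CVD) & (p == NORMAL))),
    )


def _pct(num: int, den: int) -> float:
    if den == 0:
        warnings.warn("zero denominator: metric undefined")
        return float("nan")
    return float(Fraction(num, den) * 100)


def metrics(c: ConfusionCounts) -> MetricsReport:
    """The six confusion-matrix metrics (percent)."""
    acc_frac = (
        Fraction(c.tp + c.tn, c.total) if c.total else None
    )
    return MetricsReport(
        pi=_pct(c.tp + c.tn - c.fn - c.fp, c.tp + c.tn),
        sensitivity=_pct(c.tp, c.tp + c.fn),
        specificity=_pct(c.tn, c.tn + c.fp),
        accuracy=float(acc_frac * 100) if acc_frac is not None else float("nan"),
        gdr=_pct(c.tp + c.tn - c.fp, c.tp + c.tn + c.fn),
        error_rate=float((1 - acc_frac) * 100) if acc_frac is not None else float("nan"),
    )


@dataclass
class GridResult:
    """Per-fold records plus fold-averaged summaries of one grid run."""

    fold_records: pd.DataFrame
    summary: pd.DataFrame
    mse_by_class: pd.DataFrame
    skipped_folds: list = field(default_factory=list)


def _fold_indices(y, groups, plan: FoldPlan):
    if plan.subject_level:
        splitter = GroupKFold(n_splits=plan.n_folds)
        yield from splitter.split(np.zeros_like(y), y, groups)
    else:
        splitter = StratifiedKFold(
            n_splits=plan.n_folds, shuffle=True, random_state=plan.seed
        )
        yield from splitter.split(np.zeros_like(y), y)


def run_grid(
    seg_matrices: list[SegmentMatrix],
    methods,
    classifier_kinds,
    fold_plan: FoldPlan = FoldPlan(),
    swarm_params: dimred.SwarmParams | None = None,
    classifier_params: dict | None = None,
    coding: clf.TargetCoding = clf.TargetCoding(),
    stop: clf.StopRule = clf.StopRule(),
    n_kernels: int = 4,
    seed: int = 0,
) -> GridResult:
    """Evaluate every (reduction method, classifier) cell under k-fold CV.

    Reduction happens once per method over the whole cohort (matching the
    study's pipeline order); folds then partition the segments, stratified by
    class (or by subject when ``fold_plan.subject_level``).  Per fold the
    classifier is fit on the training share and evaluated on the rest;
    per-class test MSE against the coded targets is recorded alongside the
    confusion-matrix metrics.
    """
    if not methods or not classifier_kinds:
        raise ValueError("methods and classifier_kinds must be nonempty")
    records = []
    mse_rows = []
    skipped = []
    for method in methods:
        feats = dimred.reduce_cohort(
            seg_matrices, method, params=swarm_params, n_kernels=n_kernels, seed=seed
        )
        X = np.vstack([f.features for f in feats])
        y = np.concatenate([[f.label] * f.features.shape[0] for f in feats])
        groups = np.concatenate(
            [[f.subject_id] * f.features.shape[0] for f in feats]
        )
        for kind in classifier_kinds:
            kp = (classifier_params or {}).get(kind)
            fold_mse = {CVD: [], NORMAL: []}
            for fold_i, (tr, te) in enumerate(_fold_indices(y, groups, fold_plan)):
                if len(set(y[tr])) < 2 or len(set(y[te])) < 2:
                    warnings.warn(
                        f"fold {fold_i} for ({method}, {kind}) has a single "
                        "class; skipped"
                    )
                    skipped.append((method, kind, fold_i))
                    continue
                res = clf.fit_predict(
                    kind, X[tr], y[tr], X[te], params=kp,
                    coding=coding, stop=stop, seed=seed + fold_i,
                )
                c = confusion(y[te], res.labels)
                m = metrics(c)
                coded_te = clf.code_targets(y[te], coding)
                for cls in (CVD, NORMAL):
                    sel = y[te] == cls
                    fold_mse[cls].append(
                        clf.training_mse(res.scores[sel], coded_te[sel])
                    )
                records.append(
                    {
                        "method": method, "classifier": kind, "fold": fold_i,
                        "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
                        "n_test": c.total, **m.as_dict(),
                    }
                )
            mse_rows.append(
                {
                    "method": method, "classifier": kind,
                    "mse_cvd": float(np.mean(fold_mse[CVD])) if fold_mse[CVD] else float("nan"),
                    "mse_normal": float(np.mean(fold_mse[NORMAL])) if fold_mse[NORMAL] else float("nan"),
                }
            )
    fold_df = pd.DataFrame(records)
    metric_cols = ["pi", "sensitivity", "specificity", "accuracy", "gdr", "error_rate"]
    summary = (
        fold_df.groupby(["method", "classifier"], sort=False)[metric_cols]
        .mean()
        .reset_index()
    )
    return GridResult(fold_df, summary, pd.DataFrame(mse_rows), skipped)
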