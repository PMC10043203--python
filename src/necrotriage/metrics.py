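"""Evaluation: confusion counts, ACC/SN/SP, ROC/AUC, and k-fold CV.

Orientation matters in this problem and is therefore carried
explicitly: the *positive* class is the majority (hernia without
necrosis) and the *negative* class is the minority (necrosis), matching
the source cohort's labelling.  Sensitivity is the correct-prediction
rate on positives, specificity on negatives:

    ACC = (TP + TN) / (TP + FP + TN + FN)
    SN  = TP / (TP + FN)
    SP  = TN / (TN + FP)

AUC is computed from the minority-class score by the rank
(Mann-Whitney) formulation with half credit for ties; it measures how
well ascending scores separate the minority class and is identical to
the concordant-pair fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .table import ClassLabel, ClinicalTable

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "metrics",
    "roc_auc",
    "roc_points",
    "cross_validate",
]

ORIENTATION_NOTE = (
    "positive = majority (hernia, no necrosis); negative = minority (necrosis); "
    "scores are minority-class probabilities"
)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with positive = majority (hernia) by default."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricsReport:
    """ACC/SN/SP (and optionally AUC) with undefined ratios flagged."""

    acc: float
    sn: float | None
    sp: float | None
    auc: float | None = None
    counts: ConfusionCounts | None = None
    undefined: tuple[str, ...] = ()
    per_fold: tuple["MetricsReport", ...] = ()
    orientation: str = ORIENTATION_NOTE

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "sn": self.sn,
            "sp": self.sp,
            "auc": self.auc,
            "undefined": list(self.undefined),
            "orientation": self.orientation,
            "per_fold": [f.to_dict() for f in self.per_fold],
        }


def confusion_counts(
    truth: Sequence[ClassLabel | str],
    predicted: Sequence[ClassLabel | str],
    positive: ClassLabel = ClassLabel.MAJORITY_HERNIA,
) -> ConfusionCounts:
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted lengths differ")
    if len(truth) == 0:
        raise ValueError("empty label lists")
    t = np.array([ClassLabel.coerce(v) == positive for v in truth])
    p = np.array([ClassLabel.coerce(v) == positive for v in predicted])
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    if counts.total == 0:
        raise ValueError("no evaluated samples")
    acc = (counts.tp + counts.tn) / counts.total
    undefined = []
    if counts.n_positive:
        sn = counts.tp / counts.n_positive
    else:
        sn, undefined = None, undefined + ["sn"]
    if counts.n_negative:
        sp = counts.tn / counts.n_negative
    else:
        sp, undefined = None, undefined + ["sp"]
    return MetricsReport(acc=acc, sn=sn, sp=sp, counts=counts, undefined=tuple(undefined))


def roc_auc(
    truth: Sequence[ClassLabel | str],
    scores: Sequence[float],
) -> float:
    """Mann-Whitney AUC of the minority class by ascending score.

    Equals the fraction of (minority, majority) pairs where the minority
    sample scores higher, with tied pairs counted half.
    """
    truth_arr = np.array([ClassLabel.coerce(v) for v in truth], dtype=object)
    scores_arr = np.asarray(scores, dtype=float)
    if truth_arr.size != scores_arr.size:
        raise ValueError("truth and scores lengths differ")
    is_min = truth_arr == ClassLabel.MINORITY_NECROSIS.value
    n1 = int(is_min.sum())
    n0 = int((~is_min).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores_arr)  # average ranks give half credit to ties
    u = ranks[is_min].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_points(
    truth: Sequence[ClassLabel | str], scores: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC curve points (fpr, tpr, thresholds) for the minority class."""
    y = np.array(
        [1 if ClassLabel.coerce(v) == ClassLabel.MINORITY_NECROSIS else 0 for v in truth]
    )
    return _sk_roc_curve(y, np.asarray(scores, dtype=float), pos_label=1)


def _summarize_folds(folds: Sequence[MetricsReport]) -> MetricsReport:
    def _mean(attr):
        vals = [getattr(f, attr) for f in folds]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    undefined = tuple(sorted({u for f in folds for u in f.undefined}))
    return MetricsReport(
        acc=_mean("acc"),
        sn=_mean("sn"),
        sp=_mean("sp"),
        auc=_mean("auc"),
        undefined=undefined,
        per_fold=tuple(folds),
    )


def evaluate_predictions(
    truth: Sequence[ClassLabel | str],
    predicted: Sequence[ClassLabel | str],
    scores: Sequence[float] | None = None,
) -> MetricsReport:
    """Convenience: confusion + ratios (+ AUC when scores given)."""
    rep = metrics(confusion_counts(truth, predicted))
    if scores is not None:
        truth_arr = [ClassLabel.coerce(v) for v in truth]
        classes = set(truth_arr)
        auc = roc_auc(truth_arr, scores) if len(classes) == 2 else None
        rep = MetricsReport(
            acc=rep.acc,
            sn=rep.sn,
            sp=rep.sp,
            auc=auc,
            counts=rep.counts,
            undefined=rep.undefined if auc is not None else rep.undefined + ("auc",),
        )
    return rep


def cross_validate(
    table: ClinicalTable,
    folds: int = 5,
    seed: int = 0,
    **pipeline_kwargs,
) -> MetricsReport:
    """Stratified k-fold CV of the full sub-balanced pipeline.

    Each fold re-runs imputation fitting, majority partitioning and
    ensemble training on that fold's training rows only, then scores the
    held-out rows.  ``folds=1`` degenerates to a single stratified
    hold-out evaluation.  Remaining keyword arguments are forwarded to
    :func:`necrotriage.pipeline.fit_and_evaluate`.
    """
    from .pipeline import fit_and_evaluate  # local import: avoid cycle

    if folds < 1:
        raise ValueError("folds must be >= 1")
    counts = table.class_counts()
    if folds > 1 and min(counts.values()) < folds:
        raise ValueError("each class needs at least `folds` samples")
    if folds == 1:
        rep, _ = fit_and_evaluate(table, seed=seed, **pipeline_kwargs)
        return MetricsReport(
            acc=rep.acc, sn=rep.sn, sp=rep.sp, auc=rep.auc,
            undefined=rep.undefined, per_fold=(rep,),
        )

    from sklearn.model_selection import StratifiedKFold

    y = np.array([l.value for l in table.labels])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    fold_reports = []
    for fold_i, (tr, te) in enumerate(skf.split(np.zeros(table.n_samples), y)):
        rep, _ = fit_and_evaluate(
            table,
            seed=seed + 1000003 * (fold_i + 1),
            train_indices=tr,
            test_indices=te,
            **pipeline_kwargs,
        )
        fold_reports.append(rep)
    return _summarize_folds(fold_reports)
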