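"""Evaluation toolkit: overlap and confusion-matrix metrics, subject-wise
nested cross-validation, fold aggregation, prevalence summaries and the
five-criteria activity score.

Metric definitions (positive class = 1):
  Dice        = 2 TP / (2 TP + FP + FN)       (pixel overlap; = F1 on pixels)
  accuracy    = (TP + TN) / (TP + FP + FN + TN)
  F1          = 2 TP / (2 TP + FP + FN)
  specificity = TN / (TN + FP)
  sensitivity = TP / (TP + FN)

A lesion is scored *active* when at least three of the five activity
criteria (shape, branching, anastomoses/loops, peripheral arcade, dark
halo) are present.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import nn
from .exceptions import ValidationError
from .imgio import FEATURES, ActivityLabels

ACTIVITY_THRESHOLD = 3  # "at least three of five" rule


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float
    f1: float
    specificity: float
    sensitivity: float


@dataclass
class FoldAssignment:
    outer_folds: list[list[str]]
    inner_folds: list[list[list[str]]]  # per outer fold: inner splits of its training subjects
    seed: int


@dataclass
class MetricsReport:
    per_feature: dict[str, ClassificationMetrics] = field(default_factory=dict)
    per_fold_dice: list[list[float]] = field(default_factory=list)

    @property
    def fold_dice_medians(self) -> list[float]:
        return [float(np.median(f)) for f in self.per_fold_dice if f]

    @property
    def overall_dice_median(self) -> float:
        values = [v for fold in self.per_fold_dice for v in fold]
        return float(np.median(values)) if values else float("nan")

    @property
    def overall_dice_mean(self) -> float:
        values = [v for fold in self.per_fold_dice for v in fold]
        return float(np.mean(values)) if values else float("nan")

    def to_dict(self) -> dict:
        return {
            "per_feature": {k: vars(v) for k, v in self.per_feature.items()},
            "per_fold_dice": self.per_fold_dice,
            "fold_dice_medians": self.fold_dice_medians,
            "overall_dice_median": self.overall_dice_median,
            "overall_dice_mean": self.overall_dice_mean,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def dice_to_csv(self, path: str) -> None:
        rows = [{"fold": i, "dice": d} for i, fold in enumerate(self.per_fold_dice) for d in fold]
        pd.DataFrame(rows, columns=["fold", "dice"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# metrics


def dice_coefficient(pred: np.ndarray, gt: np.ndarray, eps: float = nn.DICE_EPS) -> float:
    """Dice overlap of two binary masks; 1.0 when both are empty.

    Uses the same epsilon smoothing as the Dice loss, so
    dice_coefficient = 1 - dice_loss holds identically on binary inputs.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValidationError(f"shape mismatch {pred.shape} vs {gt.shape}")
    p = pred > 0
    g = gt > 0
    tp = float(np.count_nonzero(p & g))
    return (2.0 * tp + eps) / (float(np.count_nonzero(p)) + float(np.count_nonzero(g)) + eps)


def confusion_counts(preds, labels) -> ConfusionCounts:
    preds = np.asarray(preds).ravel()
    labels = np.asarray(labels).ravel()
    if preds.shape != labels.shape:
        raise ValidationError("predictions and labels differ in length")
    p = preds.astype(int)
    y = labels.astype(int)
    return ConfusionCounts(
        tp=int(np.count_nonzero((p == 1) & (y == 1))),
        fp=int(np.count_nonzero((p == 1) & (y == 0))),
        tn=int(np.count_nonzero((p == 0) & (y == 0))),
        fn=int(np.count_nonzero((p == 0) & (y == 1))),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def classification_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    return ClassificationMetrics(
        accuracy=_safe_ratio(c.tp + c.tn, c.total, "accuracy"),
        f1=_safe_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "F1"),
        specificity=_safe_ratio(c.tn, c.tn + c.fp, "specificity"),
        sensitivity=_safe_ratio(c.tp, c.tp + c.fn, "sensitivity"),
    )


# ---------------------------------------------------------------------------
# subject-wise nested cross-validation


def nested_cv_split(subject_ids: list[str], k: int = 5, inner_k: int = 3,
                    seed: int = 0) -> FoldAssignment:
    """Shuffle subjects, partition into k near-equal outer folds, and split
    each outer training set into inner_k validation folds.

    Every image of a subject follows its subject, so no subject can sit on
    both sides of any split.
    """
    subjects = list(dict.fromkeys(subject_ids))  # dedupe, preserve order
    if len(subjects) < k:
        raise ValidationError(f"need at least k={k} distinct subjects, got {len(subjects)}")
    if inner_k < 2:
        raise ValidationError("inner_k must be >= 2")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    shuffled = [subjects[i] for i in rng.permutation(len(subjects))]
    outer = [list(part) for part in np.array_split(np.array(shuffled, dtype=object), k)]
    inner: list[list[list[str]]] = []
    for fold in outer:
        train = [s for s in shuffled if s not in set(fold)]
        n_inner = min(inner_k, len(train))
        inner.append([list(part) for part in np.array_split(np.array(train, dtype=object), n_inner)])
    return FoldAssignment(outer_folds=[[str(s) for s in f] for f in outer],
                          inner_folds=[[[str(s) for s in f] for f in folds] for folds in inner],
                          seed=int(seed))


# ---------------------------------------------------------------------------
# activity score & prevalence


def activity_score(labels: ActivityLabels) -> tuple[str, int]:
    """'active' iff at least three of the five criteria are present."""
    count = int(sum(labels.as_tuple()))
    return ("active" if count >= ACTIVITY_THRESHOLD else "inactive", count)


def prevalence_summary(label_table: list[ActivityLabels] | pd.DataFrame) -> dict[str, dict]:
    """Per-feature presence counts and percentages (half-up, two decimals)."""
    if isinstance(label_table, pd.DataFrame):
        if label_table.empty:
            raise ValidationError("label table is empty")
        df = label_table[list(FEATURES)]
    else:
        if not label_table:
            raise ValidationError("label table is empty")
        df = pd.DataFrame([lab.as_dict() for lab in label_table])
    total = len(df)
    summary = {}
    for feature in FEATURES:
        count = int(df[feature].sum())
        pct = float((Decimal(100 * count) / Decimal(total)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
        summary[feature] = {"count": count, "total": total, "percentage": pct}
    return summary


def aggregate_folds(per_fold: list[ConfusionCounts]) -> tuple[ClassificationMetrics, list[ClassificationMetrics]]:
    """Unweighted mean of per-fold metrics, retaining the per-fold values."""
    if not per_fold:
        raise ValidationError("no folds to aggregate")
    fold_metrics = [classification_metrics(c) for c in per_fold]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = ClassificationMetrics(
            accuracy=float(np.nanmean([m.accuracy for m in fold_metrics])),
            f1=float(np.nanmean([m.f1 for m in fold_metrics])),
            specificity=float(np.nanmean([m.specificity for m in fold_metrics])),
            sensitivity=float(np.nanmean([m.sensitivity for m in fold_metrics])),
        )
    return mean, fold_metrics
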