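"""Confusion-matrix scores, ROC-AUC, cross-validation and calibration checks.

Pathogenic (PLP) is the positive class throughout. Undefined ratios (zero
denominators) are reported as ``None`` rather than silently zeroed. Metrics
are stored as fractions; report rendering multiplies by 100 with one decimal.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from savpath.predictor import Prediction, PipelineConfig, train
from savpath.variant_data import Label


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    counts: ConfusionCounts
    q2: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    mcc: float | None
    roc_auc: float | None = None
    per_fold: list["MetricsReport"] | None = None
    mean: dict[str, float] | None = None
    std: dict[str, float] | None = None

    _FIELDS = ("q2", "precision", "recall", "f1", "roc_auc", "mcc")

    def to_dict(self) -> dict:
        d = {
            "counts": {"tp": self.counts.tp, "tn": self.counts.tn,
                       "fp": self.counts.fp, "fn": self.counts.fn},
            **{k: getattr(self, k) for k in self._FIELDS},
        }
        if self.per_fold is not None:
            d["per_fold"] = [f.to_dict() for f in self.per_fold]
            d["mean"] = self.mean
            d["std"] = self.std
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def render_row(self) -> str:
        """Percent rendering with one decimal (MCC kept as a fraction)."""
        def fmt(name: str) -> str:
            v = getattr(self, name)
            if v is None:
                return "NA"
            return f"{v:.2f}" if name == "mcc" else f"{100 * v:.1f}"

        return "\t".join(fmt(name) for name in self._FIELDS)


def confusion(y_true: Sequence[Label], y_pred: Sequence[Label]) -> ConfusionCounts:
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t is Label.PLP:
            if p is Label.PLP:
                tp += 1
            else:
                fn += 1
        elif t is Label.BLB:
            if p is Label.PLP:
                fp += 1
            else:
                tn += 1
        else:
            raise ValueError(f"unexpected label {t} in evaluation")
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Evaluate accuracy, precision, recall, F1 and MCC on raw counts."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = counts.total

    q2 = (tp + tn) / total if total else None
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom > 0:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    else:
        mcc = None
    return MetricsReport(counts=counts, q2=q2, precision=precision,
                         recall=recall, f1=f1, mcc=mcc)


def roc_auc(scores: Sequence[float], y_true: Sequence[Label]) -> float | None:
    """Tie-corrected Mann-Whitney rank AUC; ``None`` if one class is absent."""
    if len(scores) != len(y_true):
        raise ValueError("length mismatch between scores and labels")
    y = np.array([1 if t is Label.PLP else 0 for t in y_true])
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(np.asarray(scores, dtype=float))  # mid-ranks for ties
    rank_sum_pos = float(ranks[y == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _aggregate(per_fold: list[MetricsReport]) -> tuple[dict, dict]:
    mean: dict[str, float] = {}
    std: dict[str, float] = {}
    for name in MetricsReport._FIELDS:
        vals = [getattr(f, name) for f in per_fold if getattr(f, name) is not None]
        if len(vals) < len(per_fold):
            warnings.warn(
                f"metric {name} undefined in {len(per_fold) - len(vals)} fold(s); "
                "excluded from the mean",
                stacklevel=2,
            )
        if vals:
            mean[name] = float(np.mean(vals))
            std[name] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return mean, std


def cross_validate(
    X: np.ndarray,
    y: Sequence[Label],
    fold_ids: Sequence[str],
    config: PipelineConfig,
) -> MetricsReport:
    """Homology-aware cross-validation of the full pipeline.

    For each fold the entire pipeline (standardization, PCA, SVM, isotonic
    calibrator) is refitted on the remaining folds and evaluated on the held
    fold. Per-fold metrics are reported with their unweighted mean and sample
    standard deviation.
    """
    X = np.asarray(X, dtype=float)
    unique_folds = sorted(set(fold_ids))
    if len(unique_folds) < 2:
        raise ValueError("cross-validation needs at least 2 folds")
    fold_arr = np.asarray(fold_ids)
    per_fold: list[MetricsReport] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for fold in unique_folds:
        val_mask = fold_arr == fold
        train_idx = np.where(~val_mask)[0]
        val_idx = np.where(val_mask)[0]
        y_train = [y[i] for i in train_idx]
        train_folds = fold_arr[train_idx]
        if len(set(train_folds)) < 2:
            # calibrator needs internal folds; split the training part in two
            train_folds = np.array(
                ["a" if i % 2 == 0 else "b" for i in range(len(train_idx))]
            )
        pipeline = train(X[train_idx], y_train, train_folds, config)
        preds = pipeline.predict_batch(X[val_idx])
        y_val = [y[i] for i in val_idx]
        counts = confusion(y_val, [p.label for p in preds])
        report = metrics(counts)
        report.roc_auc = roc_auc([p.score for p in preds], y_val)
        per_fold.append(report)
        pooled = ConfusionCounts(
            pooled.tp + counts.tp, pooled.tn + counts.tn,
            pooled.fp + counts.fp, pooled.fn + counts.fn,
        )
    overall = metrics(pooled)
    overall.per_fold = per_fold
    overall.mean, overall.std = _aggregate(per_fold)
    return overall


@dataclass
class HistogramReport:
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    n_predicted_plp: int       # probability >= 0.5
    n_predicted_blb: int       # probability < 0.5
    n_plp_high_ri: int         # predicted PLP with RI >= 6
    n_blb_high_ri: int         # predicted BLB with RI >= 6


def probability_histogram(predictions: Sequence[Prediction], bins: int = 20) -> HistogramReport:
    """Histogram of calibrated probabilities over [0, 1] plus RI summaries."""
    probs = np.array([p.probability for p in predictions], dtype=float)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities outside [0, 1]")
    counts, edges = np.histogram(probs, bins=bins, range=(0.0, 1.0))
    plp_mask = probs >= 0.5
    ris = np.array([p.reliability_index for p in predictions], dtype=int)
    return HistogramReport(
        bin_edges=edges,
        bin_counts=counts,
        n_predicted_plp=int(plp_mask.sum()),
        n_predicted_blb=int((~plp_mask).sum()),
        n_plp_high_ri=int((plp_mask & (ris >= 6)).sum()),
        n_blb_high_ri=int((~plp_mask & (ris >= 6)).sum()),
    )


def calibration_gap(
    probabilities: Sequence[float], y_true: Sequence[Label], bins: int = 10
) -> float:
    """Reliability gap over probability deciles.

    Predictions are sorted by calibrated probability and split into ``bins``
    equal-count groups (deciles by default); the returned value is the mean
    absolute difference between each group's mean predicted probability and
    its empirical positive fraction. Near zero for a well-calibrated model.
    """
    probs = np.asarray(probabilities, dtype=float)
    y = np.array([1 if t is Label.PLP else 0 for t in y_true])
    if probs.size == 0:
        return 0.0
    order = np.argsort(probs, kind="stable")
    gaps = [
        abs(probs[chunk].mean() - y[chunk].mean())
        for chunk in np.array_split(order, bins)
        if chunk.size
    ]
    return float(np.mean(gaps))
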