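"""ROC/AUC, operating-point selection and balanced accuracy.

The operating point is the threshold minimising the Euclidean distance to
the top-left corner of the ROC curve (perfect sensitivity and specificity);
ties are broken toward higher specificity.  Balanced accuracy is the mean
of sensitivity and specificity, so it is invariant to class prevalence.

Two evaluation modes mirror how a per-lung classifier is reported:
``all_lungs`` treats each lung as an independent case carrying its study
label, ``lr_max`` scores one fused probability (the max of left and right)
per study.  The operating threshold is either chosen on a held-out
reference set ("ad hoc") or on the evaluated set itself ("post hoc", an
upper bound that summarises the test set only).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from .errors import ValidationError


@dataclasses.dataclass
class RocSummary:
    """An empirical ROC curve with its chosen operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    operating_threshold: float
    sensitivity_at_op: float
    specificity_at_op: float

    @property
    def bacc(self) -> float:
        return 0.5 * (self.sensitivity_at_op + self.specificity_at_op)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocSummary:
    """Empirical ROC by threshold sweep, AUC by the trapezoidal rule.

    The returned operating point is the curve's own (post hoc) top-left
    optimum; a case is called positive when its score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1D arrays")
    if len(np.unique(labels)) < 2:
        raise ValidationError("ROC requires both classes present")
    fpr, tpr, thresholds = skmetrics.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(skmetrics.auc(fpr, tpr))
    summary = RocSummary(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        operating_threshold=np.nan,
        sensitivity_at_op=np.nan,
        specificity_at_op=np.nan,
    )
    i = _operating_index(summary)
    summary.operating_threshold = float(summary.thresholds[i])
    summary.sensitivity_at_op = float(summary.sensitivity[i])
    summary.specificity_at_op = float(summary.specificity[i])
    return summary


def _operating_index(roc: RocSummary) -> int:
    d = np.hypot(1.0 - roc.sensitivity, 1.0 - roc.specificity)
    best = d.min()
    candidates = np.flatnonzero(d <= best + 1e-12)
    return int(candidates[np.argmax(roc.specificity[candidates])])


def operating_point(roc: RocSummary) -> float:
    """Threshold minimising sqrt((1-sens)^2 + (1-spec)^2); ties -> higher specificity."""
    return float(roc.thresholds[_operating_index(roc)])


def balanced_accuracy(tp: int, fn: int, fp: int, tn: int) -> float:
    """(sensitivity + specificity) / 2 from confusion counts."""
    if tp + fn <= 0 or fp + tn <= 0:
        raise ValidationError("balanced accuracy needs at least one case per class")
    return 0.5 * (tp / (tp + fn) + tn / (fp + tn))


def bacc_at_threshold(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    """Balanced accuracy of the rule score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    return balanced_accuracy(tp, fn, fp, tn)


def cases_from_predictions(
    predictions: pd.DataFrame, labels: dict[str, int] | pd.Series, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Turn per-lung predictions into evaluation cases.

    ``predictions`` has columns study_id, side, p_cpe.  ``all_lungs`` keeps
    each lung as a case with its study label; ``lr_max`` fuses both lungs of
    a study into one case (missing lung -> error).
    """
    required = {"study_id", "side", "p_cpe"}
    if not required.issubset(predictions.columns):
        raise ValidationError(f"predictions need columns {sorted(required)}")
    labels = dict(labels)
    missing = set(predictions["study_id"]) - set(labels)
    if missing:
        raise ValidationError(f"no label for studies: {sorted(missing)}")
    if mode == "all_lungs":
        scores = predictions["p_cpe"].to_numpy(dtype=float)
        y = predictions["study_id"].map(labels).to_numpy(dtype=int)
        return scores, y
    if mode == "lr_max":
        grouped = predictions.groupby("study_id")["side"].nunique()
        incomplete = grouped[grouped < 2].index.tolist()
        if incomplete:
            raise ValidationError(f"lr_max mode needs both lungs; missing for {incomplete}")
        fused = predictions.groupby("study_id")["p_cpe"].max()
        scores = fused.to_numpy(dtype=float)
        y = np.array([labels[s] for s in fused.index], dtype=int)
        return scores, y
    raise ValidationError(f"unknown mode {mode!r}")


def evaluate(
    predictions: pd.DataFrame,
    labels: dict[str, int] | pd.Series,
    mode: str = "lr_max",
    threshold_source: str = "post_hoc",
    reference: tuple[np.ndarray, np.ndarray] | None = None,
) -> RocSummary:
    """Score per-lung predictions in one mode with one threshold policy.

    ``threshold_source='post_hoc'`` picks the operating point on the
    evaluated set itself; ``'ad_hoc'`` requires ``reference`` (scores,
    labels of a held-out set, e.g. the early-stopping set) and takes the
    threshold from there.
    """
    scores, y = cases_from_predictions(predictions, labels, mode)
    summary = roc_auc(scores, y)
    if threshold_source == "post_hoc":
        return summary
    if threshold_source == "ad_hoc":
        if reference is None:
            raise ValidationError("ad_hoc threshold needs a reference (scores, labels) set")
        ref_threshold = roc_auc(*reference).operating_threshold
        pred = scores >= ref_threshold
        tp = int(np.sum(pred & (y == 1)))
        fn = int(np.sum(~pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        tn = int(np.sum(~pred & (y == 0)))
        summary.operating_threshold = float(ref_threshold)
        summary.sensitivity_at_op = tp / (tp + fn)
        summary.specificity_at_op = tn / (fp + tn)
        return summary
    raise ValidationError(f"unknown threshold_source {threshold_source!r}")
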