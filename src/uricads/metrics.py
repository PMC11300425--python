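"""Evaluation surface: ranking metrics for triage and mask overlap scores.

Two diagnosis metrics are reported per category, treating each one as a
binary "category vs non-category" problem:

* ``AUC_SENS-SP`` — the area under the sensitivity-specificity ROC curve,
  equal to the Mann-Whitney statistic (ties credited 0.5), in percent.
* ``SP_SENS-95`` — the maximum specificity over thresholds whose
  sensitivity is at least 95%, on the empirical step ROC (no
  interpolation), in percent.  Clinically: the fraction of healthy cases
  correctly not referred while guaranteeing a 95% referral rate for
  pathological ones.

Segmentation quality is measured with IoU and Dice; the two are linked by
``Dice = 2 IoU / (1 + IoU)`` per mask pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .taxonomy import CategoryScheme, DEFAULT_SCHEME


class MetricUndefined(ValueError):
    """Raised when a ranking metric is requested with single-class labels."""


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if labels.size == 0 or labels.min() == labels.max():
        raise MetricUndefined(
            "ranking metrics need at least one positive and one negative label"
        )
    return labels


def roc_auc(scores, binary_labels) -> float:
    """Area under the sensitivity-specificity ROC curve, in percent."""
    labels = _check_binary(binary_labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float))) * 100.0


def sp_at_sens(scores, binary_labels, target_sens: float = 0.95) -> float:
    """Maximum specificity (percent) among thresholds with sensitivity >= target."""
    labels = _check_binary(binary_labels)
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float),
                            drop_intermediate=False)
    ok = tpr >= target_sens
    if not np.any(ok):  # tpr always reaches 1.0 at the lowest threshold
        return 0.0
    return float(np.max(1.0 - fpr[ok])) * 100.0


def iou(mask_a, mask_b) -> float:
    """Intersection over union of two same-shape binary masks in [0, 1]."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0  # both empty: perfect agreement on absence
    return float(np.logical_and(a, b).sum() / union)


def dice(mask_a, mask_b) -> float:
    """Dice coefficient of two same-shape binary masks in [0, 1]."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / total)


@dataclass
class EvalReport:
    """Aggregated evaluation over a prediction run (values in percent)."""

    auc_per_category: dict[str, float]
    sp95_per_category: dict[str, float]
    auc_average: float
    sp95_average: float
    auc_binary: float
    sp95_binary: float
    mean_iou: float
    mean_dice: float
    excluded_categories: list[str] = field(default_factory=list)
    n_cases: int = 0

    def to_dict(self) -> dict:
        return {
            "auc_per_category": self.auc_per_category,
            "sp95_per_category": self.sp95_per_category,
            "auc_average": self.auc_average,
            "sp95_average": self.sp95_average,
            "auc_binary": self.auc_binary,
            "sp95_binary": self.sp95_binary,
            "mean_iou": self.mean_iou,
            "mean_dice": self.mean_dice,
            "excluded_categories": self.excluded_categories,
            "n_cases": self.n_cases,
        }


def evaluate_run(
    predictions: dict[str, dict],
    annotations,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    target_sens: float = 0.95,
) -> EvalReport:
    """Score fused predictions and masks against case annotations.

    ``predictions`` maps image id -> {"p": length-(P+1) fused score vector,
    "mask": binary kidney mask (optional)}.  All test scores are pooled
    before computing per-category metrics; a category whose pooled labels
    are single-class is excluded from the averages with a warning.
    The binary healthy-vs-pathological problem scores each case with
    ``1 - p_0`` against the "any pathology present" label.
    """
    anns = {a.image_id: a for a in annotations}
    missing = set(anns) - set(predictions)
    if missing:
        raise KeyError(f"predictions missing for case ids: {sorted(missing)[:5]}")

    ids = sorted(anns)
    P = np.stack([np.asarray(predictions[i]["p"], dtype=float) for i in ids])
    Y = np.stack([anns[i].multihot(scheme) for i in ids])

    auc_cat: dict[str, float] = {}
    sp_cat: dict[str, float] = {}
    excluded: list[str] = []
    for k in range(1, scheme.P + 1):
        name = scheme.names[k]
        try:
            auc_cat[name] = roc_auc(P[:, k], Y[:, k])
            sp_cat[name] = sp_at_sens(P[:, k], Y[:, k], target_sens)
        except MetricUndefined:
            excluded.append(name)
            warnings.warn(f"category {name}: single-class labels, excluded")
    auc_avg = float(np.mean(list(auc_cat.values()))) if auc_cat else float("nan")
    sp_avg = float(np.mean(list(sp_cat.values()))) if sp_cat else float("nan")

    pathological = (1.0 - Y[:, 0]).astype(int)
    try:
        auc_bin = roc_auc(1.0 - P[:, 0], pathological)
        sp_bin = sp_at_sens(1.0 - P[:, 0], pathological, target_sens)
    except MetricUndefined:
        auc_bin = sp_bin = float("nan")
        warnings.warn("binary healthy-vs-pathological labels are single-class")

    ious, dices = [], []
    for i in ids:
        pred_mask = predictions[i].get("mask")
        if pred_mask is None:
            continue
        gt = anns[i].kidney_mask()
        ious.append(iou(pred_mask, gt))
        dices.append(dice(pred_mask, gt))
    mean_iou = float(np.mean(ious)) * 100.0 if ious else float("nan")
    mean_dice = float(np.mean(dices)) * 100.0 if dices else float("nan")

    return EvalReport(
        auc_per_category=auc_cat,
        sp95_per_category=sp_cat,
        auc_average=auc_avg,
        sp95_average=sp_avg,
        auc_binary=auc_bin,
        sp95_binary=sp_bin,
        mean_iou=mean_iou,
        mean_dice=mean_dice,
        excluded_categories=excluded,
        n_cases=len(ids),
    )
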