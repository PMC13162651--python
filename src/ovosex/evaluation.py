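"""Classification metrics, curves and feature-focus diagnostics.

The **female** class is the positive class throughout: TP counts female
embryos predicted female, FP male embryos predicted female, and so on. This
matters for precision/recall and especially for the PR curve, whose average
precision depends on which class is "positive".

Provided: confusion counts; accuracy / precision / recall / F1 / Cohen's
kappa; ROC (threshold sweep, trapezoidal AUC, equal to the pairwise
concordance probability with ties counted one half); PR with step-wise
average precision; per-quality-stratum accuracy; and a
vascular-to-background activation ratio computed from gradient-weighted
class-activation heatmaps against ground-truth vessel masks.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np
from sklearn import metrics as skm

from .backbone import Network
from .nn import Tensor

__all__ = [
    "POSITIVE_CLASS", "ConfusionCounts", "ScoredPredictions",
    "classification_metrics", "roc_auc", "pr_ap", "subset_report",
    "activation_ratio", "gradcam_heatmap", "write_report",
]

#: positive class for all metrics
POSITIVE_CLASS = "F"


def _to_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return (arr == POSITIVE_CLASS).astype(int)
    return arr.astype(int)


@dataclasses.dataclass
class ConfusionCounts:
    """2x2 confusion table with female as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        t, p = _to_binary(y_true), _to_binary(y_pred)
        return cls(tp=int(((t == 1) & (p == 1)).sum()),
                   fp=int(((t == 0) & (p == 1)).sum()),
                   fn=int(((t == 1) & (p == 0)).sum()),
                   tn=int(((t == 0) & (p == 0)).sum()))

    def normalized(self) -> dict:
        pos, neg = self.tp + self.fn, self.fp + self.tn
        return {"tpr": self.tp / pos if pos else math.nan,
                "fnr": self.fn / pos if pos else math.nan,
                "fpr": self.fp / neg if neg else math.nan,
                "tnr": self.tn / neg if neg else math.nan}


@dataclasses.dataclass
class ScoredPredictions:
    """Per-sample evaluation records with positive-class scores in [0,1]."""

    y_true: np.ndarray
    y_pred: np.ndarray
    score: np.ndarray
    quality: np.ndarray | None = None

    def __post_init__(self):
        self.y_true = _to_binary(self.y_true)
        self.y_pred = _to_binary(self.y_pred)
        self.score = np.asarray(self.score, dtype=float)
        if self.score.min() < 0 or self.score.max() > 1:
            raise ValueError("scores must lie in [0,1]")
        if self.quality is not None:
            self.quality = np.asarray(self.quality)


def classification_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, precision, recall, F1 and Cohen's kappa from a 2x2 table.

    Undefined ratios (zero denominators) are reported as ``None`` and named
    in the ``undefined`` list rather than silently coerced to 0.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    n = c.total
    undefined = []
    accuracy = (c.tp + c.tn) / n

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    precision = ratio(c.tp, c.tp + c.fp, "precision")
    recall = ratio(c.tp, c.tp + c.fn, "recall")
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
        undefined.append("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    # chance agreement from marginal products
    p_yes = ((c.tp + c.fp) / n) * ((c.tp + c.fn) / n)
    p_no = ((c.fn + c.tn) / n) * ((c.fp + c.tn) / n)
    pe = p_yes + p_no
    if pe == 1.0:
        kappa = None
        undefined.append("kappa")
    else:
        kappa = (accuracy - pe) / (1.0 - pe)
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "f1": f1, "kappa": kappa, "undefined": undefined}


def roc_auc(preds: ScoredPredictions) -> dict:
    """ROC curve over unique score thresholds and trapezoidal AUC."""
    if len(np.unique(preds.y_true)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = skm.roc_curve(preds.y_true, preds.score)
    return {"fpr": fpr, "tpr": tpr, "thresholds": thresholds,
            "auc": float(skm.auc(fpr, tpr))}


def pr_ap(preds: ScoredPredictions) -> dict:
    """Precision-recall curve and step-integrated average precision."""
    if preds.y_true.sum() == 0:
        raise ValueError("PR requires at least one positive sample")
    precision, recall, thresholds = skm.precision_recall_curve(
        preds.y_true, preds.score)
    ap = float(skm.average_precision_score(preds.y_true, preds.score))
    return {"precision": precision, "recall": recall,
            "thresholds": thresholds, "ap": ap}


def subset_report(preds: ScoredPredictions) -> dict:
    """Per-quality-stratum accuracy table plus the overall figure."""
    if preds.quality is None:
        raise ValueError("subset report requires quality tags")
    rows = {}
    for stratum in np.unique(preds.quality):
        mask = preds.quality == stratum
        n = int(mask.sum())
        acc = float((preds.y_true[mask] == preds.y_pred[mask]).mean()) if n else None
        rows[str(stratum)] = {"n": n, "accuracy": acc,
                              "flag": "empty" if n == 0 else ""}
    overall = float((preds.y_true == preds.y_pred).mean())
    return {"strata": rows, "overall": {"n": len(preds.y_true), "accuracy": overall}}


def activation_ratio(heatmap: np.ndarray, vessel_mask: np.ndarray,
                     egg_mask: np.ndarray | None = None) -> dict:
    """Mean activation over vessel pixels / mean over in-egg background.

    ``egg_mask`` restricts the background to the egg region; when omitted
    the whole non-vessel area is used. A zero background mean is reported
    as infinite with a flag rather than raising.
    """
    heatmap = np.asarray(heatmap, dtype=float)
    vessel = np.asarray(vessel_mask, dtype=bool)
    if heatmap.min() < 0:
        raise ValueError("heatmap must be non-negative")
    region = np.ones_like(vessel) if egg_mask is None else np.asarray(egg_mask, bool)
    background = region & ~vessel
    if not vessel.any() or not background.any():
        raise ValueError("need at least one vessel and one background pixel")
    v_mean = float(heatmap[vessel].mean())
    b_mean = float(heatmap[background].mean())
    if b_mean == 0.0:
        return {"ratio": math.inf, "vessel_mean": v_mean, "background_mean": 0.0,
                "flag": "infinite"}
    return {"ratio": v_mean / b_mean, "vessel_mean": v_mean,
            "background_mean": b_mean, "flag": ""}


def gradcam_heatmap(network: Network, image: np.ndarray,
                    class_idx: int | None = None) -> np.ndarray:
    """Gradient-weighted class-activation map from the final feature stage.

    Returns a non-negative heatmap at the input resolution (nearest-
    neighbour upsampled), normalised to max 1 when non-zero.
    """
    was_training = network.training
    network.eval()
    x = image[None] if image.ndim == 3 else image
    logits = network(Tensor(x.astype(np.float32)), record_features=True)
    k = int(np.argmax(logits.data[0])) if class_idx is None else class_idx
    onehot = np.zeros_like(logits.data)
    onehot[0, k] = 1.0
    logits.backward(onehot)
    feats = network._feature_cache
    weights = feats.grad[0].mean(axis=(1, 2))            # GAP of gradients
    cam = np.maximum((weights[:, None, None] * feats.data[0]).sum(axis=0), 0.0)
    scale = x.shape[-1] // cam.shape[-1]
    cam = cam.repeat(scale, axis=0).repeat(scale, axis=1)
    if cam.max() > 0:
        cam = cam / cam.max()
    network.train(was_training)
    return cam


def write_report(report: dict, json_path, text_path=None) -> None:
    """Persist a report as JSON (and optionally a plain-text table)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, default=default)
    if text_path is not None:
        lines = []
        for key, val in report.items():
            if isinstance(val, dict):
                lines.append(f"[{key}]")
                for k, v in val.items():
                    lines.append(f"  {k}: {v}")
            else:
                lines.append(f"{key}: {val}")
        with open(text_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
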