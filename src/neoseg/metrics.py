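"""Training cost and evaluation statistics.

The training cost is the hybrid of sparse categorical cross-entropy and a
soft-Dice term with equal 0.5 weights: the Dice cost is 1 minus the mean
soft Dice over all classes (background included).  Evaluation works on hard
label maps through confusion matrices: for each tissue class t the
sensitivity TPR = TP / (actual t), precision PPV = TP / (predicted t) and
Dice DSC = 2 TP / (actual + predicted) are reported, plus the overall
accuracy ACC = fraction of correctly labeled voxels across all classes.
Cohort-level summaries give mean, sample standard deviation and
linear-interpolation quartiles across records.

Undefined metrics (a class absent from truth or prediction) are reported as
NaN and excluded from aggregation, never silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ShapeError, UsageError
from .volume_io import LabelVolume, CLASS_NAMES

TISSUES = ("CSF", "GM", "WM")


def _as_probs(probs):
    arr = probs.probs if hasattr(probs, "probs") else np.asarray(probs)
    if arr.ndim != 4:
        raise ShapeError(f"expected a 4-D probability grid, got shape {arr.shape}")
    return arr


def _as_labels(truth):
    arr = truth.labels if hasattr(truth, "labels") else np.asarray(truth)
    if arr.ndim != 3:
        raise ShapeError(f"expected a 3-D label grid, got shape {arr.shape}")
    return arr


def one_hot(labels, n_classes, dtype=np.float64):
    labels = np.asarray(labels)
    out = np.zeros(labels.shape + (n_classes,), dtype=dtype)
    np.put_along_axis(out, labels[..., None], 1, axis=-1)
    return out


# ---------------------------------------------------------------------------
# Training cost
# ---------------------------------------------------------------------------

def soft_dice_per_class(probs, truth, smoothing: float = 1e-6):
    """Soft Dice coefficient per class: (2 sum(p*y) + s) / (sum p + sum y + s).

    ``y`` is the one-hot ground truth.  A class absent from both the truth
    and the prediction scores ~1 (pure smoothing ratio).
    """
    p = _as_probs(probs)
    y = _as_labels(truth)
    if p.shape[:3] != y.shape:
        raise ShapeError(f"extent mismatch: probs {p.shape[:3]} vs truth {y.shape}")
    n_classes = p.shape[3]
    yh = one_hot(y, n_classes)
    p = p.astype(np.float64)
    inter = np.einsum("zyxc,zyxc->c", p, yh)
    denom = p.sum(axis=(0, 1, 2)) + yh.sum(axis=(0, 1, 2))
    return (2.0 * inter + smoothing) / (denom + smoothing)


def hybrid_loss(probs, truth, w_ce: float = 0.5, w_dice: float = 0.5,
                smoothing: float = 1e-6, clip: float = 1e-7) -> float:
    """Hybrid cost: w_ce * cross-entropy + w_dice * (1 - mean soft Dice).

    Cross-entropy is the voxel-mean of -log p at the true class, with
    probabilities clipped at ``clip``; the Dice term averages the soft Dice
    over all classes including background.  Zero only at (clipped) perfect
    prediction.
    """
    p = _as_probs(probs)
    y = _as_labels(truth)
    if p.shape[:3] != y.shape:
        raise ShapeError(f"extent mismatch: probs {p.shape[:3]} vs truth {y.shape}")
    p_true = np.take_along_axis(p.astype(np.float64), y[..., None], axis=3)[..., 0]
    ce = float(-np.log(np.clip(p_true, clip, 1.0)).mean())
    dice = soft_dice_per_class(p, y, smoothing)
    return w_ce * ce + w_dice * (1.0 - float(dice.mean()))


def hybrid_loss_logit_grad(probs, truth, w_ce: float = 0.5, w_dice: float = 0.5,
                           smoothing: float = 1e-6, clip: float = 1e-7):
    """Hybrid loss value and its gradient with respect to the logits.

    The cross-entropy part uses the fused softmax gradient (p - y) / N; the
    Dice part differentiates the smoothed ratio and backpropagates through
    the softmax Jacobian.  Used by the training loop.
    """
    p = _as_probs(probs).astype(np.float64)
    y = _as_labels(truth)
    n_classes = p.shape[3]
    n_vox = y.size
    yh = one_hot(y, n_classes)
    loss = hybrid_loss(p, y, w_ce=w_ce, w_dice=w_dice, smoothing=smoothing, clip=clip)

    inter = np.einsum("zyxc,zyxc->c", p, yh)
    a = 2.0 * inter + smoothing
    b = p.sum(axis=(0, 1, 2)) + yh.sum(axis=(0, 1, 2)) + smoothing
    # d(1 - mean_c a_c/b_c)/dp_{c,v} = -(2*y_{c,v}*b_c - a_c) / (C * b_c^2)
    g_dice = -(2.0 * yh * b - a) / (n_classes * b * b)
    g = w_dice * g_dice
    # softmax Jacobian: dL/dz = p * (g - sum_c g_c p_c)
    grad = p * (g - np.einsum("zyxc,zyxc->zyx", g, p)[..., None])
    grad += w_ce * (p - yh) / n_vox
    return loss, grad


# ---------------------------------------------------------------------------
# Confusion matrices and per-record metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Voxel counts with rows = actual class and columns = predicted class."""

    counts: np.ndarray
    class_names: tuple = CLASS_NAMES
    record_id: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.class_names)
        if self.counts.shape != (n, n):
            raise ShapeError(f"expected a {n}x{n} count grid, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ShapeError("confusion counts must be non-negative")

    @property
    def total(self):
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=pd.Index(self.class_names, name="actual"),
                            columns=pd.Index(self.class_names, name="predicted"))


def confusion_matrix(pred, truth, n_classes: int = 4, record_id: str = "") -> ConfusionMatrix:
    """Tally voxels by (actual, predicted) class pair."""
    p = _as_labels(pred).ravel()
    t = _as_labels(truth).ravel()
    if p.shape != t.shape:
        raise ShapeError("prediction and truth extents differ")
    if p.size and (p.min() < 0 or p.max() >= n_classes or t.min() < 0 or t.max() >= n_classes):
        raise ShapeError(f"labels out of range [0, {n_classes - 1}]")
    counts = np.bincount(t * n_classes + p, minlength=n_classes * n_classes)
    return ConfusionMatrix(counts=counts.reshape(n_classes, n_classes),
                           class_names=CLASS_NAMES[:n_classes], record_id=record_id)


@dataclass
class MetricsReport:
    """Per-tissue TPR/PPV/DSC plus overall accuracy for one record.

    Undefined entries (zero denominator) are NaN.
    """

    record_id: str
    tpr: dict
    ppv: dict
    dsc: dict
    acc: float

    def as_flat_dict(self):
        out = {}
        for tissue in self.tpr:
            out[f"{tissue}_TPR"] = self.tpr[tissue]
            out[f"{tissue}_PPV"] = self.ppv[tissue]
            out[f"{tissue}_DSC"] = self.dsc[tissue]
        out["ACC"] = self.acc
        return out


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Derive sensitivity, precision, Dice and accuracy from the counts.

    For tissue t: TPR = TP / row-sum, PPV = TP / col-sum,
    DSC = 2 TP / (row-sum + col-sum); ACC = trace / total over all classes
    including background.
    """
    counts = cm.counts.astype(np.float64)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    tissues = cm.class_names[1:]
    tpr, ppv, dsc = {}, {}, {}
    for t_idx, tissue in enumerate(tissues, start=1):
        tp = counts[t_idx, t_idx]
        tpr[tissue] = tp / row[t_idx] if row[t_idx] > 0 else float("nan")
        ppv[tissue] = tp / col[t_idx] if col[t_idx] > 0 else float("nan")
        both = row[t_idx] + col[t_idx]
        dsc[tissue] = 2.0 * tp / both if both > 0 else float("nan")
    total = counts.sum()
    if total == 0:
        raise UsageError("empty confusion matrix")
    acc = float(np.trace(counts) / total)
    return MetricsReport(record_id=cm.record_id, tpr=tpr, ppv=ppv, dsc=dsc, acc=acc)


def tissue_average_f1(per_tissue_dsc) -> float:
    """Arithmetic mean of the three tissue Dice scores (background excluded)."""
    vals = np.asarray(per_tissue_dsc, dtype=np.float64)
    if vals.shape != (3,):
        raise UsageError(f"expected 3 per-tissue values, got shape {vals.shape}")
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise UsageError("Dice values must lie in [0, 1]")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# Cohort aggregation
# ---------------------------------------------------------------------------

SUMMARY_ROWS = ("avg", "std", "min", "Q1", "Q2", "Q3", "max")


def summarize(values) -> dict:
    """Distribution summary of one metric across records.

    Mean, sample (n-1) standard deviation, and min/Q1/Q2/Q3/max with
    quartiles by linear interpolation between order statistics.  NaNs
    (undefined per-record metrics) are excluded; std is NaN for fewer than
    two usable values.
    """
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise UsageError("cannot summarize an empty value list")
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return {k: float("nan") for k in SUMMARY_ROWS}
    q1, q2, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return {
        "avg": float(arr.mean()),
        "std": float(arr.std(ddof=1)) if arr.size >= 2 else float("nan"),
        "min": float(arr.min()),
        "Q1": float(q1),
        "Q2": float(q2),
        "Q3": float(q3),
        "max": float(arr.max()),
    }


@dataclass
class SummaryTable:
    """Per-metric distribution rows across a cohort of records."""

    stats: dict  # metric name -> {avg, std, min, Q1, Q2, Q3, max}
    n_records: int = 0

    def __post_init__(self):
        for name, s in self.stats.items():
            order = [s["min"], s["Q1"], s["Q2"], s["Q3"], s["max"]]
            clean = [v for v in order if not np.isnan(v)]
            if any(b < a for a, b in zip(clean, clean[1:])):
                raise UsageError(f"metric {name!r}: min/Q1/Q2/Q3/max not ordered")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({name: pd.Series(s) for name, s in self.stats.items()}).loc[
            list(SUMMARY_ROWS)
        ]

    def __getitem__(self, metric):
        return self.stats[metric]


def aggregate_reports(reports) -> SummaryTable:
    """Aggregate per-record metric reports into a cohort summary table."""
    reports = list(reports)
    if not reports:
        raise UsageError("no reports to aggregate")
    flat = [r.as_flat_dict() for r in reports]
    names = list(flat[0])
    stats = {name: summarize([d[name] for d in flat]) for name in names}
    return SummaryTable(stats=stats, n_records=len(reports))


# ---------------------------------------------------------------------------
# Report export
# ---------------------------------------------------------------------------

def reports_to_frame(reports) -> pd.DataFrame:
    rows = {r.record_id or str(i): r.as_flat_dict() for i, r in enumerate(reports)}
    return pd.DataFrame(rows).T
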