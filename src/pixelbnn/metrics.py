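"""Segmentation key-performance indicators.

All KPIs derive from per-pixel confusion counts against a designated
observer's delineation: sensitivity SN = TP/(TP+FN), specificity
SP = TN/(TN+FP), precision Pr = TP/(TP+FP), accuracy, the G-mean
sqrt(SN*SP), F1 = 2TP/(2TP+FP+FN), the Matthews correlation coefficient

    MCC = (TP/N - S*P) / sqrt(P*S*(1-S)*(1-P)),  S=(TP+FN)/N, P=(TP+FP)/N,

and Cohen's kappa with chance agreement Acc_prob = sum_k n_k1 * n_k2 over
the two classes (n_ki the fraction of pixels observer i assigns to class k).
Degenerate denominators yield NaN ("undefined") with a warning, and
undefined entries are excluded from aggregation rather than silently
substituted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage import transform

__all__ = [
    "KPI_COLUMNS",
    "ConfusionCounts",
    "confusion",
    "kpis",
    "evaluate_image",
    "aggregate",
    "information_loss",
    "auc_threshold_sweep",
]

logger = logging.getLogger(__name__)

#: report column order, matching the customary benchmark-table layout
KPI_COLUMNS = ("SN", "SP", "Pr", "Acc", "AUC", "kappa", "G", "MCC", "F1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.n < 1:
            raise ValueError("at least one evaluated pixel is required")


def _as_binary(mask) -> np.ndarray:
    arr = getattr(mask, "pixels", mask)
    return np.asarray(arr) != 0


def confusion(pred, truth, region=None) -> ConfusionCounts:
    """Per-pixel confusion tallies of a predicted mask against ground truth,
    optionally restricted to a region mask (default: the whole frame)."""
    p = _as_binary(pred)
    t = _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if region is not None:
        r = _as_binary(region)
        if r.shape != p.shape:
            raise ValueError(f"region shape {r.shape} does not match {p.shape}")
        p, t = p[r], t[r]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(p.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("KPI %s undefined (zero denominator); reported as NaN", name)
        return math.nan
    return num / den


def kpis(c: ConfusionCounts) -> dict[str, float]:
    """All confusion-derived KPIs for one evaluation region.

    Returns a dict with keys SN, SP, Pr, Acc, Acc_prob, kappa, G, F1, MCC;
    degenerate entries are NaN.
    """
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    n = float(c.n)
    sn = _safe_div(tp, tp + fn, "SN")
    sp = _safe_div(tn, tn + fp, "SP")
    pr = _safe_div(tp, tp + fp, "Pr")
    acc = (tp + tn) / n
    g = math.sqrt(sn * sp) if not (math.isnan(sn) or math.isnan(sp)) else math.nan
    f1 = _safe_div(2.0 * tp, 2.0 * tp + fp + fn, "F1")

    s = (tp + fn) / n  # truth positive fraction
    p = (tp + fp) / n  # predicted positive fraction
    mcc_den = p * s * (1.0 - s) * (1.0 - p)
    if mcc_den == 0:
        logger.warning("KPI MCC undefined (single-class pred or truth); NaN")
        mcc = math.nan
    else:
        mcc = (tp / n - s * p) / math.sqrt(mcc_den)

    acc_prob = s * p + (1.0 - s) * (1.0 - p)
    kappa = _safe_div(acc - acc_prob, 1.0 - acc_prob, "kappa")

    return {
        "SN": sn,
        "SP": sp,
        "Pr": pr,
        "Acc": acc,
        "Acc_prob": acc_prob,
        "kappa": kappa,
        "G": g,
        "F1": f1,
        "MCC": mcc,
    }


def threshold_probability(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize a probability map; strictly-greater rule, so a pixel exactly
    at the threshold is background."""
    return (np.asarray(prob) > threshold).astype(np.uint8)


def resize_probability(prob: np.ndarray, native_dims: tuple[int, int]) -> np.ndarray:
    """Bicubic-resize a probability map to ground-truth native dimensions."""
    prob = np.asarray(prob, dtype=np.float64)
    if prob.shape == tuple(native_dims):
        return prob
    out = transform.resize(prob, tuple(native_dims), order=3, mode="reflect",
                           anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def evaluate_image(
    prob, truth, threshold: float = 0.5, native_dims: tuple[int, int] | None = None,
    region=None, with_auc: bool = False,
) -> dict[str, float]:
    """KPIs of one probability map against one ground-truth mask.

    The probability map is upsampled (bicubic) to the truth's native
    resolution before thresholding, so evaluation happens at native scale.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    t = _as_binary(truth)
    dims = tuple(native_dims) if native_dims is not None else t.shape
    if t.shape != dims:
        raise ValueError(f"truth shape {t.shape} != native dims {dims}")
    p = resize_probability(np.asarray(prob, dtype=np.float64), dims)
    entry = kpis(confusion(threshold_probability(p, threshold), t, region=region))
    entry["AUC"] = auc_threshold_sweep(p, t, region=region) if with_auc else math.nan
    return entry


def aggregate(entries: list[dict[str, float]]) -> dict[str, tuple[float, float]]:
    """Per-KPI mean and sample standard deviation across images.

    NaN (undefined) entries are dropped per KPI; a single defined value has
    std 0 by convention.
    """
    if not entries:
        raise ValueError("aggregate requires at least one entry")
    keys = entries[0].keys()
    out = {}
    for key in keys:
        vals = np.array([e[key] for e in entries], dtype=np.float64)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            out[key] = (math.nan, math.nan)
        elif vals.size == 1:
            out[key] = (float(vals[0]), 0.0)
        else:
            out[key] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def gmean(sn: float, sp: float) -> float:
    """G-mean sqrt(SN*SP) from an (SN, SP) pair, e.g. for recomputing the G
    column of a benchmark table from its printed sensitivity/specificity."""
    if not (0.0 <= sn <= 1.0 and 0.0 <= sp <= 1.0):
        raise ValueError("SN and SP must lie in [0, 1]")
    return math.sqrt(sn * sp)


def information_loss(orig_h: int, orig_w: int, target: int = 256) -> float:
    """Pixel-count ratio of the native image to the resized training image,
    e.g. 565x584 vs 256x256 -> 5.0348."""
    if orig_h < 1 or orig_w < 1 or target < 1:
        raise ValueError("dimensions must be >= 1")
    return round((orig_h * orig_w) / float(target * target), 4)


def auc_threshold_sweep(prob, truth, region=None, num_thresholds: int = 257) -> float:
    """Area under the ROC curve by sweeping evenly spaced thresholds over the
    probability map and integrating TPR against FPR with the trapezoid rule."""
    p = np.asarray(prob, dtype=np.float64)
    t = _as_binary(truth)
    if region is not None:
        r = _as_binary(region)
        p, t = p[r], t[r]
    npos = int(t.sum())
    nneg = t.size - npos
    if npos == 0 or nneg == 0:
        logger.warning("AUC undefined for single-class truth; NaN")
        return math.nan
    thresholds = np.linspace(0.0, 1.0, num_thresholds)
    # strictly-greater rule at each threshold, matching evaluate_image
    pred = p[None, :] > thresholds[:, None] if p.ndim == 1 else (
        p.reshape(1, -1) > thresholds[:, None]
    )
    tflat = t.reshape(-1)
    tpr = (pred & tflat).sum(axis=1) / npos
    fpr = (pred & ~tflat).sum(axis=1) / nneg
    order = np.lexsort((tpr, fpr))  # monotone ROC polyline
    fpr, tpr = fpr[order], tpr[order]
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    return float(np.trapezoid(tpr, fpr))
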