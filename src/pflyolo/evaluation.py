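"""Detection evaluation: IoU matching, precision/recall/F1, average
precision (mAP@50 and mAP@50:95), timing statistics, gradient-weighted
class-activation maps and the heatmap area-of-interest measurement.

Average precision integrates the precision-recall curve after applying the
monotone precision envelope (all-point interpolation): AP is the rectangle
sum  sum_i (r_i - r_{i-1}) * p_env(r_i)  over the enumerated PR points.  A
101-point sampled variant is available behind a flag.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage import measure as _measure
from skimage import transform as _transform

from . import autodiff as ad
from .autodiff import Tensor

IOU_5095 = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
DEFAULT_CONF = 0.25
DEFAULT_IOU = 0.5


# ---------------------------------------------------------------------------
# geometry and matching
# ---------------------------------------------------------------------------

def iou(a, b) -> float:
    """Intersection over union of two (x1, y1, x2, y2) boxes."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union > 0 else 0.0


@dataclasses.dataclass
class ConfusionCounts:
    """Per-evaluation TP/FP/FN tallies."""
    tp: int = 0
    fp: int = 0
    fn: int = 0


def match_and_count(preds, gts, iou_thr: float = DEFAULT_IOU) -> ConfusionCounts:
    """Greedy one-to-one matching in descending confidence.

    `preds`: (image_id, class_id, conf, box); `gts`: (image_id, class_id, box).
    A prediction is a true positive when its class matches and IoU with a
    still-unmatched ground truth of the same image reaches `iou_thr`.
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i][2])
    unmatched = {i: g for i, g in enumerate(gts)}
    c = ConfusionCounts()
    for pi in order:
        img, cls, _conf, box = preds[pi]
        best, best_iou = None, iou_thr
        for gi, (gimg, gcls, gbox) in unmatched.items():
            if gimg != img or gcls != cls:
                continue
            v = iou(box, gbox)
            if v >= best_iou:
                best, best_iou = gi, v
        if best is not None:
            del unmatched[best]
            c.tp += 1
        else:
            c.fp += 1
    c.fn = len(unmatched)
    return c


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0/0 -> 0."""
    p = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    r = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (same scale as the inputs)."""
    return 2 * precision * recall / (precision + recall) if precision + recall else 0.0


# ---------------------------------------------------------------------------
# average precision
# ---------------------------------------------------------------------------

def average_precision(tp_flags, confs, n_gt: int, sampled: bool = False) -> float:
    """AP from per-prediction TP flags and confidences against n_gt truths.

    Sorts by confidence, accumulates the PR curve, applies the monotone
    envelope and integrates exactly (rectangles over the enumerated recall
    levels) — or over a 101-point recall grid when `sampled`.
    """
    if n_gt == 0:
        return 0.0
    if len(tp_flags) == 0:
        return 0.0
    order = np.argsort(-np.asarray(confs, dtype=float), kind="stable")
    tp = np.asarray(tp_flags, dtype=float)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # monotone envelope: p_env(r) = max precision at recall >= r
    p_env = np.maximum.accumulate(precision[::-1])[::-1]
    if sampled:
        grid = np.linspace(0, 1, 101)
        vals = np.zeros_like(grid)
        for i, r in enumerate(grid):
            mask = recall >= r - 1e-12
            vals[i] = p_env[mask].max(initial=0.0) if mask.any() else 0.0
        return float(vals.mean())
    ap, prev_r = 0.0, 0.0
    for r, p in zip(recall, p_env):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


@dataclasses.dataclass
class EvalResult:
    """Aggregate detection quality: per-class AP plus point metrics.

    All values are fractions in [0, 1]; `summary()` reports percentages.
    """
    ap_per_class: dict            # {class_id: {iou_thr: ap}}
    precision: float
    recall: float
    f1: float
    map50: float
    map5095: float
    n_classes: int

    def summary(self) -> str:
        return (f"P={self.precision * 100:.1f}% R={self.recall * 100:.1f}% "
                f"F1={self.f1 * 100:.2f}% mAP@50={self.map50 * 100:.1f}% "
                f"mAP@50:95={self.map5095 * 100:.1f}% (N={self.n_classes})")

    def to_json(self, path=None):
        import json
        doc = {"precision": self.precision, "recall": self.recall,
               "f1": self.f1, "map50": self.map50, "map5095": self.map5095,
               "n_classes": self.n_classes,
               "ap_per_class": {str(c): {str(t): v for t, v in d.items()}
                                for c, d in self.ap_per_class.items()}}
        if path is None:
            return json.dumps(doc, indent=2)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    def to_csv(self, path):
        """Per-class AP table (classes x IoU thresholds)."""
        import pandas as pd
        pd.DataFrame(self.ap_per_class).T.to_csv(path)


def map_at(preds, gts, thresholds=IOU_5095, conf_thr: float = DEFAULT_CONF,
           point_iou: float = DEFAULT_IOU, sampled: bool = False) -> EvalResult:
    """Mean average precision over classes and IoU thresholds.

    `preds`: (image_id, class_id, conf, box xyxy); `gts`: (image_id,
    class_id, box).  mAP@50 uses the first threshold; mAP@50:95 averages all
    of them.  The point metrics (P/R/F1) are computed at `conf_thr` and
    `point_iou`.  Matching is confidence-sorted, so input order is
    irrelevant.
    """
    classes = sorted({g[1] for g in gts})
    ap: dict = {c: {} for c in classes}
    for thr in thresholds:
        for cls in classes:
            cls_preds = [p for p in preds if p[1] == cls]
            cls_gts = [g for g in gts if g[1] == cls]
            flags = _tp_flags(cls_preds, cls_gts, thr)
            ap[cls][thr] = average_precision(flags, [p[2] for p in cls_preds],
                                             len(cls_gts), sampled)
    c = match_and_count([p for p in preds if p[2] >= conf_thr], gts, point_iou)
    p, r, f1 = precision_recall_f1(c)
    t0 = thresholds[0]
    map50 = float(np.mean([ap[c_][t0] for c_ in classes])) if classes else 0.0
    map5095 = float(np.mean([np.mean(list(ap[c_].values())) for c_ in classes])) \
        if classes else 0.0
    return EvalResult(ap, p, r, f1, map50, map5095, len(classes))


def _tp_flags(preds, gts, iou_thr):
    """Confidence-ordered greedy TP flags (one gt matches one prediction)."""
    order = sorted(range(len(preds)), key=lambda i: -preds[i][2])
    taken = set()
    flags = [0.0] * len(preds)
    for pi in order:
        img, _cls, _conf, box = preds[pi]
        best, best_iou = None, iou_thr
        for gi, (gimg, _gcls, gbox) in enumerate(gts):
            if gi in taken or gimg != img:
                continue
            v = iou(box, gbox)
            if v >= best_iou:
                best, best_iou = gi, v
        if best is not None:
            taken.add(best)
            flags[pi] = 1.0
    return flags


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float = 0.45,
        max_det: int = 300) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices."""
    order = list(np.argsort(-scores))
    keep: list[int] = []
    while order and len(keep) < max_det:
        i = order.pop(0)
        keep.append(i)
        order = [j for j in order if iou(boxes[i], boxes[j]) < iou_thr]
    return keep


# ---------------------------------------------------------------------------
# timing
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TimingStats:
    """Mean per-image detection time and the implied frame rate."""
    m: int
    dt_ms: float
    fps: float


def timing(t_list_ms) -> TimingStats:
    """Dt = mean of per-image times (ms); FPS = 1000 / Dt."""
    if len(t_list_ms) == 0:
        raise ValueError("timing requires at least one measurement")
    dt = float(np.mean(t_list_ms))
    return TimingStats(len(t_list_ms), dt, 1000.0 / dt)


# ---------------------------------------------------------------------------
# attention heatmaps
# ---------------------------------------------------------------------------

def gradcam_map(model, image: np.ndarray, target_layer: int,
                class_id: int | None = None) -> np.ndarray:
    """Gradient-weighted class-activation map at `target_layer`.

    Backpropagates the best class logit (optionally a fixed class) to the
    chosen layer, weights its activation channels by spatially averaged
    gradients, rectifies, normalises to [0, 255] and resizes to the input.
    """
    model.eval()
    x = Tensor(image[None].transpose(0, 3, 1, 2).astype(np.float32) / 255.0)
    raw = model.forward(x)
    outs = model._layer_outputs
    if not 0 <= target_layer < len(outs) or outs[target_layer] is None:
        raise ValueError(f"no activation at layer {target_layer}")
    act = outs[target_layer]
    act.requires_grad = True
    nc = model.nc
    # score: the strongest class response across scales
    score = None
    for m in raw:
        cls_logits = ad.narrow(m, 1, m.shape[1] - nc, nc)
        if class_id is not None:
            cls_logits = ad.narrow(cls_logits, 1, class_id, 1)
        s = ad.mean(ad.mul(cls_logits, Tensor(_softmax_mask(cls_logits.data))))
        score = s if score is None else ad.add(score, s)
    score.backward()
    g = act.grad[0]                       # (C, h, w)
    a = act.data[0]
    weights = g.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * a).sum(axis=0), 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    cam = _transform.resize(cam, image.shape[:2], order=1, anti_aliasing=False)
    return (cam * 255.0).astype(np.float64)


def _softmax_mask(logits: np.ndarray) -> np.ndarray:
    """A one-hot mask selecting the spatially/classwise maximal logit."""
    mask = np.zeros_like(logits)
    idx = np.unravel_index(np.argmax(logits), logits.shape)
    mask[idx] = 1.0
    return mask * logits.size  # undo the mean reduction scale


def aoi_area(heatmap: np.ndarray, threshold: float | None = None) -> float:
    """Area of interest of a heatmap in pixels.

    Grayscale conversion -> binarisation (Otsu by default, or a fixed
    threshold) -> contour extraction at the region boundary -> shoelace
    (Green's theorem) area of each outer contour, summed.  Areas can be
    half-integral because contours run between pixel centres.
    """
    hm = np.asarray(heatmap, dtype=np.float64)
    if hm.ndim == 3:
        hm = hm[..., 0] * 0.299 + hm[..., 1] * 0.587 + hm[..., 2] * 0.114
    if hm.max() <= 0:
        return 0.0
    if threshold is None:
        from skimage.filters import threshold_otsu
        threshold = threshold_otsu(hm)
    mask = (hm > threshold).astype(np.float64)
    if mask.sum() == 0:
        return 0.0
    padded = np.pad(mask, 1)
    total = 0.0
    for contour in _measure.find_contours(padded, 0.5):
        y, x = contour[:, 0], contour[:, 1]
        signed = 0.5 * np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])
        total += max(signed, 0.0)  # outer contours only; holes have opposite sign
    return float(total)
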