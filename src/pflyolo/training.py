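"""Smoke-scale training for the detector.

This is a deliberately small recipe meant to verify end-to-end
trainability (gradient flow, decoding, evaluation) on easy synthetic data,
not to reproduce full-scale training: each ground-truth box is assigned to
the grid cell containing its centre at every scale, classification is
binary cross-entropy over the class map, and box regression is the
distribution-focal cross-entropy on the centre-to-edge distances in stride
units.  The optimiser is SGD with momentum 0.937 and weight decay 5e-4 at
learning rate 0.01 (the study-scale hyperparameters; only the schedule
length differs here).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from . import evaluation as ev
from .autodiff import Tensor
from .blocks import REG_MAX, decode_head_outputs


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 5
    batch_size: int = 8
    lr: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    imgsz: int = 64
    cls_weight: float = 1.0
    dfl_weight: float = 0.3
    seed: int = 0


class SGD:
    """SGD with momentum and decoupled weight decay."""

    def __init__(self, params, lr, momentum=0.937, weight_decay=0.0):
        self.params = [p for p in params if p.trainable]
        self.lr, self.momentum, self.wd = lr, momentum, weight_decay
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _targets_for_batch(labels, nc, imgsz, strides=(8, 16, 32)):
    """Per-scale classification targets, positive masks and DFL edge
    distances for one-box-per-image labels."""
    B = len(labels)
    out = []
    for s in strides:
        g = imgsz // s
        cls_t = np.zeros((B, nc, g, g), np.float32)
        pos = np.zeros((B, 1, g, g), np.float32)
        dist = np.zeros((B, 4, g, g), np.float32)  # l, t, r, b in stride units
        for b, lbl in enumerate(labels):
            cx, cy = lbl.cx * imgsz, lbl.cy * imgsz
            gx, gy = min(int(cx / s), g - 1), min(int(cy / s), g - 1)
            cls_t[b, lbl.class_id, gy, gx] = 1.0
            pos[b, 0, gy, gx] = 1.0
            ax, ay = (gx + 0.5) * s, (gy + 0.5) * s
            x1, y1 = cx - lbl.w * imgsz / 2, cy - lbl.h * imgsz / 2
            x2, y2 = cx + lbl.w * imgsz / 2, cy + lbl.h * imgsz / 2
            d = np.array([ax - x1, ay - y1, x2 - ax, y2 - ay]) / s
            dist[b, :, gy, gx] = np.clip(d, 0.0, REG_MAX - 1 - 1e-3)
        out.append((cls_t, pos, dist))
    return out


def detection_loss(raw_maps, labels, nc, imgsz, cfg: TrainConfig):
    """BCE classification + distribution-focal box loss on centre cells."""
    targets = _targets_for_batch(labels, nc, imgsz)
    total = None
    n_pos = max(len(labels), 1)
    for m, (cls_t, pos, dist) in zip(raw_maps, targets):
        B = m.shape[0]
        box_logits = ad.narrow(m, 1, 0, 4 * REG_MAX)
        cls_logits = ad.narrow(m, 1, 4 * REG_MAX, nc)
        # class map: positives weighted up so they are not drowned out
        w = 1.0 + cls_t * (cls_t.size / max(cls_t.sum(), 1.0))
        cls_loss = ad.bce_with_logits(cls_logits, cls_t, weight=w)
        # DFL: two-hot cross-entropy between adjacent bins at positive cells
        g = m.shape[2]
        bl = ad.reshape(box_logits, (B, 4, REG_MAX, g, g))
        logp = ad.log_softmax(bl, axis=2)
        lo = np.floor(dist)
        hi = lo + 1.0
        w_lo = (hi - dist)[:, :, None]
        w_hi = (dist - lo)[:, :, None]
        bins = np.arange(REG_MAX, dtype=np.float32)[None, None, :, None, None]
        onehot_lo = (bins == lo[:, :, None]).astype(np.float32)
        onehot_hi = (bins == np.minimum(hi, REG_MAX - 1)[:, :, None]).astype(np.float32)
        mask = pos[:, :, None]
        dfl_target = (onehot_lo * w_lo + onehot_hi * w_hi) * mask
        dfl = -ad.sum_(ad.mul(logp, Tensor(dfl_target)))
        dfl = ad.mul(dfl, Tensor(np.float32(1.0 / (4 * n_pos))))
        part = ad.add(ad.mul(cls_loss, Tensor(np.float32(cfg.cls_weight))),
                      ad.mul(dfl, Tensor(np.float32(cfg.dfl_weight))))
        total = part if total is None else ad.add(total, part)
    return total


def _to_batch(items, imgsz):
    arr = np.stack([it.image for it in items]).astype(np.float32) / 255.0
    return Tensor(arr.transpose(0, 3, 1, 2))


def smoke_train(model, items, cfg: TrainConfig, log=None):
    """Train on a small labelled set; returns the per-epoch mean losses."""
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), cfg.lr, cfg.momentum, cfg.weight_decay)
    model.train()
    history = []
    n = len(items)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            batch = [items[i] for i in order[start:start + cfg.batch_size]]
            x = _to_batch(batch, cfg.imgsz)
            raw = model.forward(x)
            loss = detection_loss(raw, [b.label for b in batch], model.nc,
                                  cfg.imgsz, cfg)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        if log:
            log(f"epoch {epoch + 1}/{cfg.epochs} loss {history[-1]:.4f}")
    return history


def evaluate_detector(model, items, imgsz, conf_thr=0.25, nms_iou=0.45):
    """Run inference on labelled items and score with mAP machinery."""
    model.eval()
    preds, gts = [], []
    for it in items:
        x = _to_batch([it], imgsz)
        boxes, scores = model.predict(x)
        b, s = boxes[0], scores[0]
        conf = s.max(axis=1)
        cls = s.argmax(axis=1)
        keep = conf >= conf_thr
        idx = np.nonzero(keep)[0]
        if idx.size:
            kept = ev.nms(b[idx], conf[idx], nms_iou)
            for j in (idx[k] for k in kept):
                preds.append((it.item_id, int(cls[j]), float(conf[j]),
                              tuple(b[j].tolist())))
        lbl = it.label
        gx1 = (lbl.cx - lbl.w / 2) * imgsz
        gy1 = (lbl.cy - lbl.h / 2) * imgsz
        gx2 = (lbl.cx + lbl.w / 2) * imgsz
        gy2 = (lbl.cy + lbl.h / 2) * imgsz
        gts.append((it.item_id, lbl.class_id, (gx1, gy1, gx2, gy2)))
    return ev.map_at(preds, gts)
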