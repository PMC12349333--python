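"""Dataset curation: frame extraction, SSIM near-duplicate filtering,
annotation validation, single-draw augmentation and the split-then-augment
partition.

Labels follow the one-object-per-image YOLO-txt convention: each image has
exactly one line ``class cx cy w h`` with centre/size normalised to [0, 1].
The similarity index used for duplicate rejection is the *global-statistics*
form of SSIM — one mean/variance/covariance triple over the whole grayscale
frame — with the conventional constants k1 = 0.01, k2 = 0.03 on an L = 255
dynamic range.  A windowed variant is available behind a flag for
robustness studies.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
from skimage import color as _color
from skimage import transform as _transform

K1, K2, L = 0.01, 0.03, 255.0
C1, C2 = (K1 * L) ** 2, (K2 * L) ** 2
SSIM_THRESHOLD = 0.75
FRAME_STRIDE = 30

AUGMENTATIONS = ("hflip", "vflip", "rot90", "shift_scale_rotate",
                 "brightness_contrast", "hsv")
# geometric draw parameters (fractions of image size / degrees)
SSR_SHIFT, SSR_SCALE, SSR_ROTATE = 0.0625, 0.10, 15.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BoxLabel:
    """One normalised YOLO-txt annotation."""
    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def corners(self) -> np.ndarray:
        """The four box corners as (4, 2) normalised (x, y) points."""
        hw, hh = self.w / 2, self.h / 2
        return np.array([[self.cx - hw, self.cy - hh], [self.cx + hw, self.cy - hh],
                         [self.cx + hw, self.cy + hh], [self.cx - hw, self.cy + hh]])

    @classmethod
    def from_corners(cls, class_id: int, pts: np.ndarray) -> "BoxLabel":
        x1, y1 = pts.min(axis=0)
        x2, y2 = pts.max(axis=0)
        return cls(class_id, (x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)

    def clipped(self) -> "BoxLabel":
        pts = np.clip(self.corners(), 0.0, 1.0)
        return BoxLabel.from_corners(self.class_id, pts)

    def to_line(self) -> str:
        return f"{self.class_id} {self.cx:.6f} {self.cy:.6f} {self.w:.6f} {self.h:.6f}"

    @classmethod
    def from_line(cls, line: str) -> "BoxLabel":
        p = line.split()
        return cls(int(p[0]), *(float(v) for v in p[1:5]))


@dataclasses.dataclass
class LabeledImage:
    """An image with its single annotated target."""
    item_id: str
    image: np.ndarray          # (H, W, 3) uint8
    label: BoxLabel


@dataclasses.dataclass
class SplitManifest:
    """Item ids per split; `stage` records whether augmentation happened."""
    train: list
    val: list
    test: list
    stage: str = "filtered"

    def counts(self):
        return len(self.train), len(self.val), len(self.test)

    def to_json(self, path=None):
        doc = dataclasses.asdict(self)
        if path is None:
            return json.dumps(doc, indent=2)
        pathlib.Path(path).write_text(json.dumps(doc, indent=2))


# ---------------------------------------------------------------------------
# frame extraction and SSIM filtering
# ---------------------------------------------------------------------------

def extract_frames(source, stride: int = FRAME_STRIDE) -> list[np.ndarray]:
    """Frames 0, stride, 2*stride, ... from a frame sequence.

    `source` may be an ndarray stack (T, H, W[, C]), any iterable of frames,
    a multi-frame image file, or a directory of frames (sorted by name).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if isinstance(source, (str, pathlib.Path)):
        p = pathlib.Path(source)
        if p.is_dir():
            frames = [iio.imread(f) for f in sorted(p.iterdir()) if f.is_file()]
        else:
            frames = list(np.asarray(iio.imread(p)))
    elif isinstance(source, np.ndarray):
        frames = list(source)
    else:
        frames = list(source)
    return [np.asarray(f) for f in frames[::stride]]


def load_class_counts() -> list[int]:
    """Shipped per-identity image counts of the filtered study dataset
    (60 classes summing to 6418)."""
    import csv
    import importlib.resources
    src = importlib.resources.files("pflyolo.configs") / "class_counts.csv"
    with src.open() as fh:
        rows = [r for r in csv.reader(ln for ln in fh if not ln.startswith("#"))]
    return [int(r[1]) for r in rows[1:]]


def to_gray(img: np.ndarray) -> np.ndarray:
    """Luma-weighted grayscale as float64 on the [0, 255] scale."""
    a = np.asarray(img, dtype=np.float64)
    if a.ndim == 3:
        a = a[..., 0] * 0.299 + a[..., 1] * 0.587 + a[..., 2] * 0.114
    return a


def ssim(x: np.ndarray, y: np.ndarray, windowed: bool = False) -> float:
    """Structural similarity of two images in [-1, 1].

    The default is the global-statistics form
    ((2 mx my + C1)(2 sxy + C2)) / ((mx^2 + my^2 + C1)(sx^2 + sy^2 + C2));
    `windowed=True` switches to the sliding-window mean variant.
    """
    gx, gy = to_gray(x), to_gray(y)
    if gx.shape != gy.shape:
        raise ValueError(f"image dimensions differ: {gx.shape} vs {gy.shape}")
    if windowed:
        from skimage.metrics import structural_similarity
        return float(structural_similarity(gx, gy, data_range=L))
    mx, my = gx.mean(), gy.mean()
    vx, vy = gx.var(), gy.var()
    cxy = ((gx - mx) * (gy - my)).mean()
    return float(((2 * mx * my + C1) * (2 * cxy + C2))
                 / ((mx * mx + my * my + C1) * (vx + vy + C2)))


def dedup_filter(images: Sequence[np.ndarray],
                 threshold: float = SSIM_THRESHOLD) -> list[int]:
    """Greedy sequential near-duplicate rejection within one identity class.

    Scans in input order; an image is rejected when its SSIM against any
    already-retained image exceeds `threshold`.  Returns retained indices
    in input order.  Idempotent: re-filtering a retained set removes nothing.
    """
    kept: list[int] = []
    for i, img in enumerate(images):
        if all(ssim(img, images[j]) <= threshold for j in kept):
            kept.append(i)
    return kept


def dedup_dataset(items: Iterable[LabeledImage],
                  threshold: float = SSIM_THRESHOLD) -> list[LabeledImage]:
    """Apply `dedup_filter` independently within each identity class."""
    by_class: dict[int, list[LabeledImage]] = {}
    order: dict[str, int] = {}
    for pos, it in enumerate(items):
        by_class.setdefault(it.label.class_id, []).append(it)
        order[it.item_id] = pos
    kept: list[LabeledImage] = []
    for cid in sorted(by_class):
        group = by_class[cid]
        for idx in dedup_filter([g.image for g in group], threshold):
            kept.append(group[idx])
    return sorted(kept, key=lambda it: order[it.item_id])


# ---------------------------------------------------------------------------
# label validation
# ---------------------------------------------------------------------------

def validate_labels(items: Iterable[LabeledImage], nc: int) -> dict:
    """Check class range, box containment and the single-target rule.

    Returns {"flags": {item_id: [messages]}, "n_checked": int, "ok": bool}.
    """
    flags: dict[str, list[str]] = {}
    n = 0
    for it in items:
        n += 1
        msgs = validate_label(it.label, nc)
        if msgs:
            flags[it.item_id] = msgs
    return {"flags": flags, "n_checked": n, "ok": not flags}


def validate_label(label: BoxLabel | None, nc: int) -> list[str]:
    if label is None:
        return ["missing label: each image must contain exactly one target"]
    msgs = []
    if not 0 <= label.class_id < nc:
        msgs.append(f"class id {label.class_id} outside 0..{nc - 1}")
    for name, lo, hi in (("x", label.cx - label.w / 2, label.cx + label.w / 2),
                         ("y", label.cy - label.h / 2, label.cy + label.h / 2)):
        if lo < -1e-9 or hi > 1 + 1e-9:
            msgs.append(f"box {name}-extent [{lo:.4f}, {hi:.4f}] outside [0, 1]")
    if label.w <= 0 or label.h <= 0:
        msgs.append("degenerate box (non-positive width/height)")
    return msgs


# ---------------------------------------------------------------------------
# augmentation (one transform per draw)
# ---------------------------------------------------------------------------

def _rot90_label(lbl: BoxLabel, k: int) -> BoxLabel:
    cx, cy, w, h = lbl.cx, lbl.cy, lbl.w, lbl.h
    for _ in range(k % 4):  # one counter-clockwise quarter turn per step
        cx, cy, w, h = cy, 1.0 - cx, h, w
    return BoxLabel(lbl.class_id, cx, cy, w, h)


def _warp_uint8(img: np.ndarray, tform, order=1) -> np.ndarray:
    out = _transform.warp(img.astype(np.float64) / 255.0, tform.inverse,
                          order=order, mode="constant", cval=0.0)
    return np.clip(out * 255.0, 0, 255).astype(np.uint8)


def augment_once(item: LabeledImage, rng: np.random.Generator,
                 max_redraws: int = 10) -> LabeledImage:
    """Apply exactly one transform drawn uniformly from the six-member family
    (h-flip, v-flip, random 90-degree rotation, shift-scale-rotate,
    brightness-contrast, hue-saturation-value).

    Geometric transforms move the box through its four corner points and
    re-fit the axis-aligned box (clipped to the frame); photometric
    transforms leave the label untouched.  A draw whose clipped box is
    degenerate is rejected and redrawn.
    """
    H, W = item.image.shape[:2]
    for _ in range(max_redraws):
        name = AUGMENTATIONS[rng.integers(len(AUGMENTATIONS))]
        img, lbl = item.image, item.label
        if name == "hflip":
            img = img[:, ::-1].copy()
            lbl = BoxLabel(lbl.class_id, 1.0 - lbl.cx, lbl.cy, lbl.w, lbl.h)
        elif name == "vflip":
            img = img[::-1].copy()
            lbl = BoxLabel(lbl.class_id, lbl.cx, 1.0 - lbl.cy, lbl.w, lbl.h)
        elif name == "rot90":
            k = int(rng.integers(1, 4))
            img = np.rot90(img, k).copy()
            lbl = _rot90_label(lbl, k)
        elif name == "shift_scale_rotate":
            dx = rng.uniform(-SSR_SHIFT, SSR_SHIFT) * W
            dy = rng.uniform(-SSR_SHIFT, SSR_SHIFT) * H
            s = 1.0 + rng.uniform(-SSR_SCALE, SSR_SCALE)
            ang = np.deg2rad(rng.uniform(-SSR_ROTATE, SSR_ROTATE))
            centre = np.array([W / 2, H / 2])
            tf = (_transform.EuclideanTransform(translation=-centre)
                  + _transform.SimilarityTransform(scale=s, rotation=ang)
                  + _transform.EuclideanTransform(translation=centre + [dx, dy]))
            img = _warp_uint8(img, tf)
            pts = lbl.corners() * [W, H]
            pts = tf(pts) / [W, H]
            lbl = BoxLabel.from_corners(lbl.class_id, np.asarray(pts)).clipped()
        elif name == "brightness_contrast":
            alpha = 1.0 + rng.uniform(-0.2, 0.2)
            beta = rng.uniform(-0.2, 0.2) * 255.0
            img = np.clip(item.image.astype(np.float64) * alpha + beta,
                          0, 255).astype(np.uint8)
        else:  # hsv
            hsv = _color.rgb2hsv(item.image)
            hsv[..., 0] = (hsv[..., 0] + rng.uniform(-0.05, 0.05)) % 1.0
            hsv[..., 1] = np.clip(hsv[..., 1] * (1 + rng.uniform(-0.3, 0.3)), 0, 1)
            hsv[..., 2] = np.clip(hsv[..., 2] * (1 + rng.uniform(-0.3, 0.3)), 0, 1)
            img = np.clip(_color.hsv2rgb(hsv) * 255.0, 0, 255).astype(np.uint8)
        lbl = lbl.clipped()
        if lbl.w > 1e-3 and lbl.h > 1e-3:
            return LabeledImage(f"{item.item_id}_aug", img, lbl)
    raise RuntimeError(f"could not draw a non-degenerate augmentation for {item.item_id}")


# ---------------------------------------------------------------------------
# split-then-augment
# ---------------------------------------------------------------------------

def split_ids(ids: Sequence, seed: int) -> tuple[list, list, list]:
    """Global random 8:1:1 split with val = test = floor(N/10)."""
    ids = list(ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_hold = len(ids) // 10
    val = [ids[i] for i in perm[:n_hold]]
    test = [ids[i] for i in perm[n_hold:2 * n_hold]]
    train = [ids[i] for i in perm[2 * n_hold:]]
    return train, val, test


def split_then_augment(items: Sequence[LabeledImage], seed: int,
                       augment: bool = True):
    """Partition first, then add exactly one augmented copy of every item
    inside its own split (so each split and each per-class count doubles).

    Returns (manifest, items_by_id).
    """
    by_id = {it.item_id: it for it in items}
    if len(by_id) != len(items):
        raise ValueError("duplicate item ids")
    train, val, test = split_ids([it.item_id for it in items], seed)
    if not augment:
        return SplitManifest(train, val, test, "filtered"), by_id
    rng = np.random.default_rng(seed + 1)
    out_splits = []
    for split in (train, val, test):
        aug_ids = []
        for iid in split:
            new = augment_once(by_id[iid], rng)
            by_id[new.item_id] = new
            aug_ids.append(new.item_id)
        out_splits.append(split + aug_ids)
    return SplitManifest(*out_splits, stage="augmented"), by_id


# ---------------------------------------------------------------------------
# directory layout I/O
# ---------------------------------------------------------------------------

def write_dataset(root, manifest: SplitManifest, items_by_id: dict):
    """Write images/{split}/*.png and labels/{split}/*.txt."""
    root = pathlib.Path(root)
    for split_name in ("train", "val", "test"):
        (root / "images" / split_name).mkdir(parents=True, exist_ok=True)
        (root / "labels" / split_name).mkdir(parents=True, exist_ok=True)
        for iid in getattr(manifest, split_name):
            it = items_by_id[iid]
            iio.imwrite(root / "images" / split_name / f"{iid}.png", it.image)
            (root / "labels" / split_name / f"{iid}.txt").write_text(
                it.label.to_line() + "\n")
    manifest.to_json(root / "manifest.json")


def read_dataset(root) -> dict[str, list[LabeledImage]]:
    """Read the images/labels layout back into per-split item lists."""
    root = pathlib.Path(root)
    out = {}
    for split_name in ("train", "val", "test"):
        items = []
        img_dir = root / "images" / split_name
        if not img_dir.is_dir():
            continue
        for f in sorted(img_dir.glob("*.png")):
            lbl_file = root / "labels" / split_name / (f.stem + ".txt")
            lines = [ln for ln in lbl_file.read_text().splitlines() if ln.strip()]
            label = BoxLabel.from_line(lines[0]) if len(lines) == 1 else None
            if label is None:
                raise ValueError(f"{f.stem}: expected exactly one label line")
            items.append(LabeledImage(f.stem, iio.imread(f), label))
        out[split_name] = items
    return out
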