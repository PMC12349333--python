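"""Synthetic fixture datasets with the statistical structure the pipeline
assumes: many identity classes, exactly one annotated face box per image,
and an adjustable fraction of near-duplicate frames.

Faces are procedural — an ellipse with a class-specific hue and stripe
pattern plus eye/nose dots on a textured background — a stand-in for real
livestock imagery that is sufficient to exercise annotation handling,
similarity filtering, augmentation, training smoke tests and attention
heatmaps.  Class signatures (hue + stripe frequency/orientation) are
designed to be easily separable so a small detector can overfit a handful
of images.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage import color as _color
from skimage import draw as _draw

from .datakit import BoxLabel, LabeledImage


@dataclasses.dataclass
class SynthConfig:
    """Generator settings; defaults emulate the study's dataset shape
    (60 identity classes, one face box per image)."""
    n_classes: int = 60
    per_class: int = 10
    image_size: int = 96
    near_duplicate_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1 or self.per_class < 1:
            raise ValueError("n_classes and per_class must be >= 1")


def _class_signature(cid: int, n_classes: int):
    """Distinct (hue, stripe frequency, stripe angle) per identity."""
    hue = (cid * 0.61803398875) % 1.0  # golden-ratio hue spacing
    freq = 2 + (cid % 5)
    angle = (cid * 37) % 180
    return hue, freq, angle


def _textured_background(rng: np.random.Generator, n: int) -> np.ndarray:
    """Smooth mid-variance texture so unrelated frames are dissimilar under
    a global SSIM but not trivially flat."""
    coarse = rng.uniform(40, 200, (n // 8 + 1, n // 8 + 1))
    idx = np.minimum(np.arange(n) // 8, coarse.shape[0] - 1)
    img = coarse[np.ix_(idx, idx)]
    img = img + rng.normal(0, 6, (n, n))
    return np.clip(img, 0, 255)


def render_face(cid: int, n_classes: int, image_size: int,
                cx: float, cy: float, scale: float,
                rng: np.random.Generator) -> tuple[np.ndarray, BoxLabel]:
    """One synthetic face image and its ground-truth box."""
    n = image_size
    hue, freq, angle = _class_signature(cid, n_classes)
    gray = _textured_background(rng, n)
    img = np.stack([gray] * 3, axis=-1)

    a = scale * n / 2                      # semi-axes in pixels
    b = 0.8 * a
    rr, cc = _draw.ellipse(cy * n, cx * n, b, a, shape=(n, n))
    yy, xx = np.mgrid[0:n, 0:n]
    th = np.deg2rad(angle)
    stripes = 0.5 + 0.5 * np.sin(2 * np.pi * freq * ((xx * np.cos(th) + yy * np.sin(th)) / n))
    hsv = np.zeros((n, n, 3))
    hsv[..., 0] = hue
    hsv[..., 1] = 0.85
    hsv[..., 2] = 0.45 + 0.5 * stripes
    face_rgb = _color.hsv2rgb(hsv) * 255.0
    img[rr, cc] = face_rgb[rr, cc]

    # eyes and nose (shared face geometry, class-independent)
    for ex in (-0.35, 0.35):
        err, ecc = _draw.disk((cy * n - 0.25 * b, cx * n + ex * a),
                              max(1.5, 0.09 * a), shape=(n, n))
        img[err, ecc] = 15
    nrr, ncc = _draw.disk((cy * n + 0.45 * b, cx * n), max(1.5, 0.12 * a), shape=(n, n))
    img[nrr, ncc] = (40, 25, 25)

    # tight box around the ellipse, clipped to the frame
    x1, x2 = max(cx - scale / 2, 0.0), min(cx + scale / 2, 1.0)
    y1, y2 = max(cy - 0.8 * scale / 2, 0.0), min(cy + 0.8 * scale / 2, 1.0)
    label = BoxLabel(cid, (x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)
    return img.astype(np.uint8), label


def gen_face_dataset(cfg: SynthConfig) -> list[LabeledImage]:
    """Generate per-class labelled face images, fully reproducible from
    `cfg.seed`.

    A `near_duplicate_rate` fraction of each class's images are jittered
    copies of the preceding original (global SSIM against the source above
    the 0.75 duplicate threshold), interleaved source-first so a greedy
    duplicate filter sees each original before its copy.
    """
    rng = np.random.default_rng(cfg.seed)
    n_dup = int(round(cfg.per_class * cfg.near_duplicate_rate))
    n_orig = cfg.per_class - n_dup
    if n_orig < 1:
        raise ValueError("near_duplicate_rate leaves no original images")
    items: list[LabeledImage] = []
    for cid in range(cfg.n_classes):
        originals = []
        for j in range(n_orig):
            cx = rng.uniform(0.32, 0.68)
            cy = rng.uniform(0.32, 0.68)
            scale = rng.uniform(0.45, 0.6)
            img, lbl = render_face(cid, cfg.n_classes, cfg.image_size,
                                   cx, cy, scale, rng)
            originals.append(LabeledImage(f"c{cid:03d}_i{j:03d}", img, lbl))
        dups = []
        for j in range(n_dup):
            src = originals[j % n_orig]
            noisy = np.clip(src.image.astype(np.int16)
                            + rng.integers(-3, 4, src.image.shape), 0, 255)
            dups.append(LabeledImage(f"c{cid:03d}_d{j:03d}",
                                     noisy.astype(np.uint8), src.label))
        # interleave so every duplicate follows its source
        per_source: dict[int, list] = {}
        for j, d in enumerate(dups):
            per_source.setdefault(j % n_orig, []).append(d)
        for j, o in enumerate(originals):
            items.append(o)
            items.extend(per_source.get(j, []))
    return items


def gen_heatmap(shape: tuple[int, int], regions, seed: int = 0) -> np.ndarray:
    """A grayscale map with stated hot regions on a zero background.

    `regions` is a list of dicts: {"kind": "rect"|"ellipse", ...geometry...,
    "intensity": value}; rectangles give (row, col, height, width), ellipses
    (row, col, r_radius, c_radius) — all in pixels.
    """
    hm = np.zeros(shape, dtype=np.float64)
    for reg in regions:
        inten = reg.get("intensity", 255)
        if reg["kind"] == "rect":
            r, c, h, w = reg["row"], reg["col"], reg["height"], reg["width"]
            hm[r:r + h, c:c + w] = inten
        elif reg["kind"] == "ellipse":
            rr, cc = _draw.ellipse(reg["row"], reg["col"], reg["r_radius"],
                                   reg["c_radius"], shape=shape)
            hm[rr, cc] = inten
        else:
            raise ValueError(f"unknown region kind {reg['kind']!r}")
    return hm
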