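"""Declarative assembly of the 23-layer detector graphs.

Both the baseline and PFL-YOLO use the same 23-layer wiring (indices 0-22):
layers 0-9 backbone (width multiple 0.25, depth multiple 0.33 of the
full-size plan, giving the 16/32/64/128/256 channel ladder), 10-21 the
FPN/PAN neck, 22 the detection head fed from strides 8/16/32.  The four
variant flags substitute, layer-for-layer:

* ``esppf``    -> layer 9
* ``ehconv``   -> the plain stride-2 convolutions (0, 1, 3, 5, 7, 16, 19)
* ``rc2f``     -> every C2f stage (2, 4, 6, 8, 12, 15, 18, 21)
* ``pfdetect`` -> layer 22

so that layer indexing is stable across variants and per-layer budget
comparisons are meaningful.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Any

import numpy as np
import yaml

from . import autodiff as ad
from . import blocks as B
from .autodiff import Tensor

STRIDES = (8, 16, 32)
HEAD_CHANNELS = (64, 128, 256)


@dataclasses.dataclass
class BlockSpec:
    """One layer of the graph: kind, kind-specific args, and source layers
    (-1 = previous layer)."""
    index: int
    kind: str
    args: dict[str, Any] = dataclasses.field(default_factory=dict)
    from_: list[int] = dataclasses.field(default_factory=lambda: [-1])

    def resolve_from(self) -> list[int]:
        """Absolute source indices; -1 denotes the network input (layer 0 only)."""
        out = [self.index - 1 if f == -1 else f for f in self.from_]
        if any(f >= self.index or f < -1 for f in out):
            raise ValueError(f"layer {self.index}: from-indices {out} must be earlier layers")
        return out


@dataclasses.dataclass
class VariantFlags:
    """Which improved modules replace their baseline counterparts."""
    esppf: bool = False
    ehconv: bool = False
    rc2f: bool = False
    pfdetect: bool = False

    @classmethod
    def all_true(cls):
        return cls(True, True, True, True)

    @classmethod
    def lattice(cls):
        """All 16 combinations, baseline first."""
        for e, h, r, p in itertools.product((False, True), repeat=4):
            yield cls(e, h, r, p)

    def short(self) -> str:
        parts = [n for n, v in (("esppf", self.esppf), ("ehconv", self.ehconv),
                                ("rc2f", self.rc2f), ("pfdetect", self.pfdetect)) if v]
        return "+".join(parts) if parts else "baseline"


@dataclasses.dataclass
class ModelGraph:
    blocks: list[BlockSpec]
    nc: int
    strides: tuple = STRIDES

    def __post_init__(self):
        if len(self.blocks) != 23:
            raise ValueError(f"graph must have 23 layers, got {len(self.blocks)}")

    # -- config documents ---------------------------------------------------
    def to_yaml(self) -> str:
        doc = {"nc": self.nc, "strides": list(self.strides),
               "layers": [{"index": b.index, "kind": b.kind, "args": b.args,
                           "from": b.from_} for b in self.blocks]}
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelGraph":
        doc = yaml.safe_load(text)
        blocks = [BlockSpec(d["index"], d["kind"], d.get("args", {}),
                            d.get("from", [-1])) for d in doc["layers"]]
        return cls(blocks, doc["nc"], tuple(doc.get("strides", STRIDES)))


# conv layers replaced by EHConv and C2f layers replaced by RC2f
EHCONV_SITES = (0, 1, 3, 5, 7, 16, 19)
RC2F_SITES = (2, 4, 6, 8, 12, 15, 18, 21)


def build_baseline(nc: int) -> ModelGraph:
    """The 23-layer baseline graph at class count `nc`."""
    if nc < 1:
        raise ValueError("nc must be >= 1")
    L = []

    def add(kind, args=None, frm=(-1,)):
        L.append(BlockSpec(len(L), kind, dict(args or {}), list(frm)))

    add("conv", dict(cin=3, cout=16, k=3, s=2))
    add("conv", dict(cin=16, cout=32, k=3, s=2))
    add("c2f", dict(cin=32, cout=32, n=1, shortcut=True))
    add("conv", dict(cin=32, cout=64, k=3, s=2))
    add("c2f", dict(cin=64, cout=64, n=2, shortcut=True))
    add("conv", dict(cin=64, cout=128, k=3, s=2))
    add("c2f", dict(cin=128, cout=128, n=2, shortcut=True))
    add("conv", dict(cin=128, cout=256, k=3, s=2))
    add("c2f", dict(cin=256, cout=256, n=1, shortcut=True))
    add("sppf", dict(cin=256, cout=256))
    add("upsample", dict(scale=2))
    add("concat", frm=(-1, 6))
    add("c2f", dict(cin=384, cout=128, n=1, shortcut=False))
    add("upsample", dict(scale=2))
    add("concat", frm=(-1, 4))
    add("c2f", dict(cin=192, cout=64, n=1, shortcut=False))
    add("conv", dict(cin=64, cout=64, k=3, s=2))
    add("concat", frm=(-1, 12))
    add("c2f", dict(cin=192, cout=128, n=1, shortcut=False))
    add("conv", dict(cin=128, cout=128, k=3, s=2))
    add("concat", frm=(-1, 9))
    add("c2f", dict(cin=384, cout=256, n=1, shortcut=False))
    add("detect", dict(nc=nc, chs=list(HEAD_CHANNELS)), frm=(15, 18, 21))
    return ModelGraph(L, nc)


def build_variant(flags: VariantFlags, nc: int) -> ModelGraph:
    """Patch the baseline graph according to the variant flags."""
    g = build_baseline(nc)
    if flags.esppf:
        g.blocks[9] = BlockSpec(9, "esppf", dict(cin=256, cout=256), [-1])
    if flags.ehconv:
        for i in EHCONV_SITES:
            a = g.blocks[i].args
            g.blocks[i] = BlockSpec(i, "ehconv",
                                    dict(cin=a["cin"], cout=a["cout"], k=3, s=2),
                                    list(g.blocks[i].from_))
    if flags.rc2f:
        for i in RC2F_SITES:
            a = g.blocks[i].args
            g.blocks[i] = BlockSpec(i, "rc2f", dict(cin=a["cin"], cout=a["cout"]),
                                    list(g.blocks[i].from_))
    if flags.pfdetect:
        g.blocks[22] = BlockSpec(22, "pfdetect", dict(nc=nc, chs=list(HEAD_CHANNELS)),
                                 [15, 18, 21])
    return g


def build_pfl_yolo(nc: int) -> ModelGraph:
    """The fully assembled PFL-YOLO graph (all four modules substituted)."""
    return build_variant(VariantFlags.all_true(), nc)


def trace_shapes(graph: ModelGraph, imgsz: int):
    """Channels and spatial size after every layer for a square input."""
    if imgsz % 32:
        raise ValueError("input size must be divisible by 32")
    shapes: list[tuple] = []
    inp = (3, imgsz, imgsz)
    for spec in graph.blocks:
        srcs = spec.resolve_from()
        ins = [inp if i == -1 else shapes[i] for i in srcs]
        if spec.kind in ("conv", "ehconv"):
            _, h, w = ins[0]
            s = spec.args.get("s", 2)
            out = (spec.args["cout"], h // s, w // s)
        elif spec.kind in ("c2f", "rc2f", "sppf", "esppf"):
            out = (spec.args["cout"], ins[0][1], ins[0][2])
        elif spec.kind == "upsample":
            sc = spec.args.get("scale", 2)
            out = (ins[0][0], ins[0][1] * sc, ins[0][2] * sc)
        elif spec.kind == "concat":
            if len({p[1:] for p in ins}) != 1:
                raise ValueError(f"layer {spec.index}: concat inputs have unequal spatial sizes")
            out = (sum(p[0] for p in ins), ins[0][1], ins[0][2])
        elif spec.kind in ("detect", "pfdetect"):
            out = (4 * B.REG_MAX + spec.args["nc"], 0, 0)
        else:
            raise ValueError(f"unknown layer kind {spec.kind!r}")
        shapes.append(out)
    return shapes


_KIND_BUILDERS = {
    "conv": lambda a, rng: B.ConvBlock(a["cin"], a["cout"], a.get("k", 3),
                                       a.get("s", 2), a.get("g", 1), rng=rng),
    "ehconv": lambda a, rng: B.EHConv(a["cin"], a["cout"], a.get("k", 3),
                                      a.get("s", 2), a.get("g"), rng=rng),
    "c2f": lambda a, rng: B.C2f(a["cin"], a["cout"], a.get("n", 1),
                                a.get("shortcut", False), rng=rng),
    "rc2f": lambda a, rng: B.RC2f(a["cin"], a["cout"], rng=rng),
    "sppf": lambda a, rng: B.SPPF(a["cin"], a["cout"], rng=rng),
    "esppf": lambda a, rng: B.ESPPF(a["cin"], a["cout"], rng=rng),
    "detect": lambda a, rng: B.Detect(a["nc"], tuple(a["chs"]), rng=rng),
    "pfdetect": lambda a, rng: B.PFDetect(a["nc"], tuple(a["chs"]), rng=rng),
}


class Model(B.Module):
    """An instantiated, runnable graph."""

    def __init__(self, graph: ModelGraph, seed: int = 0):
        super().__init__()
        self.graph = graph
        self.nc = graph.nc
        rng = np.random.default_rng(seed)
        self.layers = []
        for spec in graph.blocks:
            if spec.kind in ("upsample", "concat"):
                self.layers.append(None)
            else:
                self.layers.append(_KIND_BUILDERS[spec.kind](spec.args, rng))

    def forward(self, x: Tensor):
        """Run the graph; returns the per-scale raw head maps."""
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("input spatial size must be divisible by 32")
        outs: list = []
        for spec, mod in zip(self.graph.blocks, self.layers):
            srcs = spec.resolve_from()
            ins = [x if i == -1 else outs[i] for i in srcs]
            if spec.kind == "upsample":
                y = ad.upsample_nearest(ins[0], spec.args.get("scale", 2))
            elif spec.kind == "concat":
                y = ad.concat(ins, axis=1)
            elif spec.kind in ("detect", "pfdetect"):
                y = mod(ins)
            else:
                y = mod(ins[0])
            outs.append(y)
        self._layer_outputs = outs
        return outs[-1]

    def predict(self, x: Tensor):
        """Forward + decode: (boxes_xyxy_pixels, class_scores)."""
        raw = self.forward(x)
        return B.decode_head_outputs(raw, self.nc, self.graph.strides)

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data for name, p in self.named_parameters()}
        for i, mod in enumerate(self.layers):
            if mod is None:
                continue
            for sub_name, sub in _walk_modules(mod, f"layers.{i}"):
                if hasattr(sub, "running_mean"):
                    state[f"{sub_name}.running_mean"] = sub.running_mean
                    state[f"{sub_name}.running_var"] = sub.running_var
        return state

    def named_parameters(self, prefix: str = ""):
        for i, mod in enumerate(self.layers):
            if mod is None:
                continue
            yield from mod.named_parameters(f"{prefix}layers.{i}.")

    def save_weights(self, path, precision: str = "fp32"):
        dtype = np.float16 if precision == "fp16" else np.float32
        np.savez(path, **{k: v.astype(dtype) for k, v in self.state_dict().items()})

    def load_weights(self, path):
        with np.load(path) as z:
            state = {k: z[k] for k in z.files}
        for name, p in self.named_parameters():
            p.data = state[name].astype(np.float32)
        for i, mod in enumerate(self.layers):
            if mod is None:
                continue
            for sub_name, sub in _walk_modules(mod, f"layers.{i}"):
                if hasattr(sub, "running_mean"):
                    sub.running_mean = state[f"{sub_name}.running_mean"].astype(np.float32)
                    sub.running_var = state[f"{sub_name}.running_var"].astype(np.float32)


def _walk_modules(mod: B.Module, prefix: str):
    yield prefix, mod
    for name, v in mod.__dict__.items():
        if isinstance(v, B.Module):
            yield from _walk_modules(v, f"{prefix}.{name}")
        elif isinstance(v, (list, tuple)):
            stack = [(f"{prefix}.{name}.{j}", u) for j, u in enumerate(v)]
            for sub_prefix, u in stack:
                if isinstance(u, B.Module):
                    yield from _walk_modules(u, sub_prefix)
                elif isinstance(u, (list, tuple)):
                    stack.extend((f"{sub_prefix}.{j}", w) for j, w in enumerate(u))
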