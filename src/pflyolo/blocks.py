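"""Building blocks of the detector.

The baseline stage types of an anchor-free single-stage detector (Conv,
C2f, SPPF, Detect) and the four lightweight replacements that define
PFL-YOLO:

* **EHConv** — grouped 3x3 convolution -> efficient channel attention (ECA)
  -> batch norm -> Hardswish.
* **RC2f** — a Res2Net-style ladder: two 1x1 stem convolutions, a split
  into four channel groups with cumulative cross-group summation, a fusing
  1x1 convolution and ECA.
* **ESPPF** — SPPF with both 1x1 convolutions grouped and ECA on the output.
* **PFDetect** — a merged detection head: per-scale grouped 3x3 projector to
  a common width, two stem convolutions *shared across the three scales*
  (ECA between them, channel shuffle after), and grouped 1x1 box/class
  projections.

Every block reports its trainable-parameter count and FLOPs in closed form
(`param_count`, `flop_count`); the test-suite checks these against
introspection of the instantiated weight arrays.  The FLOP convention is
2 FLOPs per multiply-accumulate, convolutions (2-D and the 1-D ECA kernel)
only.
"""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

REG_MAX = 16  # distribution-focal bins per box edge


# ---------------------------------------------------------------------------
# small free functions
# ---------------------------------------------------------------------------

def eca_kernel_size(channels: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive 1-D kernel width for efficient channel attention.

    k = |log2(C)/gamma + b/gamma| rounded to the nearest odd integer,
    with a floor of 3.
    """
    if channels < 1:
        raise ValueError(f"channels must be >= 1, got {channels}")
    t = int(abs((math.log2(channels) + b) / gamma))
    k = t if t % 2 else t + 1
    return max(k, 3)


def hardswish_scalar(x: float) -> float:
    """Hardswish: 0 for x <= -3, x for x >= 3, x*(x+3)/6 between."""
    if x <= -3.0:
        return 0.0
    if x >= 3.0:
        return float(x)
    return x * (x + 3.0) / 6.0


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Permute channels by reshape (g, C/g) -> transpose -> flatten.

    Restores cross-group information flow after a grouped convolution;
    spatial content of every channel is untouched.
    """
    B, C, H, W = x.shape
    if groups < 1 or C % groups:
        raise ValueError(f"groups={groups} does not divide channels={C}")
    y = ad.reshape(x, (B, groups, C // groups, H, W))
    y = ad.transpose(y, (0, 2, 1, 3, 4))
    return ad.reshape(y, (B, C, H, W))


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """The channel permutation applied by `channel_shuffle`."""
    return np.arange(channels).reshape(groups, channels // groups).T.ravel()


def conv_params(cin: int, cout: int, k: int, groups: int = 1,
                bn: bool = True, bias: bool = False) -> int:
    """Closed-form trainable-parameter count of a (grouped) convolution."""
    if cin % groups or cout % groups:
        raise ValueError(f"groups={groups} must divide cin={cin} and cout={cout}")
    p = k * k * cin * cout // groups
    if bias:
        p += cout
    if bn:
        p += 2 * cout
    return p


def conv_flops(cin: int, cout: int, k: int, out_hw: int, groups: int = 1) -> int:
    """FLOPs of a (grouped) convolution: 2 x MACs = 2 k^2 Cin Cout HW / g."""
    return 2 * k * k * cin * cout // groups * out_hw


# ---------------------------------------------------------------------------
# module machinery
# ---------------------------------------------------------------------------

class Module:
    """Minimal container: attribute-discovered parameters and submodules."""

    def __init__(self):
        self.training = True

    def children(self):
        def flat(v):
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for u in v:
                    yield from flat(u)

        for v in self.__dict__.values():
            yield from flat(v)

    def named_parameters(self, prefix: str = ""):
        def walk(name, v):
            if isinstance(v, Tensor) and v.requires_grad:
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(name + ".")
            elif isinstance(v, (list, tuple)):
                for i, u in enumerate(v):
                    yield from walk(f"{name}.{i}", u)

        for name, v in self.__dict__.items():
            yield from walk(prefix + name, v)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_params(self) -> int:
        """Introspected parameter count (sum of weight-array sizes)."""
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for c in self.children():
            c.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)


def _kaiming(rng: np.random.Generator, cout, cin_g, k) -> np.ndarray:
    fan_in = cin_g * k * k
    std = math.sqrt(2.0 / fan_in)
    return (rng.standard_normal((cout, cin_g, k, k)) * std).astype(np.float32)


ACTS = {"silu": ad.silu, "hardswish": ad.hardswish, "none": lambda t: t, None: lambda t: t}


class ConvBlock(Module):
    """Convolution -> batch norm -> activation (the baseline Conv module)."""

    def __init__(self, cin, cout, k=1, s=1, g=1, act="silu", bn=True, bias=False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if cin % g or cout % g:
            raise ValueError(f"groups={g} must divide cin={cin} and cout={cout}")
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.s, self.g = cin, cout, k, s, g
        self.act, self.has_bn, self.has_bias = act, bn, bias
        self.weight = Tensor(_kaiming(rng, cout, cin // g, k), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None
        if bn:
            self.gamma = Tensor(np.ones(cout, np.float32), requires_grad=True)
            self.beta = Tensor(np.zeros(cout, np.float32), requires_grad=True)
            self.running_mean = np.zeros(cout, np.float32)
            self.running_var = np.ones(cout, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        y = ad.conv2d(x, self.weight, self.bias, stride=self.s, groups=self.g)
        if self.has_bn:
            y = ad.batch_norm2d(y, self.gamma, self.beta, self.running_mean,
                                self.running_var, self.training)
        return ACTS[self.act](y)

    def param_count(self) -> int:
        return conv_params(self.cin, self.cout, self.k, self.g, self.has_bn, self.has_bias)

    def flop_count(self, out_hw: int) -> int:
        return conv_flops(self.cin, self.cout, self.k, out_hw, self.g)


class ECA(Module):
    """Efficient channel attention: global average pool -> 1-D convolution of
    adaptive width across channels -> sigmoid -> per-channel rescaling."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.k = eca_kernel_size(channels)
        self.weight = Tensor((rng.standard_normal(self.k) / self.k).astype(np.float32),
                             requires_grad=True)

    def attention_weights(self, x: Tensor) -> Tensor:
        """Per-channel gate values in (0, 1), shape (B, C)."""
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        y = ad.global_avg_pool(x)
        y = ad.conv1d_channels(y, self.weight)
        return ad.sigmoid(y)

    def forward(self, x: Tensor) -> Tensor:
        w = self.attention_weights(x)
        B, C = w.shape
        return ad.mul(x, ad.reshape(w, (B, C, 1, 1)))

    def param_count(self) -> int:
        return self.k

    def flop_count(self, out_hw: int) -> int:
        return 2 * self.k * self.channels


class EHConv(Module):
    """Grouped convolution -> ECA -> batch norm -> Hardswish.

    The attention is applied to the raw convolution output (before
    normalisation), matching the stated layer order of the block; set
    `eca_before_bn=False` for the conventional post-norm placement.
    """

    def __init__(self, cin, cout, k=3, s=2, g=None, eca_before_bn=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if g is None:
            g = default_ehconv_groups(cin, cout)
        self.conv = ConvBlock(cin, cout, k, s, g, act="none", bn=False, rng=rng)
        self.eca = ECA(cout, rng=rng)
        self.eca_before_bn = eca_before_bn
        self.cout = cout
        self.gamma = Tensor(np.ones(cout, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(cout, np.float32), requires_grad=True)
        self.running_mean = np.zeros(cout, np.float32)
        self.running_var = np.ones(cout, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if self.eca_before_bn:
            y = self.eca(y)
        y = ad.batch_norm2d(y, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training)
        if not self.eca_before_bn:
            y = self.eca(y)
        return ad.hardswish(y)

    def param_count(self) -> int:
        return self.conv.param_count() + 2 * self.cout + self.eca.param_count()

    def flop_count(self, out_hw: int) -> int:
        return self.conv.flop_count(out_hw) + self.eca.flop_count(out_hw)


def _largest_divisor_le(n: int, cap: int) -> int:
    return max((d for d in range(1, n + 1) if n % d == 0 and d <= cap), default=1)


def default_ehconv_groups(cin: int, cout: int) -> int:
    """Calibrated group rule: the largest divisor of gcd(cin, cout) that does
    not exceed cout/4 (1 where no such divisor exists)."""
    return _largest_divisor_le(math.gcd(cin, cout), max(cout // 4, 1))


class Bottleneck(Module):
    """Two 3x3 convolutions with optional residual add (C2f inner block)."""

    def __init__(self, c: int, shortcut: bool = True, rng=None):
        super().__init__()
        self.cv1 = ConvBlock(c, c, 3, 1, rng=rng)
        self.cv2 = ConvBlock(c, c, 3, 1, rng=rng)
        self.add = shortcut

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return ad.add(x, y) if self.add else y

    def param_count(self) -> int:
        return self.cv1.param_count() + self.cv2.param_count()

    def flop_count(self, out_hw: int) -> int:
        return self.cv1.flop_count(out_hw) + self.cv2.flop_count(out_hw)


class C2f(Module):
    """Split-bottleneck fusion block: 1x1 expand, split in two, n bottlenecks
    chained on the second half, concat of all intermediates, 1x1 fuse."""

    def __init__(self, cin, cout, n=1, shortcut=False, rng=None):
        super().__init__()
        self.c = cout // 2
        self.n = n
        self.cv1 = ConvBlock(cin, 2 * self.c, 1, 1, rng=rng)
        self.cv2 = ConvBlock((2 + n) * self.c, cout, 1, 1, rng=rng)
        self.m = [Bottleneck(self.c, shortcut, rng=rng) for _ in range(n)]

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        parts = [ad.narrow(y, 1, 0, self.c), ad.narrow(y, 1, self.c, self.c)]
        for b in self.m:
            parts.append(b(parts[-1]))
        return self.cv2(ad.concat(parts, axis=1))

    def param_count(self) -> int:
        return (self.cv1.param_count() + self.cv2.param_count()
                + sum(b.param_count() for b in self.m))

    def flop_count(self, out_hw: int) -> int:
        return (self.cv1.flop_count(out_hw) + self.cv2.flop_count(out_hw)
                + sum(b.flop_count(out_hw) for b in self.m))


class SPPF(Module):
    """Fast spatial pyramid pooling: 1x1 reduce, three chained 5x5 stride-1
    max pools, concat of the four stages, 1x1 fuse."""

    def __init__(self, cin, cout, k=5, rng=None):
        super().__init__()
        c = cin // 2
        self.k = k
        self.cv1 = ConvBlock(cin, c, 1, 1, rng=rng)
        self.cv2 = ConvBlock(4 * c, cout, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(ad.max_pool2d_same(y[-1], self.k))
        return self.cv2(ad.concat(y, axis=1))

    def param_count(self) -> int:
        return self.cv1.param_count() + self.cv2.param_count()

    def flop_count(self, out_hw: int) -> int:
        return self.cv1.flop_count(out_hw) + self.cv2.flop_count(out_hw)


class ESPPF(Module):
    """SPPF with both 1x1 convolutions grouped and ECA filtering the output.

    Calibrated groups: cin/8 on the reduce conv, (4*cin/2)/8 on the fuse conv.
    """

    def __init__(self, cin, cout, k=5, g1=None, g2=None, rng=None):
        super().__init__()
        c = cin // 2
        self.k = k
        g1 = g1 if g1 is not None else max(cin // 8, 1)
        g2 = g2 if g2 is not None else max(4 * c // 8, 1)
        self.cv1 = ConvBlock(cin, c, 1, 1, g1, rng=rng)
        self.cv2 = ConvBlock(4 * c, cout, 1, 1, g2, rng=rng)
        self.eca = ECA(cout, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(ad.max_pool2d_same(y[-1], self.k))
        return self.eca(self.cv2(ad.concat(y, axis=1)))

    def param_count(self) -> int:
        return (self.cv1.param_count() + self.cv2.param_count()
                + self.eca.param_count())

    def flop_count(self, out_hw: int) -> int:
        return (self.cv1.flop_count(out_hw) + self.cv2.flop_count(out_hw)
                + self.eca.flop_count(out_hw))


class RC2f(Module):
    """Res2Net-style replacement for C2f.

    Two 1x1 stem convolutions produce m = 3*cin/4 channels, split into four
    equal groups x1..x4; y1 = x1 and, for i >= 2, yi = Ti(xi + y_{i-1})
    where Ti is a grouped 3x3 convolution.  The concatenated ladder is fused
    by a grouped 1x1 convolution and re-weighted by ECA.
    """

    def __init__(self, cin, cout, e=0.75, ladder_groups=2, fuse_groups=2, rng=None):
        super().__init__()
        m = int(cin * e)
        if m % 4:
            raise ValueError(f"hidden width {m} not divisible into 4 groups")
        self.m, self.q = m, m // 4
        lg = _largest_divisor_le(self.q, ladder_groups)
        self.stem1 = ConvBlock(cin, m, 1, 1, rng=rng)
        self.stem2 = ConvBlock(m, m, 1, 1, rng=rng)
        self.ladder = [ConvBlock(self.q, self.q, 3, 1, lg, rng=rng)
                       for _ in range(3)]
        self.fuse = ConvBlock(m, cout, 1, 1, fuse_groups, rng=rng)
        self.eca = ECA(cout, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.stem2(self.stem1(x))
        xs = [ad.narrow(y, 1, i * self.q, self.q) for i in range(4)]
        ys = [xs[0]]
        for i in range(1, 4):
            ys.append(self.ladder[i - 1](ad.add(xs[i], ys[-1])))
        return self.eca(self.fuse(ad.concat(ys, axis=1)))

    def param_count(self) -> int:
        return (self.stem1.param_count() + self.stem2.param_count()
                + sum(t.param_count() for t in self.ladder)
                + self.fuse.param_count() + self.eca.param_count())

    def flop_count(self, out_hw: int) -> int:
        return (self.stem1.flop_count(out_hw) + self.stem2.flop_count(out_hw)
                + sum(t.flop_count(out_hw) for t in self.ladder)
                + self.fuse.flop_count(out_hw) + self.eca.flop_count(out_hw))


# ---------------------------------------------------------------------------
# detection heads
# ---------------------------------------------------------------------------

def _dfl_kernel() -> np.ndarray:
    return np.arange(REG_MAX, dtype=np.float32).reshape(1, REG_MAX, 1, 1)


def dfl_expectation(box_logits: Tensor) -> Tensor:
    """Decode distribution-focal logits (B, 4*REG_MAX, L) to expected edge
    distances (B, 4, L) in stride units."""
    B = box_logits.shape[0]
    L = box_logits.shape[-1]
    y = ad.reshape(box_logits, (B, 4, REG_MAX, L))
    p = ad.softmax(y, axis=2)
    bins = np.arange(REG_MAX, dtype=np.float32).reshape(1, 1, REG_MAX, 1)
    return ad.sum_(ad.mul(p, Tensor(bins)), axis=2)


def make_anchors(hw_list, strides, offset=0.5):
    """Grid-cell centres (in pixels) and per-cell strides for each scale."""
    pts, strs = [], []
    for (h, w), s in zip(hw_list, strides):
        sx = (np.arange(w, dtype=np.float32) + offset) * s
        sy = (np.arange(h, dtype=np.float32) + offset) * s
        gx, gy = np.meshgrid(sx, sy)
        pts.append(np.stack([gx.ravel(), gy.ravel()], axis=-1))
        strs.append(np.full(h * w, s, np.float32))
    return np.concatenate(pts), np.concatenate(strs)


class Detect(Module):
    """Baseline decoupled anchor-free head: per scale a 3x3+3x3+1x1 box
    branch (4*REG_MAX channels, distribution-focal bins) and a like class
    branch (nc channels)."""

    def __init__(self, nc, chs=(64, 128, 256), rng=None):
        super().__init__()
        self.nc, self.chs = nc, tuple(chs)
        self.no = 4 * REG_MAX + nc
        c2 = max(16, chs[0] // 4, REG_MAX * 4)
        c3 = max(chs[0], min(nc, 100))
        self.c2, self.c3 = c2, c3
        rng = rng or np.random.default_rng(0)
        self.box_branch = [
            [ConvBlock(ch, c2, 3, 1, rng=rng), ConvBlock(c2, c2, 3, 1, rng=rng),
             ConvBlock(c2, 4 * REG_MAX, 1, 1, act="none", bn=False, bias=True, rng=rng)]
            for ch in chs]
        self.cls_branch = [
            [ConvBlock(ch, c3, 3, 1, rng=rng), ConvBlock(c3, c3, 3, 1, rng=rng),
             ConvBlock(c3, nc, 1, 1, act="none", bn=False, bias=True, rng=rng)]
            for ch in chs]
        # fixed integral kernel: counted as a parameter, excluded from updates
        self.dfl_weight = Tensor(_dfl_kernel(), requires_grad=True, trainable=False)

    def forward(self, maps):
        if len(maps) != len(self.chs):
            raise ValueError(f"expected {len(self.chs)} scales, got {len(maps)}")
        outs = []
        for x, bb, cb in zip(maps, self.box_branch, self.cls_branch):
            b = x
            for m in bb:
                b = m(b)
            c = x
            for m in cb:
                c = m(c)
            outs.append(ad.concat([b, c], axis=1))
        return outs

    def param_count(self) -> int:
        p = REG_MAX  # fixed DFL kernel, counted by convention
        for branch in (self.box_branch, self.cls_branch):
            for mods in branch:
                p += sum(m.param_count() for m in mods)
        return p

    def flop_count(self, hw_list) -> int:
        f = 0
        for hw, bb, cb in zip(hw_list, self.box_branch, self.cls_branch):
            n = hw[0] * hw[1]
            f += sum(m.flop_count(n) for m in bb) + sum(m.flop_count(n) for m in cb)
        return f


class PFDetect(Module):
    """Merged lightweight head.

    Each scale is first projected by its own grouped 3x3 convolution to a
    common width; two further 3x3 grouped convolutions — their weights
    shared by all three scales — refine the feature, with ECA between them
    and a channel shuffle after the grouped second stem.  Grouped 1x1
    convolutions (shared across scales) emit the 4*REG_MAX box-bin channels
    and nc class channels.  Decoding is identical to the baseline head.

    Defaults are the calibrated configuration (width 48, projector groups
    (2, 8, 4), stem groups (3, 8), head groups 4).
    """

    def __init__(self, nc, chs=(64, 128, 256), width=48, proj_groups=(2, 8, 4),
                 stem_groups=(3, 8), head_groups=4, shuffle_groups=None, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.nc, self.chs, self.width = nc, tuple(chs), width
        self.no = 4 * REG_MAX + nc
        self.proj = [ConvBlock(ch, width, 3, 1, g, act="hardswish", rng=rng)
                     for ch, g in zip(chs, proj_groups)]
        self.stem1 = ConvBlock(width, width, 3, 1, stem_groups[0], act="hardswish", rng=rng)
        self.eca = ECA(width, rng=rng)
        self.stem2 = ConvBlock(width, width, 3, 1, stem_groups[1], act="hardswish", rng=rng)
        self.shuffle_groups = shuffle_groups or stem_groups[1]
        self.head_groups = head_groups
        cls_g = _largest_divisor_le(math.gcd(width, nc), head_groups)
        self.box_head = ConvBlock(width, 4 * REG_MAX, 1, 1, head_groups,
                                  act="none", bn=False, bias=True, rng=rng)
        self.cls_head = ConvBlock(width, nc, 1, 1, cls_g,
                                  act="none", bn=False, bias=True, rng=rng)
        self.dfl_weight = Tensor(_dfl_kernel(), requires_grad=True, trainable=False)

    def forward(self, maps):
        if len(maps) != len(self.chs):
            raise ValueError(f"expected {len(self.chs)} scales, got {len(maps)}")
        outs = []
        for x, proj in zip(maps, self.proj):
            y = proj(x)
            y = self.stem1(y)
            y = self.eca(y)
            y = self.stem2(y)
            y = channel_shuffle(y, self.shuffle_groups)
            outs.append(ad.concat([self.box_head(y), self.cls_head(y)], axis=1))
        return outs

    def param_count(self) -> int:
        p = REG_MAX + self.eca.param_count()
        p += sum(m.param_count() for m in self.proj)
        p += self.stem1.param_count() + self.stem2.param_count()
        p += self.box_head.param_count() + self.cls_head.param_count()
        return p

    def flop_count(self, hw_list) -> int:
        f = 0
        for hw, proj in zip(hw_list, self.proj):
            n = hw[0] * hw[1]
            f += proj.flop_count(n) + self.stem1.flop_count(n) + self.eca.flop_count(n)
            f += self.stem2.flop_count(n) + self.box_head.flop_count(n)
            f += self.cls_head.flop_count(n)
        return f


def decode_head_outputs(raw_maps, nc: int, strides=(8, 16, 32)):
    """Decode per-scale raw maps into (B, L, 4+nc): xyxy boxes in pixels and
    per-class sigmoid scores, via distribution-focal expectation."""
    B = raw_maps[0].shape[0]
    hw_list = [(m.shape[2], m.shape[3]) for m in raw_maps]
    anchors, strs = make_anchors(hw_list, strides)
    flat = ad.concat([ad.reshape(m, (B, m.shape[1], -1)) for m in raw_maps], axis=2)
    box_logits = ad.narrow(flat, 1, 0, 4 * REG_MAX)
    cls_logits = ad.narrow(flat, 1, 4 * REG_MAX, nc)
    d = dfl_expectation(box_logits)            # (B, 4, L) stride units: l,t,r,b
    dist = d.data * strs                       # pixels
    x1 = anchors[:, 0] - dist[:, 0]
    y1 = anchors[:, 1] - dist[:, 1]
    x2 = anchors[:, 0] + dist[:, 2]
    y2 = anchors[:, 1] + dist[:, 3]
    boxes = np.stack([x1, y1, x2, y2], axis=-1)            # (B, L, 4)
    scores = 1.0 / (1.0 + np.exp(-cls_logits.data))        # (B, nc, L)
    return boxes, np.transpose(scores, (0, 2, 1))
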