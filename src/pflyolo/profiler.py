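"""Per-layer parameter and FLOP accounting.

Counts are closed-form functions of the layer specifications — never read
off instantiated arrays — so they can serve as an independent check of the
built network (the test-suite compares both routes).

Conventions (chosen to reproduce the reference budgets, and stated in the
project methods note):

* FLOPs = 2 x multiply-accumulates, convolutions only (2-D convolutions and
  the 1-D ECA kernel); pooling, upsampling, concatenation, activations and
  normalisation are counted as zero.
* Trainable parameters include batch-norm affine pairs (2C) and the fixed
  16-weight distribution-focal kernel; batch-norm running statistics are
  excluded.
* Serialized size = params x bytes-per-value / 1e6 + a fixed 0.1 MB
  container overhead.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import math

import pandas as pd

from . import blocks as B
from .assembly import BlockSpec, ModelGraph, trace_shapes

SIZE_OVERHEAD_MB = 0.1
BYTES = {"fp16": 2, "fp32": 4}


# ---------------------------------------------------------------------------
# closed-form per-kind counts
# ---------------------------------------------------------------------------

def _conv_pc(a):
    return B.conv_params(a["cin"], a["cout"], a.get("k", 3), a.get("g", 1))


def _ehconv_pc(a):
    g = a.get("g") or B.default_ehconv_groups(a["cin"], a["cout"])
    return (B.conv_params(a["cin"], a["cout"], a.get("k", 3), g)
            + B.eca_kernel_size(a["cout"]))


def _c2f_pc(a):
    c = a["cout"] // 2
    n = a.get("n", 1)
    p = B.conv_params(a["cin"], 2 * c, 1) + B.conv_params((2 + n) * c, a["cout"], 1)
    p += n * 2 * B.conv_params(c, c, 3)
    return p


def _rc2f_pc(a, e=0.75, gl=2, gf=2):
    m = int(a["cin"] * e)
    q = m // 4
    p = B.conv_params(a["cin"], m, 1) + B.conv_params(m, m, 1)
    p += 3 * B.conv_params(q, q, 3, gl)
    p += B.conv_params(m, a["cout"], 1, gf) + B.eca_kernel_size(a["cout"])
    return p


def _sppf_pc(a):
    c = a["cin"] // 2
    return B.conv_params(a["cin"], c, 1) + B.conv_params(4 * c, a["cout"], 1)


def _esppf_pc(a):
    c = a["cin"] // 2
    g1, g2 = max(a["cin"] // 8, 1), max(4 * c // 8, 1)
    return (B.conv_params(a["cin"], c, 1, g1) + B.conv_params(4 * c, a["cout"], 1, g2)
            + B.eca_kernel_size(a["cout"]))


def _detect_pc(a):
    nc, chs = a["nc"], a["chs"]
    c2 = max(16, chs[0] // 4, B.REG_MAX * 4)
    c3 = max(chs[0], min(nc, 100))
    p = B.REG_MAX
    for ch in chs:
        p += B.conv_params(ch, c2, 3) + B.conv_params(c2, c2, 3)
        p += B.conv_params(c2, 4 * B.REG_MAX, 1, bn=False, bias=True)
        p += B.conv_params(ch, c3, 3) + B.conv_params(c3, c3, 3)
        p += B.conv_params(c3, nc, 1, bn=False, bias=True)
    return p


def _pfdetect_pc(a, width=48, proj_groups=(2, 8, 4), stem_groups=(3, 8), gh=4):
    nc, chs = a["nc"], a["chs"]
    cls_g = B._largest_divisor_le(math.gcd(width, nc), gh)
    p = B.REG_MAX + B.eca_kernel_size(width)
    for ch, g in zip(chs, proj_groups):
        p += B.conv_params(ch, width, 3, g)
    p += B.conv_params(width, width, 3, stem_groups[0])
    p += B.conv_params(width, width, 3, stem_groups[1])
    p += B.conv_params(width, 4 * B.REG_MAX, 1, gh, bn=False, bias=True)
    p += B.conv_params(width, nc, 1, cls_g, bn=False, bias=True)
    return p


_PARAM_COUNTERS = {
    "conv": _conv_pc, "ehconv": _ehconv_pc, "c2f": _c2f_pc, "rc2f": _rc2f_pc,
    "sppf": _sppf_pc, "esppf": _esppf_pc, "detect": _detect_pc,
    "pfdetect": _pfdetect_pc, "upsample": lambda a: 0, "concat": lambda a: 0,
}


def _head_grids(imgsz, strides=(8, 16, 32)):
    return [(imgsz // s, imgsz // s) for s in strides]


def _flops_of(spec: BlockSpec, out_hw: int, imgsz: int):
    a = spec.args
    k = spec.kind
    cf, ek = B.conv_flops, B.eca_kernel_size
    if k == "conv":
        return cf(a["cin"], a["cout"], a.get("k", 3), out_hw, a.get("g", 1))
    if k == "ehconv":
        g = a.get("g") or B.default_ehconv_groups(a["cin"], a["cout"])
        return (cf(a["cin"], a["cout"], a.get("k", 3), out_hw, g)
                + 2 * ek(a["cout"]) * a["cout"])
    if k == "c2f":
        c = a["cout"] // 2
        n = a.get("n", 1)
        return (cf(a["cin"], 2 * c, 1, out_hw) + cf((2 + n) * c, a["cout"], 1, out_hw)
                + n * 2 * cf(c, c, 3, out_hw))
    if k == "rc2f":
        m = int(a["cin"] * 0.75)
        q = m // 4
        return (cf(a["cin"], m, 1, out_hw) + cf(m, m, 1, out_hw)
                + 3 * cf(q, q, 3, out_hw, 2) + cf(m, a["cout"], 1, out_hw, 2)
                + 2 * ek(a["cout"]) * a["cout"])
    if k == "sppf":
        c = a["cin"] // 2
        return cf(a["cin"], c, 1, out_hw) + cf(4 * c, a["cout"], 1, out_hw)
    if k == "esppf":
        c = a["cin"] // 2
        g1, g2 = max(a["cin"] // 8, 1), max(4 * c // 8, 1)
        return (cf(a["cin"], c, 1, out_hw, g1) + cf(4 * c, a["cout"], 1, out_hw, g2)
                + 2 * ek(a["cout"]) * a["cout"])
    if k == "detect":
        nc, chs = a["nc"], a["chs"]
        c2 = max(16, chs[0] // 4, B.REG_MAX * 4)
        c3 = max(chs[0], min(nc, 100))
        f = 0
        for ch, (h, w) in zip(chs, _head_grids(imgsz)):
            n = h * w
            f += cf(ch, c2, 3, n) + cf(c2, c2, 3, n) + cf(c2, 4 * B.REG_MAX, 1, n)
            f += cf(ch, c3, 3, n) + cf(c3, c3, 3, n) + cf(c3, nc, 1, n)
        return f
    if k == "pfdetect":
        nc, chs = a["nc"], a["chs"]
        W, pg, sg, gh = 48, (2, 8, 4), (3, 8), 4
        cls_g = B._largest_divisor_le(math.gcd(W, nc), gh)
        f = 0
        for ch, g, (h, w) in zip(chs, pg, _head_grids(imgsz)):
            n = h * w
            f += cf(ch, W, 3, n, g) + cf(W, W, 3, n, sg[0]) + cf(W, W, 3, n, sg[1])
            f += cf(W, 4 * B.REG_MAX, 1, n, gh) + cf(W, nc, 1, n, cls_g)
            f += 2 * B.eca_kernel_size(W) * W
        return f
    return 0  # upsample / concat


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ProfileReport:
    """Per-layer and total parameter/FLOP budget at a stated input size."""
    rows: list[dict]
    input_size: int

    @property
    def total_params(self) -> int:
        return sum(r["params"] for r in self.rows)

    @property
    def total_flops(self) -> int:
        return sum(r["flops"] for r in self.rows)

    @property
    def params_million(self) -> float:
        return self.total_params / 1e6

    @property
    def flops_g(self) -> float:
        return self.total_flops / 1e9

    def size_mb(self, precision: str = "fp16") -> float:
        return size_estimate(self.total_params, precision)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path=None):
        doc = {"input_size": self.input_size, "rows": self.rows,
               "totals": {"params": self.total_params, "flops": self.total_flops,
                          "size_mb_fp16": self.size_mb("fp16"),
                          "size_mb_fp32": self.size_mb("fp32")}}
        if path is None:
            return json.dumps(doc, indent=2)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def count_params(graph: ModelGraph) -> list[dict]:
    """Per-layer trainable-parameter counts (exact integers, closed form)."""
    return [{"index": s.index, "kind": s.kind,
             "params": _PARAM_COUNTERS[s.kind](s.args)} for s in graph.blocks]


def count_flops(graph: ModelGraph, input_size: int = 640) -> list[dict]:
    """Per-layer FLOPs under the 2-FLOPs-per-MAC convolution convention."""
    if input_size % 32:
        raise ValueError("input size must be divisible by 32")
    shapes = trace_shapes(graph, input_size)
    rows = []
    for spec, (c, h, w) in zip(graph.blocks, shapes):
        rows.append({"index": spec.index, "kind": spec.kind,
                     "flops": _flops_of(spec, h * w, input_size)})
    return rows


def profile(graph: ModelGraph, input_size: int = 640) -> ProfileReport:
    pr = count_params(graph)
    fr = count_flops(graph, input_size)
    rows = [{"index": p["index"], "kind": p["kind"], "params": p["params"],
             "flops": f["flops"]} for p, f in zip(pr, fr)]
    return ProfileReport(rows, input_size)


def size_estimate(params: int, precision: str = "fp16") -> float:
    """Serialized model size in MB: params x bytes / 1e6 + fixed overhead."""
    return params * BYTES[precision] / 1e6 + SIZE_OVERHEAD_MB


def diff_against_reference(report: ProfileReport, reference: pd.DataFrame,
                           rel_tol: float = 0.01) -> pd.DataFrame:
    """Per-layer deviations of a report from a reference budget table.

    `reference` needs columns index, params (and optionally flops).  Returns
    a frame with absolute and relative deviations and a `flagged` column for
    layers exceeding `rel_tol`.
    """
    mine = report.to_dataframe().set_index("index")
    ref = reference.set_index("index")
    if not mine.index.equals(ref.index):
        raise ValueError("layer indexing mismatch between report and reference")
    out = pd.DataFrame(index=mine.index)
    for col in ("params", "flops"):
        if col not in ref.columns:
            continue
        out[f"{col}_abs_dev"] = mine[col] - ref[col]
        denom = ref[col].where(ref[col] != 0, 1)
        out[f"{col}_rel_dev"] = (mine[col] - ref[col]) / denom
    rel_cols = [c for c in out.columns if c.endswith("_rel_dev")]
    out["flagged"] = (out[rel_cols].abs() > rel_tol).any(axis=1)
    return out.reset_index()


def load_reference_budget(which: str = "baseline") -> pd.DataFrame:
    """The shipped per-layer reference budget (params and FLOPs at 640)."""
    src = importlib.resources.files("pflyolo.configs") / "reference_budgets.csv"
    df = pd.read_csv(src, comment="#")
    df = df[df["model"] == which].drop(columns=["model"])
    if df.empty:
        raise ValueError(f"unknown reference model {which!r}")
    return df.reset_index(drop=True)


def load_printed_budgets() -> pd.DataFrame:
    """The published variant-level budget table (params M, FLOPs G, size MB)."""
    src = importlib.resources.files("pflyolo.configs") / "printed_budgets.csv"
    return pd.read_csv(src, comment="#")
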