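"""Metric formulas against enumeration oracles; Grad-CAM and heatmap-area
contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pflyolo import evaluation as ev
from pflyolo import synthetic as syn
from pflyolo.evaluation import ConfusionCounts


# ---------------------------------------------------------------------------
# IoU and matching
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a,b,expected", [
    ((0, 0, 2, 2), (0, 0, 2, 2), 1.0),
    ((0, 0, 1, 1), (2, 2, 3, 3), 0.0),
    ((0, 0, 2, 2), (1, 1, 3, 3), 1 / 7),
    ((0, 0, 0, 0), (0, 0, 0, 0), 0.0),   # degenerate union
])
def test_iou_examples(a, b, expected):
    assert ev.iou(a, b) == pytest.approx(expected)


def test_match_perfect_predictions():
    gts = [("im", 0, (0, 0, 10, 10)), ("im", 1, (20, 20, 30, 30))]
    preds = [("im", 0, 0.9, (0, 0, 10, 10)), ("im", 1, 0.8, (20, 20, 30, 30))]
    c = ev.match_and_count(preds, gts)
    assert (c.tp, c.fp, c.fn) == (2, 0, 0)


def test_match_no_predictions_all_fn():
    gts = [("im", 0, (0, 0, 10, 10))] * 0 + [("im", 0, (0, 0, 10, 10)),
                                             ("im", 0, (5, 5, 9, 9))]
    c = ev.match_and_count([], gts)
    assert (c.tp, c.fp, c.fn) == (0, 0, 2)


def test_match_one_to_one_rule():
    """Two class-correct predictions on one truth: only the higher-confidence
    one matches."""
    gts = [("im", 0, (0, 0, 10, 10))]
    preds = [("im", 0, 0.9, (0, 0, 10, 9)),    # IoU 0.9
             ("im", 0, 0.8, (0, 0, 10, 8))]    # IoU 0.8
    c = ev.match_and_count(preds, gts)
    assert (c.tp, c.fp, c.fn) == (1, 1, 0)


def test_match_wrong_class_is_fp():
    gts = [("im", 1, (0, 0, 10, 10))]
    preds = [("im", 0, 0.9, (0, 0, 10, 10))]
    c = ev.match_and_count(preds, gts)
    assert (c.tp, c.fp, c.fn) == (0, 1, 1)


# ---------------------------------------------------------------------------
# P/R/F1
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p,r,expected", [
    (98.5, 98.8, 98.65), (98.9, 99.0, 98.95), (99.7, 99.6, 99.65),
])
def test_f1_reproduces_published_values(p, r, expected):
    assert round(ev.f1_score(p, r), 2) == expected


def test_f1_fixed_point_when_p_equals_r():
    assert ev.f1_score(0.7, 0.7) == pytest.approx(0.7)


def test_precision_recall_f1_zero_conventions():
    p, r, f1 = ev.precision_recall_f1(ConfusionCounts(0, 0, 0))
    assert (p, r, f1) == (0.0, 0.0, 0.0)
    p, r, f1 = ev.precision_recall_f1(ConfusionCounts(3, 1, 2))
    assert p == pytest.approx(0.75) and r == pytest.approx(0.6)
    assert f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)


# ---------------------------------------------------------------------------
# average precision
# ---------------------------------------------------------------------------

def brute_force_ap(tp_flags, confs, n_gt):
    """Rectangle-sum oracle: enumerate PR points in confidence order, apply
    the monotone envelope, sum width x envelope-height over recall steps."""
    order = np.argsort(-np.asarray(confs, dtype=float), kind="stable")
    flags = [tp_flags[i] for i in order]
    points = []
    tp = fp = 0
    for f in flags:
        tp += f
        fp += 1 - f
        points.append((tp / n_gt, tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for i, (r, _p) in enumerate(points):
        if r > prev_r:
            env = max(q for (rr, q) in points if rr >= r - 1e-12)
            ap += (r - prev_r) * env
            prev_r = r
    return ap


def test_ap_all_correct_is_one():
    assert ev.average_precision([1, 1, 1], [0.3, 0.9, 0.5], 3) == pytest.approx(1.0)


def test_ap_no_tp_is_zero():
    assert ev.average_precision([0, 0], [0.9, 0.8], 2) == 0.0
    assert ev.average_precision([], [], 3) == 0.0


def test_ap_toy_example_matches_oracle():
    flags, confs = [1, 0, 1], [0.9, 0.8, 0.7]
    expected = brute_force_ap(flags, confs, 2)
    assert expected == pytest.approx(5 / 6)
    assert ev.average_precision(flags, confs, 2) == pytest.approx(expected)


@given(st.lists(st.tuples(st.integers(0, 1), st.floats(0.01, 0.99)),
                min_size=1, max_size=12))
@settings(deadline=None, max_examples=60)
def test_ap_matches_oracle_on_random_sets(pairs):
    flags = [f for f, _ in pairs]
    confs = [c for _, c in pairs]
    n_gt = max(sum(flags), 1) + 1
    got = ev.average_precision(flags, confs, n_gt)
    assert got == pytest.approx(brute_force_ap(flags, confs, n_gt), abs=1e-9)


def test_envelope_ap_not_below_raw_trapezoid():
    flags, confs = [1, 0, 0, 1, 0, 1], [0.9, 0.85, 0.8, 0.7, 0.6, 0.5]
    n_gt = 4
    order = np.argsort(-np.asarray(confs))
    tp = np.cumsum([flags[i] for i in order])
    fp = np.cumsum([1 - flags[i] for i in order])
    rec = tp / n_gt
    prec = tp / (tp + fp)
    raw = np.trapezoid(prec, rec)
    assert ev.average_precision(flags, confs, n_gt) >= raw - 1e-12


def test_map_invariant_to_input_order(rng):
    gts = [(f"im{i}", i % 2, (0, 0, 10, 10)) for i in range(6)]
    preds = [(f"im{i}", i % 2, rng.uniform(0.3, 0.9), (0, 0, 10, 9 + (i % 3)))
             for i in range(6)]
    a = ev.map_at(preds, gts)
    perm = list(reversed(range(6)))
    b = ev.map_at([preds[i] for i in perm], gts)
    assert a.map50 == pytest.approx(b.map50)
    assert a.map5095 == pytest.approx(b.map5095)


def test_single_confidence_perfect_detector_all_ones(tmp_path):
    gts = [(f"im{i}", 0, (0, 0, 10, 10)) for i in range(4)]
    preds = [(f"im{i}", 0, 0.7, (0, 0, 10, 10)) for i in range(4)]
    res = ev.map_at(preds, gts)
    assert (res.precision, res.recall, res.f1, res.map50) == (1, 1, 1, 1)
    assert res.map5095 == pytest.approx(1.0)
    doc = res.to_json()
    assert '"map50": 1' in doc
    res.to_csv(tmp_path / "ap.csv")
    assert (tmp_path / "ap.csv").exists()


def test_map_sampled_variant_close_to_exact():
    gts = [("im", 0, (0, 0, 10, 10)), ("im", 0, (20, 0, 30, 10))]
    preds = [("im", 0, 0.9, (0, 0, 10, 10)), ("im", 0, 0.7, (20, 0, 30, 10)),
             ("im", 0, 0.8, (50, 50, 60, 60))]
    exact = ev.map_at(preds, gts)
    sampled = ev.map_at(preds, gts, sampled=True)
    assert abs(exact.map50 - sampled.map50) < 0.02


# ---------------------------------------------------------------------------
# NMS and timing
# ---------------------------------------------------------------------------

def test_nms_suppresses_overlaps():
    boxes = np.array([(0, 0, 10, 10), (1, 1, 11, 11), (30, 30, 40, 40)], float)
    keep = ev.nms(boxes, np.array([0.9, 0.8, 0.7]), iou_thr=0.45)
    assert keep == [0, 2]


@pytest.mark.parametrize("ts,dt,fps", [([10, 10, 10], 10.0, 100.0),
                                       ([5, 15], 10.0, 100.0),
                                       ([11.2], 11.2, 1000 / 11.2)])
def test_timing_mean_and_reciprocal(ts, dt, fps):
    stats = ev.timing(ts)
    assert stats.dt_ms == pytest.approx(dt)
    assert stats.fps == pytest.approx(fps)
    assert round(1000 / 11.2, 1) == 89.3


def test_timing_rejects_empty():
    with pytest.raises(ValueError):
        ev.timing([])


# ---------------------------------------------------------------------------
# heatmap area
# ---------------------------------------------------------------------------

def test_aoi_rectangle_fixture():
    hm = syn.gen_heatmap((200, 220), [{"kind": "rect", "row": 10, "col": 20,
                                       "height": 100, "width": 150}])
    area = ev.aoi_area(hm, threshold=128)
    # contour convention: level-0.5 contours cut each convex corner, so a
    # solid n-pixel rectangle measures n - 0.5
    assert area == pytest.approx(15000, abs=1.0)


def test_aoi_empty_and_additive():
    assert ev.aoi_area(np.zeros((30, 30))) == 0.0
    two = syn.gen_heatmap((200, 200), [
        {"kind": "rect", "row": 10, "col": 10, "height": 50, "width": 40},
        {"kind": "rect", "row": 120, "col": 120, "height": 30, "width": 30}])
    single_a = ev.aoi_area(syn.gen_heatmap((200, 200), [
        {"kind": "rect", "row": 10, "col": 10, "height": 50, "width": 40}]),
        threshold=128)
    single_b = ev.aoi_area(syn.gen_heatmap((200, 200), [
        {"kind": "rect", "row": 120, "col": 120, "height": 30, "width": 30}]),
        threshold=128)
    assert ev.aoi_area(two, threshold=128) == pytest.approx(single_a + single_b)


def test_aoi_monotone_under_region_growth():
    small = syn.gen_heatmap((100, 100), [{"kind": "rect", "row": 20, "col": 20,
                                          "height": 20, "width": 20}])
    big = syn.gen_heatmap((100, 100), [{"kind": "rect", "row": 20, "col": 20,
                                        "height": 30, "width": 30}])
    assert ev.aoi_area(big, threshold=128) > ev.aoi_area(small, threshold=128)


def test_aoi_half_pixel_values_possible():
    hm = syn.gen_heatmap((64, 64), [{"kind": "ellipse", "row": 30, "col": 30,
                                     "r_radius": 10, "c_radius": 6}])
    area = ev.aoi_area(hm, threshold=128)
    assert area == pytest.approx(round(area * 2) / 2)


def test_aoi_accepts_three_channel_maps():
    hm = syn.gen_heatmap((50, 50), [{"kind": "rect", "row": 5, "col": 5,
                                     "height": 10, "width": 10}])
    rgb = np.stack([hm] * 3, axis=-1)
    assert ev.aoi_area(rgb, threshold=128) == ev.aoi_area(hm, threshold=128)


# ---------------------------------------------------------------------------
# Grad-CAM contracts (cheap model)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_model():
    from pflyolo.assembly import Model, build_pfl_yolo
    return Model(build_pfl_yolo(2), seed=0)


def test_gradcam_range_and_shape(tiny_model, rng):
    img = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
    cam = ev.gradcam_map(tiny_model, img, target_layer=15)
    assert cam.shape == (64, 64)
    assert cam.min() >= 0 and cam.max() <= 255


def test_gradcam_zero_input_zero_map(tiny_model):
    cam = ev.gradcam_map(tiny_model, np.zeros((64, 64, 3), np.uint8), 15)
    assert cam.max() == 0.0


def test_gradcam_rejects_bad_layer(tiny_model, rng):
    with pytest.raises(ValueError):
        ev.gradcam_map(tiny_model, rng.integers(0, 255, (64, 64, 3),
                                                dtype=np.uint8), 99)
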