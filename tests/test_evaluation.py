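"""IoU, confusion counts, derived metrics, F-beta and the threshold grid search."""

import numpy as np
import pytest

from nestseg.evaluation import (
    ConfusionCounts,
    SelectionConfig,
    confusion_counts,
    f_beta,
    grid_search_thresholds,
    iou,
    metrics_from_counts,
    sectionwise_metrics,
)
from nestseg.pipeline import Heatmap

# reference test-set composition and error counts used across the metric tests
TEST_COUNTS = ConfusionCounts(tp=1078, fp=30, tn=813, fn=41)


def labels_from_counts(c: ConfusionCounts):
    truth = ["Tumor"] * (c.tp + c.fn) + ["Normal"] * (c.tn + c.fp)
    pred = (["Tumor"] * c.tp + ["Normal"] * c.fn
            + ["Normal"] * c.tn + ["Tumor"] * c.fp)
    return pred, truth


class TestIoU:
    def test_identical_masks(self):
        m = np.zeros((4, 4), bool)
        m[1:3, 1:3] = True
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0], b[3, 3] = True, True
        assert iou(a, b) == 0.0

    def test_partial_overlap(self):
        a = np.zeros((2, 2), bool)
        b = np.zeros((2, 2), bool)
        a[0, 0] = a[0, 1] = True
        b[0, 1] = b[1, 1] = True
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_both_empty_is_one(self):
        assert iou(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            iou(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestConfusionCounts:
    def test_all_correct(self):
        pred = ["Tumor", "Normal", "Tumor"]
        c = confusion_counts(pred, pred)
        assert (c.fp, c.fn) == (0, 0) and c.total == 3

    def test_reference_test_set_counts(self):
        """1119 Tumor + 843 Normal sections with 41 misses and 30 false alarms."""
        pred, truth = labels_from_counts(TEST_COUNTS)
        c = confusion_counts(pred, truth)
        assert (c.tp, c.fp, c.tn, c.fn) == (1078, 30, 813, 41)
        assert c.total == 1962

    def test_three_item_manual_tally(self):
        c = confusion_counts(["Tumor", "Normal", "Tumor"],
                             ["Normal", "Normal", "Tumor"])
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 0)

    def test_errors(self):
        with pytest.raises(ValueError):
            confusion_counts(["Tumor"], ["Tumor", "Normal"])
        with pytest.raises(ValueError):
            confusion_counts(["Maybe"], ["Tumor"])


class TestMetrics:
    def test_reference_test_set_metrics(self):
        m = metrics_from_counts(TEST_COUNTS)
        assert m["accuracy"] == pytest.approx(1891 / 1962)
        assert round(m["accuracy"], 3) == 0.964
        assert m["sensitivity"] == pytest.approx(1078 / 1119)
        assert round(m["sensitivity"], 3) == 0.963
        assert m["specificity"] == pytest.approx(813 / 843)

    def test_perfect_counts(self):
        m = metrics_from_counts(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_guarded_denominators(self):
        m = metrics_from_counts(ConfusionCounts(tp=0, fp=0, tn=4, fn=0))
        assert m["sensitivity"] is None and m["precision"] is None
        with pytest.raises(ValueError):
            metrics_from_counts(ConfusionCounts(tp=0, fp=0, tn=0, fn=0))

    def test_accuracy_identity(self, rng):
        """accuracy == (sens*P + spec*N) / (P+N) for arbitrary counts."""
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(1, 50, 4)
            m = metrics_from_counts(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            p, n = tp + fn, tn + fp
            assert m["accuracy"] == pytest.approx(
                (m["sensitivity"] * p + m["specificity"] * n) / (p + n))

    def test_brute_force_random_label_vectors(self, rng):
        """Metric bundle agrees with direct tallies over random label vectors."""
        for _ in range(200):
            n = int(rng.integers(2, 40))
            truth = list(rng.choice(["Tumor", "Normal"], n))
            pred = list(rng.choice(["Tumor", "Normal"], n))
            c = confusion_counts(pred, truth)
            acc = sum(p == t for p, t in zip(pred, truth)) / n
            m = metrics_from_counts(c)
            assert m["accuracy"] == pytest.approx(acc)


class TestFBeta:
    def test_reference_value(self):
        m = metrics_from_counts(TEST_COUNTS)
        fb = f_beta(m["precision"], m["sensitivity"], beta=1.5)
        assert round(fb, 3) == 0.966

    def test_equal_precision_recall_fixed_point(self):
        for p in (0.2, 0.5, 0.9):
            for beta in (0.5, 1.0, 1.5):
                assert f_beta(p, p, beta) == pytest.approx(p)

    def test_zero_recall(self):
        assert f_beta(0.8, 0.0) == 0.0

    def test_undefined_when_both_zero(self):
        with pytest.raises(ValueError):
            f_beta(0.0, 0.0)

    def test_strictly_increasing(self, rng):
        for _ in range(50):
            p, r = rng.uniform(0.05, 0.95, 2)
            eps = 0.02
            assert f_beta(p + eps, r) > f_beta(p, r)
            assert f_beta(p, r + eps) > f_beta(p, r)


def _separable_heatmaps():
    """Two sections separable only by the pair (0.6, 100 um^2):
    the tumor section has a large 0.65 blob, the normal one a small 0.65 blob
    plus a large 0.55 smear."""
    tumor = np.zeros((32, 32), np.float32)
    tumor[2:14, 2:14] = 0.65  # 144 px >= 100
    normal = np.zeros((32, 32), np.float32)
    normal[2:10, 2:10] = 0.65  # 64 px < 100
    normal[16:31, 16:31] = 0.55  # 225 px, only above a 0.5 threshold
    return ([Heatmap(tumor, mpp=1.0), Heatmap(normal, mpp=1.0)],
            ["Tumor", "Normal"])


class TestGridSearch:
    def test_single_grid_point_returned(self):
        heatmaps, truth = _separable_heatmaps()
        cfg = SelectionConfig(prediction_grid=(0.6,), area_grid=(100.0,))
        (pt, at), table = grid_search_thresholds(heatmaps, truth, cfg)
        assert (pt, at) == (0.6, 100.0) and len(table) == 1

    def test_constructed_unique_separator(self):
        heatmaps, truth = _separable_heatmaps()
        cfg = SelectionConfig(prediction_grid=(0.5, 0.6), area_grid=(50.0, 100.0))
        (pt, at), table = grid_search_thresholds(heatmaps, truth, cfg)
        assert (pt, at) == (0.6, 100.0)
        best = table[(table.prediction_threshold == pt)
                     & (table.area_threshold_um2 == at)].iloc[0]
        assert best["f_beta"] == pytest.approx(1.0)
        assert (table["f_beta"] < 1.0).sum() == 3  # every other pair errs

    def test_tie_broken_by_lower_prediction_threshold(self):
        hm = Heatmap(np.zeros((8, 8), np.float32), mpp=1.0)
        cfg = SelectionConfig(prediction_grid=(0.7, 0.4), area_grid=(0.0,))
        (pt, _), _ = grid_search_thresholds([hm], ["Normal"], cfg)
        assert pt == 0.4

    def test_grid_order_invariance(self):
        heatmaps, truth = _separable_heatmaps()
        a = grid_search_thresholds(heatmaps, truth, SelectionConfig(
            prediction_grid=(0.5, 0.6), area_grid=(50.0, 100.0)))[0]
        b = grid_search_thresholds(heatmaps, truth, SelectionConfig(
            prediction_grid=(0.6, 0.5), area_grid=(100.0, 50.0)))[0]
        assert a == b

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            SelectionConfig(prediction_grid=())


def test_per_block_table_shape_and_final_row(study_result):
    """The per-block table has one row per decoder block; its last row is the
    full-model evaluation."""
    k = study_result.network.config.n_decoder_blocks
    pb = study_result.per_block
    assert list(pb.index) == list(range(k))
    m = study_result.test_metrics
    assert pb.loc[k - 1, "accuracy"] == pytest.approx(m["accuracy"])
    assert pb.loc[k - 1, "f_beta"] == pytest.approx(m["f_beta"])
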