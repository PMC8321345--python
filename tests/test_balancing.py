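"""Coverage computation, patch categorization, resampling plans, the
unbalance statistic, and paired augmentation."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from nestseg import balancing as bal
from nestseg.balancing import (
    AugmentConfig,
    PatchRecord,
    augment,
    build_resampling_plan,
    categorize_patch,
    compute_coverage,
    pixel_unbalance,
    rasterize_polygons,
)


def record(cov_t=0.0, cov_s=0.0, cov_n=0.0, pid="p", size=64):
    return PatchRecord(patch_id=pid, section_id="s", origin_x=0, origin_y=0,
                       tile_size=size, coverage_t=cov_t, coverage_s=cov_s,
                       coverage_n=cov_n)


def point_in_polygon_oracle(xy, vertices):
    """Even-odd ray casting, written independently of shapely."""
    x, y = xy
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


class TestCoverage:
    def test_tile_fully_inside_polygon(self):
        ann = {bal.CLASS_TUMORNEST: [box(-10, -10, 100, 100)]}
        cov = compute_coverage(0, 0, 64, ann)
        assert cov == (1.0, 0.0, 0.0)

    def test_no_polygons(self):
        assert compute_coverage(0, 0, 64, {}) == (0.0, 0.0, 0.0)

    def test_half_covering_rectangle(self):
        """An axis-aligned rectangle over the left half covers exactly 50%."""
        ann = {bal.CLASS_TUMORNEST: [box(0, 0, 32, 64)]}
        assert compute_coverage(0, 0, 64, ann)[0] == pytest.approx(0.5)

    def test_matches_ray_casting_oracle(self, rng):
        """Rasterization equals a per-pixel point-in-polygon oracle exactly."""
        for _ in range(10):
            n_vert = int(rng.integers(3, 8))
            angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
            radius = rng.uniform(5, 20, n_vert)
            verts = [(16 + r * np.cos(a), 16 + r * np.sin(a))
                     for r, a in zip(radius, angles)]
            poly = Polygon(verts)
            mask = rasterize_polygons([poly], 32, 32)
            oracle = np.zeros((32, 32), bool)
            for i in range(32):
                for j in range(32):
                    oracle[i, j] = point_in_polygon_oracle((j + 0.5, i + 0.5), verts)
            np.testing.assert_array_equal(mask, oracle)

    def test_invalid_polygon_repaired(self):
        bowtie = Polygon([(0, 0), (10, 10), (10, 0), (0, 10)])
        assert not bowtie.is_valid
        mask = rasterize_polygons([bowtie], 12, 12)
        assert mask.sum() > 0  # both triangles of the repaired bowtie


class TestCategorize:
    @pytest.mark.parametrize("cov,expected", [
        (dict(cov_t=0.12), bal.CAT_T_HIGH),
        (dict(cov_t=0.001, cov_s=0.2), bal.CAT_T_LOW),
        (dict(), bal.CAT_BACKGROUND),
        (dict(cov_t=0.10), bal.CAT_T_HIGH),          # tie goes to the higher category
        (dict(cov_t=0.0005), bal.CAT_T_LOW),
        (dict(cov_s=0.0004, cov_n=0.3), bal.CAT_N),
    ])
    def test_precedence(self, cov, expected):
        assert categorize_patch(record(**cov)) == expected

    def test_categories_partition_inventory(self, rng):
        inv = [record(cov_t=float(rng.random() * 0.2),
                      cov_s=float(rng.random() * 0.2),
                      cov_n=float(rng.random() * 0.2), pid=f"p{i}")
               for i in range(200)]
        from collections import Counter
        counts = Counter(categorize_patch(r) for r in inv)
        assert sum(counts.values()) == len(inv)
        assert set(counts) <= set(bal.CATEGORIES)


class TestResamplingPlan:
    def test_identity_targets(self):
        inv = [record(cov_t=0.2, pid=f"p{i}") for i in range(5)]
        plan = build_resampling_plan(inv, {bal.CAT_T_HIGH: 5})
        assert all(v == 1 for v in plan.repetitions.values())

    def test_round_robin_distribution(self):
        inv = [record(cov_t=0.2, pid=f"p{i}") for i in range(3)]
        plan = build_resampling_plan(inv, {bal.CAT_T_HIGH: 10})
        assert sorted(plan.repetitions.values(), reverse=True) == [4, 3, 3]
        assert plan.total == 10

    def test_conservation_property(self, rng):
        inv = ([record(cov_t=0.2, pid=f"t{i}") for i in range(7)]
               + [record(cov_s=0.1, pid=f"s{i}") for i in range(4)]
               + [record(pid=f"b{i}") for i in range(20)])
        targets = {bal.CAT_T_HIGH: 23, bal.CAT_S: 9}
        plan = build_resampling_plan(inv, targets)
        assert plan.total == 23 + 9 + 20
        assert min(plan.repetitions.values()) >= 1

    def test_target_below_count_rejected(self):
        inv = [record(cov_t=0.2, pid=f"p{i}") for i in range(5)]
        with pytest.raises(ValueError, match="below"):
            build_resampling_plan(inv, {bal.CAT_T_HIGH: 3})

    def test_empty_category_with_target_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_resampling_plan([record(pid="a")], {bal.CAT_S: 5})


class TestPixelUnbalance:
    def test_symmetric_patch(self):
        assert pixel_unbalance([record(cov_t=0.5)]) == pytest.approx(1.0)

    def test_two_patch_hand_computation(self):
        inv = [record(cov_t=0.1, pid="a"), record(cov_t=0.0, pid="b")]
        assert pixel_unbalance(inv) == pytest.approx(19.0)

    def test_oversampling_tumor_reduces_ratio(self):
        inv = [record(cov_t=0.3, pid="t"), record(pid="b1"), record(pid="b2")]
        plan = build_resampling_plan(inv, {bal.CAT_T_HIGH: 4})
        assert pixel_unbalance(inv, plan) < pixel_unbalance(inv)

    def test_no_tumor_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            pixel_unbalance([record()])


class TestAugment:
    def _pair(self, rng, n=64):
        img = rng.random((n, n, 3)).astype(np.float32)
        mask = np.zeros((n, n), bool)
        mask[10:40, 20:50] = True
        tgt = np.zeros((n, n, 2), np.float32)
        tgt[..., 0], tgt[..., 1] = mask, ~mask
        return img, tgt

    def test_identity_config(self, rng):
        img, tgt = self._pair(rng)
        out_img, out_tgt = augment(img, tgt, rng, AugmentConfig(enabled=False))
        assert out_img is img and out_tgt is tgt

    def test_quarter_rotation_rotates_mask_exactly(self, rng):
        img, tgt = self._pair(rng)
        cfg = AugmentConfig(rotation_degrees=(90.0, 90.0), scale_range=(1.0, 1.0),
                            smooth_sigma_range=(0.0, 0.0), smooth_prob=0.0,
                            color_jitter=0.0, elastic_alpha=0.0, elastic_prob=0.0)
        _, out_tgt = augment(img, tgt, rng, cfg)
        np.testing.assert_array_equal(out_tgt[..., 0], np.rot90(tgt[..., 0], 1))

    def test_small_elastic_deformation_roughly_preserves_area(self, rng):
        img, tgt = self._pair(rng)
        cfg = AugmentConfig(rotation_degrees=(0.0, 0.0), scale_range=(1.0, 1.0),
                            smooth_prob=0.0, color_jitter=0.0,
                            elastic_alpha=3.0, elastic_sigma=8.0, elastic_prob=1.0)
        before = tgt[..., 0].sum()
        for _ in range(5):
            _, out_tgt = augment(img, tgt, rng, cfg)
            after = out_tgt[..., 0].sum()
            assert abs(after - before) < 0.10 * before

    def test_output_stays_one_hot_with_shapes(self, rng):
        img, tgt = self._pair(rng)
        for _ in range(5):
            out_img, out_tgt = augment(img, tgt, rng, AugmentConfig())
            assert out_img.shape == img.shape and out_tgt.shape == tgt.shape
            assert set(np.unique(out_tgt)) <= {0.0, 1.0}
            np.testing.assert_array_equal(out_tgt.sum(-1), 1.0)
            assert out_img.min() >= 0.0 and out_img.max() <= 1.0
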