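"""Loss identities, target downsampling, the LR schedule, and training-loop
behavior (determinism, overfitting sanity, merge-weight updates)."""

import numpy as np
import pytest

from nestseg import balancing as bal
from nestseg.models import DecoderOutputs, NetworkConfig, build_network
from nestseg.nn import tensor as T
from nestseg.nn.tensor import Tensor
from nestseg.training import (
    LossConfig,
    TrainConfig,
    deep_supervision_loss,
    downsample_target,
    focal_loss,
    learning_rate_at,
    train,
    validation_iou,
)
from .conftest import small_fixture_params
from nestseg.synthetic import generate_split


def one_hot(tumor_mask):
    t = np.zeros(tumor_mask.shape + (2,), np.float32)
    t[..., 0] = tumor_mask
    t[..., 1] = ~np.asarray(tumor_mask, bool)
    return t


def random_probs(rng, shape):
    p = rng.random(shape + (2,))
    return p / p.sum(-1, keepdims=True)


class TestFocalLoss:
    @pytest.mark.parametrize("gamma,pt,expected", [
        (0.0, 0.5, np.log(2.0)),                    # reduces to cross-entropy
        (2.0, 0.9, 0.01 * -np.log(0.9)),            # (1-0.9)^2 * -ln 0.9
        (2.0, 1.0, 0.0),                            # perfect prediction
    ])
    def test_single_pixel_closed_form(self, gamma, pt, expected):
        prob = np.array([[[pt, 1.0 - pt]]], np.float32)
        target = np.array([[[1.0, 0.0]]], np.float32)
        assert focal_loss(prob, target, gamma) == pytest.approx(expected, abs=1e-7)

    def test_gamma_zero_equals_cross_entropy(self, rng):
        for _ in range(20):
            p = random_probs(rng, (6, 6))
            t = one_hot(rng.random((6, 6)) > 0.5)
            ce = float(-np.log((p * t).sum(-1)).mean())
            assert focal_loss(p, t, 0.0) == pytest.approx(ce, abs=1e-6)

    def test_matches_logit_space_implementation(self, rng):
        z = rng.normal(size=(2, 2, 5, 5)).astype(np.float32)
        t_hwc = one_hot(rng.random((2, 5, 5)) > 0.5)
        p = T.softmax(z, axis=1)
        via_logits = float(T.focal_from_logits(Tensor(z), t_hwc.transpose(0, 3, 1, 2), 2.0).data)
        via_probs = focal_loss(p.transpose(0, 2, 3, 1), t_hwc, 2.0)
        assert via_logits == pytest.approx(via_probs, rel=1e-5)

    def test_rejects_bad_inputs(self, rng):
        p = random_probs(rng, (4, 4))
        with pytest.raises(ValueError, match="shape"):
            focal_loss(p, one_hot(np.zeros((5, 5), bool)))
        bad = one_hot(np.zeros((4, 4), bool))
        bad[0, 0] = (0.5, 0.5)
        with pytest.raises(ValueError, match="one-hot|binary"):
            focal_loss(p, bad)


class TestDownsampleTarget:
    def test_reaches_operator_signature_size(self):
        y = one_hot(np.zeros((512, 512), bool))
        assert downsample_target(y, 0, 5).shape == (32, 32, 2)
        assert downsample_target(y, 4, 5).shape == (512, 512, 2)

    def test_constant_map_invariant(self):
        y = one_hot(np.ones((64, 64), bool))
        for level in range(5):
            out = downsample_target(y, level, 5)
            assert (out[..., 0] == 1).all()

    def test_max_decimation_preserves_single_quadrant(self):
        """A 2x2 Tumor quadrant of a 4x4 map survives one halving as 1 pixel."""
        mask = np.zeros((4, 4), bool)
        mask[0:2, 2:4] = True
        out = downsample_target(one_hot(mask), 0, 2)
        expected = np.zeros((2, 2))
        expected[0, 1] = 1
        np.testing.assert_array_equal(out[..., 0], expected)

    def test_output_always_one_hot(self, rng):
        for _ in range(10):
            y = one_hot(rng.random((32, 32)) > 0.7)
            for level in range(3):
                out = downsample_target(y, level, 3)
                assert set(np.unique(out)) <= {0.0, 1.0}
                np.testing.assert_array_equal(out.sum(-1), 1.0)

    def test_level_out_of_range(self):
        with pytest.raises(ValueError):
            downsample_target(one_hot(np.zeros((8, 8), bool)), 3, 3)


class TestDeepSupervisionLoss:
    def _outputs(self, prob_maps):
        return DecoderOutputs(score_maps=[], prob_maps=prob_maps, final=prob_maps[-1])

    def test_perfect_predictions_zero(self):
        mask = np.zeros((8, 8), bool)
        mask[:4] = True
        maps = [downsample_target(one_hot(mask), l, 3).astype(np.float32) for l in range(3)]
        assert deep_supervision_loss(self._outputs(maps), one_hot(mask),
                                     LossConfig()) == pytest.approx(0.0, abs=1e-6)

    def test_single_block_equals_focal(self, rng):
        p = random_probs(rng, (8, 8)).astype(np.float32)
        y = one_hot(rng.random((8, 8)) > 0.5)
        cfg = LossConfig(gamma=2.0)
        assert deep_supervision_loss(self._outputs([p]), y, cfg) == \
            pytest.approx(focal_loss(p, y, 2.0))

    def test_two_block_toy_sum(self, rng):
        p0 = random_probs(rng, (2, 2)).astype(np.float32)
        p1 = random_probs(rng, (4, 4)).astype(np.float32)
        y = one_hot(rng.random((4, 4)) > 0.5)
        cfg = LossConfig(gamma=2.0)
        expected = focal_loss(p0, downsample_target(y, 0, 2), 2.0) + focal_loss(p1, y, 2.0)
        assert deep_supervision_loss(self._outputs([p0, p1]), y, cfg) == pytest.approx(expected)

    def test_at_least_final_map_loss(self, rng):
        p0 = random_probs(rng, (2, 2)).astype(np.float32)
        p1 = random_probs(rng, (4, 4)).astype(np.float32)
        y = one_hot(rng.random((4, 4)) > 0.5)
        cfg = LossConfig(gamma=2.0)
        assert deep_supervision_loss(self._outputs([p0, p1]), y, cfg) >= \
            focal_loss(p1, y, 2.0)


class TestSchedule:
    @pytest.mark.parametrize("epoch,expected", [(0, 5e-4), (5, 4e-4), (12, 3.2e-4)])
    def test_printed_values(self, epoch, expected):
        assert learning_rate_at(epoch, TrainConfig()) == pytest.approx(expected)

    def test_non_increasing(self):
        cfg = TrainConfig()
        rates = [learning_rate_at(e, cfg) for e in range(41)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))


def _fixture_patches(n_tumor=8, n_other=8):
    recs = generate_split(small_fixture_params(4, tumor_prevalence=1.0,
                                               size_range=(256, 320),
                                               distractor_count_range=(0, 2)),
                          "overfit", seed=11)
    tumor, other = [], []
    for rec in recs:
        inv = bal.build_inventory(rec.section.section_id, rec.section.image.shape[:2],
                                  64, rec.annotations, stride=64)
        for r in inv:
            patch = bal.extract_patch(rec.section.image, r, rec.annotations)
            cat = bal.categorize_patch(r)
            (tumor if cat in (bal.CAT_T_HIGH, bal.CAT_T_LOW) else other).append(patch)
    return tumor[:n_tumor] + other[:n_other]


class TestTrainingLoop:
    def test_overfits_small_patch_set(self):
        """A tiny network memorizes 16 fixture patches: final-epoch loss falls
        below 10% of the first epoch's."""
        patches = _fixture_patches()
        cfg = NetworkConfig(encoder_kind="vanilla", input_size=64, base_width=8,
                            n_decoder_blocks=4, seed=2)
        net = build_network(cfg)
        history, best = train(net, patches, patches,
                              TrainConfig(max_epochs=30, batch_size=4,
                                          learning_rate=1e-3, seed=1),
                              LossConfig(strategy="plain"))
        assert history.records[-1].train_loss < 0.10 * history.records[0].train_loss
        assert len(best) == 5
        assert best == sorted(best, key=lambda c: -c["val_iou"])

    def test_identical_seeds_identical_history(self):
        patches = _fixture_patches(4, 4)
        losses = []
        for _ in range(2):
            net = build_network(NetworkConfig(encoder_kind="vanilla", input_size=64,
                                              base_width=8, n_decoder_blocks=4, seed=2))
            hist, _ = train(net, patches, [], TrainConfig(max_epochs=2, batch_size=4, seed=5),
                            LossConfig())
            losses.append([r.train_loss for r in hist.records])
        assert losses[0] == losses[1]

    def test_linear_merge_weights_update_and_stay_finite(self):
        patches = _fixture_patches(4, 4)
        net = build_network(NetworkConfig(encoder_kind="vanilla", input_size=64,
                                          base_width=8, n_decoder_blocks=4,
                                          use_linear_merge=True, seed=2))
        before = net.merge_w.data.copy()
        train(net, patches, [], TrainConfig(max_epochs=2, batch_size=4, seed=5),
              LossConfig(strategy="linear_merge"))
        assert np.isfinite(net.merge_w.data).all()
        assert not np.array_equal(before, net.merge_w.data)

    def test_empty_dataset_rejected(self):
        net = build_network(NetworkConfig(encoder_kind="vanilla", input_size=64,
                                          base_width=8, n_decoder_blocks=4))
        with pytest.raises(ValueError, match="empty"):
            train(net, [], [], TrainConfig(max_epochs=1), LossConfig())


def test_validation_iou_empty_masks_is_one():
    net = build_network(NetworkConfig(encoder_kind="vanilla", input_size=32,
                                      base_width=8, n_decoder_blocks=3, seed=0))
    # a network that predicts no tumor anywhere on a no-tumor target
    img = np.ones((1, 32, 32, 3), np.float32)
    tgt = one_hot(np.zeros((1, 32, 32), bool))
    v = validation_iou(net, img, tgt)
    assert 0.0 <= v <= 1.0


def test_deep_supervision_trained_block0_close_to_final(study_result):
    """After deep-supervision training, the thresholded psi_0 mask largely
    agrees with the final block's mask (coarse map already localizes tumor)."""
    assert study_result.block0_final_mask_iou >= 0.8
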