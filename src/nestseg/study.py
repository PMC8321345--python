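"""End-to-end synthetic benchmark study.

Reproduces the full workflow at CPU-friendly scale: generate annotated
synthetic sections, build and resample the patch inventory, train a small
deeply supervised network, select prediction/area thresholds by F-beta grid
search on validation heatmaps, then evaluate sectionwise classification on a
held-out test split — including the per-decoder-block evaluation that checks
how early in the decoder the tumor call is already decided.

The default problem sizes (sections of 256–384 px, 64-px patches, a width-8
four-block vanilla encoder, 60 test sections) are chosen so the whole study runs in a
few minutes on one CPU core while leaving every pipeline stage non-trivial:
nests span multiple tiles, distractors produce occasional small false
detections, and the area filter genuinely matters.
"""

from __future__ import annotations

import time
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import balancing as bal
from .evaluation import (
    ConfusionCounts,
    SelectionConfig,
    grid_search_thresholds,
    per_block_evaluation,
    sectionwise_metrics,
)
from .models import NetworkConfig, build_network
from .pipeline import compute_heatmaps
from .synthetic import FixtureParams, generate_split, split_seed
from .training import LossConfig, TrainConfig, train


@dataclass
class StudyConfig:
    """Scaled study profile; every size is an explicit, documented choice."""

    patch_size: int = 64
    encoder_kind: str = "vanilla"
    n_decoder_blocks: int = 4
    base_width: int = 8
    strategy: str = "deep_supervision"
    n_train_sections: int = 10
    n_val_sections: int = 16
    n_test_sections: int = 60
    train_stride: int = 48
    epochs: int = 10
    batch_size: int = 16
    learning_rate: float = 5e-4
    oversample: dict = field(default_factory=lambda: {
        bal.CAT_T_LOW: 4, bal.CAT_T_HIGH: 3, bal.CAT_S: 2, bal.CAT_N: 3})
    prediction_grid: tuple = tuple(np.round(np.arange(0.30, 0.8001, 0.05), 2))
    area_grid: tuple = tuple(range(0, 2561, 320))  # um^2, scaled to fixture nests

    def fixture_profile(self, n_sections: int) -> FixtureParams:
        return FixtureParams(
            n_sections=n_sections, size_range=(256, 384), mpp=1.0,
            nest_area_median_um2=4000.0, nest_area_sigma=0.3,
            stroma_halo_um=12.0, distractor_area_median_um2=700.0,
            distractor_count_range=(0, 3))


@dataclass
class StudyResult:
    config: StudyConfig
    network: object
    history: object
    best_epoch: int
    val_iou: float
    thresholds: tuple[float, float]
    test_metrics: dict
    per_block: pd.DataFrame
    block0_final_mask_iou: float
    n_test: int
    train_seconds: float
    total_seconds: float


def _patches_for(records, patch_size, stride):
    pairs = []
    for rec in records:
        inv = bal.build_inventory(rec.section.section_id, rec.section.image.shape[:2],
                                  patch_size, rec.annotations, stride=stride)
        pairs.extend((r, rec) for r in inv)
    return pairs


def run_study(seed: int, config: StudyConfig | None = None,
              progress: bool = False) -> StudyResult:
    """Run the complete study; deterministic in ``seed``."""
    config = config or StudyConfig()
    t_start = time.time()

    train_recs = generate_split(config.fixture_profile(config.n_train_sections),
                                "train", seed=split_seed(seed, "train"))
    val_recs = generate_split(config.fixture_profile(config.n_val_sections),
                              "val", seed=split_seed(seed, "val"))
    test_recs = generate_split(config.fixture_profile(config.n_test_sections),
                               "test", seed=split_seed(seed, "test"))

    train_pairs = _patches_for(train_recs, config.patch_size, config.train_stride)
    val_pairs = _patches_for(val_recs[: max(config.n_val_sections // 2, 1)],
                             config.patch_size, config.patch_size)
    inventory = [r for r, _ in train_pairs]
    counts = Counter(bal.categorize_patch(r) for r in inventory)
    targets = {cat: counts.get(cat, 0) * mult
               for cat, mult in config.oversample.items() if counts.get(cat, 0)}
    plan = bal.build_resampling_plan(inventory, targets)

    train_patches = []
    for rec, sec in train_pairs:
        patch = bal.extract_patch(sec.section.image, rec, sec.annotations)
        train_patches.extend([patch] * plan.repetitions.get(rec.patch_id, 1))
    val_patches = [bal.extract_patch(sec.section.image, rec, sec.annotations)
                   for rec, sec in val_pairs]

    net_cfg = NetworkConfig(
        encoder_kind=config.encoder_kind, input_size=config.patch_size,
        base_width=config.base_width, n_decoder_blocks=config.n_decoder_blocks,
        use_linear_merge=(config.strategy == "linear_merge"),
        seed=split_seed(seed, "network"))
    network = build_network(net_cfg)
    train_cfg = TrainConfig(max_epochs=config.epochs, batch_size=config.batch_size,
                            learning_rate=config.learning_rate,
                            seed=split_seed(seed, "training"))
    aug_cfg = bal.AugmentConfig(elastic_prob=0.3, smooth_prob=0.2)
    t0 = time.time()
    history, best = train(network, train_patches, val_patches, train_cfg,
                          LossConfig(strategy=config.strategy),
                          augment_fn=lambda im, tg, rng: bal.augment(im, tg, rng, aug_cfg),
                          progress=progress)
    train_seconds = time.time() - t0
    network.load_state_dict(best[0]["state"])

    k = net_cfg.n_decoder_blocks
    sel = SelectionConfig(prediction_grid=config.prediction_grid,
                          area_grid=config.area_grid)
    val_heat_blocks = [compute_heatmaps(r.section, network, blocks=[0, k - 1])
                       for r in val_recs]
    (pred_thr, area_thr), _table = grid_search_thresholds(
        [h[k - 1] for h in val_heat_blocks], [r.label for r in val_recs], sel)

    truth = [r.label for r in test_recs]
    per_block = per_block_evaluation(network, [r.section for r in test_recs], truth,
                                     pred_thr, area_thr)
    row = per_block.loc[k - 1]
    final_counts = ConfusionCounts(tp=int(row["tp"]), fp=int(row["fp"]),
                                   tn=int(row["tn"]), fn=int(row["fn"]))
    test_metrics = sectionwise_metrics(final_counts)

    # how close psi0's coarse mask is to the final mask: IoU of the stitched
    # heatmaps thresholded at 0.5, pooled over the validation sections
    inter = union = 0
    for heats in val_heat_blocks:
        m0 = heats[0].probabilities >= 0.5
        mk = heats[k - 1].probabilities >= 0.5
        inter += np.logical_and(m0, mk).sum()
        union += np.logical_or(m0, mk).sum()
    block0_iou = 1.0 if union == 0 else float(inter / union)

    return StudyResult(
        config=config, network=network, history=history, best_epoch=best[0]["epoch"],
        val_iou=best[0]["val_iou"], thresholds=(pred_thr, area_thr),
        test_metrics=test_metrics, per_block=per_block,
        block0_final_mask_iou=block0_iou, n_test=len(test_recs),
        train_seconds=train_seconds, total_seconds=time.time() - t_start)
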