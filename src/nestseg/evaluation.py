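"""Segmentation and sectionwise metrics, threshold selection, per-block evaluation.

The sectionwise task treats Tumor as the positive class.  Thresholds
(prediction probability and region area in um^2) are chosen by a full grid
search maximizing the F-beta score with beta = 1.5, which weights recall
(sensitivity) above precision — missing a tumor section is costlier than a
false alarm.  Ties are broken by higher sensitivity, then lower prediction
threshold, then lower area threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import NORMAL, TUMOR, Heatmap, classify_section, extract_regions

DEFAULT_PREDICTION_GRID = tuple(np.round(np.arange(0.30, 0.8001, 0.05), 2))
DEFAULT_AREA_GRID = tuple(range(0, 10241, 1280))


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class SelectionConfig:
    beta: float = 1.5
    prediction_grid: tuple = DEFAULT_PREDICTION_GRID
    area_grid: tuple = DEFAULT_AREA_GRID
    connectivity: int = 8

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not self.prediction_grid or not self.area_grid:
            raise ValueError("threshold grids must be non-empty")


def iou(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Intersection over union of two binary masks (1.0 when both are empty)."""
    pred_mask = np.asarray(pred_mask, dtype=bool)
    true_mask = np.asarray(true_mask, dtype=bool)
    if pred_mask.shape != true_mask.shape:
        raise ValueError(f"shape mismatch: {pred_mask.shape} vs {true_mask.shape}")
    union = np.logical_or(pred_mask, true_mask).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred_mask, true_mask).sum() / union)


def confusion_counts(predicted: list[str], truth: list[str]) -> ConfusionCounts:
    if len(predicted) != len(truth):
        raise ValueError("label lists differ in length")
    tp = fp = tn = fn = 0
    for p, t in zip(predicted, truth):
        if p not in (TUMOR, NORMAL) or t not in (TUMOR, NORMAL):
            raise ValueError(f"labels must be {TUMOR!r} or {NORMAL!r}, got ({p!r}, {t!r})")
        if t == TUMOR:
            tp += p == TUMOR
            fn += p == NORMAL
        else:
            tn += p == NORMAL
            fp += p == TUMOR
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics_from_counts(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and precision; denominators of zero
    yield ``None`` for the affected metric rather than NaN."""
    if counts.total == 0:
        raise ValueError("no sections evaluated")
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    pred_pos = counts.tp + counts.fp
    return {
        "accuracy": (counts.tp + counts.tn) / counts.total,
        "sensitivity": counts.tp / pos if pos else None,
        "specificity": counts.tn / neg if neg else None,
        "precision": counts.tp / pred_pos if pred_pos else None,
    }


def f_beta(precision: float, recall: float, beta: float = 1.5) -> float:
    """F-beta = (1+beta^2) * precision * recall / (beta^2 * precision + recall)."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must be in [0, 1]")
    if precision == 0 and recall == 0:
        raise ValueError("F-beta is undefined when precision and recall are both zero")
    b2 = beta * beta
    return (1.0 + b2) * precision * recall / (b2 * precision + recall)


def sectionwise_metrics(counts: ConfusionCounts, beta: float = 1.5) -> dict[str, float]:
    """The reporting bundle: accuracy/sensitivity/specificity/precision + F-beta."""
    m = metrics_from_counts(counts)
    if m["precision"] in (None, 0) and m["sensitivity"] in (None, 0):
        m["f_beta"] = None
    else:
        m["f_beta"] = f_beta(m["precision"] or 0.0, m["sensitivity"] or 0.0, beta)
    return m


# ---------------------------------------------------------------------------
# threshold grid search
# ---------------------------------------------------------------------------

def _labels_for_thresholds(heatmaps: list[Heatmap], pred_thr: float, area_thr: float,
                           connectivity: int, region_cache: dict) -> list[str]:
    labels = []
    for i, hm in enumerate(heatmaps):
        key = (i, pred_thr)
        if key not in region_cache:
            region_cache[key] = extract_regions(hm, pred_thr, connectivity=connectivity)
        labels.append(classify_section(region_cache[key], area_thr).label)
    return labels


def grid_search_thresholds(heatmaps: list[Heatmap], truth: list[str],
                           config: SelectionConfig = SelectionConfig(),
                           ) -> tuple[tuple[float, float], pd.DataFrame]:
    """Evaluate every (prediction, area) threshold pair; return the F-beta
    maximizer plus the full score table for audit.

    Regions are extracted once per prediction threshold and reused across area
    thresholds, so the heatmaps are only scanned ``len(prediction_grid)`` times.
    """
    if len(heatmaps) != len(truth):
        raise ValueError("one truth label per heatmap required")
    cache: dict = {}
    rows = []
    for pt in config.prediction_grid:
        for at in config.area_grid:
            labels = _labels_for_thresholds(heatmaps, pt, at, config.connectivity, cache)
            counts = confusion_counts(labels, truth)
            m = sectionwise_metrics(counts, beta=config.beta)
            rows.append({"prediction_threshold": pt, "area_threshold_um2": at,
                         "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
                         **m})
    table = pd.DataFrame(rows)
    score = table["f_beta"].astype(float).fillna(-1.0)
    sens = table["sensitivity"].astype(float).fillna(-1.0)
    order = sorted(
        range(len(table)),
        key=lambda i: (-score[i], -sens[i],
                       table["prediction_threshold"][i], table["area_threshold_um2"][i]))
    best = table.iloc[order[0]]
    return (float(best["prediction_threshold"]), float(best["area_threshold_um2"])), table


# ---------------------------------------------------------------------------
# per-decoder-block evaluation
# ---------------------------------------------------------------------------

def per_block_evaluation(network, sections, truth: list[str],
                         prediction_threshold: float, area_threshold_um2: float,
                         beta: float = 1.5, connectivity: int = 8,
                         min_overlap: int | None = None) -> pd.DataFrame:
    """Sectionwise metrics when heatmaps come from each decoder block in turn,
    using the *same* thresholds selected for the full model.

    Heatmaps for all blocks are produced from one shared (full) forward pass
    per tile, which is exactly equivalent to truncated inference per block.
    Only meaningful for deep-supervision-trained models; other models get a
    warning since their intermediate heads were never supervised.
    """
    from .pipeline import compute_heatmaps  # local import to avoid cycle

    k = network.config.n_decoder_blocks
    if getattr(network, "_trained_strategy", None) not in (None, "deep_supervision"):
        import warnings

        warnings.warn("per-block evaluation on a model not trained with deep "
                      "supervision; intermediate outputs may be meaningless")
    labels_by_block: dict[int, list[str]] = {l: [] for l in range(k)}
    for sec in sections:
        heats = compute_heatmaps(sec, network, blocks=list(range(k)),
                                 min_overlap=min_overlap)
        for l in range(k):
            regions = extract_regions(heats[l], prediction_threshold,
                                      connectivity=connectivity)
            labels_by_block[l].append(classify_section(regions, area_threshold_um2).label)
    rows = []
    for l in range(k):
        counts = confusion_counts(labels_by_block[l], truth)
        rows.append({"block": l, **sectionwise_metrics(counts, beta=beta),
                     "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn})
    return pd.DataFrame(rows).set_index("block")


def select_model(checkpoint_states: list[dict], network_factory, heatmap_fn,
                 truth: list[str], config: SelectionConfig = SelectionConfig()):
    """Rank candidate checkpoints on the sectionwise task.

    ``network_factory(state)`` must return a network with that state loaded and
    ``heatmap_fn(network)`` the heatmaps of the validation sections.  Returns
    (best index, best thresholds, per-candidate summary table).
    """
    summaries = []
    best_idx, best_score, best_thr = None, -np.inf, None
    for i, state in enumerate(checkpoint_states):
        net = network_factory(state)
        heatmaps = heatmap_fn(net)
        (pt, at), table = grid_search_thresholds(heatmaps, truth, config)
        row = table[(table["prediction_threshold"] == pt)
                    & (table["area_threshold_um2"] == at)].iloc[0]
        score = float(row["f_beta"]) if row["f_beta"] is not None else -1.0
        summaries.append({"candidate": i, "prediction_threshold": pt,
                          "area_threshold_um2": at, "f_beta": score,
                          "accuracy": row["accuracy"]})
        if score > best_score:
            best_idx, best_score, best_thr = i, score, (pt, at)
    return best_idx, best_thr, pd.DataFrame(summaries)
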