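"""Loss functions, target downsampling and the training loop.

Three training strategies are supported:

``plain``
    focal loss on the final decoder output against the full-resolution target;
``deep_supervision``
    the sum over all decoder blocks l of the focal loss between psi_l and a
    downsampled target Pi_l(y), with equal weight per scale;
``linear_merge``
    focal loss on the softmax of the learned weighted sum of upsampled
    per-block score maps.

The target-downsampling operator Pi_l is class-preserving 2x2 max decimation
on the Tumor channel (a window is Tumor if any of its pixels is Tumor),
re-one-hotted; this preserves thin tumor structures at coarse scales.
Focal probabilities are clamped to [1e-7, 1] inside logarithms.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .models import (
    TUMOR_CHANNEL,
    DecoderOutputs,
    Patch,
    SegmentationNetwork,
)
from .nn import Adam
from .nn import tensor as T
from .nn.tensor import Tensor

PROB_EPS = 1e-7


@dataclass
class LossConfig:
    gamma: float = 2.0
    strategy: str = "deep_supervision"

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.strategy not in ("plain", "deep_supervision", "linear_merge"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass
class TrainConfig:
    max_epochs: int = 40
    batch_size: int = 64
    learning_rate: float = 5e-4
    lr_decay_factor: float = 0.8
    lr_decay_every: int = 5
    seed: int = 0

    def __post_init__(self):
        if min(self.max_epochs, self.batch_size, self.lr_decay_every) <= 0:
            raise ValueError("epochs, batch size and decay period must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 < self.lr_decay_factor <= 1:
            raise ValueError("decay factor must be in (0, 1]")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_iou: float
    lr: float


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def as_rows(self) -> list[dict]:
        return [vars(r) for r in self.records]


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _check_one_hot(target: np.ndarray) -> None:
    if not np.all((target == 0) | (target == 1)):
        raise ValueError("target map must be binary one-hot")
    if not np.all(target.sum(axis=-1) == 1):
        raise ValueError("target channels must sum to 1 at every pixel")


def focal_loss(prob_map: np.ndarray, target_map: np.ndarray, gamma: float = 2.0) -> float:
    """Mean focal loss -(1-p_t)^gamma log(p_t) over all pixels.

    ``prob_map`` and ``target_map`` are channel-last with the class axis last;
    ``target_map`` must be one-hot.  With gamma=0 this is mean cross-entropy.
    """
    prob_map = np.asarray(prob_map, dtype=np.float64)
    target_map = np.asarray(target_map)
    if prob_map.shape != target_map.shape:
        raise ValueError(f"shape mismatch: {prob_map.shape} vs {target_map.shape}")
    _check_one_hot(target_map)
    pt = (prob_map * target_map).sum(axis=-1)
    ptc = np.clip(pt, PROB_EPS, 1.0)
    return float((-((1.0 - pt) ** gamma) * np.log(ptc)).mean())


def downsample_target(target_map: np.ndarray, level: int, k: int) -> np.ndarray:
    """Pi_l: reduce a one-hot target to the resolution of decoder block ``level``
    (k-1-level rounds of 2x2 max decimation on the Tumor channel)."""
    if not 0 <= level < k:
        raise ValueError(f"level {level} out of range [0, {k})")
    target_map = np.asarray(target_map)
    _check_one_hot(target_map)
    tumor = target_map[..., TUMOR_CHANNEL]
    for _ in range(k - 1 - level):
        h, w = tumor.shape[-2:]
        if h % 2 or w % 2:
            raise ValueError(f"cannot halve odd spatial size {(h, w)}")
        tumor = tumor.reshape(tumor.shape[:-2] + (h // 2, 2, w // 2, 2)).max(axis=(-3, -1))
    out = np.zeros(tumor.shape + (2,), dtype=target_map.dtype)
    out[..., TUMOR_CHANNEL] = tumor
    out[..., 1 - TUMOR_CHANNEL] = 1 - tumor
    return out


def deep_supervision_loss(outputs: DecoderOutputs, target_map: np.ndarray,
                          loss_config: LossConfig) -> float:
    """Sum over decoder blocks of the focal loss against downsampled targets."""
    k = len(outputs.prob_maps)
    if k == 0:
        raise ValueError("DecoderOutputs carries no intermediate maps")
    total = 0.0
    for level, prob in enumerate(outputs.prob_maps):
        total += focal_loss(prob, downsample_target(target_map, level, k), loss_config.gamma)
    return total


def learning_rate_at(epoch: int, train_config: TrainConfig) -> float:
    """Step-decay schedule: base * factor^floor(epoch / period)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    steps = epoch // train_config.lr_decay_every
    return train_config.learning_rate * train_config.lr_decay_factor ** steps


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _as_arrays(patches) -> tuple[np.ndarray, np.ndarray]:
    images, targets = [], []
    for p in patches:
        img, tgt = (p.image, p.target) if isinstance(p, Patch) else p
        images.append(np.asarray(img, dtype=np.float32))
        targets.append(np.asarray(tgt, dtype=np.float32))
    return np.stack(images), np.stack(targets)


def _batch_loss(network: SegmentationNetwork, x_nchw: np.ndarray, t_nhwc: np.ndarray,
                loss_config: LossConfig, training: bool) -> Tensor:
    scores, merged = network.forward_tensors(Tensor(x_nchw), training=training)
    k = len(scores)
    if loss_config.strategy == "deep_supervision":
        total: Tensor | None = None
        for level, s in enumerate(scores):
            tgt = downsample_target(t_nhwc, level, k).transpose(0, 3, 1, 2)
            term = T.focal_from_logits(s, tgt, loss_config.gamma)
            total = term if total is None else T.add(total, term)
        return total
    target_nchw = t_nhwc.transpose(0, 3, 1, 2)
    if loss_config.strategy == "linear_merge":
        if merged is None:
            raise ValueError("linear_merge strategy requires use_linear_merge=True in the network")
        return T.focal_from_logits(merged, target_nchw, loss_config.gamma)
    return T.focal_from_logits(scores[-1], target_nchw, loss_config.gamma)


def validation_iou(network: SegmentationNetwork, images: np.ndarray, targets: np.ndarray,
                   batch_size: int = 8) -> float:
    """Tumor-class IoU pooled over all validation pixels (argmax masks)."""
    inter = union = 0
    with T.no_grad():
        for i in range(0, len(images), batch_size):
            x = images[i : i + batch_size].transpose(0, 3, 1, 2)
            scores, merged = network.forward_tensors(Tensor(x), training=False)
            logits = merged.data if merged is not None else scores[-1].data
            pred = logits.argmax(axis=1) == TUMOR_CHANNEL
            true = targets[i : i + batch_size, :, :, TUMOR_CHANNEL].astype(bool)
            inter += int(np.logical_and(pred, true).sum())
            union += int(np.logical_or(pred, true).sum())
    return 1.0 if union == 0 else inter / union


def train(network: SegmentationNetwork, train_patches, val_patches,
          train_config: TrainConfig, loss_config: LossConfig,
          augment_fn=None, n_best: int = 5, progress: bool = False,
          ) -> tuple[TrainHistory, list[dict]]:
    """Train with Adam under the step-decay schedule.

    ``train_patches`` should already be resampled (see :mod:`nestseg.balancing`);
    augmentation is applied on the fly through ``augment_fn(image, target, rng)``.
    Validation patches are used as-is.  Returns the history plus checkpoints of
    the ``n_best`` epochs ranked by validation IoU, each a dict with ``epoch``,
    ``val_iou`` and ``state`` (a state-dict for :meth:`Module.load_state_dict`).
    """
    if len(train_patches) == 0:
        raise ValueError("empty training set")
    tr_images, tr_targets = _as_arrays(train_patches)
    val_images, val_targets = _as_arrays(val_patches) if len(val_patches) else (None, None)
    rng = np.random.default_rng(train_config.seed)
    opt = Adam(network.parameters(), lr=train_config.learning_rate)
    history = TrainHistory()
    best: list[dict] = []
    n = len(tr_images)
    for epoch in range(train_config.max_epochs):
        opt.lr = learning_rate_at(epoch, train_config)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            imgs, tgts = tr_images[idx], tr_targets[idx]
            if augment_fn is not None:
                pairs = [augment_fn(im, tg, rng) for im, tg in zip(imgs, tgts)]
                imgs = np.stack([p[0] for p in pairs])
                tgts = np.stack([p[1] for p in pairs])
            network.zero_grad()
            loss = _batch_loss(network, imgs.transpose(0, 3, 1, 2), tgts, loss_config, training=True)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={opt.lr:.2e}); training aborted")
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_iou = (validation_iou(network, val_images, val_targets)
                   if val_images is not None else float("nan"))
        rec = EpochRecord(epoch=epoch, train_loss=float(np.mean(losses)),
                          val_iou=val_iou, lr=opt.lr)
        history.records.append(rec)
        if progress:
            print(f"epoch {epoch:3d}  loss {rec.train_loss:.4f}  "
                  f"val IoU {rec.val_iou:.4f}  lr {rec.lr:.2e}")
        best.append({"epoch": epoch, "val_iou": val_iou,
                     "state": copy.deepcopy(network.state_dict())})
        best.sort(key=lambda c: (-(c["val_iou"] if np.isfinite(c["val_iou"]) else -1.0), c["epoch"]))
        del best[n_best:]
    return history, best
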