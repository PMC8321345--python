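"""UNet variants for tumor-nest segmentation.

Two encoders are available: a *vanilla* UNet-style encoder and the
convolutional backbone of a ResNet34.  Both expose five (in general ``k``)
feature scales at 1/2, 1/4, ... 1/2^k of the input resolution; both start with
a 7x7 stride-2 convolution so a 512-px patch carries wide context at moderate
cost.  The shared decoder mirrors the encoder: each block bilinearly doubles
the resolution, concatenates the symmetric encoder feature (the last block has
no skip connection), and applies two 3x3 conv-BN-ReLU units while halving the
channel count.  Every decoder block additionally owns a 1x1 *score head*
producing a 2-channel (Tumor, Normal) score map psi_hat_l; after a softmax
these become the per-block probability maps psi_l used for deep supervision,
and the final output Phi is psi_{k-1} (or, with the linear-merge strategy, the
softmax of a learned weighted sum of all upsampled score maps).

Class channel 0 is Tumor, channel 1 is Normal, throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor

TUMOR_CHANNEL = 0
NORMAL_CHANNEL = 1


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``base_width`` scales every channel count so CPU-sized test networks share
    the exact topology of the full-width model (width 64).
    """

    encoder_kind: str = "resnet34"
    input_size: int = 512
    in_channels: int = 3
    n_classes: int = 2
    n_decoder_blocks: int = 5
    base_width: int = 64
    use_linear_merge: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.encoder_kind not in ("vanilla", "resnet34"):
            raise ValueError(f"unknown encoder_kind {self.encoder_kind!r}")
        k = self.n_decoder_blocks
        if k < 1:
            raise ValueError("n_decoder_blocks must be >= 1")
        if self.input_size % (2 ** (k + 1)) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^(k+1)={2 ** (k + 1)}"
            )
        if self.n_classes != 2:
            raise ValueError("only the two-class (Tumor/Normal) setting is supported")
        if self.encoder_kind == "resnet34" and k != 5:
            raise ValueError("the resnet34 backbone has exactly 5 stages; k must be 5")


@dataclass
class Patch:
    """A training example: RGB tile plus its one-hot (Tumor, Normal) target."""

    image: np.ndarray  # (H, W, 3) in [0, 1]
    target: np.ndarray  # (H, W, 2) one-hot

    def __post_init__(self):
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be (H, W, 3)")
        if self.target.shape != self.image.shape[:2] + (2,):
            raise ValueError("target must be (H, W, 2) matching the image")


@dataclass
class DecoderOutputs:
    """Per-block score/probability maps and the final map Phi (channel-last)."""

    score_maps: list[np.ndarray]  # psi_hat_l, (h_l, w_l, 2), pre-softmax
    prob_maps: list[np.ndarray]  # psi_l = softmax(psi_hat_l)
    final: np.ndarray  # Phi, (input, input, 2)


@dataclass
class MergeWeights:
    """The k trainable scalars of the linear-merge head."""

    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float32).reshape(-1)


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

class _VanillaEncoder(nn.Module):
    """UNet-style encoder: an initial 7x7/2 block, then double-3x3 blocks that
    halve resolution and double channels."""

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        k = cfg.n_decoder_blocks
        self.widths = [cfg.base_width * (2 ** i) for i in range(k)]
        self.stem = nn.ConvBNReLU(cfg.in_channels, self.widths[0], kernel=7, stride=2, rng=rng)
        self.blocks = nn.Module()
        for i in range(1, k):
            blk = nn.Module()
            blk.c1 = nn.ConvBNReLU(self.widths[i - 1], self.widths[i], stride=2, rng=rng)
            blk.c2 = nn.ConvBNReLU(self.widths[i], self.widths[i], rng=rng)
            setattr(self.blocks, f"b{i}", blk)

    def forward(self, x: Tensor, training: bool) -> list[Tensor]:
        feats = [self.stem.forward(x, training)]
        for i in range(1, len(self.widths)):
            blk = getattr(self.blocks, f"b{i}")
            h = blk.c1.forward(feats[-1], training)
            feats.append(blk.c2.forward(h, training))
        return feats


class _BasicBlock(nn.Module):
    """ResNet basic residual block (two 3x3 convs)."""

    def __init__(self, in_ch, out_ch, stride, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride, pad=0, bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_ch)
            self.has_down = True
        else:
            self.has_down = False

    def forward(self, x: Tensor, training: bool) -> Tensor:
        h = T.relu(self.bn1.forward(self.conv1.forward(x), training))
        h = self.bn2.forward(self.conv2.forward(h), training)
        sc = x
        if self.has_down:
            sc = self.down_bn.forward(self.down_conv.forward(x), training)
        return T.relu(T.add(h, sc))


class _ResNet34Encoder(nn.Module):
    """ResNet34 backbone as 5 feature stages: 7x7/2 stem (1/2 scale), then the
    four residual stages with [3, 4, 6, 3] basic blocks (1/4 ... 1/32)."""

    LAYERS = (3, 4, 6, 3)

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        w = cfg.base_width
        self.widths = [w, w, 2 * w, 4 * w, 8 * w]
        self.stem = nn.ConvBNReLU(cfg.in_channels, w, kernel=7, stride=2, rng=rng)
        self.stages = nn.Module()
        in_ch = w
        for s, (n_blocks, out_ch) in enumerate(zip(self.LAYERS, self.widths[1:])):
            stage = nn.Module()
            for b in range(n_blocks):
                stride = 2 if (b == 0 and s > 0) else 1  # stage 1 downsampling comes from maxpool
                setattr(stage, f"b{b}", _BasicBlock(in_ch, out_ch, stride, rng))
                in_ch = out_ch
            setattr(self.stages, f"s{s}", stage)

    def forward(self, x: Tensor, training: bool) -> list[Tensor]:
        feats = [self.stem.forward(x, training)]
        h = T.max_pool2d(feats[0], kernel=3, stride=2, pad=1)
        for s, n_blocks in enumerate(self.LAYERS):
            stage = getattr(self.stages, f"s{s}")
            for b in range(n_blocks):
                h = getattr(stage, f"b{b}").forward(h, training)
            feats.append(h)
        return feats


# ---------------------------------------------------------------------------
# decoder
# ---------------------------------------------------------------------------

class _DecoderBlock(nn.Module):
    def __init__(self, in_ch, skip_ch, out_ch, n_classes, rng):
        super().__init__()
        self.c1 = nn.ConvBNReLU(in_ch + skip_ch, out_ch, rng=rng)
        self.c2 = nn.ConvBNReLU(out_ch, out_ch, rng=rng)
        self.head = nn.Conv2d(out_ch, n_classes, 1, pad=0, rng=rng)  # 1x1 score head

    def forward(self, x: Tensor, skip: Tensor | None, training: bool) -> tuple[Tensor, Tensor]:
        h, w = x.shape[2] * 2, x.shape[3] * 2
        up = T.upsample_bilinear(x, (h, w))
        if skip is not None:
            up = T.concat([up, skip], axis=1)
        out = self.c2.forward(self.c1.forward(up, training), training)
        return out, self.head.forward(out)


DECODER_MIN_WIDTH = 16


class SegmentationNetwork(nn.Module):
    """Encoder-decoder network with per-block score heads.

    ``forward_tensors`` is the autodiff entry point used by the training loop;
    :func:`forward_segment` wraps it for NumPy in/out inference.
    """

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        if config.encoder_kind == "vanilla":
            self.encoder = _VanillaEncoder(config, rng)
        else:
            self.encoder = _ResNet34Encoder(config, rng)
        k = config.n_decoder_blocks
        enc_widths = self.encoder.widths
        self.decoder = nn.Module()
        in_ch = enc_widths[-1]
        for l in range(k):
            skip_ch = enc_widths[k - 2 - l] if l <= k - 2 else 0
            out_ch = max(in_ch // 2, DECODER_MIN_WIDTH)
            setattr(self.decoder, f"d{l}",
                    _DecoderBlock(in_ch, skip_ch, out_ch, config.n_classes, rng))
            in_ch = out_ch
        if config.use_linear_merge:
            # initialized to the standard-model special case w = (0, ..., 0, 1)
            w0 = np.zeros(k, dtype=np.float32)
            w0[-1] = 1.0
            self.register_parameter("merge_w", w0)
        else:
            self.merge_w = None

    # -- forward ------------------------------------------------------------

    def forward_tensors(self, x: Tensor, training: bool, up_to: int | None = None
                        ) -> tuple[list[Tensor], Tensor | None]:
        """Return the per-block score-map tensors (psi_hat) and, when the
        linear-merge head is enabled and the full decoder ran, the merged
        full-resolution logit map."""
        if x.shape[2] != self.config.input_size or x.shape[3] != self.config.input_size:
            raise ValueError(
                f"input spatial size {x.shape[2:]} does not match configured "
                f"input_size {self.config.input_size}")
        if x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} input channels")
        k = self.config.n_decoder_blocks
        last = k - 1 if up_to is None else up_to
        if not 0 <= last < k:
            raise IndexError(f"block index {last} out of range [0, {k})")
        feats = self.encoder.forward(x, training)
        scores: list[Tensor] = []
        h = feats[-1]
        for l in range(last + 1):
            skip = feats[k - 2 - l] if l <= k - 2 else None
            h, score = getattr(self.decoder, f"d{l}").forward(h, skip, training)
            scores.append(score)
        merged = None
        if self.merge_w is not None and last == k - 1:
            full = (self.config.input_size, self.config.input_size)
            ups = [T.upsample_bilinear(s, full) for s in scores]
            merged = T.weighted_map_sum(ups, self.merge_w)
        return scores, merged

    @property
    def merge_weights(self) -> MergeWeights | None:
        if self.merge_w is None:
            return None
        return MergeWeights(self.merge_w.data.copy())


def build_network(config: NetworkConfig) -> SegmentationNetwork:
    """Construct a UNet variant per ``config`` (deterministic in ``config.seed``)."""
    return SegmentationNetwork(config)


# ---------------------------------------------------------------------------
# NumPy inference API (channel-last in and out)
# ---------------------------------------------------------------------------

def _to_nchw(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 3:
        image = image[None]
    if image.ndim != 4 or image.shape[3] not in (1, 3):
        raise ValueError("image must be (H, W, C) or (N, H, W, C)")
    return image.transpose(0, 3, 1, 2)


def forward_segment(network: SegmentationNetwork, image: np.ndarray) -> DecoderOutputs:
    """Evaluation-mode forward pass: all per-block maps plus the final map Phi.

    ``image`` is a single (H, W, 3) patch or an (N, H, W, 3) batch in [0, 1];
    maps come back channel-last, squeezed when a single patch was given.
    """
    single = np.asarray(image).ndim == 3
    x = _to_nchw(image)
    with T.no_grad():
        scores, merged = network.forward_tensors(Tensor(x), training=False)
    score_np = [s.data.transpose(0, 2, 3, 1) for s in scores]
    prob_np = [T.softmax(s.data, axis=1).transpose(0, 2, 3, 1) for s in scores]
    if merged is not None:
        final = T.softmax(merged.data, axis=1).transpose(0, 2, 3, 1)
    else:
        final = prob_np[-1]
    if single:
        score_np = [s[0] for s in score_np]
        prob_np = [p[0] for p in prob_np]
        final = final[0]
    return DecoderOutputs(score_maps=score_np, prob_maps=prob_np, final=final)


def merge_linear(score_maps: list[np.ndarray], weights: MergeWeights | np.ndarray) -> np.ndarray:
    """Softmax of the weighted sum of bilinearly upsampled score maps (Eq.-style
    linear merge).  The softmax is applied once, after the combination."""
    w = weights.w if isinstance(weights, MergeWeights) else np.asarray(weights, dtype=np.float32)
    if len(score_maps) != w.shape[0]:
        raise ValueError(f"{len(score_maps)} score maps but {w.shape[0]} weights")
    full = max(m.shape[0] for m in score_maps)
    acc = np.zeros((full, full, score_maps[-1].shape[-1]), dtype=np.float32)
    with T.no_grad():
        for wl, m in zip(w, score_maps):
            x = Tensor(np.asarray(m, dtype=np.float32).transpose(2, 0, 1)[None])
            up = T.upsample_bilinear(x, (full, full)).data[0].transpose(1, 2, 0)
            acc += wl * up
    return T.softmax(acc, axis=-1)


def truncated_forward(network: SegmentationNetwork, image: np.ndarray, block_index: int
                      ) -> np.ndarray:
    """Run the encoder plus decoder blocks 0..block_index only, softmax the
    block's score map, and bilinearly upsample it to input resolution.

    Identical to the corresponding prefix of a full forward pass; with
    ``block_index = k-1`` it reproduces the final map exactly.
    """
    single = np.asarray(image).ndim == 3
    x = _to_nchw(image)
    with T.no_grad():
        scores, _ = network.forward_tensors(Tensor(x), training=False, up_to=block_index)
        prob = T.softmax(scores[block_index].data, axis=1)
        full = (network.config.input_size, network.config.input_size)
        up = T.upsample_bilinear(Tensor(prob), full).data
    out = up.transpose(0, 2, 3, 1)
    return out[0] if single else out


def upsampled_block_probabilities(outputs: DecoderOutputs, input_size: int) -> list[np.ndarray]:
    """Per-block probability maps upsampled to input resolution (single patch).

    Equals ``truncated_forward`` for every block, computed from one shared
    forward pass — used to generate all per-block heatmaps at once.
    """
    maps = []
    with T.no_grad():
        for p in outputs.prob_maps:
            x = Tensor(p.transpose(2, 0, 1)[None])
            maps.append(T.upsample_bilinear(x, (input_size, input_size)).data[0].transpose(1, 2, 0))
    return maps


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(network: SegmentationNetwork, path, extra: dict | None = None) -> None:
    """Write parameters with the config embedded, so inference never needs the
    training configuration separately."""
    meta = {"config": asdict(network.config), "extra": extra or {}}
    arrays = {"param:" + k: v for k, v in network.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_network(path) -> tuple[SegmentationNetwork, dict]:
    """Rebuild a network from a checkpoint; returns (network, extra metadata)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")}
    net = build_network(NetworkConfig(**meta["config"]))
    net.load_state_dict(state)
    return net, meta.get("extra", {})
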