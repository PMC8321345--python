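# Methods

## Problem and model

The package addresses margin assessment of basal cell carcinoma on H&E
histology: every physically separate tissue section on a slide must be
declared *Tumor* or *Normal*. The approach is semantic segmentation of
512×512 RGB patches into two classes followed by a rule-based sectionwise
decision, so the pixelwise evidence behind every call remains inspectable.

Two encoder–decoder networks are provided. Both encoders open with a 7×7
stride-2 convolution (base_width filters), so a patch is halved immediately
and the network sees wide context cheaply, and both expose k = 5 feature
scales at 1/2 … 1/32 of the input. The *vanilla* encoder follows the initial
block with double-3×3 blocks (first conv stride 2, channels doubling); the
*resnet34* encoder is the standard 34-layer residual backbone (stem,
max-pool, four basic-block stages of 3/4/6/3 blocks) whose stem output is the
shallowest skip. The decoder has k blocks; block ℓ bilinearly doubles the
resolution, concatenates the symmetric encoder feature (the last block has
none — it upsamples from the 1/2 scale to full resolution without a skip),
and applies two 3×3 convolutions. Every convolution except the 1×1 heads is
followed by batch normalization and ReLU, and padding preserves spatial size.
Each block's 1×1 head yields a score map ψ̂ℓ of side `input/2^(k−1−ℓ)`
(32·2^ℓ for 512-px input); ψℓ is its softmax, and the final map Φ is ψ_{k−1}
unless the linear-merge head is active.

Decoder widths start from the bottleneck channel count and halve per block
with a floor of 16; the floor keeps the shallow blocks expressive when
base_width is scaled down for CPU-sized models, which share the exact
topology of the width-64 configuration.

The whole network stack runs on a small reverse-mode autodiff core
(`nestseg.nn`) written on NumPy: conv via im2col + BLAS, batch norm with
explicit train/eval semantics, bilinear resizing in the half-pixel
(align_corners = False) convention, and a fused focal-from-logits objective.
Every operation's gradient is checked against central differences in the
test suite. Training/eval mode is an explicit argument to `forward`, never
ambient state, so a forward pass is a pure function of its inputs.

## Training

The focal loss `−(1−p_t)^γ log p_t` (γ = 2.0 by default, mean-reduced over
pixels; mean rather than sum so the loss scale is independent of patch and
batch size) down-weights the abundant easy background pixels. Probabilities
are clamped to [1e−7, 1] inside logarithms. Optimization is Adam with
conventional moments (β₁ = 0.9, β₂ = 0.999), base learning rate 5·10⁻⁴
multiplied by 0.8 every 5 epochs, up to 40 epochs with batch 64 at full
scale (scaled-down values are used in the CPU study below). Checkpoints of
the five best epochs by validation IoU are retained; validation data is
never resampled or augmented.

Deep supervision adds a focal term per decoder block against a downsampled
target, with equal weight per scale. The target-downsampling operator Πℓ is
class-preserving 2×2 max decimation on the Tumor channel, re-one-hotted: a
window is Tumor if any of its pixels is. This dialect (rather than
nearest-neighbour decimation) preserves thin tumor strands at coarse scales;
it is isolated behind `downsample_target` and documented as a choice, since
any decimation that maps one-hot maps to one-hot maps would satisfy the same
interface. The linear-merge strategy instead trains
`softmax(Σ_ℓ w_ℓ Γℓ(ψ̂ℓ))`; the weight vector is initialized to
(0, …, 0, 1) — exactly the standard model — so learning starts from the
plain-UNet special case.

Augmentation (rotations, scaling, smoothing, color jitter, elastic
deformation) applies geometric transforms identically to image and target
(nearest-neighbour for the mask, so targets stay exactly one-hot) and
photometric transforms to the image only. Magnitudes default to conservative
ranges and are fully config-exposed.

## Balancing

Patch categories follow the coverage thresholds T ≥ 10 %, T ≥ 0.05 %,
S ≥ 0.05 %, N ≥ 0.05 % with that precedence; the precedence makes the five
categories a partition of the inventory (their counts sum to the inventory
size), and the dense-tumor category realizes the extra oversampling of
tumor-rich patches as a separate target. Comparisons use ≥ on the exact
fractions (0.0005, 0.10), ties falling upward. Oversampling assigns
round-robin repetition counts inside each category — counts differ by at
most one, no patch is dropped — so the plan total equals the sum of targets
exactly. Coverage itself is defined as the fraction of pixel centers
(x + 0.5, y + 0.5) inside the class's polygons; rasterization and the
polygon-repair path (shapely `make_valid`) share this convention with the
target-mask extraction, so coverages and training masks can never disagree.

## Inference pipeline

Tiling places `ceil((L−512)/256)+1` evenly spaced origins per axis (integer
rounding of a linspace), guaranteeing full coverage and ≥ 256 px overlap for
adjacent tiles; sections smaller than a patch get one tile padded with
background white. Overlapping tile predictions are combined by per-pixel
arithmetic mean — order-invariant and a smoother of tile-border artifacts;
max-combination was rejected because it lets a single noisy tile dominate.
Regions are 8-connected components (switchable to 4) of the mask
`p ≥ prediction_threshold`; 8-connectivity avoids splitting thin diagonal
tumor strands. Region area is pixel count × mpp²; the default mpp at the 10×
working magnification is 0.92 μm/px and is configurable (it is metadata of
the section, not of the model). Both threshold comparisons are ≥. A section
is Tumor iff any region with area ≥ the area threshold remains. Heatmaps are
computed per section (the label is per section); tiles entirely outside an
optional tissue mask may be skipped and contribute probability 0.

Truncated inference after block ℓ applies the ℓ-th head and softmax at the
block's native resolution and bilinearly upsamples the probabilities to full
size. Because it is literally a prefix of the full forward pass, the
per-block evaluation computes all k heatmaps from one shared forward pass per
tile; equality with block-by-block truncated passes is asserted in tests.

## Evaluation and selection

Tumor is the positive class. Metrics come from exact confusion counts;
metric denominators of zero yield explicit `None`, never NaN. Fβ uses
β = 1.5 (β² = 2.25 exactly), weighting sensitivity above precision because a
missed tumor section is the costly error in margin control. The threshold
grid search evaluates the full product grid (defaults: prediction 0.30–0.80
step 0.05; area 0–10,240 μm² in 1,280 μm² steps; both configurable),
extracting regions once per prediction threshold. Ties are broken by higher
sensitivity, then lower prediction threshold, then lower area threshold —
the rule being: prefer the more sensitive, less restrictive
configuration. IoU of two empty masks is defined as 1.0 (a correctly empty
prediction is perfect, not undefined).

## Synthetic fixtures

The generator emulates the *structure* of the real data — bright background,
one tissue blob per section, exhaustively annotated tumor nests with stroma
halos, non-exhaustive distractor annotations, sectionwise labels — with
band-limited noise plus speckle textures. It makes no attempt at visual
realism: fixtures must be separable by texture so a width-8 network learns
them in minutes on a CPU. Distractors share the nests' dense dark speckle
but keep a pink base tone, so trained models occasionally emit small
false detections and the area filter is genuinely exercised. Nest polygons
are random star-convex blobs rescaled so the polygon area equals the
requested μm² area exactly; labels are Tumor iff at least one nest polygon
exists, by construction. Everything derives from a single seed (per-split
seeds are CRC-derived, < 2³¹), and identical seeds reproduce identical bytes.

What passing fixture tests does **not** show: robustness to stain variation
beyond mild tone jitter, scanner artifacts, tissue folds, multi-blob
sections, or the hard subtypes (e.g. sclerodermiform growth patterns) that
make the clinical problem difficult. Fixture results validate the plumbing
and the learning dynamics, not clinical performance.

## The scaled end-to-end study

`nestseg.study.run_study` is the package's benchmark: sections of 256–384 px
at mpp 1.0 with ~4,000 μm² nests, 64-px patches (k = 4, width-8 vanilla
encoder), 10 training sections (stride-48 inventory, oversampling multipliers
4/3/2/3 for the T/T-dense/S/N categories), 16 validation and 60 test
sections, 10 epochs of batch 16. The selection grid scales with the
geometry: prediction 0.30–0.80 step 0.05, area 0–2,560 μm² step 320. These
sizes are the package's own study profile, chosen so the complete study —
generation, training, selection, test inference over all decoder blocks —
finishes in minutes on one CPU core while every stage stays non-degenerate.

Two profile choices deserve a note. First, k = 4: the area thresholds of the
sectionwise filter should be large relative to the footprint of one ψ0 cell,
as they are at full scale (where a 5,120 μm² threshold spans ~24 ψ0 cells).
A five-block decoder on 64-px patches leaves ψ0 with 16-px cells, whose
rasterized footprint (256 μm² at mpp 1) is about the size of the scaled
area thresholds — coarse-block detections of small distractors then
straddle the filter and the per-block comparison measures quantization, not
the model. With k = 4 the ψ0 cell is 8 px (64 μm²), restoring the
full-scale regime. Second, the validation split is deliberately larger than
the training split's section count (16 sections): with few validation
sections many threshold pairs tie at a perfect Fβ and the documented
tie-break then picks the most permissive pair, which transfers poorly; more
validation sections make the grid search discriminating. The ψ0-vs-final
agreement statistic is the IoU of the two stitched heatmaps thresholded at
0.5, pooled over validation sections — stitched maps rather than single
tiles, because overlapping-tile averaging removes the tile-boundary
quantization that is an artifact of tiling, not of the decoder.
The acceptance script reports exactly what this study computes at run time.

## Numerical and degenerate-input notes

- Probability maps are asserted to sum to 1 per pixel to 1e−5 (float32).
- Batch norm uses biased batch variance for normalization and running-stat
  updates with momentum 0.1; evaluation mode freezes running statistics.
- `pixel_unbalance` with zero tumor pixels raises rather than returning inf.
- Sections smaller than a patch, blank slides, empty region lists, and empty
  masks all have defined behavior (single padded tile, empty box list,
  Normal call, IoU 1.0 respectively).
- Checkpoints embed the full network configuration, so inference can never
  be run against a mismatched architecture.

## Known limitations

- No pretrained encoders: the residual backbone is randomly initialized
  (ImageNet pretraining would require external weights).
- The NumPy core is single-threaded apart from BLAS; full-width 512-px
  training is out of its intended range — it exists to make the method
  executable and testable, not fast.
- The slide reader handles plain PNG/TIFF with JSON mpp sidecars; pyramidal
  vendor formats are out of scope.
- Grid-search tie-breaking and the Πℓ dialect are documented conventions;
  other reasonable choices exist and are deliberately isolated behind single
  functions.
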