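"""Section -> heatmap -> region -> Tumor/Normal call.

A section image is tiled with at least 50% overlap, each tile is pushed
through a trained network, and the per-tile tumor probabilities are stitched
into a heatmap by per-pixel averaging (order-invariant and smooths tile-border
artifacts).  Thresholding the heatmap gives connected candidate regions whose
physical areas (via the micrometre-per-pixel metadata) are filtered before the
final call: a section is Tumor iff any region at probability >= the prediction
threshold has area >= the area threshold in um^2.

Coordinates are 0-based and half-open everywhere; connectivity of the region
labelling defaults to 8 (switchable to 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

from .models import (
    TUMOR_CHANNEL,
    SegmentationNetwork,
    forward_segment,
    upsampled_block_probabilities,
)

#: default physical resolution (um per pixel) at the 10x working magnification
DEFAULT_MPP = 0.92

TUMOR = "Tumor"
NORMAL = "Normal"


@dataclass
class SectionBox:
    """Half-open bounding box of one tissue section in slide coordinates."""

    row0: int
    col0: int
    row1: int
    col1: int

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row1 - self.row0, self.col1 - self.col0)


@dataclass
class SectionImage:
    image: np.ndarray  # (H, W, 3) RGB in [0, 1]
    mpp: float = DEFAULT_MPP
    section_id: str = "section"
    box: SectionBox | None = None

    def __post_init__(self):
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")


@dataclass
class Heatmap:
    probabilities: np.ndarray  # (H, W) tumor probability
    mpp: float

    def __post_init__(self):
        p = self.probabilities
        if p.size and (p.min() < -1e-6 or p.max() > 1 + 1e-6):
            raise ValueError("heatmap values must lie in [0, 1]")


@dataclass
class TumorRegion:
    coords: np.ndarray  # (n, 2) array of (row, col) pixels
    area_um2: float
    peak_probability: float

    @property
    def n_pixels(self) -> int:
        return len(self.coords)


@dataclass
class SectionResult:
    section_id: str
    regions: list[TumorRegion]  # regions surviving the area filter
    label: str

    @property
    def largest_area_um2(self) -> float:
        return max((r.area_um2 for r in self.regions), default=0.0)


# ---------------------------------------------------------------------------
# section detection
# ---------------------------------------------------------------------------

def detect_sections(slide_image: np.ndarray, intensity_threshold: float = 0.88,
                    saturation_threshold: float = 0.12, min_area_px: int = 256,
                    closing_radius: int = 2) -> list[SectionBox]:
    """Find tissue sections on a bright-background slide image.

    Tissue is whatever is darker than the background or noticeably saturated;
    connected tissue groups become axis-aligned boxes sorted top-left to
    bottom-right (row-major on the box origin).
    """
    img = np.asarray(slide_image, dtype=np.float32)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("slide image must be (H, W, 3)")
    value = img.max(axis=2)
    sat = skcolor.rgb2hsv(img)[..., 1]
    mask = (value < intensity_threshold) | (sat > saturation_threshold)
    if closing_radius:
        mask = ndimage.binary_closing(mask, structure=np.ones((3, 3)),
                                      iterations=closing_radius)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    boxes = []
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        if h * w < min_area_px:
            continue
        boxes.append(SectionBox(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop))
    boxes.sort(key=lambda b: (b.row0, b.col0))
    return boxes


# ---------------------------------------------------------------------------
# tiling and stitching
# ---------------------------------------------------------------------------

def _axis_origins(length: int, patch: int, stride_max: int) -> np.ndarray:
    if length <= patch:
        return np.array([0], dtype=int)
    n = int(np.ceil((length - patch) / stride_max)) + 1
    return np.rint(np.linspace(0, length - patch, n)).astype(int)


def plan_tiles(section_shape: tuple[int, int], patch_size: int = 512,
               min_overlap: int = 256) -> list[tuple[int, int]]:
    """Tile origins (row, col) covering the section with >= ``min_overlap``
    pixels of overlap between adjacent tiles on both axes.

    Sections smaller than the patch yield a single origin (0, 0); callers pad.
    """
    h, w = section_shape[:2]
    if h <= 0 or w <= 0:
        raise ValueError("section dimensions must be positive")
    if patch_size <= min_overlap:
        raise ValueError("patch_size must exceed min_overlap")
    rows = _axis_origins(h, patch_size, patch_size - min_overlap)
    cols = _axis_origins(w, patch_size, patch_size - min_overlap)
    return [(int(r), int(c)) for r in rows for c in cols]


def stitch_heatmap(tile_maps: list[np.ndarray], origins: list[tuple[int, int]],
                   section_shape: tuple[int, int], mpp: float = DEFAULT_MPP) -> Heatmap:
    """Per-pixel mean of all tiles covering each pixel; padded tile parts that
    extend past the section are excluded."""
    h, w = section_shape[:2]
    acc = np.zeros((h, w), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.int32)
    for tile, (r0, c0) in zip(tile_maps, origins):
        th, tw = tile.shape[:2]
        if r0 < 0 or c0 < 0 or r0 >= h or c0 >= w:
            raise ValueError(f"tile origin {(r0, c0)} outside section {section_shape}")
        vh, vw = min(th, h - r0), min(tw, w - c0)
        acc[r0 : r0 + vh, c0 : c0 + vw] += tile[:vh, :vw]
        cnt[r0 : r0 + vh, c0 : c0 + vw] += 1
    if (cnt == 0).any():
        raise ValueError("planned tiles do not cover the section")
    return Heatmap(probabilities=(acc / cnt).astype(np.float32), mpp=mpp)


# ---------------------------------------------------------------------------
# regions and classification
# ---------------------------------------------------------------------------

def extract_regions(heatmap: Heatmap, prediction_threshold: float,
                    connectivity: int = 8) -> list[TumorRegion]:
    """Connected components of the mask probability >= threshold, with
    physical areas in um^2 (pixel count x mpp^2)."""
    if not 0.0 <= prediction_threshold <= 1.0:
        raise ValueError("prediction threshold must be in [0, 1]")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = heatmap.probabilities >= prediction_threshold
    structure = np.ones((3, 3)) if connectivity == 8 else None
    labels, n = ndimage.label(mask, structure=structure)
    regions = []
    px_area = heatmap.mpp ** 2
    for i in range(1, n + 1):
        coords = np.argwhere(labels == i)
        probs = heatmap.probabilities[coords[:, 0], coords[:, 1]]
        regions.append(TumorRegion(coords=coords,
                                   area_um2=float(len(coords) * px_area),
                                   peak_probability=float(probs.max())))
    return regions


def classify_section(regions: list[TumorRegion], area_threshold_um2: float,
                     section_id: str = "section") -> SectionResult:
    """Keep regions with area >= the threshold; Tumor iff any survive."""
    if area_threshold_um2 < 0:
        raise ValueError("area threshold must be non-negative")
    kept = [r for r in regions if r.area_um2 >= area_threshold_um2]
    return SectionResult(section_id=section_id, regions=kept,
                         label=TUMOR if kept else NORMAL)


# ---------------------------------------------------------------------------
# end-to-end inference
# ---------------------------------------------------------------------------

def _pad_tile(img: np.ndarray, r0: int, c0: int, size: int,
              fill: float = 1.0) -> np.ndarray:
    h, w = img.shape[:2]
    tile = np.full((size, size, img.shape[2]), fill, dtype=np.float32)
    vh, vw = min(size, h - r0), min(size, w - c0)
    tile[:vh, :vw] = img[r0 : r0 + vh, c0 : c0 + vw]
    return tile


def compute_heatmaps(section: SectionImage, network: SegmentationNetwork,
                     blocks: list[int] | None = None, min_overlap: int | None = None,
                     tissue_mask: np.ndarray | None = None,
                     batch_size: int = 8) -> dict[int, Heatmap]:
    """Stitched tumor-probability heatmaps for the requested decoder blocks.

    All per-block maps come from one shared forward pass per tile (identical to
    truncated inference, which is a prefix of the full pass).  ``blocks=None``
    means the final block only.  Tiles entirely outside ``tissue_mask`` (when
    given) are skipped and contribute probability 0.
    """
    patch = network.config.input_size
    k = network.config.n_decoder_blocks
    want = [k - 1] if blocks is None else list(blocks)
    for b in want:
        if not 0 <= b < k:
            raise IndexError(f"decoder block {b} out of range [0, {k})")
    overlap = patch // 2 if min_overlap is None else min_overlap
    origins = plan_tiles(section.image.shape[:2], patch_size=patch, min_overlap=overlap)
    tiles = []
    keep_origins = []
    zero_origins = []
    for (r0, c0) in origins:
        if tissue_mask is not None:
            sub = tissue_mask[r0 : r0 + patch, c0 : c0 + patch]
            if not sub.any():
                zero_origins.append((r0, c0))
                continue
        tiles.append(_pad_tile(section.image, r0, c0, patch))
        keep_origins.append((r0, c0))
    maps: dict[int, list[np.ndarray]] = {b: [] for b in want}
    for i in range(0, len(tiles), batch_size):
        batch = np.stack(tiles[i : i + batch_size])
        outputs = forward_segment(network, batch)
        for j in range(len(batch)):
            single = type(outputs)(score_maps=[s[j] for s in outputs.score_maps],
                                   prob_maps=[p[j] for p in outputs.prob_maps],
                                   final=outputs.final[j])
            ups = upsampled_block_probabilities(single, patch)
            for b in want:
                if network.merge_w is not None and b == k - 1:
                    maps[b].append(single.final[..., TUMOR_CHANNEL])
                else:
                    maps[b].append(ups[b][..., TUMOR_CHANNEL])
    zeros = [np.zeros((patch, patch), dtype=np.float32) for _ in zero_origins]
    out = {}
    for b in want:
        out[b] = stitch_heatmap(maps[b] + zeros, keep_origins + zero_origins,
                                section.image.shape[:2], mpp=section.mpp)
    return out


def run_inference(section: SectionImage, network: SegmentationNetwork,
                  prediction_threshold: float, area_threshold_um2: float,
                  block: int | None = None, min_overlap: int | None = None,
                  connectivity: int = 8, tissue_mask: np.ndarray | None = None,
                  ) -> tuple[SectionResult, Heatmap]:
    """Full pipeline on one section: tile, segment (optionally truncated at
    decoder ``block``), stitch, threshold, area-filter, classify."""
    b = network.config.n_decoder_blocks - 1 if block is None else block
    heat = compute_heatmaps(section, network, blocks=[b], min_overlap=min_overlap,
                            tissue_mask=tissue_mask)[b]
    regions = extract_regions(heat, prediction_threshold, connectivity=connectivity)
    result = classify_section(regions, area_threshold_um2, section_id=section.section_id)
    return result, heat


def run_inference_slide(slide_image: np.ndarray, network: SegmentationNetwork,
                        prediction_threshold: float, area_threshold_um2: float,
                        mpp: float = DEFAULT_MPP, slide_id: str = "slide",
                        **kwargs) -> list[tuple[SectionResult, Heatmap]]:
    """Detect sections on a slide image and classify each independently."""
    results = []
    for i, box in enumerate(detect_sections(slide_image)):
        sec = SectionImage(image=slide_image[box.row0 : box.row1, box.col0 : box.col1],
                           mpp=mpp, section_id=f"{slide_id}:{i}", box=box)
        results.append(run_inference(sec, network, prediction_threshold,
                                     area_threshold_um2, **kwargs))
    return results
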