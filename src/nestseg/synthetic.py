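"""Synthetic histology-like fixtures.

Generates tissue sections on a bright background with implanted tumor nests
(dark, basophilic, densely speckled blobs), surrounding stroma halos and
benign distractor structures, together with pixel-accurate polygon
annotations (Tumornest / Stroma / Normal) and sectionwise Tumor/Normal
labels.  The textures are band-limited noise plus speckle clusters — they
make no attempt at visual realism, only at being separable by texture so a
small network can learn them quickly on a CPU.  Distractors deliberately
share part of the nests' appearance (dark nuclear speckle) so the
area/threshold filtering stage is genuinely exercised by occasional small
false positives.

Everything is deterministic in the seed: the same seed reproduces the same
sections, annotations and labels byte for byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely import affinity
from shapely.geometry import Polygon

from .balancing import (
    CLASS_NORMAL,
    CLASS_STROMA,
    CLASS_TUMORNEST,
    rasterize_polygons,
    repair_polygon,
)
from .pipeline import NORMAL, TUMOR, SectionImage

ANNOTATED_SPLITS = ("train", "val_i")


@dataclass
class FixtureParams:
    """Knobs of the generator; defaults describe the standard fixture scale."""

    n_sections: int = 16
    size_range: tuple[int, int] = (1024, 2048)  # px, per axis
    mpp: float = 1.0  # um per pixel of the synthetic sections
    tumor_prevalence: float = 0.5  # fraction of sections labelled Tumor
    nest_count_range: tuple[int, int] = (1, 3)
    nest_area_median_um2: float = 15000.0
    nest_area_sigma: float = 0.35  # lognormal spread of nest areas
    stroma_halo_um: float = 25.0
    distractor_count_range: tuple[int, int] = (0, 3)
    distractor_area_median_um2: float = 1200.0
    distractor_area_sigma: float = 0.4
    background_texture_scale: float = 6.0  # px, band-limited noise correlation
    stain_variation: float = 0.04  # per-section color-tone jitter
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.tumor_prevalence <= 1.0:
            raise ValueError("tumor prevalence must be in [0, 1]")
        if min(self.size_range) <= 0 or self.mpp <= 0:
            raise ValueError("sizes and mpp must be positive")


@dataclass
class SectionRecord:
    section: SectionImage
    annotations: dict[str, list[Polygon]]
    label: str


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _blob_polygon(cx: float, cy: float, area_px: float, rng: np.random.Generator,
                  roughness: float = 0.15, n_vertices: int = 48) -> Polygon:
    """Random star-convex blob rescaled so its polygon area equals ``area_px``."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.ones_like(theta)
    for harmonic in range(1, 5):
        amp = rng.normal(0.0, roughness / harmonic)
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(harmonic * theta + phase)
    r = np.clip(r, 0.2, None)
    poly = Polygon(np.column_stack([np.cos(theta) * r, np.sin(theta) * r]))
    poly = repair_polygon(poly)
    scale = np.sqrt(area_px / poly.area)
    poly = affinity.scale(poly, xfact=scale, yfact=scale, origin=(0, 0))
    return affinity.translate(poly, xoff=cx, yoff=cy)


def _place_blob(area_px: float, allowed: np.ndarray, occupied, rng,
                roughness: float = 0.15, tries: int = 40) -> Polygon | None:
    """Sample a blob of the given area whose footprint stays inside ``allowed``
    and clear of ``occupied``; None when no placement is found."""
    radius = int(np.ceil(np.sqrt(area_px / np.pi) * 1.3))
    interior = ndimage.binary_erosion(allowed, iterations=max(radius, 1))
    candidates = np.argwhere(interior)
    if len(candidates) == 0:
        return None
    for _ in range(tries):
        cy, cx = candidates[rng.integers(len(candidates))]
        poly = _blob_polygon(float(cx), float(cy), area_px, rng, roughness)
        if occupied is None or not poly.intersects(occupied):
            return poly
    return None


# ---------------------------------------------------------------------------
# texture rendering
# ---------------------------------------------------------------------------

def _band_noise(shape, scale, rng):
    return ndimage.gaussian_filter(rng.standard_normal(shape), scale)


def _speckle(shape, rng, density: float, size: float = 1.2):
    """Nuclei-like dark speckle: thresholded fine-scale noise."""
    fine = ndimage.gaussian_filter(rng.standard_normal(shape), size)
    thr = np.quantile(fine, 1.0 - density)
    return fine > thr


def _paint(image, mask, base_rgb, rng, noise_scale, noise_amp,
           speckle_density, speckle_darkness):
    if not mask.any():
        return
    h, w = mask.shape
    tone = _band_noise((h, w), noise_scale, rng) * noise_amp
    spots = _speckle((h, w), rng, speckle_density)
    for c, base in enumerate(base_rgb):
        layer = base + tone
        layer = np.where(spots, layer * (1.0 - speckle_darkness), layer)
        image[..., c][mask] = layer[mask]


# ---------------------------------------------------------------------------
# section generation
# ---------------------------------------------------------------------------

def generate_section(params: FixtureParams, rng: np.random.Generator,
                     section_id: str = "section", force_label: str | None = None
                     ) -> SectionRecord:
    """One synthetic section with annotations and its Tumor/Normal label.

    ``force_label`` pins the outcome (used by the balanced split assignment);
    otherwise the label is drawn from ``tumor_prevalence``.
    """
    h = int(rng.integers(params.size_range[0], params.size_range[1] + 1))
    w = int(rng.integers(params.size_range[0], params.size_range[1] + 1))
    if force_label is None:
        label = TUMOR if rng.uniform() < params.tumor_prevalence else NORMAL
    else:
        label = force_label

    # tissue blob on a bright background
    tissue_poly = _blob_polygon(w / 2 + rng.uniform(-w * 0.05, w * 0.05),
                                h / 2 + rng.uniform(-h * 0.05, h * 0.05),
                                0.52 * h * w, rng, roughness=0.12)
    tissue_poly = tissue_poly.intersection(
        Polygon([(1, 1), (w - 1, 1), (w - 1, h - 1), (1, h - 1)]))
    tissue = rasterize_polygons([tissue_poly], h, w)

    image = np.empty((h, w, 3), dtype=np.float32)
    for c, base in enumerate((0.96, 0.95, 0.96)):
        image[..., c] = base + 0.01 * _band_noise((h, w), 2.0, rng)

    tone = rng.normal(0.0, params.stain_variation, size=3)
    tissue_rgb = np.clip(np.array([0.90, 0.72, 0.82]) + tone, 0, 1)
    nest_rgb = np.clip(np.array([0.45, 0.32, 0.60]) + tone, 0, 1)
    stroma_rgb = np.clip(np.array([0.84, 0.76, 0.86]) + tone, 0, 1)
    distractor_rgb = np.clip(np.array([0.78, 0.55, 0.68]) + tone, 0, 1)

    _paint(image, tissue, tissue_rgb, rng, params.background_texture_scale,
           0.05, speckle_density=0.04, speckle_darkness=0.35)

    px_area = params.mpp ** 2
    annotations: dict[str, list[Polygon]] = {CLASS_TUMORNEST: [], CLASS_STROMA: [],
                                             CLASS_NORMAL: []}
    occupied = None

    n_nests = 0
    if label == TUMOR:
        lo, hi = params.nest_count_range
        n_nests = int(rng.integers(max(lo, 1), hi + 1))
    for _ in range(n_nests):
        area_um2 = float(rng.lognormal(np.log(params.nest_area_median_um2),
                                       params.nest_area_sigma))
        area_px = area_um2 / px_area
        if area_px >= 0.5 * tissue.sum():
            raise ValueError(
                f"nest area {area_um2:.0f} um^2 does not fit a {h}x{w} section "
                f"at mpp {params.mpp}")
        poly = _place_blob(area_px, tissue, occupied, rng)
        if poly is None:
            continue
        halo_px = params.stroma_halo_um / params.mpp
        stroma_poly = poly.buffer(halo_px).difference(poly).intersection(tissue_poly)
        nest_mask = rasterize_polygons([poly], h, w)
        stroma_mask = rasterize_polygons([stroma_poly], h, w) & tissue
        _paint(image, stroma_mask, stroma_rgb, rng,
               params.background_texture_scale * 0.8, 0.04,
               speckle_density=0.02, speckle_darkness=0.3)
        _paint(image, nest_mask & tissue, nest_rgb, rng,
               params.background_texture_scale * 0.5, 0.06,
               speckle_density=0.22, speckle_darkness=0.45)
        annotations[CLASS_TUMORNEST].append(poly)
        if not stroma_poly.is_empty:
            annotations[CLASS_STROMA].append(stroma_poly)
        occupied = poly.buffer(halo_px * 2) if occupied is None \
            else occupied.union(poly.buffer(halo_px * 2))

    if n_nests and not annotations[CLASS_TUMORNEST]:
        raise RuntimeError("could not place any tumor nest; enlarge the section "
                           "or shrink the nest area distribution")
    label = TUMOR if annotations[CLASS_TUMORNEST] else NORMAL

    lo, hi = params.distractor_count_range
    n_distractors = int(rng.integers(lo, hi + 1))
    for _ in range(n_distractors):
        area_um2 = float(rng.lognormal(np.log(params.distractor_area_median_um2),
                                       params.distractor_area_sigma))
        poly = _place_blob(area_um2 / px_area, tissue, occupied, rng, roughness=0.1)
        if poly is None:
            continue
        mask = rasterize_polygons([poly], h, w) & tissue
        # shares the nests' dense dark speckle but keeps a pink-ish base tone
        _paint(image, mask, distractor_rgb, rng,
               params.background_texture_scale * 0.5, 0.05,
               speckle_density=0.18, speckle_darkness=0.45)
        annotations[CLASS_NORMAL].append(poly)
        occupied = poly.buffer(4.0) if occupied is None else occupied.union(poly.buffer(4.0))

    image = np.clip(image, 0.0, 1.0)
    section = SectionImage(image=image, mpp=params.mpp, section_id=section_id)
    return SectionRecord(section=section, annotations=annotations, label=label)


def generate_split(params: FixtureParams, split_name: str = "split",
                   seed: int | None = None) -> list[SectionRecord]:
    """A list of sections with a balanced label assignment: exactly
    round(prevalence * n) sections are Tumor, in seed-shuffled order."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_sections
    n_tumor = int(round(params.tumor_prevalence * n))
    labels = np.array([TUMOR] * n_tumor + [NORMAL] * (n - n_tumor))
    rng.shuffle(labels)
    return [generate_section(params, rng, section_id=f"{split_name}_{i:03d}",
                             force_label=labels[i]) for i in range(n)]


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------

def split_seed(master_seed: int, split_name: str) -> int:
    """Stable per-split seed derived from the master seed (< 2^31)."""
    return (master_seed * 1_000_003 + zlib.crc32(split_name.encode())) % (2 ** 31)


def generate_dataset(out_dir, params_by_split: dict[str, FixtureParams],
                     master_seed: int = 0, force: bool = False) -> dict:
    """Write a train/validation/test tree and return its manifest.

    Detailed GeoJSON annotations are written for the annotated splits
    ("train", "val_i"), sectionwise label CSVs and mpp sidecars for every
    split, mirroring a study setup where exhaustive annotation is affordable
    only for a fraction of the data.
    """
    from . import io as nio

    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty; pass force=True")
    manifest = {"master_seed": master_seed, "splits": {}}
    hasher_input = []
    for split_name, params in params_by_split.items():
        seed = split_seed(master_seed, split_name)
        records = generate_split(params, split_name=split_name, seed=seed)
        split_dir = out_dir / split_name
        split_dir.mkdir(parents=True, exist_ok=True)
        labels = {}
        for rec in records:
            png = nio.save_section(rec.section, split_dir / f"{rec.section.section_id}.png")
            hasher_input.append(png.read_bytes())
            if split_name in ANNOTATED_SPLITS:
                ann_path = split_dir / f"{rec.section.section_id}.geojson"
                nio.save_annotations(rec.annotations, ann_path)
                hasher_input.append(ann_path.read_bytes())
            labels[rec.section.section_id] = rec.label
        nio.save_labels_csv(labels, split_dir / "labels.csv")
        manifest["splits"][split_name] = {
            "seed": seed, "n_sections": len(records),
            "n_tumor": sum(1 for r in records if r.label == TUMOR),
            "params": asdict(params), "annotated": split_name in ANNOTATED_SPLITS,
        }
    manifest["content_crc32"] = zlib.crc32(b"".join(hasher_input))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
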