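"""Patch inventory, class-imbalance resampling and augmentation.

Training patches are tiled from annotated sections.  For every patch we
compute the fraction of its pixels covered by *Tumornest* (T), *Stroma* (S)
and *Normal* (N) polygon annotations, and assign it to exactly one of five
disjoint categories with precedence

    T >= 10%  >  T >= 0.05%  >  S >= 0.05%  >  N >= 0.05%  >  background (T < 0.05%)

Tumor-containing, stroma and distractor categories are then oversampled to
per-category target counts (patches repeat; none are dropped), which lowers
the pixelwise tumor/non-tumor unbalance the training stream sees.  Threshold
comparisons use >= on the exact fractions 0.0005 and 0.10; a tie falls into
the higher category.

Coordinates are 0-based with half-open tiles; polygon coordinates are
(x, y) = (column, row) in the same pixel frame, and a pixel counts as covered
when its center (x+0.5, y+0.5) lies inside the polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon, mapping, shape as shapely_shape
from shapely.validation import make_valid

from .models import TUMOR_CHANNEL, Patch

CLASS_TUMORNEST = "Tumornest"
CLASS_STROMA = "Stroma"
CLASS_NORMAL = "Normal"
ANNOTATION_CLASSES = (CLASS_TUMORNEST, CLASS_STROMA, CLASS_NORMAL)

CAT_BACKGROUND = "T<0.05%"
CAT_T_LOW = "T>=0.05%"
CAT_T_HIGH = "T>=10%"
CAT_S = "S>=0.05%"
CAT_N = "N>=0.05%"
CATEGORIES = (CAT_BACKGROUND, CAT_T_LOW, CAT_T_HIGH, CAT_S, CAT_N)

T_HIGH_THRESHOLD = 0.10
PRESENCE_THRESHOLD = 0.0005  # 0.05%


@dataclass
class PatchRecord:
    patch_id: str
    section_id: str
    origin_x: int
    origin_y: int
    tile_size: int
    coverage_t: float = 0.0
    coverage_s: float = 0.0
    coverage_n: float = 0.0

    def __post_init__(self):
        for c in (self.coverage_t, self.coverage_s, self.coverage_n):
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coverage {c} outside [0, 1]")


@dataclass
class ResamplingPlan:
    """Per-category targets and the per-patch repetition counts realizing them."""

    targets: dict[str, int]
    repetitions: dict[str, int]  # patch_id -> count (>= 1)

    @property
    def total(self) -> int:
        return sum(self.repetitions.values())


# ---------------------------------------------------------------------------
# annotations and rasterization
# ---------------------------------------------------------------------------

def repair_polygon(geom):
    """Return a valid polygonal geometry, or raise if unrepairable."""
    if geom.is_valid:
        return geom
    fixed = make_valid(geom)
    if fixed.is_empty or fixed.geom_type not in ("Polygon", "MultiPolygon", "GeometryCollection"):
        raise ValueError(f"cannot repair invalid polygon: {shapely.is_valid_reason(geom)}")
    if fixed.geom_type == "GeometryCollection":
        polys = [g for g in fixed.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        if not polys:
            raise ValueError("invalid polygon repaired to a non-areal geometry")
        fixed = shapely.unary_union(polys)
    return fixed


def rasterize_polygons(polygons, height: int, width: int,
                       origin_x: int = 0, origin_y: int = 0) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside any polygon.

    The mask covers the half-open window [origin_y, origin_y+height) x
    [origin_x, origin_x+width).
    """
    mask = np.zeros((height, width), dtype=bool)
    if not polygons:
        return mask
    geom = shapely.unary_union([repair_polygon(p) for p in polygons])
    minx, miny, maxx, maxy = geom.bounds
    x0 = max(int(np.floor(minx - origin_x - 0.5)), 0)
    x1 = min(int(np.ceil(maxx - origin_x + 0.5)), width)
    y0 = max(int(np.floor(miny - origin_y - 0.5)), 0)
    y1 = min(int(np.ceil(maxy - origin_y + 0.5)), height)
    if x0 >= x1 or y0 >= y1:
        return mask
    xs = origin_x + np.arange(x0, x1) + 0.5
    ys = origin_y + np.arange(y0, y1) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(gy.shape)
    mask[y0:y1, x0:x1] = inside
    return mask


def compute_coverage(origin_x: int, origin_y: int, tile_size: int,
                     annotations: dict[str, list[Polygon]]) -> tuple[float, float, float]:
    """Fractions of tile pixels covered by each annotation class (T, S, N)."""
    fracs = []
    for cls in ANNOTATION_CLASSES:
        mask = rasterize_polygons(annotations.get(cls, []), tile_size, tile_size,
                                  origin_x=origin_x, origin_y=origin_y)
        fracs.append(float(mask.mean()))
    return tuple(fracs)


def annotations_to_geojson(annotations: dict[str, list[Polygon]]) -> dict:
    features = []
    for cls in ANNOTATION_CLASSES:
        for poly in annotations.get(cls, []):
            features.append({"type": "Feature", "properties": {"class": cls},
                             "geometry": mapping(poly)})
    return {"type": "FeatureCollection", "features": features}


def annotations_from_geojson(collection: dict) -> dict[str, list[Polygon]]:
    out: dict[str, list[Polygon]] = {cls: [] for cls in ANNOTATION_CLASSES}
    for feat in collection.get("features", []):
        cls = feat.get("properties", {}).get("class")
        if cls not in out:
            raise ValueError(f"unknown annotation class {cls!r}")
        geom = shapely_shape(feat["geometry"])
        out[cls].append(geom)
    return out


# ---------------------------------------------------------------------------
# categorization and resampling
# ---------------------------------------------------------------------------

def categorize_patch(record: PatchRecord) -> str:
    """Assign exactly one of the five disjoint categories (documented precedence)."""
    if record.coverage_t >= T_HIGH_THRESHOLD:
        return CAT_T_HIGH
    if record.coverage_t >= PRESENCE_THRESHOLD:
        return CAT_T_LOW
    if record.coverage_s >= PRESENCE_THRESHOLD:
        return CAT_S
    if record.coverage_n >= PRESENCE_THRESHOLD:
        return CAT_N
    return CAT_BACKGROUND


def build_resampling_plan(inventory: list[PatchRecord],
                          targets: dict[str, int]) -> ResamplingPlan:
    """Assign per-patch repetition counts so each category hits its target count.

    Within a category, counts are distributed round-robin (they differ by at
    most one across its patches, and every patch keeps at least one draw).
    """
    by_cat: dict[str, list[PatchRecord]] = {c: [] for c in CATEGORIES}
    for rec in inventory:
        by_cat[categorize_patch(rec)].append(rec)
    reps: dict[str, int] = {}
    for cat in CATEGORIES:
        members = by_cat[cat]
        target = targets.get(cat, len(members))
        if target != len(members) and not members:
            raise ValueError(f"category {cat!r} is empty but has target {target}")
        if not members:
            continue
        if target < len(members):
            raise ValueError(
                f"target {target} for category {cat!r} is below its current count "
                f"{len(members)}; no patch may be dropped")
        base, extra = divmod(target, len(members))
        for i, rec in enumerate(members):
            reps[rec.patch_id] = base + (1 if i < extra else 0)
    return ResamplingPlan(targets=dict(targets), repetitions=reps)


def expand_plan(inventory: list[PatchRecord], plan: ResamplingPlan) -> list[PatchRecord]:
    """Materialize the resampled patch list (records repeated per the plan)."""
    out = []
    for rec in inventory:
        out.extend([rec] * plan.repetitions.get(rec.patch_id, 1))
    return out


def pixel_unbalance(inventory: list[PatchRecord],
                    plan: ResamplingPlan | None = None) -> float:
    """Ratio of tumor-free to tumor pixels over the (optionally resampled) set."""
    tumor = 0.0
    total = 0.0
    for rec in inventory:
        reps = plan.repetitions.get(rec.patch_id, 1) if plan is not None else 1
        area = float(rec.tile_size) ** 2 * reps
        tumor += rec.coverage_t * area
        total += area
    if tumor == 0.0:
        raise ValueError("pixel unbalance is undefined: the inventory has no tumor pixels")
    return (total - tumor) / tumor


# ---------------------------------------------------------------------------
# inventory construction from annotated sections
# ---------------------------------------------------------------------------

def build_inventory(section_id: str, section_shape: tuple[int, int], tile_size: int,
                    annotations: dict[str, list[Polygon]],
                    stride: int | None = None) -> list[PatchRecord]:
    """Tile a section into a patch inventory with annotation coverages."""
    stride = stride or tile_size
    h, w = section_shape[:2]
    records = []
    for oy in range(0, max(h - tile_size, 0) + 1, stride):
        for ox in range(0, max(w - tile_size, 0) + 1, stride):
            cov_t, cov_s, cov_n = compute_coverage(ox, oy, tile_size, annotations)
            records.append(PatchRecord(
                patch_id=f"{section_id}:{ox}:{oy}", section_id=section_id,
                origin_x=ox, origin_y=oy, tile_size=tile_size,
                coverage_t=cov_t, coverage_s=cov_s, coverage_n=cov_n))
    return records


def extract_patch(section_image: np.ndarray, record: PatchRecord,
                  annotations: dict[str, list[Polygon]]) -> Patch:
    """Cut the tile and rasterize its Tumornest target as a one-hot map."""
    s = record.tile_size
    tile = section_image[record.origin_y : record.origin_y + s,
                         record.origin_x : record.origin_x + s]
    tumor = rasterize_polygons(annotations.get(CLASS_TUMORNEST, []), s, s,
                               origin_x=record.origin_x, origin_y=record.origin_y)
    target = np.zeros((s, s, 2), dtype=np.float32)
    target[..., TUMOR_CHANNEL] = tumor
    target[..., 1 - TUMOR_CHANNEL] = ~tumor
    return Patch(image=np.asarray(tile, dtype=np.float32), target=target)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    """Magnitudes for on-the-fly augmentation; all ranges are conservative and
    fully exposed.  Zeros/None disable each transform (an all-default
    ``AugmentConfig(enabled=False)`` is the identity)."""

    enabled: bool = True
    rotation_degrees: tuple[float, float] = (-180.0, 180.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    smooth_sigma_range: tuple[float, float] = (0.0, 1.0)
    smooth_prob: float = 0.3
    color_jitter: float = 0.08  # multiplicative/additive per-channel strength
    elastic_alpha: float = 4.0  # displacement amplitude, pixels
    elastic_sigma: float = 8.0  # displacement field smoothness, pixels
    elastic_prob: float = 0.5


def _geometric_pair(image, tumor, transform):
    """Apply the same spatial transform to image (linear) and mask (nearest)."""
    img = np.stack([transform(image[..., c], order=1) for c in range(image.shape[-1])], axis=-1)
    msk = transform(tumor, order=0)
    return img, msk


def augment(image: np.ndarray, target_map: np.ndarray, rng: np.random.Generator,
            config: AugmentConfig = AugmentConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Paired augmentation: rotation, scaling, elastic deformation (applied
    identically to image and target) and smoothing/color jitter (image only).
    The returned target stays exactly one-hot."""
    if not config.enabled:
        return image, target_map
    image = np.asarray(image, dtype=np.float32)
    tumor = np.asarray(target_map[..., TUMOR_CHANNEL], dtype=np.float32)

    lo, hi = config.rotation_degrees
    if hi > lo or lo != 0.0:
        angle = float(rng.uniform(lo, hi))
        if angle != 0.0:
            image, tumor = _geometric_pair(
                image, tumor,
                lambda a, order: ndimage.rotate(a, angle, reshape=False, order=order,
                                                mode="reflect"))

    s_lo, s_hi = config.scale_range
    if s_hi > s_lo or s_lo != 1.0:
        factor = float(rng.uniform(s_lo, s_hi))
        if factor != 1.0:
            center = (np.asarray(tumor.shape, dtype=np.float64) - 1.0) / 2.0
            matrix = np.eye(2) / factor
            offset = center - matrix @ center
            image, tumor = _geometric_pair(
                image, tumor,
                lambda a, order: ndimage.affine_transform(a, matrix, offset=offset,
                                                          order=order, mode="reflect"))

    if config.elastic_alpha > 0 and rng.uniform() < config.elastic_prob:
        shape = tumor.shape
        dy = ndimage.gaussian_filter(rng.standard_normal(shape), config.elastic_sigma) * config.elastic_alpha
        dx = ndimage.gaussian_filter(rng.standard_normal(shape), config.elastic_sigma) * config.elastic_alpha
        yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        coords = (yy + dy, xx + dx)
        image, tumor = _geometric_pair(
            image, tumor,
            lambda a, order: ndimage.map_coordinates(a, coords, order=order, mode="reflect"))

    if config.smooth_sigma_range[1] > 0 and rng.uniform() < config.smooth_prob:
        sigma = float(rng.uniform(*config.smooth_sigma_range))
        if sigma > 0:
            image = np.stack([ndimage.gaussian_filter(image[..., c], sigma)
                              for c in range(image.shape[-1])], axis=-1)

    if config.color_jitter > 0:
        mult = 1.0 + rng.uniform(-config.color_jitter, config.color_jitter, size=3)
        shift = rng.uniform(-config.color_jitter, config.color_jitter, size=3)
        image = image * mult[None, None, :] + shift[None, None, :]

    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    tumor_bin = tumor > 0.5
    out_target = np.zeros_like(target_map)
    out_target[..., TUMOR_CHANNEL] = tumor_bin
    out_target[..., 1 - TUMOR_CHANNEL] = ~tumor_bin
    return image, out_target
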