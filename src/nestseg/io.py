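"""File formats: sections (PNG/TIFF + JSON mpp sidecar), GeoJSON annotations,
label/inventory/result CSVs and heatmap PNGs."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .balancing import (
    PatchRecord,
    ResamplingPlan,
    annotations_from_geojson,
    annotations_to_geojson,
    categorize_patch,
)
from .pipeline import Heatmap, SectionImage, SectionResult


def _to_uint8(image: np.ndarray) -> np.ndarray:
    if image.dtype == np.uint8:
        return image
    return np.clip(np.asarray(image) * 255.0 + 0.5, 0, 255).astype(np.uint8)


def _to_float(image: np.ndarray) -> np.ndarray:
    if image.dtype == np.uint8:
        return image.astype(np.float32) / 255.0
    return np.asarray(image, dtype=np.float32)


def save_section(section: SectionImage, path) -> Path:
    """Write the section image plus a JSON sidecar with mpp metadata."""
    path = Path(path)
    data = _to_uint8(section.image)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"section_id": section.section_id, "mpp": section.mpp}))
    return path


def load_section(path) -> SectionImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing mpp sidecar {sidecar}; physical areas need mpp metadata")
    meta = json.loads(sidecar.read_text())
    return SectionImage(image=_to_float(data), mpp=float(meta["mpp"]),
                        section_id=str(meta.get("section_id", path.stem)))


def save_annotations(annotations, path) -> None:
    Path(path).write_text(json.dumps(annotations_to_geojson(annotations)))


def load_annotations(path):
    return annotations_from_geojson(json.loads(Path(path).read_text()))


def save_labels_csv(labels: dict[str, str], path) -> None:
    pd.DataFrame({"section_id": list(labels), "label": list(labels.values())}
                 ).to_csv(path, index=False)


def load_labels_csv(path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df["section_id"], df["label"]))


def save_heatmap(heatmap: Heatmap, path, extra_meta: dict | None = None) -> None:
    """Probability x 255 as single-channel 8-bit PNG, plus JSON metadata."""
    path = Path(path)
    iio.imwrite(path, np.clip(heatmap.probabilities * 255.0 + 0.5, 0, 255).astype(np.uint8))
    meta = {"mpp": heatmap.mpp, **(extra_meta or {})}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_heatmap(path) -> Heatmap:
    path = Path(path)
    probs = iio.imread(path).astype(np.float32) / 255.0
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return Heatmap(probabilities=probs, mpp=float(meta["mpp"]))


def save_results_csv(results: list[SectionResult], path) -> None:
    pd.DataFrame([{"section_id": r.section_id, "label": r.label,
                   "n_regions": len(r.regions),
                   "largest_area_um2": r.largest_area_um2} for r in results]
                 ).to_csv(path, index=False)


def save_inventory_csv(inventory: list[PatchRecord], path,
                       plan: ResamplingPlan | None = None) -> None:
    rows = []
    for rec in inventory:
        rows.append({
            "patch_id": rec.patch_id, "section_id": rec.section_id,
            "origin_x": rec.origin_x, "origin_y": rec.origin_y,
            "tile_size": rec.tile_size,
            "coverage_T": rec.coverage_t, "coverage_S": rec.coverage_s,
            "coverage_N": rec.coverage_n, "category": categorize_patch(rec),
            "repetitions": plan.repetitions.get(rec.patch_id, 1) if plan else 1,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_inventory_csv(path) -> tuple[list[PatchRecord], dict[str, int]]:
    df = pd.read_csv(path)
    records, reps = [], {}
    for row in df.itertuples():
        records.append(PatchRecord(
            patch_id=row.patch_id, section_id=row.section_id,
            origin_x=int(row.origin_x), origin_y=int(row.origin_y),
            tile_size=int(row.tile_size), coverage_t=float(row.coverage_T),
            coverage_s=float(row.coverage_S), coverage_n=float(row.coverage_N)))
        reps[row.patch_id] = int(row.repetitions)
    return records, reps
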