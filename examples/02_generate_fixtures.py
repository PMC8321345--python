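"""Generate synthetic annotated sections and inspect the patch inventory.

Creates a handful of histology-like sections with tumor-nest / stroma / normal
polygon annotations, tiles one of them into 64-px patches, and shows how the
category counts and the tumor-pixel unbalance change under oversampling.
"""

from collections import Counter

from nestseg import balancing as bal
from nestseg.synthetic import FixtureParams, generate_split

params = FixtureParams(n_sections=6, size_range=(256, 384), mpp=1.0,
                       nest_area_median_um2=4000, nest_area_sigma=0.3,
                       stroma_halo_um=12, distractor_area_median_um2=700)
records = generate_split(params, "demo", seed=7)
print("labels:", [r.label for r in records])

inventory = []
for rec in records:
    inventory += bal.build_inventory(rec.section.section_id,
                                     rec.section.image.shape[:2], 64,
                                     rec.annotations, stride=64)
counts = Counter(bal.categorize_patch(r) for r in inventory)
print(f"{len(inventory)} patches by category:", dict(counts))

targets = {bal.CAT_T_LOW: counts[bal.CAT_T_LOW] * 4,
           bal.CAT_T_HIGH: counts[bal.CAT_T_HIGH] * 3,
           bal.CAT_S: counts[bal.CAT_S] * 2,
           bal.CAT_N: counts[bal.CAT_N] * 2}
plan = bal.build_resampling_plan(inventory, targets)
print(f"plan: {len(inventory)} patches -> {plan.total} draws")
print(f"tumor-free : tumor pixel ratio  "
      f"{bal.pixel_unbalance(inventory):.1f} before, "
      f"{bal.pixel_unbalance(inventory, plan):.1f} after resampling")
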