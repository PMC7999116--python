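"""Locate the displacement threshold with ROC curves and Youden's index.

Builds a slice-level dataset directly from the response model (no meshes —
this isolates the statistics): each of 45 simulated patients contributes
25 slices whose ΔArea% is noise below the 5.5 mm threshold and linear
above it.  A slice is "positive" when ΔArea% ≥ +50; sweeping the
patient-level AP displacement as the classifier score yields the ROC, and
the threshold maximising J = sensitivity + specificity − 1 estimates θ.
"""

import numpy as np
import pandas as pd

from airwaymorph import ResponseModel, SliceDataset, roc_threshold
from airwaymorph.metrics import REGION_NAMES, SLAB_REGIONS
from airwaymorph.synth import draw_displacement

rng = np.random.default_rng(3)
response = ResponseModel(theta=5.5, slope=25.0, noise_sd=15.0)

rows = []
for i in range(45):
    group = "MMA" if i < 29 else "MAMS"
    mx = draw_displacement(group, "maxilla", rng)
    md = draw_displacement(group, "mandible", rng)
    deltas = response.draw_slab_deltas(mx, md, rng)
    for slab, (region, d) in enumerate(zip(SLAB_REGIONS, deltas), start=1):
        rows.append(dict(patient=f"P{i:03d}", group=group, maxilla_ap=mx,
                         mandible_ap=md, slab=slab, region=region,
                         delta_area_pct=d))
slices = pd.DataFrame(rows)
vols = slices.groupby("patient", as_index=False).first()[
    ["patient", "group", "maxilla_ap", "mandible_ap"]]
vols["delta_volume_pct"] = 0.0
ds = SliceDataset(slices=slices, volumes=vols)

print("ROC threshold detection at +50% ΔArea (true θ = 5.5 mm):")
primaries = []
for segment in ("maxilla", "mandible"):
    for region in REGION_NAMES:
        roc = roc_threshold(ds, segment, region, cutoff_pct=50.0)
        primaries.append(roc.primary_threshold)
        print(f"  {segment:9s} {region:12s} threshold {roc.primary_threshold:5.2f} mm"
              f"  J={roc.j_max:.3f}  AUC={roc.auc:.3f}")
print(f"\npooled mean threshold: {np.mean(primaries):.2f} mm")
print("A slice needs ΔArea ≥ +50, i.e. an effective displacement of "
      "θ + 50/slope = 7.5 mm, so cutpoints land between θ and θ + 2; each "
      "region also mixes both jaws (weights 0.8/0.5/0.2), which scatters "
      "the single-segment estimates around that band.")
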