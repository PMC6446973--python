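"""Generate the synthetic study region and report its composition.

Builds the 6 km x 6 km landscape (terra firme with a degraded fraction,
wetland, mangrove, nonforest), places five 500-ha lidar flight footprints by
stratified random sampling, and writes the realised class composition and
scene table. The realised forest-class shares should sit close to the
configured 90.8 / 7.8 / 1.4 % split.
"""

import numpy as np
import pandas as pd

from common import RESULTS, result
from chocoforest.simulate import CLASS_NAMES

res = result()
truth, scenes = res.truth, res.scenes

v = truth.class_map.values
forest = v > 0
rows = []
for code, name in CLASS_NAMES.items():
    sel = v == code
    rows.append({
        "class": name,
        "cells_30m": int(sel.sum()),
        "share_of_region": sel.sum() / v.size,
        "share_of_forest": sel.sum() / forest.sum() if code > 0 else np.nan,
        "mean_height_m": float(truth.height_true.values[
            np.kron(sel, np.ones((30, 30), bool))[:truth.height_true.shape[0],
                                                   :truth.height_true.shape[1]]
        ].mean()) if sel.any() else np.nan,
    })
comp = pd.DataFrame(rows)
comp.to_csv(RESULTS / "landscape_composition.csv", index=False)

scene_tab = pd.DataFrame([
    {"origin_x": s.origin[0], "origin_y": s.origin[1], "width_m": s.width,
     "length_m": s.length, "heading_deg": s.heading, "stratum": s.stratum,
     "area_ha": s.area_ha}
    for s in scenes
])
scene_tab.to_csv(RESULTS / "lidar_scenes.csv", index=False)

truth.class_map.to_ascii(RESULTS / "class_map.asc", fmt="%d")
truth.degradation_severity.to_ascii(RESULTS / "degradation_severity.asc", fmt="%.3f")

print(comp.round(3).to_string(index=False))
forest_shares = comp.dropna(subset=["share_of_forest"])
tf = forest_shares[forest_shares["class"].str.startswith("terra")]["share_of_forest"].sum()
print(f"\nforest split: terra firme {tf:.1%}, "
      f"wetland {float(forest_shares.set_index('class').loc['wetland','share_of_forest']):.1%}, "
      f"mangrove {float(forest_shares.set_index('class').loc['mangrove','share_of_forest']):.1%}")
print(f"{len(scenes)} lidar scenes placed; headings "
      f"{sorted(set(int(s.heading) for s in scenes))} (all multiples of 45)")
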