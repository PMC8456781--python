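"""Simulate a four-channel scene and build filopodia maps from it.

Renders a cell with 30 filopodia (MYO10 and active beta-1 integrin
concentrated at tips, F-actin and inactive integrin uniform), extracts
tip-to-base profiles, reduces each to 40 median bins, and reports the
tip/shaft enrichment ratio and tip-positivity per channel.
"""

import numpy as np

from filotip import (
    enrichment_ratio, make_scene, paper_like_config, percent_positive,
)
from filotip.mapping import build_map
from filotip.pipeline import bin_records, scene_profiles

scene = make_scene(paper_like_config(seed=1))
binned = bin_records(scene_profiles(scene))
fmap = build_map(binned)

print(f"{'channel':20s} {'median enrichment':>18s} {'% tip-positive':>15s}")
for name in scene.channel_names:
    sub = [b for b in binned if b.channel == name]
    ratios = [enrichment_ratio(b) for b in sub]
    print(f"{name:20s} {np.median(ratios):18.2f} {percent_positive(sub):15.1f}")

print(
    "\nEnrichment > 1 means the signal concentrates in tip bins 1-6 relative "
    "to the shaft (bins 7-40); tip-positivity applies the 5000-ADU threshold "
    "to the tip-bin average on the normalized 16-bit scale."
)
print(
    f"Ground-truth active-integrin positive fraction: "
    f"{100 * scene.ground_truth_positive['active-integrin'].mean():.1f}%"
)
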