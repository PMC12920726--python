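"""Calibrate alignment uncertainty and build a per-voxel uncertainty map.

Aligns a few phantom pairs, propagates the baseline organ masks with the
estimated transforms, and records per-organ Hausdorff distances; the 75th
percentile becomes the within-organ uncertainty, growing at 0.2 mm per mm
outside organs.
"""

from percist.phantom import default_spec, make_calibration_set, make_phantom_pair
from percist.uncertainty import calibrate, uncertainty_map

pairs = make_calibration_set(3, seed=50, mode="estimated")
grid = default_spec().grid
table = calibrate(pairs, grid)

print("within-organ uncertainty (75th pct of Hausdorff residuals):")
for organ, value in sorted(table.values.items()):
    print(f"  {organ:18s} {value:5.2f} mm")

pair = make_phantom_pair(default_spec(seed=50))
umap = uncertainty_map(pair.followup_organs, table)
inside = pair.followup_organs.labels > 0
print(
    f"map range: {umap.values[inside].min():.2f} mm (in-organ) to "
    f"{umap.values.max():.2f} mm (far from any organ)"
)
print(
    "The uncertainty at a lesion's peak voxel sets the radius of the\n"
    "search sphere used to find its baseline counterpart."
)
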