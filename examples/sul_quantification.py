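"""Convert a PET activity volume to SUL using the James lean body mass.

Builds a tiny uniform activity volume, converts it with patient metadata,
and prints the intermediate quantities.
"""

import numpy as np

from percist import ImageGrid, PatientMeta, ScalarVolume, compute_lbm, to_sul

meta = PatientMeta(sex="male", weight_kg=70, height_cm=170, injected_dose_mbq=400)
lbm = compute_lbm(meta.sex, meta.weight_kg, meta.height_cm)
print(f"lean body mass (James): {lbm:.3f} kg")

grid = ImageGrid(shape=(16, 16, 16), spacing=(2.0, 2.0, 2.0))
activity = ScalarVolume(
    grid=grid, values=np.full(grid.shape, 5.0), kind="activity_kBq_per_mL"
)
sul = to_sul(activity, meta)
print(f"5 kBq/mL at 400 MBq -> SUL = {sul.values[0, 0, 0]:.4f}")
print(
    "SUL is uptake normalised by injected dose per gram of lean body mass;\n"
    "a value of 1 means uptake equal to a uniform whole-LBM distribution."
)
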