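"""Align a moving phantom pair and score the displacement field.

Each organ moved by a known rigid/affine transform; the alignment
estimates per-organ transforms by surface ICP and interpolates them
harmonically into a dense displacement field.  Prints per-organ models
and the in-organ recovery error against the ground truth.
"""

import numpy as np

from percist.alignment import align_images
from percist.phantom import default_spec, make_phantom_pair

pair = make_phantom_pair(default_spec(seed=2, scenario="identity", moving=True))
result = align_images(pair.followup_organs, pair.baseline_organs)
grid = pair.followup_organs.grid

print(f"{'organ':16s} {'model':6s} {'ICP iters':>9s} {'err mean/max mm':>16s}")
all_errors = []
for lab in pair.followup_organs.present_labels:
    name = pair.followup_organs.legend[lab]
    truth = pair.truth["transforms"][name]
    mat = np.array(truth["matrix"])
    t = np.array(truth["translation"])
    vox = np.argwhere(pair.followup_organs.mask(lab))[::13]
    w = grid.voxel_to_world(vox)
    true_disp = (w - t) @ np.linalg.inv(mat).T - w  # follow-up -> baseline
    est_disp = result.field.u[tuple(vox.T)]
    err = np.linalg.norm(est_disp - true_disp, axis=1)
    all_errors.append(err)
    tr = result.transforms[name]
    print(f"{name:16s} {tr.model:6s} {tr.iterations:9d} {err.mean():8.2f}/{err.max():.2f}")

errors = np.concatenate(all_errors)
print(
    f"overall in-organ error: mean {errors.mean():.2f} mm, "
    f"95th percentile {np.percentile(errors, 95):.2f} mm "
    f"(voxel size {grid.spacing[0]:.0f} mm)"
)
print(
    "Errors are bounded by the voxel quantisation of the resampled masks;\n"
    "sub-voxel agreement means lesions map back to the right neighbourhood."
)
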