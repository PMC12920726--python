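# Methods

This package implements a semi-automated PERCIST 1.0 workflow for
longitudinal PET-CT response assessment.  Organ and normal-activity
segmentations are *inputs* (label maps, e.g. from a deep-learning
segmenter); the package implements everything downstream: quantification,
alignment, lesion tracking, and classification.

## SUL quantification

PET uptake is expressed as SUL, the standardized uptake value normalised
by lean body mass: `SUL(x) = C(x)[Bq/mL] · LBM[g] / dose[Bq]`, assuming
1 g/mL tissue density.  Lean body mass follows the James equations
(weight W in kg, height H in cm):

- male: `LBM = 1.10 W − 128 (W/H)²`
- female: `LBM = 1.07 W − 148 (W/H)²`

Inputs outside the equations' physiological envelope (non-positive LBM)
raise rather than propagate a meaningless value.  Activity volumes are
assumed decay-corrected by the exporting scanner; pre-computed SUL
volumes are accepted directly.  All geometry uses world millimetres with
voxel values at voxel centres, fixed by the NIfTI affine.

## Background activity and threshold

Background uptake is measured in a 3 cm diameter sphere in the liver or,
as a fallback, a 1 cm × 2 cm cylinder in the descending aorta (axis
aligned to the vessel's principal axis).  The lesion-measurability
threshold is `1.5·SULmean + 2·SD` (liver) or `2.0·SULmean + 2·SD`
(aorta).  Two scans are comparable when the background SULmean differs by
less than 0.3 SUL units *and* less than 20% (strict bounds); an
incomparable pair is flagged but the analysis continues.

**VOI placement** is this package's concrete rule: among all voxel
centres where the VOI fits entirely inside the organ mask (candidates
subsampled on a 2-voxel stride; stride 1 for an exhaustive search), the
centre minimising `|VOI mean − organ interquartile mean| + VOI SD` is
chosen, with ties broken on the lexicographically smallest voxel index.
The interquartile (25–75%) organ mean is robust to focal lesions, so the
score steers the VOI away from hot lesions and noisy regions.  The rule
is isolated in one function so an alternative placement policy can be
swapped in.

## Hotspots and SULpeak

Hotspots are 26-connected components of voxels with SUL strictly above
the threshold, retained when their SULpeak also reaches the threshold.
SULpeak is the PERCIST metric: the maximal mean SUL over a 1 cm³ sphere
(radius 6.2035 mm) whose centre ranges over the component dilated by one
voxel; the sphere mean counts every voxel in the sphere regardless of
component membership.  Near the grid edge the mean is taken over the
in-grid part of the footprint.  A hotspot is classified *physiological*
when more than half its voxels lie inside the normal-activity mask, else
*lesion*; a per-hotspot override field models the manual confirmation
step.  Lesions are ranked by SULpeak (ties: component size, then centre
index).

## Alignment

The follow-up (source) study is aligned to the baseline (target) using
only the organ label maps:

1. **Per-organ transforms.**  Marching-cubes surfaces (level 0.5 of the
   binary mask, one-voxel zero padding so edge-touching organs stay
   closed) are registered with point-to-point ICP.  Initialisation
   superposes the surface point closest to the image centre in each
   scan; because that single-point init can slide into a local optimum
   on boxy, symmetric organs, a centroid-superposition restart is run
   whenever the first pass does not reach numerical convergence, and the
   result with the smaller mean correspondence distance wins.  Each
   iteration re-matches nearest neighbours and refits: bones and
   vertebrae rigidly (Kabsch with reflection excluded, after discarding
   pairs beyond 4× the median distance), soft tissue with a full affine
   least-squares fit.  Iteration stops when the mean correspondence
   distance changes by < 1e-3 mm or after 100 iterations (flagged, not
   raised).  Surfaces above 4000 vertices are stride-subsampled.
2. **Harmonic interpolation.**  Organ voxels fix the displacement
   `u(x) = T(x) − x` as Dirichlet data; free voxels start at the
   unweighted mean of the organ displacements and relax under the
   component-wise discrete Laplace equation with a 6-neighbour Jacobi
   scheme until the largest update falls below 0.01 mm or 5000
   iterations.  The solve runs independently in six regions — head,
   torso, left/right arms, left/right legs — with mirrored (zero-flux)
   region borders, so an arm transform cannot leak into the abdomen.
   Non-organ voxels take the region of the nearest organ voxel; the
   organ→region and organ→rigid/affine tables ship with the package and
   are overridable.

**Numerical notes.**  The Jacobi solve is run coarse-to-fine by default
(block-aggregated 4× and 2× grids, trilinear upsampling); block
aggregation rather than striding preserves thin Dirichlet structures.
The coarse-to-fine and plain single-level solvers agree to well under
0.05 mm once converged; at the loose default update tolerance both carry
the same iteration-truncation error on boundary-sparse problems, because
a small Jacobi update does not imply a small residual error.  For
whole-body label maps, where organs are dense in every region, the
default tolerance is adequate.  A region containing no organ is filled
with the global mean displacement and flagged.

## Alignment uncertainty

Uncertainty is calibrated by propagating baseline organ masks with the
estimated transforms and measuring the symmetric Hausdorff distance
(between boundary voxel centres) to the actual follow-up masks, per
organ, over a set of study pairs.  The within-organ uncertainty is the
75th percentile (linear interpolation between order statistics) of those
distances; outside organs it grows at 0.2 mm per mm of Euclidean
distance to the nearest organ voxel, starting from that organ's own
value.  Organs absent from the table use the table-wide maximum
(conservative).  An optional grouping pools several labels into one
shared distance list.  The shipped default table
(`data/phantom_uncertainty_table.json`) is calibrated on phantom pairs
(synthetic data; regenerate with `scripts/build_uncertainty_table.py`);
real deployments should calibrate on their own scanner data and pass the
table explicitly.

## Longitudinal comparison and response

Each follow-up lesion's SULpeak location is mapped into the baseline by
trilinear interpolation of the displacement field.  Within a sphere
centred on the mapped point — radius taken from the uncertainty map at
the lesion's peak voxel — the highest baseline SULpeak is extracted over
candidate voxel centres, excluding centres whose 1 cm³ sphere
majority-overlaps the normal-activity mask (the same >50% vote as
hotspot classification).  If no admissible centre exists, the baseline
value is *absent* and the pair is a new-lesion candidate.  No one-to-one
assignment is enforced: two follow-up lesions whose search spheres reach
the same hotter baseline lesion both report it — a documented failure
mode surfaced in the pair table rather than silently resolved.

Response classification, evaluated in order:

- **CMR** — no confirmed lesions at follow-up;
- **PMR** — no new lesions, no unequivocal progression, target SULpeak
  decreased ≥ 30% and ≥ 0.8 SUL units (both inclusive);
- **PMD** — target SULpeak increased > 30% (exclusive) and ≥ 0.8 SUL
  units, or unequivocal progression, or new lesions;
- **SMD** — otherwise.

The target SULpeak is the hottest confirmed lesion per scan (up to three
target lesions are recorded in the report); a config switch compares the
hottest follow-up lesion with its *paired* baseline value instead.  The
new-lesion and unequivocal-progression flags are manual inputs, echoed
in the report.

## Phantom generator

The synthetic study generator is first-class, tested code and defines
the conditions under which the pipeline is validated: a 96×96×160 grid
at 3 mm isotropic (a desk-scale whole body), ~15 analytic organs
spanning all six regions with field-typical uptake (liver 2.0, blood
1.6, bone 1.2, lung 0.5, body 1.0 SUL), physiological structures (brain
5.0, heart 4.0, bladder 6.0) carried in the normal-activity mask,
uniform spherical lesions, and additive Gaussian noise (SD 0.05 SUL, a
small-but-nonzero level that keeps designed changes recoverable to
within ±2%).  Follow-up masks are the baseline masks moved by known
rigid/affine transforms and nearest-neighbour resampled; lesions have a
radius (9 mm) larger than the SULpeak sphere, so the designed amplitude
*is* the designed SULpeak and percent changes are exact by construction.
Scenario presets fix the designed response class (−40% → PMR, +40% →
PMD, new lesion → PMD, +10% → SMD, lesion disappearance → CMR).

What the phantom does **not** emulate: PET point-spread and partial
volume effects, attenuation artefacts, anatomically realistic organ
shapes and deformations, respiratory motion, or heterogeneous lesion
texture.  Passing tests therefore demonstrate the correctness of the
pipeline's rules and numerics under known ground truth, not clinical
accuracy on patient data.

Because the ground-truth follow-up masks are nearest-neighbour
resampled, organ positions are quantised to the 3 mm lattice; alignment
recovery against the analytic transforms is quantisation-limited to
roughly half a voxel, and the validation targets sub-voxel (not
sub-millimetre) agreement.

## Problem sizes

Tests and the acceptance script run at desk scale: whole-body phantoms
at 3 mm / 96×96×160, fine-geometry checks (VOI shapes, SULpeak sphere)
at 0.5 mm on small crops, and the end-to-end validation on ten seeded
phantom pairs.

## Known limitations

- VOI placement is a reproducible stand-in rule; a clinical deployment
  may prefer a site-specific policy (the function is isolated for that).
- ICP is point-to-point; sliding along large flat surfaces is only
  mitigated (restart heuristic), not eliminated.
- The outside-organ uncertainty base value (nearest organ's own value)
  and the organ grouping are package choices exposed as configuration.
- New-lesion and unequivocal-progression calls are manual inputs, not
  detected automatically.
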