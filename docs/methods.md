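# Methods

This note documents the models, conventions, numerical choices and known
limitations of `diamotion`. It is the package's own account; every number it
mentions is computed by the test suite or `scripts/acceptance.py`.

## Grid and axis contract

One convention is enforced at I/O and assumed everywhere else: axis 0 runs
subject right→left, axis 1 posterior→anterior, axis 2 caudal→cranial
(nibabel axis codes `L`, `A`, `S`); voxel indices are 0-based and the
physical coordinate of a voxel center is `index × spacing` (mm, per-axis
spacing, anisotropy allowed). `load_mask` reorients any NIfTI to this frame
from its header affine and reorders the spacing accordingly; masks are
binarized at > 0 with multi-label inputs preserved on the side.

## Outcome definitions and their numerical conventions

* **Volumes** are voxel count × voxel volume. No partial-volume or surface
  correction is applied; sub-voxel surface fitting is deliberately out of
  scope.
* **Diaphragm surface**: per (axis 0, axis 1) column containing lung, the
  minimum axis-2 index of lung voxels — defined exactly on the lung
  footprint, absent (NaN) elsewhere.
* **Diaphragm volume ratio**: swept volume over the shared footprint,
  `Σ max(0, z_exp − z_insp) × voxel cross-section`, divided by the total
  volume gain `V_insp − V_exp`. The denominator choice makes the outcome
  read as the diaphragm's fractional contribution to inspiration and gives
  an exact conservation law: with a rigid chest wall and fixed apex the
  ratio is identically 1. If `V_insp ≤ V_exp` the outcome is undefined
  (reason `nonpositive_volume_gain`).
* **Sagittal level**: rounded midpoint of the right lung's axis-0 extent on
  the expiratory mask. The right lung is the connected component with the
  smaller mean axis-0 coordinate. The same level is reused for the
  inspiratory mask of the visit (breath-holds share a scanner frame, so no
  within-visit registration is attempted).
* **Cross-visit matching**: exhaustive integer-shift search (±10 voxels per
  axis, computed in one FFT cross-correlation over the joint bounding box)
  maximizing Dice overlap of the expiratory right-lung masks; the follow-up
  level is the initial level plus the best axis-0 shift. Ties break toward
  the zero shift (smallest L1 norm, then lexicographically). Best Dice
  below 0.5 triggers a warning and a fallback to independent level
  selection on the follow-up scan.
* **Extents** use the inclusive index span, `(max − min + 1) × spacing`,
  which is exact for rasterized blocks and makes ratios bit-reproducible.
* **Dome geometry**: the contour takes, per anterior-posterior column, the
  caudal-most lung pixel in mm coordinates; the chord joins the
  anterior-most and posterior-most contour points; height is the maximum
  perpendicular point-to-chord distance; area is the absolute shoelace area
  of the contour path closed by the chord. A contour of fewer than 3 points
  is undefined (`short_contour`); an expiratory dome height below one voxel
  makes both curvature ratios undefined (`flat_expiratory_dome`), because
  the denominator would be rasterization noise.
* Undefined outcomes propagate as NaN with a reason code per outcome;
  subjects are never dropped wholesale.

## Statistics

Summaries are sample medians (midpoint of the two central order statistics
for even n) with min–max ranges. Group comparisons use the two-sided
Mann-Whitney U test: the exact null distribution when both groups have ≤ 25
observations and no ties, otherwise the normal approximation with tie and
continuity correction; the method used is recorded on every result. Sex
tables use Pearson's chi-square without continuity correction (df = 1).
Change scores are follow-up − initial. Classification from the
diaphragm-height-ratio change: positive = deterioration, negative =
improvement, exact zero = stable (the dichotomy leaves zero open; a third
label is the only convention that avoids an arbitrary side), missing =
unclassified. ERT subgroups close the "≤ 3 years" boundary at 3.0 and keep
negative durations (treatment started between visits) in the ≤ 3 y group;
weakness subgroups split patients at an initial cranial-caudal ratio of
1.4, the lowest value recorded in healthy controls. Subgroup-vs-control
tests are not corrected for multiple testing, matching their indicative
role. Significance level 0.05 throughout.

## The phantom

Each lung is an elliptic cylinder (lateral semiaxis fixed across phases, AP
semiaxis = chest-wall depth / 2) capped cranially by a flat apex plane and
caudally by a dome

    z_d(x, y) = base + h · f(1 − (x−cx)²/a² − (y−cy)²/b²),   f(t) = max(0, t)

for the default elliptic paraboloid, or `f(t) = sqrt(max(0, t))` for the
spherical-cap variant. A voxel is lung when its center lies inside the lung
ellipse, strictly above the dome and strictly below the apex. Closed forms:
cap volume `π a b h / 2` (paraboloid) or `2π a b h / 3` (spherical);
mid-sagittal dome segment area `(4/3) b h` or `π b h / 2`; CC extent
`apex − base`; AP extent = chest-wall depth; slice lung area
`2 b_l (apex − base) −` segment area. The swept volume integrates
`max(0, z_exp − z_insp)` over the shared lung footprint: closed form when
both dome footprints nest inside the shared footprint and the gap is
non-negative (checked on a fine grid), otherwise deterministic midpoint
quadrature at ~0.1 mm cells. Inspiration must not raise the dome base
(validated); geometry that does not fit the box raises a sizing error.

Defaults model an adult thorax at the acquisition-matched 3 mm isotropic
grid: ~3.6 L expiratory and ~7.4 L inspiratory total lung volume, 80 mm
diaphragm descent, 40 mm AP expansion. `render_intensity` produces
two-level grayscale volumes (lung 0.1, body 1.0) with seeded additive
Gaussian noise to exercise the reference Otsu/connected-component
segmenter; there is no MR physics in the rendering.

### Voxelization tolerances

Oracle tests compare rasterized measures against the analytic truth with
tolerances derived from the grid, not fitted to observed errors: one voxel
per phase on extents and on the dome height; 3% on volumes and slice areas;
`0.75·spacing/h` per phase (+1% interior) on the dome segment area (a
half-voxel band along a contour of chord length `2b` over an area
`(4/3)bh`); a ratio inherits the sum of its numerator's and denominator's
tolerances. On 20 randomized 1 mm phantoms the worst outcome error is a
few percent (reported by `scripts/acceptance.py` as
`oracle_max_outcome_error_pct`).

## The cohort simulator

`simulate_cohort` draws, per subject, a latent baseline geometry from a
group model (patients: mean descent 45 mm, baseline height ratio 1.19;
controls: 85 mm and 1.12 — weak vs strong diaphragms with overlapping
curvature, matching the study population the pipeline targets) and two
visits: the second shifts the latent dome-height ratio by the group drift
(defaults +0.05/year for patients, 0 for controls). Measurement noise is
applied to geometry parameters — the per-visit height-ratio SD
(`noise_scale`, default 0.015) plus proportional jitter on descent and AP
expansion — so each subject-visit's true outcomes stay analytic.

`noise_scale` represents repeat-measurement precision of an automated
pipeline, set so that median-change recovery at the design's group sizes
(30/10) has a comfortable margin: the n=10 control median of changes has
SE ≈ 1.25·√2·noise/√10 ≈ 0.008, well under the 0.02 recovery tolerance the
validation uses. The simulator deliberately does **not** model biological
heterogeneity of progression (real cohorts show change ranges several
times wider), scanner drift, segmentation failures, or anatomy beyond the
two-lung geometry; passing its tests therefore demonstrates correctness of
the measurement and statistics code under the stated geometric model, not
clinical performance.

### Problem sizes in validation

The parameter-recovery run rasterizes one 30/10 cohort at (3, 3, 0.5) mm:
the measured dome-height change is quantized in steps of
`z-spacing / height ≈ spacing/35`, so the cranio-caudal step must keep that
quantum below the 0.02 recovery tolerance (at 3 mm the quantum is ≈ 0.09
and group medians snap to whole quanta; 0.5 mm gives ≈ 0.014). In-plane
resolution stays at the acquisition-matched 3 mm. The power estimate runs
100 replicate cohorts on the subjects' geometry-level (analytic) outcomes —
that is where the simulator injects measurement noise, and rasterizing all
replicates would only re-add the voxelization error already characterized
by the oracle tests. Oracle-equivalence tests use scaled-down (~half
linear size) randomized phantoms at 1 mm.

## Design choices on open points

* The displaced-volume denominator (total volume gain) and the
  chord/shoelace curvature definitions are reconstructions consistent with
  the outcome descriptions and the magnitudes such studies report; an
  authoritative per-study definition, if available, should be reconciled
  against them.
* The CC-AP ratio is computed per subject as the quotient of the two
  ratios.
* Mann-Whitney exactness: published analyses rarely state the variant;
  when checking printed p-values a |Δp| ≤ 0.01 tolerance is appropriate
  for the exact/asymptotic difference at these group sizes.
* The reference segmenter (Otsu + two largest 26-connected components,
  minimum size 1% of the grid, hole filling) is a deterministic baseline
  for synthetic intensity volumes only; real segmentations are expected to
  come from an external tool and enter via `load_mask`. Merged lungs are
  an error rather than a splitting heuristic.
* Supplementary per-subject tables are expected as CSV against the
  documented schema (extra columns tolerated), not parsed from document
  formats.

## Known limitations

Left-hemidiaphragm outcomes, dynamic (time-resolved) imaging, DICOM input,
sub-voxel surface fitting and percent-predicted computation from raw
spirometry are out of scope. The matching search assumes pure translation
(±10 voxels); rotations or scanner-frame rescaling are not modeled. The
conservation law for the diaphragm volume ratio holds exactly only for the
phantom's geometry class; on real anatomy the outcome remains a ratio of
well-defined measured quantities but has no closed-form oracle.
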