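# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `wbrt_aperture`. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate conventions

World axes are DICOM-LPS-like for a head-first supine patient: `+x` right →
left, `+y` anterior → posterior, `+z` inferior → superior, with the beam
isocenter (and head centre) at the origin. The canonical beam's-eye-view
(BEV) is the gantry-270 lateral: `u = -y` (increasing toward the patient's
anterior), `v = z` (toward superior). The opposed gantry-90 view is the
exact `u`-mirror; all landmark rules are written in the canonical frame and
gantry-90 structure sets are mirrored through the same rules
(`design_aperture`) and mirrored back.

## Synthetic head phantom

The phantom emulates the anatomy that drives a WBRT field: an ellipsoidal
head (semi-axes 75 × 95 × 85 mm) with a neck cylinder (radius 45 mm), an
ellipsoidal brain (60 × 75 × 45 mm) centred 30 mm above the head centre, a
4 mm bony skull shell 2 mm outside the brain surface, spherical eyes
(radius 12 mm) sitting 3 mm inside the facial surface at the level of the
brain's inferior surface, lenses (radius 4 mm) at each eye's anterior pole,
and two stacked vertebral-body cylinders (C1/C2, radius 12 mm, heights
15/17 mm, 2 mm apart) beginning 11 mm below the brain's inferior extent.
Default HU values: air −1000, soft tissue 40, brain 35, eye 20, lens 80,
bone 700 — chosen so the DRR segmenter has usable but not generous contrast
(the eye differs from soft tissue by only 20 HU).

Voxelization tests a voxel centre against the analytic surface; the default
grid is 2 mm isotropic (≈ 90 × 107 × 119 voxels). Optional Gaussian HU noise
(default 0, so geometry tests are exact) and a small head tilt (rotation
about the left–right axis, limited to ±15°) are supported; tilt 0 bypasses
the rotation entirely and is bit-exact. `sample_spec` draws randomized but
anatomically coherent variants: ±5 % global scale per axis, ±2 % independent
brain jitter, globe radius 11–13 mm, ±2 mm orbit placement, vertebra radius
10.5–13 mm, tilt ±3°. These ranges are our choice of a plausible
patient-to-patient variability; no published anatomy distribution backs
them.

The brain centre is deliberately high relative to the orbits (as in a real
head). This is load-bearing: the 15 mm brain expansion must dip below the
eye-box top at the back-of-lens line (otherwise landmark C is undefined for
`bc_position="lens"`), while the eye box's posterior edge must stay anterior
of the brain contour at eye level (otherwise `bc_position="eye"` would cut
brain). The default geometry satisfies both with a few millimetres to
spare, which is about what real anatomy allows.

What the phantom does **not** emulate: skull-base foramina, orbital rims,
mandible, air cavities, couch, heterogeneous soft tissue, partial-volume
voxels. Passing tests therefore demonstrate the correctness of the
geometric pipeline and the self-consistency of the two approaches, not
performance on clinical images.

## Projection and DRR

The default projection model is parallel (rays along `x`), which makes every
landmark exactly computable; a divergent fan model (source-to-axis distance
1000 mm, source on the patient's right at gantry 270) is available since
clinical DRRs diverge. The DRR pixel value is the line integral of
`max(HU + 1000, 0)` in HU·mm — a water-equivalent attenuation proxy, linear
in the input for the parallel model. BEV grids are isocenter-centred with
pixel centres on the `spacing · k` lattice, so that at matched spacing a BEV
pixel coincides exactly with a projected voxel column (this is what makes
the brute-force per-pixel oracle an equality, not an approximation). The
pipeline default is 1 mm BEV sampling from 2 mm voxels.

Boundary extraction uses the 0.5 iso-contour with bilinear interpolation
(`skimage.measure.find_contours`, `fully_connected="high"`, i.e. the
marching-squares saddle resolves toward foreground); polylines are closed
and oriented counter-clockwise.

## Landmark rules

All nine placements are constructive (see the `aperture` module docstring).
Decisions where the underlying geometry left freedom:

* "Moderate distance between the backs of the lenses and eyes" is encoded as
  the midpoint of the two posterior box edges (`bc_position="mid"`, the
  default).
* The forehead's anterior extreme is measured only over rows at/above the
  eye-box top, so the nose can never drive the anterior field edge.
* The diagonal AB rises 10 mm (`ab_diagonal_rise`); no published angle
  exists.
* E sits 5 mm anterior of the vertebra box (`vertebra_anterior_margin`).
* D is the lowest point of the expanded-brain arc between C and E; exact
  ties (flat arc bottom) resolve to the candidate nearest the C–E midpoint
  in `u`. With `ce_shape="straight"` D is the chord midpoint.
* The posterior boundary is flashed beyond the skin like the cranial and
  anterior ones (symmetry); F–G extends posteriorly all the way to the GH
  line.
* `include_orbits=True` collapses the carve-out: the anterior boundary is a
  single vertical at the face's anterior extreme + flash, with A, B, C, D, E
  reported coincident on it at the eye-box-top level.
* If the downward vertical from B never meets the expanded brain, landmark C
  is reported as an error rather than guessed; the pipeline converts such
  errors on the QA path into a flagged report.

Polygon assembly keeps every landmark vertex; only interior vertices of the
sampled expansion arc (≤ 2 mm spacing) are merged when collinear within
0.1 mm. This preserves the documented 9-vertex polygon for straight-chord
configurations even though D is collinear by construction.

## DRR segmentation (approach 2)

The classical segmenter replaces the trained 2D networks used clinically;
it is an interface, and a learned model could be slotted in behind the same
signature. The chain, in order: air/tissue threshold (1 mm water-equivalent,
plus a noise-pedestal estimate from the image border, since the rectified
attenuation proxy gives through-air rays a uniform positive pedestal under
CT noise); a robust quadratic fit of the *squared* line integral over a
3–12 mm band inside the skin (exact for an ellipsoidal head) giving the
bone-free background; the calvaria as the largest 6 mm-bone-excess
component, whose filled outer contour eroded by a nominal 6 mm vault
thickness yields the brain; vertebral bodies as narrow bone columns below
the brain isolated by a per-row 1D grey opening (the neck chord is unimodal
along `u`), recursively split at their weakest interior row when fused, and
sharpened per-row against a flank-interpolated background; a second-pass
cubic background refit on structure-free pixels; the superimposed globes as
a projected-sphere disk fitted by area-averaged contrast in an anatomical
window anchored at the brain's anterior-inferior corner, with the radius
read from the steepest descent of the radial deficit profile (the rim of a
projected sphere has unbounded slope); and the lens core as the strongest
positive residual after subtracting the fitted globe model.

On a lateral view the left and right globes (and lenses) superimpose almost
exactly, so the segmenter reports the shared BEV footprint under both the
`_L` and `_R` names — exactly what the aperture rules need, since they only
ever use the union boxes.

Intensity thresholds are expressed as water-equivalent path lengths and
scaled by `IntensityHints` derived from the HU calibration (never
hard-coded), keeping the module honest about being phantom-class-scoped.
Anatomical priors (vault thickness 6 mm, globe radius 9–15.5 mm, vertebral
body width < 29 mm, orbit position relative to the brain) are properties of
human heads, not of one phantom.

Measured against the projected ground truth on the noise-free default
phantom (computed by the test suite and `scripts/acceptance.py`): external
≈ 0.97, brain ≈ 0.99, eyes ≈ 0.91, C1/C2 ≈ 0.95, lens ≈ 0.70 Dice. The lens
is held to a lower documented floor (0.5): an 8 mm structure whose contrast
contributes under 1 % of the line integral cannot be delineated to 0.9 on a
radiograph — clinically reported lens agreement on DRRs is near 0.55 even
for trained networks. With 20 HU CT noise every structure is still found
and Dice moves by < 0.02.

## QA metrics

HD and MSD are computed point-to-point on boundaries densified to ≤ 0.5 mm
vertex spacing (bounding the discrepancy against point-to-segment distances
by 0.25 mm), after clipping both point sets to the evaluation rectangle.
MSD uses the average-of-both-directed-means convention. The ROI spans from
5 mm behind the vertebral bodies to 20 mm anterior of the forehead, and
vertically from the caudal landmark level to the cranial one, padded by
5 mm on each vertical end — without the pad, a boundary lying exactly on
the ROI edge would drop its (few millimetres offset) counterpart
asymmetrically and produce spurious hundred-millimetre Hausdorff values.
Default decision thresholds are 10 mm HD and 5 mm MSD; agreeing pipelines
sit far below (typically ≈ 5 mm HD / 2 mm MSD on randomized phantoms),
while a failed segmentation or a displaced structure flags the case.

## Problem sizes

Defaults keep everything desk-scale: 2 mm phantom voxels (≈ 1.1 M voxels),
1 mm BEV pixels (≈ 221 × 273), 20 randomized phantoms for the geometric
contract checks and 10 for the two-approach agreement batch. The full test
suite runs in well under a minute; the acceptance script in a few seconds.

## Known limitations

* The segmenter is scoped to head-like, convex, near-ellipsoidal anatomies
  with calibrated HU; it is a stand-in interface, not a clinical contouring
  tool.
* Lens delineation on the DRR is approximate (Dice ≈ 0.6–0.7); downstream
  this costs only ~1–2 mm on landmark B via the lens-box posterior edge.
* On a few per cent of sampled anatomies the globe-localization window
  contains a background-ripple pocket that out-scores the true orbit; the
  resulting aperture disagreement then exceeds the QA thresholds and the
  case is flagged — the designed failure mode, not a crash.
* Dose calculation, beam modelling, DICOM-RT export and clinical-image
  validation are out of scope.
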