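# Methods

## Imaging model

The world coordinate system is pinned to the flat-panel detector: the origin
is the panel's upper-left corner, x runs mediolaterally along the panel,
y superoinferiorly down it, and z = x × y points out of the panel toward the
X-ray source. The detector plane is z = 0. The default panel is 420 × 420 mm
at 0.274 mm/pixel, the source sits on the central ray at 1000 mm — the
geometry of a clinical flat-panel radiography setup. Because the world frame
is defined by the panel itself, calibration has exactly one unknown, the
source position; it is recovered from ≥ 4 non-coplanar fiducials by
Levenberg–Marquardt least squares on the 2D reprojection residuals, and the
per-coordinate residual RMS is attached to the returned geometry. Flat
panels are treated as distortion-free.

Poses are 6-vectors (tx, ty, tz in mm; rx, ry, rz in degrees, intrinsic
rotations about the moving x, then y, then z axes). All composition and
inversion go through 4×4 homogeneous matrices; the Euler form is only an
interface convention, so no sequence ambiguity can accumulate.

## DRR rendering

A DRR pixel is the line integral of trilinearly interpolated density along
the source→pixel-center ray, in density·mm. The log-domain (line-integral)
formulation was chosen over exponential attenuation because the NCC metric
is invariant under monotone intensity maps, so the extra nonlinearity buys
nothing and costs dynamic range. Interpolation is trilinear with zero
outside the grid; rays are clipped to the volume's interpolation support
(one voxel beyond the outer voxel centers, where the trilinear ramp reaches
zero) before sampling, and pixels outside the projected bounding box of the
volume are skipped entirely. Sample positions are accumulated in float32 —
at index magnitudes below ~10³ this keeps coordinate rounding near 1e-4
voxel, far below any tolerance used here — and each ray's samples are summed
and scaled by the step length.

The default step is half the smallest voxel spacing (Nyquist-safe for a
trilinear field); halving it changes smooth-phantom renders by well under
1%, which bounds the consequence of the integration-scheme choice. Coarse
registration passes decimate the *pixel grid* (every n-th pixel), never the
volume, so the projection geometry stays exact across resolutions and a
decimated render equals a slice of the full one.

## Registration

Similarity is measured either by Pearson correlation of pixel values (NCC,
default) or by the count of silhouette pixels present in exactly one of the
two binarized images (exclusive disjunction, lower is better) — the
historical stage-experiment fitness. NCC is the default because it uses the
full density information and tolerates affine intensity differences between
DRR and radiograph.

The NCC evaluation region is configurable: the whole image (default) or
only the nonzero-DRR support. The full-image default is deliberate. A
support region that follows the candidate DRR shrinks and grows with the
pose, so a slightly too-small silhouette (a depth error, via magnification)
simply excludes the mismatching rim from the score — the metric cannot see
its own error, and the weakly constrained depth axis inherits a bias.
Evaluating over the fixed panel region keeps silhouette-size mismatch
inside the score; on noisy synthetic frames this roughly halves the
depth-axis displacement of the metric optimum while leaving in-plane and
rotational behavior unchanged.

The 6-DOF search is a staged derivative-free Nelder–Mead simplex:

| stage | pixel decimation | max evals | initial simplex | tolerance |
|------:|-----------------:|----------:|----------------:|----------:|
| 1 | 4× | 150 | 2 mm / 2° | 0.05 |
| 2 | 2× | 300 | 0.5 mm / 0.5° | 0.02 |
| 3 | 1× | 100 | 0.1 mm / 0.1° | 0.01 |

The metric is non-smooth at sub-pixel scale, which rules out gradient
methods without smoothing; a simplex with a stage-matched initial size is
robust to that and needs nothing but function values. The budgets were
sized so that most evaluations are spent at the cheap decimated levels while
the final stage only polishes; the termination tolerance (0.01 mm / 0.01°)
sits an order of magnitude below the accuracy the pipeline is expected to
deliver. Multi-start is available as an explicit list of initial
perturbations (the unperturbed start always runs; best final metric wins),
keeping every search fully deterministic. Sequences are tracked by chaining
each frame's estimate into the next frame's initialization.

Out-of-plane translation (world z) is searched like any other axis but
reported separately: a single view constrains depth only through
magnification, so its error is structurally larger than in-plane error.
Occlusion by other structures is not modelled; each registration target is
rendered alone.

## Anatomical frames and angles

Pelvis: origin at the midpoint of the bilateral ASIS; x along RASIS→LASIS
(subject's left positive); z perpendicular to x within the anterior pelvic
plane (both ASIS plus a single mid-pubic landmark — the minimal landmark
set that defines the APP), pointing superiorly; y = z × x (anterior).
Femur: origin at the femoral head center (given directly or fitted as a
least-squares sphere to head-surface points); x parallel to the
transepicondylar axis (medial minus lateral epicondyle); z perpendicular to
x in the plane through the origin and the TEA midpoint, pointing proximally;
y = z × x.

All angle triplets use the intrinsic x→y→z sequence — flexion/tilt about x,
adduction/obliquity about y, axial rotation about z — matching the standard
clinical ordering for these axis labels. The sequence matters beyond small
angles and is therefore fixed package-wide and stated here prominently.
Segment angles decompose R_pose · R_frame against the world axes; hip angles
decompose R_pelvis⁻¹ · R_femur, never the difference of segment triplets
(the two agree only to first order; the small-angle consistency
hip flexion ≈ femoral flexion − pelvic tilt is a test, not the definition).
Decompositions within 1° of the ry = ±90° singularity are flagged but still
returned. The conventions assume right-side data; left-side inputs are
folded onto them by mirroring world x (`mirror_pose`), so one sign
convention serves both sides. Cycle normalization linearly interpolates each
channel onto 101 points between a start and end time; extrema report value
and %cycle with ties broken earliest.

## Synthetic phantoms and the accuracy protocol

Phantoms are unions of analytic solids on a voxel grid, smoothed by a
1-voxel Gaussian at the edges: a binary phantom gives silhouette-driven
metrics flat plateaus, while a smooth edge gives the simplex usable local
structure. The femur-like phantom is a shaft cylinder, a spherical head
(center = HEAD_CENTER landmark), a connecting neck, and two condylar
spheres (MED_EPI, LAT_EPI); the pelvis-like phantom is an ellipsoidal shell
with protrusions whose apices are the LASIS/RASIS/PUBIS landmarks. Landmarks
are stored exactly as constructed, so frame constructions on phantoms have
zero landmark error. What the phantoms deliberately omit: cortical/
trabecular texture, soft-tissue background, and overlapping anatomy —
passing tests therefore demonstrate the geometry and search machinery, not
robustness to clutter in clinical images.

The accuracy protocol mirrors a stage experiment with known displacements:
10 ground-truth poses drawn uniformly within ±10 mm / ±10° of a base pose
(phantom centered on the central ray, 500 mm from the panel, magnification
2), three noise realizations per pose (zero-mean Gaussian, σ = 1% of each
clean render's intensity range — three repeats mirroring repeat scans per
stage position), registration initialized at truth offset by 3 mm / 3° per
axis with seeded random signs. The default problem size — a 96³ phantom at
1.5 mm spacing rendered onto the 420 mm panel decimated 8× (≈191² pixels) —
was chosen as the smallest configuration whose projected silhouette still
spans hundreds of pixels, i.e. desk-scale but not toy-scale. One master
seed feeds three substreams (pose sweep, per-frame noise, initialization
signs), so reports are bit-reproducible.

RMS errors pool squared residuals over poses and repeats: in-plane pools
x and y, out-of-plane is z alone, translational pools all three axes, and
rotational pools the three intrinsic-angle residuals of
R_truth⁻¹ · R_est (the single-number rotation RMS uses this pooled
three-axis rule). Residual tables are stored in the report so every RMS is
recomputable from raw values.

## Numerical choices and degenerate inputs

- Calibration and sphere fitting reject coplanar point sets via an SVD rank
  check at 1e-8 relative tolerance.
- Projection rejects points at or beyond the plane through the source
  parallel to the detector; points behind the detector project normally.
- NCC on a constant region is undefined and raises; during search an
  undefined metric is treated as an infinitely bad cost, while an undefined
  metric at the *initial* pose is an error (bone outside the field of view).
- `crop_to_mask` shifts the origin so voxel model coordinates are invariant;
  cropping is idempotent.
- Otsu binarization of a constant image raises rather than guessing a
  threshold.
- Euler decomposition near ry = ±90° is flagged, not suppressed.

## Known limitations

- Single-plane depth (world z) accuracy is noise-limited and an order of
  magnitude worse than in-plane accuracy; the protocol reports it
  separately so the pooled number cannot hide it.
- The NCC support region follows the moving DRR silhouette, so the metric
  is not strictly continuous in pose; the simplex search tolerates the
  resulting micro-discontinuities but gradient-based refinement would not.
- No scatter, beam hardening, detector blur, or polyenergetic effects are
  modelled; noise is additive Gaussian only.
- Registration assumes one bone per image; overlapping bones (e.g. pelvis
  behind femur in an AP view) are out of scope of the synthetic experiments.
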