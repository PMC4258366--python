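# hipkin

Single-plane 3D-to-2D model-to-image registration for skeletal kinematics:
recover the 6-DOF pose of a bone in each frame of a radiographic sequence by
matching digitally reconstructed radiographs (DRRs) of its CT-like density
model to the measured images, then convert the tracked poses into clinical
pelvic, femoral, and hip joint angles.

It is aimed at motion-analysis and orthopaedic-research groups who track
bones with a flat-panel detector and a single X-ray view (no biplane rig),
and at anyone who needs a transparent, dependency-light reference pipeline
for DRR-based pose recovery with a quantified accuracy budget.

## Method

The world frame is anchored to the detector: origin at the panel's upper-left
corner, x mediolateral, y superoinferior, z = x × y, detector plane z = 0,
point source at z ≈ 1000 mm (calibrated from a fiducial frame by nonlinear
least squares). A bone pose is T = (t, R) with translations in mm and
intrinsic x→y→z Euler rotations in degrees.

A DRR pixel is the line integral of trilinearly interpolated density along
the source→pixel ray,

    I(u, v) = ∫ ρ(T⁻¹ x(s)) ds,

sampled at half the smallest voxel spacing. The pose of each frame maximizes
the normalized cross correlation (NCC) between the DRR and the radiograph
over the DRR's support (an exclusive-disjunction silhouette-mismatch count is
available as an alternative metric), using a staged coarse-to-fine
Nelder–Mead simplex search over (tx, ty, tz, rx, ry, rz). Sequences are
tracked by chaining each frame's result as the next initialization.

Anatomical frames follow the standard radiographic conventions: the pelvic
frame from the bilateral ASIS and a pubic landmark (anterior pelvic plane),
the femoral frame from the femoral head center (given or sphere-fitted) and
the transepicondylar axis. Segment angles are the intrinsic x→y→z
decomposition of each frame's world orientation (pelvic tilt/obliquity/
rotation; femoral flexion/adduction/rotation); hip angles decompose the
femoral frame expressed in the pelvic frame. Series are resampled onto
0–100% of a movement cycle (101 points).

A synthetic phantom generator (femur-like, pelvis-like, cube, blob density
volumes with exact landmarks) plus an accuracy protocol reproduce the
classic stage experiment: render frames at known poses, add noise, register,
and report RMS errors split into in-plane (x, y), out-of-plane (z), and
rotational components.

## Worked example

```python
import hipkin as hk

# a femur-like phantom, cropped to its bounding box
volume = hk.crop_to_mask(hk.make_phantom(hk.PhantomSpec()), margin=3.0)
g = hk.default_geometry()          # 420 mm panel, source at 1000 mm

truth = hk.Pose(210, 210, 500, 3, -5, 7)   # mm / deg, bone at depth 500 mm
frame = hk.render(volume, truth, g).pixels  # synthetic radiograph

init = hk.Pose(213, 207, 503, 0, -2, 10)    # a few mm / deg off
res = hk.register_frame(volume, frame, g, init)
print(res.metric_value)                     # 0.9999999999996548
print(hk.pose_residual(res.pose, truth))    # [0. 0. 0.0001 -0. -0. -0.]
```

On this noise-free frame the search returns to the true pose to within a
ten-thousandth of a millimetre. With realistic noise (σ = 1% of the
intensity range, as in the accuracy protocol) in-plane translations and
rotations stay at the hundredth-of-a-unit level while the out-of-plane
(depth) component, which a single view constrains only through
magnification, degrades to a few tenths of a millimetre — exactly the
split the accuracy report quantifies.

The same pipeline is scriptable from the shell:

```bash
hipkin phantom --out exp/ --seed 1          # volume, geometry, frames, truth
hipkin track --volume exp/phantom.nii.gz --images exp/ \
    --geometry exp/geometry.yaml --init 210,210,500,0,0,0 --out poses.csv
hipkin angles --pelvis-poses pelvis.csv --femur-poses femur.csv \
    --pelvis-volume pelvis.nii.gz --femur-volume femur.nii.gz --out angles/
```

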