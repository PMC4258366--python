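"""Synthetic bone phantoms, projection geometries, and noisy experiments.

The phantoms stand in for CT-derived bone models so the whole pipeline is
testable without imaging data.  ``femur_like`` is a shaft cylinder with a
spherical head, a connecting neck, and two condylar bulges; ``pelvis_like``
an ellipsoidal shell with protrusions whose apices carry the ASIS and pubic
landmarks.  Landmark coordinates are stored exactly as constructed, so
frame constructions on phantoms are exact.  Densities are smoothed with a
Gaussian kernel at the edges: a binary phantom would give the correlation
metric flat plateaus, a smooth one gives the search usable gradients.

The default experiment geometry mirrors a floor-mounted flat-panel setup:
source-to-detector 1000 mm, 420 mm panel at 0.274 mm/pixel decimated x8 to
desk scale, the phantom centered about 500 mm from the panel (magnification
close to 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .drr import render, save_image16
from .errors import FieldOfViewError, ParameterError
from .geometry import Pose, ProjectionGeometry, project
from .volume_io import DensityVolume, write_volume

PANEL_MM = 420.0
PIXEL_MM = 0.274
SOURCE_DETECTOR_MM = 1000.0
OBJECT_DEPTH_MM = 500.0


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic bone volume.

    Identical spec + seed always produces bit-identical output.  Geometric
    parameters are in mm in model coordinates, which are centered on the
    grid.  ``noise_sigma`` (fraction of the clean render's intensity range)
    and ``seed`` govern the noisy projections of an experiment built from
    this phantom, not the volume itself, which is deterministic.
    """

    kind: str = "femur_like"
    shape: tuple = (96, 96, 96)
    spacing: tuple = (1.5, 1.5, 1.5)
    density: float = 1.0
    edge_sigma_vox: float = 1.0
    noise_sigma: float = 0.01
    seed: int = 0
    cube_edge_vox: int = 32
    # femur_like geometry
    shaft_radius: float = 11.0
    shaft_z: tuple = (-58.0, 30.0)
    head_center: tuple = (18.0, 0.0, 45.0)
    head_radius: float = 20.0
    neck_radius: float = 9.0
    condyle_offset: float = 20.0
    condyle_radius: float = 13.0
    # pelvis_like geometry
    shell_semiaxes: tuple = (52.0, 34.0, 40.0)
    shell_thickness: float = 0.30
    asis: tuple = (55.0, 22.0, 30.0)
    pubis: tuple = (0.0, 28.0, -35.0)
    protrusion_radius: float = 10.0

    def __post_init__(self):
        if self.kind not in ("femur_like", "pelvis_like", "cube", "blob"):
            raise ParameterError(f"unknown phantom kind: {self.kind!r}")
        if any(s <= 0 for s in self.spacing) or any(n < 4 for n in self.shape):
            raise ParameterError("invalid phantom grid")


def _grid(spec: PhantomSpec):
    """Voxel-center model coordinates, grid centered on the origin."""
    shape = np.asarray(spec.shape, int)
    spacing = np.asarray(spec.spacing, float)
    origin = -(shape - 1) / 2.0 * spacing
    axes = [origin[i] + np.arange(shape[i]) * spacing[i] for i in range(3)]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    return x.astype(np.float32), y.astype(np.float32), z.astype(np.float32), origin


def _seg_dist2(x, y, z, a, b):
    """Squared distance of grid points to the segment a-b."""
    a = np.asarray(a, np.float32)
    d = np.asarray(b, np.float32) - a
    l2 = float(d @ d)
    px, py, pz = x - a[0], y - a[1], z - a[2]
    t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / l2, 0.0, 1.0)
    return ((px - t * d[0]) ** 2 + (py - t * d[1]) ** 2
            + (pz - t * d[2]) ** 2)


def _sphere(x, y, z, c, r):
    return ((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) <= r * r


def _check_landmarks(landmarks: dict, spec: PhantomSpec) -> None:
    half = (np.asarray(spec.shape) - 1) / 2.0 * np.asarray(spec.spacing)
    for name, p in landmarks.items():
        if np.any(np.abs(np.asarray(p)) > half):
            raise ParameterError(f"landmark {name} lies outside the grid")


def make_phantom(spec: PhantomSpec) -> DensityVolume:
    """Build the density volume (and exact landmarks) for a phantom spec."""
    from scipy.ndimage import gaussian_filter

    x, y, z, origin = _grid(spec)
    landmarks: dict[str, np.ndarray] = {}

    if spec.kind == "cube":
        half_mm = spec.cube_edge_vox / 2.0 * np.asarray(spec.spacing)
        # half-open bounds select exactly cube_edge_vox voxel centers per axis
        mask = ((np.abs(x) < half_mm[0]) & (np.abs(y) < half_mm[1])
                & (np.abs(z) < half_mm[2]))
        data = mask.astype(np.float32) * spec.density
        return DensityVolume(data, spec.spacing, origin, landmarks)

    if spec.kind == "blob":
        a, b, c = (np.asarray(spec.shape) - 1) / 5.0 * np.asarray(spec.spacing)
        q = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2
        data = (spec.density * np.exp(-q)).astype(np.float32)
        return DensityVolume(data, spec.spacing, origin, landmarks)

    if spec.kind == "femur_like":
        mask = _seg_dist2(x, y, z, (0, 0, spec.shaft_z[0]),
                          (0, 0, spec.shaft_z[1])) <= spec.shaft_radius**2
        head = np.asarray(spec.head_center, float)
        mask |= _sphere(x, y, z, head, spec.head_radius)
        mask |= _seg_dist2(x, y, z, (0, 0, spec.shaft_z[1]),
                           head) <= spec.neck_radius**2
        med = np.array([spec.condyle_offset, 0.0, spec.shaft_z[0]])
        lat = np.array([-spec.condyle_offset, 0.0, spec.shaft_z[0]])
        mask |= _sphere(x, y, z, med, spec.condyle_radius)
        mask |= _sphere(x, y, z, lat, spec.condyle_radius)
        landmarks = {"HEAD_CENTER": head, "MED_EPI": med, "LAT_EPI": lat}
    else:  # pelvis_like
        a, b, c = spec.shell_semiaxes
        q = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2
        mask = np.abs(q - 1.0) <= spec.shell_thickness
        for name, apex in (("LASIS", np.array(spec.asis)),
                           ("RASIS", np.array(spec.asis) * (-1, 1, 1)),
                           ("PUBIS", np.array(spec.pubis, float))):
            outward = apex / np.linalg.norm(apex)
            center = apex - spec.protrusion_radius * outward
            mask |= _sphere(x, y, z, center, spec.protrusion_radius)
            landmarks[name] = apex.astype(float)

    _check_landmarks(landmarks, spec)
    data = mask.astype(np.float32)
    if spec.edge_sigma_vox > 0:
        data = gaussian_filter(data, spec.edge_sigma_vox)
    return DensityVolume(data * spec.density, spec.spacing, origin, landmarks)


def default_geometry(downsample: int = 8) -> ProjectionGeometry:
    """Flat-panel geometry at desk scale (pixel grid decimated ``downsample``x)."""
    return ProjectionGeometry(
        source_position=(PANEL_MM / 2, PANEL_MM / 2, SOURCE_DETECTOR_MM),
        pixel_spacing=(PIXEL_MM * downsample, PIXEL_MM * downsample),
    )


def base_object_pose() -> Pose:
    """Pose placing a centered phantom on the central ray at depth 500 mm."""
    return Pose(PANEL_MM / 2, PANEL_MM / 2, OBJECT_DEPTH_MM)


def default_pose_table(
    n_poses: int = 10,
    seed: int = 0,
    base: Pose | None = None,
    max_translation_mm: float = 10.0,
    max_rotation_deg: float = 10.0,
) -> list[Pose]:
    """Ground-truth sweep: uniform offsets within +-max about the base pose."""
    if base is None:
        base = base_object_pose()
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(-1.0, 1.0, size=(n_poses, 6))
    offsets[:, :3] *= max_translation_mm
    offsets[:, 3:] *= max_rotation_deg
    return [Pose.from_vector(base.as_vector() + off) for off in offsets]


@dataclass
class SyntheticExperiment:
    """Rendered frames at known poses, with the truth stored losslessly.

    Frames are ordered pose-major (all repeats of pose 0, then pose 1, ...);
    ``truth`` has one row per frame: frame, pose_index, repeat, tx..rz.
    """

    volume: DensityVolume
    geometry: ProjectionGeometry
    poses: list[Pose]
    frames: list[np.ndarray]
    truth: pd.DataFrame
    noise_sigma: float
    seed: int

    def truth_pose(self, frame_index: int) -> Pose:
        row = self.truth.iloc[frame_index]
        return Pose(row.tx, row.ty, row.tz, row.rx, row.ry, row.rz)


def _check_fov(v: DensityVolume, pose: Pose, g: ProjectionGeometry,
               index: int) -> None:
    lo, hi = v.bounds()
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    try:
        uv = project(g, pose.apply(corners))
    except Exception as exc:
        raise FieldOfViewError(f"pose {index} not projectable: {exc}") from exc
    w, h = g.panel_size
    if (uv[:, 0].min() < 0 or uv[:, 0].max() > w
            or uv[:, 1].min() < 0 or uv[:, 1].max() > h):
        raise FieldOfViewError(
            f"pose {index} places the phantom outside the field of view"
        )


def make_experiment(
    volume: DensityVolume,
    geometry: ProjectionGeometry,
    pose_table: list[Pose],
    noise_sigma: float = 0.01,
    seed: int = 0,
    n_repeats: int = 3,
    step: float | None = None,
) -> SyntheticExperiment:
    """Render noisy frames of ``volume`` at each ground-truth pose.

    Each pose is rendered once; ``n_repeats`` independent zero-mean Gaussian
    noise realizations of standard deviation ``noise_sigma * (max - min)``
    of the clean render are added (three repeats mirror repeat radiographic
    scans per stage position).  A master seed spawns one substream per
    frame, so frames are individually reproducible.
    """
    if n_repeats < 1:
        raise ParameterError("n_repeats must be >= 1")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(len(pose_table) * n_repeats)
    frames: list[np.ndarray] = []
    rows = []
    k = 0
    for i, pose in enumerate(pose_table):
        _check_fov(volume, pose, geometry, i)
        clean = render(volume, pose, geometry, step=step).pixels
        span = float(clean.max() - clean.min())
        for rep in range(n_repeats):
            rng = np.random.default_rng(children[k])
            if noise_sigma > 0:
                frame = clean + rng.normal(0.0, noise_sigma * span,
                                           size=clean.shape)
            else:
                frame = clean.copy()
            frames.append(frame)
            rows.append((k, i, rep, *pose.as_vector()))
            k += 1
    truth = pd.DataFrame(
        rows, columns=["frame", "pose_index", "repeat",
                       "tx", "ty", "tz", "rx", "ry", "rz"]
    )
    return SyntheticExperiment(volume, geometry, list(pose_table), frames,
                               truth, noise_sigma, seed)


def save_experiment(exp: SyntheticExperiment, outdir) -> None:
    """Write volume (NIfTI + landmark JSON), geometry, frames, truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(exp.volume, outdir / "phantom.nii.gz")
    exp.geometry.save(outdir / "geometry.yaml")
    for k, frame in enumerate(exp.frames):
        save_image16(outdir / f"frame_{k:04d}.tif", frame)
    exp.truth.to_csv(outdir / "truth.csv", index=False)
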