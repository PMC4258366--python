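"""Anatomical frames and clinical joint angles.

Pelvis frame: origin at the midpoint of the bilateral anterior superior
iliac spines (ASIS); x mediolateral along the ASIS line (subject's left
positive); z perpendicular to x within the anterior pelvic plane (APP,
spanned by both ASIS and the pubis), pointing superiorly; y = z x x,
pointing anteriorly.

Femur frame: origin at the femoral head center (given, or fitted as a
least-squares sphere to head-surface points); x parallel to the
transepicondylar axis (TEA, medial minus lateral epicondyle); z
perpendicular to x in the plane through the origin and the TEA midpoint,
pointing proximally (from the TEA midpoint toward the head); y = z x x.

Angles use the intrinsic x -> y -> z Euler sequence: for the pelvis
(tilt, obliquity, axial rotation) and femur (flexion, adduction, axial
rotation) against the world axes, and for the hip the femoral frame is
decomposed in the pelvic frame.  The same sequence everywhere makes the
small-angle relation "hip flexion = femoral flexion - pelvic tilt" hold to
first order.  Conventions assume right-side data; mirror left-side inputs
(negate world x) before angle computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import DegenerateConfigurationError, ParameterError
from .geometry import Pose

logger = logging.getLogger(__name__)

GIMBAL_LIMIT_DEG = 89.0

ANGLE_CHANNELS = (
    "pelvic_tilt", "pelvic_obliquity", "pelvic_rotation",
    "femoral_flexion", "femoral_adduction", "femoral_rotation",
    "hip_flexion", "hip_adduction", "hip_rotation",
)


class AngleTriplet(NamedTuple):
    """Euler angles (deg) of the intrinsic x->y->z decomposition.

    ``gimbal`` flags proximity to the sequence singularity
    (|second angle| > 89 deg); the values are still returned.
    """

    a1: float
    a2: float
    a3: float
    gimbal: bool = False


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal right-handed frame embedded in a bone model.

    ``axes`` rows are the x, y, z unit vectors expressed in model
    coordinates; the rotation matrix mapping frame coordinates into model
    coordinates has those vectors as columns.
    """

    origin: tuple
    axes: tuple

    def __post_init__(self):
        r = self.rotation_matrix()
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ParameterError("frame axes must be orthonormal")
        if np.linalg.det(r) < 0:
            raise ParameterError("frame must be right-handed")

    def rotation_matrix(self) -> np.ndarray:
        """Columns = frame axes in model coordinates."""
        return np.asarray(self.axes, dtype=float).T

    @property
    def origin_point(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateConfigurationError("zero-length axis vector")
    return v / n


def _frame(origin, x, z) -> AnatomicalFrame:
    y = np.cross(z, x)
    return AnatomicalFrame(
        origin=tuple(float(c) for c in origin),
        axes=(tuple(x), tuple(y), tuple(z)),
    )


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least-squares sphere through >= 4 non-coplanar points.

    Returns (center, radius, residual_rms) where the residual is the
    distance of each point to the fitted sphere surface.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 4:
        raise DegenerateConfigurationError("sphere fit needs >= 4 points")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[2] <= 1e-8 * s[0]:
        raise DegenerateConfigurationError("sphere-fit points are coplanar")
    # |p|^2 = 2 c.p + (r^2 - |c|^2) is linear in (c, r^2 - |c|^2)
    a = np.column_stack([2 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    resid = np.linalg.norm(pts - center, axis=1) - radius
    return center, radius, float(np.sqrt(np.mean(resid**2)))


def pelvis_frame(lasis, rasis, pubis) -> AnatomicalFrame:
    """Pelvic anatomical frame from the two ASIS and a mid-pubic landmark."""
    lasis = np.asarray(lasis, float)
    rasis = np.asarray(rasis, float)
    pubis = np.asarray(pubis, float)
    origin = (lasis + rasis) / 2
    x = _unit(lasis - rasis)
    w = origin - pubis  # inferior -> superior within the APP
    z = w - (w @ x) * x
    if np.linalg.norm(z) < 1e-9 * max(np.linalg.norm(w), 1.0):
        raise DegenerateConfigurationError(
            "pelvic landmarks are collinear; the APP is undefined"
        )
    return _frame(origin, x, _unit(z))


def femur_frame(head_center, med_epi, lat_epi) -> AnatomicalFrame:
    """Femoral anatomical frame from the head center and both epicondyles."""
    head = np.asarray(head_center, float)
    med = np.asarray(med_epi, float)
    lat = np.asarray(lat_epi, float)
    x = _unit(med - lat)
    mid = (med + lat) / 2
    w = head - mid  # distal -> proximal
    z = w - (w @ x) * x
    if np.linalg.norm(z) < 1e-9 * max(np.linalg.norm(w), 1.0):
        raise DegenerateConfigurationError(
            "femoral head center lies on the transepicondylar axis"
        )
    return _frame(head, x, _unit(z))


def _decompose(r: np.ndarray) -> AngleTriplet:
    a1, a2, a3 = Rotation.from_matrix(r).as_euler("XYZ", degrees=True)
    gimbal = abs(a2) > GIMBAL_LIMIT_DEG
    if gimbal:
        logger.warning("Euler decomposition near gimbal lock (|a2|=%.2f deg)",
                       abs(a2))
    return AngleTriplet(float(a1), float(a2), float(a3), gimbal)


def segment_angles(world_pose: Pose, frame: AnatomicalFrame) -> AngleTriplet:
    """Orientation of a bone's anatomical frame relative to the world axes.

    The tracked world pose moves the bone model; the anatomical frame rides
    with it.  For the pelvis the triplet reads (anterior tilt, upward
    obliquity, contralateral rotation); for the femur (flexion, adduction,
    internal rotation).
    """
    r = world_pose.rotation_matrix() @ frame.rotation_matrix()
    return _decompose(r)


def hip_angles(
    pelvis_world: Pose,
    pelvis_anat: AnatomicalFrame,
    femur_world: Pose,
    femur_anat: AnatomicalFrame,
) -> AngleTriplet:
    """Hip (flexion, adduction, internal rotation) of femur relative to pelvis.

    Computed from the relative rotation of the femoral anatomical frame
    expressed in the pelvic anatomical frame — not as differences of the
    two segment-angle triplets.
    """
    r_p = pelvis_world.rotation_matrix() @ pelvis_anat.rotation_matrix()
    r_f = femur_world.rotation_matrix() @ femur_anat.rotation_matrix()
    return _decompose(r_p.T @ r_f)


def mirror_pose(p: Pose) -> Pose:
    """Mirror a world pose across the x = const sagittal-like plane.

    Used to fold left-side data onto the right-side sign conventions: the
    world x axis is negated, which flips tx and the ry/rz rotations.
    """
    m = np.diag([-1.0, 1.0, 1.0])
    r = m @ p.rotation_matrix() @ m
    out = np.eye(4)
    out[:3, :3] = r
    out[:3, 3] = m @ p.translation
    return Pose.from_matrix(out)


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------


def kinematic_table(
    times,
    pelvis_poses,
    femur_poses,
    pelvis_anat: AnatomicalFrame,
    femur_anat: AnatomicalFrame,
) -> pd.DataFrame:
    """Per-frame pelvic, femoral, and hip angle triplets as a DataFrame."""
    times = np.asarray(times, dtype=float)
    if not (len(times) == len(pelvis_poses) == len(femur_poses)):
        raise ParameterError("times and pose lists must have equal length")
    rows = []
    for t, pp, fp in zip(times, pelvis_poses, femur_poses):
        pel = segment_angles(pp, pelvis_anat)
        fem = segment_angles(fp, femur_anat)
        hip = hip_angles(pp, pelvis_anat, fp, femur_anat)
        rows.append((t, *pel[:3], *fem[:3], *hip[:3]))
    return pd.DataFrame(rows, columns=("time",) + ANGLE_CHANNELS)


def normalize_cycle(
    samples: pd.DataFrame, t_start: float, t_end: float
) -> pd.DataFrame:
    """Resample angle channels onto 0..100% of the movement cycle.

    Linear interpolation of each channel at 101 evenly spaced cycle points
    between ``t_start`` and ``t_end`` (both must lie within the sampled
    time range).
    """
    if "time" not in samples.columns:
        raise ParameterError("samples must have a 'time' column")
    if len(samples) < 2:
        raise ParameterError("need at least 2 samples to normalize a cycle")
    t = samples["time"].to_numpy(float)
    order = np.argsort(t)
    t = t[order]
    if not (t[0] <= t_start < t_end <= t[-1]):
        raise ParameterError(
            f"cycle window [{t_start}, {t_end}] outside sampled range "
            f"[{t[0]}, {t[-1]}]"
        )
    pct = np.linspace(0.0, 100.0, 101)
    grid = t_start + (t_end - t_start) * pct / 100.0
    out = {"percent_cycle": pct}
    for col in samples.columns:
        if col == "time":
            continue
        out[col] = np.interp(grid, t, samples[col].to_numpy(float)[order])
    return pd.DataFrame(out)


class ChannelExtrema(NamedTuple):
    max_value: float
    max_percent: float
    min_value: float
    min_percent: float


def extrema(series: pd.DataFrame, channel: str) -> ChannelExtrema:
    """Extreme values of one angle channel and their cycle locations.

    Ties are broken by the earliest percent-cycle occurrence.
    """
    if channel not in series.columns:
        raise ParameterError(f"unknown channel: {channel!r}")
    if len(series) == 0:
        raise ParameterError("empty series")
    vals = series[channel].to_numpy(float)
    pct = (series["percent_cycle"].to_numpy(float)
           if "percent_cycle" in series.columns
           else np.arange(len(vals), dtype=float))
    imax = int(np.argmax(vals))
    imin = int(np.argmin(vals))
    return ChannelExtrema(float(vals[imax]), float(pct[imax]),
                          float(vals[imin]), float(pct[imin]))


def extrema_summary(series: pd.DataFrame) -> dict:
    """Per-channel extrema dict — the shape of a clinical angle summary."""
    out = {}
    for ch in ANGLE_CHANNELS:
        if ch in series.columns:
            ex = extrema(series, ch)
            out[ch] = {
                "max": ex.max_value, "max_percent_cycle": ex.max_percent,
                "min": ex.min_value, "min_percent_cycle": ex.min_percent,
            }
    return out
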