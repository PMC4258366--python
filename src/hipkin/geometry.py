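"""Rigid transforms, the world frame, perspective projection, and calibration.

The world coordinate system is anchored to the flat-panel detector: its
origin is the upper-left corner of the panel, the x-axis runs mediolaterally
along the panel rows, the y-axis superoinferiorly down the columns, and the
z-axis (anteroposterior) is their cross product, so the detector plane is
z = 0 and the X-ray point source sits at positive z.  All lengths are in
millimetres and all angles in degrees.

Rigid poses are parameterized as three translations plus intrinsic Euler
rotations about the moving x, then y, then z axes.  Composition and
inversion go through 4x4 homogeneous matrices, which keeps the Euler
parameterization purely an interface convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateConfigurationError,
    GeometryError,
    NonProjectablePointError,
)

_EULER_SEQ = "XYZ"  # intrinsic x -> y -> z


# ---------------------------------------------------------------------------
# Pose
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pose:
    """A 6-DOF rigid transform: translation in mm, rotation in degrees.

    Rotations are intrinsic Euler angles about the moving x, y, z axes in
    that order.  Applying a pose to a point computes ``R @ p + t``.
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz], dtype=float)

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler(
            _EULER_SEQ, [self.rx, self.ry, self.rz], degrees=True
        ).as_matrix()

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix of this pose."""
        m = np.eye(4)
        m[:3, :3] = self.rotation_matrix()
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "Pose":
        m = np.asarray(m, dtype=float)
        angles = Rotation.from_matrix(m[:3, :3]).as_euler(_EULER_SEQ, degrees=True)
        return cls(m[0, 3], m[1, 3], m[2, 3], *angles)

    @classmethod
    def identity(cls) -> "Pose":
        return cls()

    def as_vector(self) -> np.ndarray:
        """(tx, ty, tz, rx, ry, rz) — the optimizer's parameter layout."""
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz])

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "Pose":
        return cls(*(float(x) for x in v))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.rotation_matrix().T + self.translation

    def apply_inverse(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - self.translation) @ self.rotation_matrix()


def compose(a: Pose, b: Pose) -> Pose:
    """Pose that applies ``b`` first, then ``a``."""
    return Pose.from_matrix(a.matrix() @ b.matrix())


def invert(p: Pose) -> Pose:
    r = p.rotation_matrix()
    m = np.eye(4)
    m[:3, :3] = r.T
    m[:3, 3] = -r.T @ p.translation
    return Pose.from_matrix(m)


def transform_points(p: Pose, pts: np.ndarray) -> np.ndarray:
    """Apply the rigid transform ``p`` to an (N, 3) point array."""
    return p.apply(pts)


# ---------------------------------------------------------------------------
# Projection geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProjectionGeometry:
    """Point X-ray source plus flat-panel detector.

    ``detector_origin`` is the upper-left corner of the panel (the world
    origin in the default setup); ``detector_axes`` span the panel in-plane
    (u along mediolateral x, v along superoinferior y).  Panel coordinates
    (u, v) are in mm from the origin corner.
    """

    source_position: tuple = (210.0, 210.0, 1000.0)
    detector_origin: tuple = (0.0, 0.0, 0.0)
    detector_axes: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0))
    panel_size: tuple = (420.0, 420.0)
    pixel_spacing: tuple = (0.274, 0.274)
    calibration_rms: float | None = None

    def __post_init__(self):
        ax, ay = (np.asarray(a, dtype=float) for a in self.detector_axes)
        if not (
            np.isclose(np.linalg.norm(ax), 1.0)
            and np.isclose(np.linalg.norm(ay), 1.0)
            and np.isclose(ax @ ay, 0.0, atol=1e-9)
        ):
            raise GeometryError("detector axes must be orthonormal")
        if np.any(np.asarray(self.pixel_spacing) <= 0):
            raise GeometryError("pixel spacing must be positive")
        n = np.cross(ax, ay)
        src = np.asarray(self.source_position, dtype=float)
        org = np.asarray(self.detector_origin, dtype=float)
        if abs(n @ (src - org)) < 1e-9:
            raise GeometryError("source lies in the detector plane")

    @property
    def axis_u(self) -> np.ndarray:
        return np.asarray(self.detector_axes[0], dtype=float)

    @property
    def axis_v(self) -> np.ndarray:
        return np.asarray(self.detector_axes[1], dtype=float)

    @property
    def source(self) -> np.ndarray:
        return np.asarray(self.source_position, dtype=float)

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.detector_origin, dtype=float)

    @property
    def normal(self) -> np.ndarray:
        """Unit plane normal oriented toward the source."""
        n = np.cross(self.axis_u, self.axis_v)
        if n @ (self.source - self.origin) < 0:
            n = -n
        return n / np.linalg.norm(n)

    @property
    def source_detector_distance(self) -> float:
        return float(self.normal @ (self.source - self.origin))

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) = pixels along v and u."""
        nu = int(self.panel_size[0] // self.pixel_spacing[0])
        nv = int(self.panel_size[1] // self.pixel_spacing[1])
        return nv, nu

    def pixel_center(self, u_idx, v_idx) -> np.ndarray:
        """World coordinates of pixel centers for index arrays (u, v)."""
        u = (np.asarray(u_idx, dtype=float) + 0.5) * self.pixel_spacing[0]
        v = (np.asarray(v_idx, dtype=float) + 0.5) * self.pixel_spacing[1]
        return (
            self.origin
            + u[..., None] * self.axis_u
            + v[..., None] * self.axis_v
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "source_position": [float(x) for x in self.source],
            "detector_origin": [float(x) for x in self.origin],
            "detector_axes": [
                [float(x) for x in self.axis_u],
                [float(x) for x in self.axis_v],
            ],
            "panel_size": [float(x) for x in self.panel_size],
            "pixel_spacing": [float(x) for x in self.pixel_spacing],
        }
        if self.calibration_rms is not None:
            d["calibration_rms"] = float(self.calibration_rms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionGeometry":
        kwargs = {k: d[k] for k in d}
        kwargs["detector_axes"] = tuple(tuple(a) for a in kwargs.get(
            "detector_axes", ((1, 0, 0), (0, 1, 0))))
        for key in ("source_position", "detector_origin", "panel_size",
                    "pixel_spacing"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                import json

                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ProjectionGeometry":
        path = Path(path)
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# Projection and calibration
# ---------------------------------------------------------------------------


def project(g: ProjectionGeometry, pts: np.ndarray) -> np.ndarray:
    """Project 3D world points to panel (u, v) coordinates in mm.

    Each output is the intersection of the source->point ray with the
    detector plane.  Points at or beyond the plane through the source
    parallel to the detector are not projectable and raise
    :class:`NonProjectablePointError`.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    n = g.normal
    src = g.source
    d_src = n @ (src - g.origin)  # > 0 by construction of the normal
    d_pts = (pts - g.origin) @ n
    if np.any(d_pts >= d_src - 1e-12 * abs(d_src)):
        bad = int(np.argmax(d_pts >= d_src - 1e-12 * abs(d_src)))
        raise NonProjectablePointError(
            f"point {bad} lies at or beyond the source plane"
        )
    t = d_src / (d_src - d_pts)
    hit = src + t[:, None] * (pts - src)
    rel = hit - g.origin
    return np.column_stack([rel @ g.axis_u, rel @ g.axis_v])


def _check_fiducials(fids3d: np.ndarray) -> None:
    if len(fids3d) < 4:
        raise DegenerateConfigurationError(
            f"calibration needs at least 4 fiducials, got {len(fids3d)}"
        )
    centered = fids3d - fids3d.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[2] <= 1e-8 * s[0]:
        raise DegenerateConfigurationError("fiducials are coplanar")


def calibrate(
    fids3d: np.ndarray,
    fids2d: np.ndarray,
    initial: ProjectionGeometry,
) -> ProjectionGeometry:
    """Recover the source position from a fiducial frame.

    The world frame is pinned to the detector panel, so the only unknown of
    the imaging geometry is the source position; it is found by nonlinear
    least squares on the 2D reprojection residuals.  The returned geometry
    carries the per-coordinate residual RMS in ``calibration_rms``.
    """
    fids3d = np.atleast_2d(np.asarray(fids3d, dtype=float))
    fids2d = np.atleast_2d(np.asarray(fids2d, dtype=float))
    if fids3d.shape[0] != fids2d.shape[0]:
        raise DegenerateConfigurationError("3D and 2D fiducial counts differ")
    _check_fiducials(fids3d)

    def residuals(src):
        g = replace(initial, source_position=tuple(src), calibration_rms=None)
        return (project(g, fids3d) - fids2d).ravel()

    sol = least_squares(residuals, x0=np.asarray(initial.source, dtype=float),
                        method="lm")
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return replace(
        initial, source_position=tuple(sol.x), calibration_rms=rms
    )


def read_fiducials(path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read a fiducial CSV with columns name, X, Y, Z, u, v."""
    df = pd.read_csv(path)
    required = {"name", "X", "Y", "Z", "u", "v"}
    missing = required - set(df.columns)
    if missing:
        raise DegenerateConfigurationError(
            f"fiducial file missing columns: {sorted(missing)}"
        )
    return (
        df["name"].astype(str).tolist(),
        df[["X", "Y", "Z"]].to_numpy(float),
        df[["u", "v"]].to_numpy(float),
    )
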