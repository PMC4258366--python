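"""Anatomical frame construction and clinical angle decomposition."""

import numpy as np
import pandas as pd
import pytest

import hipkin as hk
from hipkin.errors import DegenerateConfigurationError, ParameterError

from conftest import random_pose


def rotation_oracle(rx, ry, rz):
    """Independent intrinsic x->y->z rotation matrix."""
    cx, sx = np.cos(np.deg2rad(rx)), np.sin(np.deg2rad(rx))
    cy, sy = np.cos(np.deg2rad(ry)), np.sin(np.deg2rad(ry))
    cz, sz = np.cos(np.deg2rad(rz)), np.sin(np.deg2rad(rz))
    mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return mx @ my @ mz


class TestFitSphere:
    def test_exact_sphere_from_axis_points(self):
        c = np.array([1.0, 2.0, 3.0])
        pts = c + np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                            [0, 0, 1], [0, 0, -1]], dtype=float)
        center, radius, rms = hk.fit_sphere(pts)
        assert np.allclose(center, c, atol=1e-12)
        assert radius == pytest.approx(1.0, abs=1e-12)
        assert rms < 1e-12

    def test_noisy_recovery(self, rng):
        c = np.array([-4.0, 7.0, 2.0])
        r = 23.0
        dirs = rng.normal(size=(400, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        pts = c + r * dirs + rng.normal(0, 0.01, (400, 3))
        center, radius, rms = hk.fit_sphere(pts)
        assert np.linalg.norm(center - c) < 0.01
        assert abs(radius - r) < 0.01
        assert rms < 0.02

    def test_coplanar_points_rejected(self, rng):
        pts = np.column_stack([rng.normal(size=(8, 2)), np.zeros(8)])
        with pytest.raises(DegenerateConfigurationError):
            hk.fit_sphere(pts)


class TestPelvisFrame:
    LASIS = np.array([120.0, 0.0, 0.0])
    RASIS = np.array([-120.0, 0.0, 0.0])
    PUBIS = np.array([0.0, 0.0, -100.0])

    def test_stated_toy_landmarks(self):
        f = hk.pelvis_frame(self.LASIS, self.RASIS, self.PUBIS)
        assert np.allclose(f.origin_point, 0)
        assert np.allclose(f.axes[0], (1, 0, 0))
        assert np.allclose(f.axes[2], (0, 0, 1))
        assert np.allclose(f.axes[1], (0, 1, 0))

    def test_equivariance_under_rigid_motion(self, rng):
        for _ in range(10):
            p = random_pose(rng)
            f0 = hk.pelvis_frame(self.LASIS, self.RASIS, self.PUBIS)
            f1 = hk.pelvis_frame(p.apply(self.LASIS)[0],
                                 p.apply(self.RASIS)[0],
                                 p.apply(self.PUBIS)[0])
            assert np.allclose(f1.origin_point,
                               p.apply(f0.origin_point)[0], atol=1e-9)
            assert np.allclose(f1.rotation_matrix(),
                               p.rotation_matrix() @ f0.rotation_matrix(),
                               atol=1e-9)

    def test_swapping_asis_flips_x_and_y_keeps_z(self):
        f = hk.pelvis_frame(self.LASIS, self.RASIS, self.PUBIS)
        g = hk.pelvis_frame(self.RASIS, self.LASIS, self.PUBIS)
        assert np.allclose(g.axes[0], -np.asarray(f.axes[0]))
        assert np.allclose(g.axes[1], -np.asarray(f.axes[1]))
        assert np.allclose(g.axes[2], f.axes[2])

    def test_collinear_landmarks_rejected(self):
        with pytest.raises(DegenerateConfigurationError):
            hk.pelvis_frame((1, 0, 0), (-1, 0, 0), (0.5, 0, 0))


class TestFemurFrame:
    HEAD = np.array([0.0, 0.0, 400.0])
    MED = np.array([40.0, 0.0, 0.0])
    LAT = np.array([-40.0, 0.0, 0.0])

    def test_stated_toy_landmarks(self):
        f = hk.femur_frame(self.HEAD, self.MED, self.LAT)
        assert np.allclose(f.origin_point, (0, 0, 400))
        assert np.allclose(f.axes[0], (1, 0, 0))
        assert np.allclose(f.axes[2], (0, 0, 1))
        assert np.allclose(f.axes[1], (0, 1, 0))

    def test_axes_orthonormal_by_construction(self, rng):
        head = rng.normal(scale=100, size=3)
        med = rng.normal(scale=50, size=3)
        lat = rng.normal(scale=50, size=3)
        f = hk.femur_frame(head, med, lat)
        r = f.rotation_matrix()
        assert np.allclose(r.T @ r, np.eye(3), atol=1e-12)
        assert np.isclose(np.linalg.det(r), 1.0)

    def test_equivariance_under_rigid_motion(self, rng):
        for _ in range(10):
            p = random_pose(rng)
            f0 = hk.femur_frame(self.HEAD, self.MED, self.LAT)
            f1 = hk.femur_frame(p.apply(self.HEAD)[0], p.apply(self.MED)[0],
                                p.apply(self.LAT)[0])
            assert np.allclose(f1.rotation_matrix(),
                               p.rotation_matrix() @ f0.rotation_matrix(),
                               atol=1e-9)

    def test_head_on_tea_rejected(self):
        with pytest.raises(DegenerateConfigurationError):
            hk.femur_frame((10, 0, 0), (40, 0, 0), (-40, 0, 0))


class TestSegmentAngles:
    def test_identity_gives_zero(self):
        f = hk.pelvis_frame((120, 0, 0), (-120, 0, 0), (0, 0, -100))
        ang = hk.segment_angles(hk.Pose.identity(), f)
        assert np.allclose(ang[:3], 0, atol=1e-12)

    def test_single_axis_rotation(self):
        f = hk.pelvis_frame((120, 0, 0), (-120, 0, 0), (0, 0, -100))
        ang = hk.segment_angles(hk.Pose(rx=30.0), f)
        assert np.allclose(ang[:3], (30, 0, 0), atol=1e-9)

    def test_round_trip_against_matrix_oracle(self):
        world_frame = hk.pelvis_frame((120, 0, 0), (-120, 0, 0), (0, 0, -100))
        ang = hk.segment_angles(hk.Pose(rx=20.0, ry=10.0, rz=5.0), world_frame)
        assert np.allclose(ang[:3], (20, 10, 5), atol=1e-9)
        # and the pose matrix equals the independent oracle
        assert np.allclose(hk.Pose(rx=20, ry=10, rz=5).rotation_matrix(),
                           rotation_oracle(20, 10, 5), atol=1e-12)

    def test_gimbal_proximity_flagged(self):
        f = hk.pelvis_frame((120, 0, 0), (-120, 0, 0), (0, 0, -100))
        ang = hk.segment_angles(hk.Pose(ry=89.9), f)
        assert ang.gimbal
        assert not hk.segment_angles(hk.Pose(ry=45.0), f).gimbal

    def test_decomposition_identity_on_random_triplets(self, rng):
        """compose-then-decompose is the identity away from gimbal lock."""
        f = hk.AnatomicalFrame(origin=(0, 0, 0),
                               axes=((1, 0, 0), (0, 1, 0), (0, 0, 1)))
        n = 1000
        trips = np.column_stack([
            rng.uniform(-179, 179, n),
            rng.uniform(-89, 89, n),
            rng.uniform(-179, 179, n),
        ])
        for rx, ry, rz in trips:
            ang = hk.segment_angles(hk.Pose(rx=rx, ry=ry, rz=rz), f)
            assert np.allclose(ang[:3], (rx, ry, rz), atol=1e-9)


class TestHipAngles:
    PF = hk.pelvis_frame((120, 0, 0), (-120, 0, 0), (0, 0, -100))
    FF = hk.femur_frame((0, 0, 400), (40, 0, 0), (-40, 0, 0))

    def test_identical_poses_and_frames_give_zero(self):
        ang = hk.hip_angles(hk.Pose.identity(), self.PF,
                            hk.Pose.identity(), self.PF)
        assert ang[:3] == (0.0, 0.0, 0.0)

    def test_pure_flexion(self):
        ang = hk.hip_angles(hk.Pose.identity(), self.FF,
                            hk.Pose(rx=90.0), self.FF)
        assert np.allclose(ang[:3], (90, 0, 0), atol=1e-9)

    def test_matches_relative_rotation_oracle(self, rng):
        for _ in range(20):
            pp, fp = random_pose(rng), random_pose(rng)
            ang = hk.hip_angles(pp, self.PF, fp, self.FF)
            rp = pp.rotation_matrix() @ self.PF.rotation_matrix()
            rf = fp.rotation_matrix() @ self.FF.rotation_matrix()
            from scipy.spatial.transform import Rotation

            expected = Rotation.from_matrix(rp.T @ rf).as_euler(
                "XYZ", degrees=True)
            assert np.allclose(ang[:3], expected, atol=1e-9)

    def test_small_angle_linearization(self):
        """hip flexion ~ femoral flexion - pelvic anterior tilt below 5 deg."""
        for tilt, flex in [(2.0, 4.0), (-3.0, 1.0), (4.5, -2.0)]:
            pel = hk.Pose(rx=tilt)
            fem = hk.Pose(rx=flex)
            hip = hk.hip_angles(pel, self.PF, fem, self.FF)
            fem_ang = hk.segment_angles(fem, self.FF)
            pel_ang = hk.segment_angles(pel, self.PF)
            assert abs(hip.a1 - (fem_ang.a1 - pel_ang.a1)) < 0.2

    def test_equivariance_when_landmarks_and_pose_co_move(self, rng):
        """Angles are unchanged when a rigid motion moves the landmarks and
        is compensated in the world pose."""
        m = random_pose(rng)
        lm = {k: np.asarray(v, float) for k, v in
              (("H", (0, 0, 400)), ("M", (40, 0, 0)), ("L", (-40, 0, 0)))}
        f0 = hk.femur_frame(lm["H"], lm["M"], lm["L"])
        f1 = hk.femur_frame(m.apply(lm["H"])[0], m.apply(lm["M"])[0],
                            m.apply(lm["L"])[0])
        pose = random_pose(rng)
        a0 = hk.segment_angles(pose, f0)
        a1 = hk.segment_angles(hk.compose(pose, hk.invert(m)), f1)
        assert np.allclose(a0[:3], a1[:3], atol=1e-9)


class TestCycleNormalization:
    def make_table(self, times, values):
        return pd.DataFrame({"time": times, "hip_flexion": values})

    def test_constant_series_stays_constant(self):
        t = self.make_table([0, 1, 2], [7.0, 7.0, 7.0])
        out = hk.normalize_cycle(t, 0, 2)
        assert len(out) == 101
        assert np.allclose(out["hip_flexion"], 7.0)

    def test_linear_ramp_midpoint(self):
        t = self.make_table([0, 2], [0.0, 10.0])
        out = hk.normalize_cycle(t, 0, 2)
        assert out["hip_flexion"][out["percent_cycle"] == 50].iloc[0] == \
            pytest.approx(5.0)

    def test_radiographic_frame_rate_resampling(self):
        # 3.5 frames/sec over 2 s -> 8 input samples onto 101 cycle points
        times = np.arange(8) / 3.5
        vals = np.linspace(3.0, 17.0, 8)
        out = hk.normalize_cycle(self.make_table(times, vals),
                                 times[0], times[-1])
        assert len(out) == 101
        assert out["hip_flexion"].iloc[0] == pytest.approx(vals[0])
        assert out["hip_flexion"].iloc[-1] == pytest.approx(vals[-1])

    def test_out_of_range_window_rejected(self):
        t = self.make_table([0, 1, 2], [0, 1, 2])
        with pytest.raises(ParameterError):
            hk.normalize_cycle(t, 0, 5)


class TestExtrema:
    def test_constant_series(self):
        s = pd.DataFrame({"percent_cycle": np.linspace(0, 100, 101),
                          "hip_flexion": np.full(101, 4.0)})
        ex = hk.extrema(s, "hip_flexion")
        assert ex == (4.0, 0.0, 4.0, 0.0)

    def test_sinusoid_peak_location(self):
        pct = np.linspace(0, 100, 101)
        s = pd.DataFrame({"percent_cycle": pct,
                          "hip_flexion": np.sin(2 * np.pi * pct / 100)})
        ex = hk.extrema(s, "hip_flexion")
        assert abs(ex.max_percent - 25.0) <= 1.0
        assert abs(ex.min_percent - 75.0) <= 1.0

    def test_tie_broken_by_earliest(self):
        s = pd.DataFrame({"percent_cycle": [0, 25, 50, 75, 100.0],
                          "hip_flexion": [1.0, 5.0, 1.0, 5.0, 0.0]})
        assert hk.extrema(s, "hip_flexion").max_percent == 25.0

    def test_unknown_channel_rejected(self):
        s = pd.DataFrame({"percent_cycle": [0.0], "hip_flexion": [1.0]})
        with pytest.raises(ParameterError):
            hk.extrema(s, "knee_flexion")


class TestMirror:
    def test_mirroring_twice_is_identity(self, rng):
        p = random_pose(rng)
        back = hk.mirror_pose(hk.mirror_pose(p))
        assert np.allclose(back.as_vector(), p.as_vector(), atol=1e-9)

    def test_mirrored_pose_negates_tx(self, rng):
        p = random_pose(rng)
        assert hk.mirror_pose(p).tx == pytest.approx(-p.tx)
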