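"""DLT calibration and triangulation against exact pinhole oracles."""

import numpy as np
import pytest

from tetherdic.calib import (CalibrationError, CameraDLT, CameraPair,
                             dlt_calibrate, propagate_displacement_error,
                             triangulate, triangulate_many)
from tetherdic.cameras import PinholeCamera
from tetherdic.synthgen import make_cylinder_target


@pytest.fixture(scope="module")
def noiseless_pair(rig=None):
    from tetherdic.synthgen import default_stereo_rig

    rig = default_stereo_rig()
    tgt = make_cylinder_target(rig, axial_extent=12.0, arc_deg=66.0, center_z=-0.7)
    cams = [dlt_calibrate(tgt.points3d, tgt.projections[c.name], name=c.name)
            for c in rig]
    return rig, tgt, CameraPair(cams[0], cams[1])


class TestDltCalibrate:
    def test_noiseless_projection_identity(self, noiseless_pair):
        _, tgt, pair = noiseless_pair
        assert pair.cam_a.rms_reprojection < 1e-6
        assert pair.cam_b.rms_reprojection < 1e-6
        rec, resid = triangulate_many(pair, tgt.projections["cam_a"],
                                      tgt.projections["cam_b"])
        assert np.abs(rec - tgt.points3d).max() < 1e-6
        assert resid.max() < 1e-6

    def test_coplanar_points_raise(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-5, 5, (40, 2)), np.full(40, 12.0)])
        cam = PinholeCamera.looking_at((0, 0, 60), (0, 0, 12), 1600)
        with pytest.raises(CalibrationError, match="condition"):
            dlt_calibrate(pts, cam.project(pts))

    def test_too_few_points_raise(self):
        cam = PinholeCamera.looking_at((0, 0, 60), (0, 0, 12), 1600)
        pts = np.random.default_rng(0).uniform(-3, 3, (5, 3)) + [0, 0, 12]
        with pytest.raises(CalibrationError):
            dlt_calibrate(pts, cam.project(pts))

    def test_rigid_target_frame_invariance(self, noiseless_pair):
        """Rigidly moving the target frame moves reconstructions identically."""
        from scipy.spatial.transform import Rotation

        rig, tgt, _ = noiseless_pair
        R = Rotation.from_euler("xyz", [11.0, -7.0, 23.0], degrees=True).as_matrix()
        t = np.array([3.0, -2.0, 5.0])
        pts_rot = tgt.points3d @ R.T + t
        cams = [dlt_calibrate(pts_rot, tgt.projections[c.name], name=c.name)
                for c in rig]
        rec, _ = triangulate_many(CameraPair(*cams), tgt.projections["cam_a"],
                                  tgt.projections["cam_b"])
        assert np.abs(rec - pts_rot).max() < 1e-6


class TestTriangulate:
    def test_noise_mse_matches_jacobian_oracle(self, noiseless_pair):
        """3D RMSE under px noise agrees with a finite-difference sensitivity
        oracle within 20% (Monte-Carlo over 100 seeds)."""
        rig, _, pair = noiseless_pair
        rng = np.random.default_rng(42)
        pts = rng.uniform(-3, 3, (50, 3)) * [1, 1, 0.4] + [0, 0, 11]
        ua = rig[0].project(pts)
        ub = rig[1].project(pts)
        sigma = 0.5

        # oracle: per-point Jacobian of the triangulation output wrt the 4
        # pixel inputs, by central finite differences
        expected_sq = []
        for i in range(len(pts)):
            J = np.zeros((3, 4))
            for j in range(4):
                d = np.zeros(4)
                d[j] = 1e-3
                pa, pb = ua[i] + d[:2], ub[i] + d[2:]
                xp, _ = triangulate(pair, pa, pb)
                pa, pb = ua[i] - d[:2], ub[i] - d[2:]
                xm, _ = triangulate(pair, pa, pb)
                J[:, j] = (xp - xm) / 2e-3
            expected_sq.append(sigma ** 2 * np.sum(J ** 2))
        rmse_pred = np.sqrt(np.mean(expected_sq))

        errs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            rec, _ = triangulate_many(pair, ua + r.normal(0, sigma, ua.shape),
                                      ub + r.normal(0, sigma, ub.shape))
            errs.append(np.mean(np.sum((rec - pts) ** 2, axis=1)))
        rmse_mc = np.sqrt(np.mean(errs))
        assert rmse_mc == pytest.approx(rmse_pred, rel=0.2)

    def test_single_pixel_perturbation_scale(self, noiseless_pair):
        """1 px image error maps to roughly (depth/focal) mm of 3D error."""
        rig, _, pair = noiseless_pair
        pt = np.array([0.0, 0.0, 12.0])
        ua, ub = rig[0].project(pt)[0], rig[1].project(pt)[0]
        rec, _ = triangulate(pair, ua + [1.0, 0.0], ub)
        err = np.linalg.norm(rec - pt)
        depth = float(rig[0].depths(pt)[0])
        scale = depth / rig[0].focal_px
        assert scale / 3 < err < scale * 12   # order of magnitude, geometry-dependent

    def test_symmetric_perturbation_midpoint(self, noiseless_pair):
        """Equal/opposite perturbations orthogonal to the epipolar direction
        are inconsistent between views: the residual grows with the
        perturbation while the estimate stays midway between the two."""
        rig, _, pair = noiseless_pair
        pt = np.array([0.0, 0.0, 12.0])
        ua, ub = rig[0].project(pt)[0], rig[1].project(pt)[0]
        depth_over_f = 48.0 / rig[0].focal_px
        resids, lateral = [], []
        for delta in (0.0, 0.5, 1.0, 2.0):
            rec, r = triangulate(pair, ua + [0.0, delta], ub + [0.0, -delta])
            resids.append(r)
            lateral.append(abs(rec[1] - pt[1]))
        assert np.all(np.diff(resids) > 0)
        # midway: the y estimate moves far less than one view alone implies
        assert max(lateral) < 0.6 * 2.0 * depth_over_f

    def test_zero_baseline_raises(self, noiseless_pair):
        _, _, pair = noiseless_pair
        with pytest.raises(ValueError, match="baseline"):
            CameraPair(pair.cam_a, CameraDLT(pair.cam_a.L.copy()))


class TestErrorPropagation:
    def test_sqrt2_factor(self):
        assert propagate_displacement_error(0.010) == pytest.approx(0.01414, abs=5e-5)
        assert propagate_displacement_error(0.0) == 0.0

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            propagate_displacement_error(-1e-3)

    def test_monte_carlo_difference_of_positions(self):
        """Difference of two iid isotropic positions with 10 um RMS each has
        14.1 +- 0.3 um RMS over 1e5 draws."""
        rng = np.random.default_rng(99)
        sigma = 0.010 / np.sqrt(3.0)
        a = rng.normal(0, sigma, (100_000, 3))
        b = rng.normal(0, sigma, (100_000, 3))
        rms = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        assert rms * 1e3 == pytest.approx(14.1, abs=0.3)
        assert propagate_displacement_error(0.010) * 1e3 == pytest.approx(rms * 1e3,
                                                                          abs=0.3)


def test_dlt_json_roundtrip(noiseless_pair):
    _, _, pair = noiseless_pair
    cam = CameraDLT.from_json(pair.cam_a.to_json())
    assert np.allclose(cam.L, pair.cam_a.L)
    assert cam.image_size == pair.cam_a.image_size
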