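"""Area-ratio field laws, regional statistics, strips, mesh I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from tetherdic import io as tdio
from tetherdic.pipeline import scene_region_spec
from tetherdic.surface import (AreaRatioField, RegionSpec, SurfaceMesh,
                               area_ratio, build_mesh, fit_sphere, heatmap,
                               mad_from_unity, regionalize, repeat_difference,
                               strip_profile, total_area_ratio)
from tetherdic.synthgen import SceneSpec, Tether, _annulus_mesh


@pytest.fixture(scope="module")
def sphere_cap():
    """Dense spherical-cap point grid (r = 12 mm) for mesh-accuracy checks."""
    rg = 12.0
    theta = np.linspace(0.0, np.deg2rad(20.0), 40)
    phi = np.linspace(0.0, 2 * np.pi, 90, endpoint=False)
    T, P = np.meshgrid(theta[1:], phi, indexing="ij")
    pts = rg * np.column_stack([(np.sin(T) * np.cos(P)).ravel(),
                                (np.sin(T) * np.sin(P)).ravel(),
                                np.cos(T).ravel()])
    return np.vstack([[0.0, 0.0, rg], pts])


@pytest.fixture(scope="module")
def tether_gt_field(tether_scene):
    """Area-ratio field straight from ground-truth meshes (no imaging)."""
    spec, _, gt = tether_scene
    ref = SurfaceMesh(gt.vertices_ref, gt.faces, "reference", "synthetic")
    load = SurfaceMesh(gt.vertices_def, gt.faces, "loaded", "synthetic")
    return spec, area_ratio(ref, load)


class TestBuildMesh:
    def test_square_two_faces_shared_connectivity(self):
        ref = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        m_ref, m_def = build_mesh(ref, ref + [0.3, -0.2, 0.5],
                                  min_angle_deg=0, min_area_frac=0)
        assert len(m_ref.faces) == 2
        assert np.array_equal(m_ref.faces, m_def.faces)

    def test_collinear_raises(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            build_mesh(pts, pts)

    def test_cap_area_matches_analytic(self, sphere_cap):
        rg, theta = 12.0, np.deg2rad(20.0)
        m_ref, _ = build_mesh(sphere_cap, sphere_cap)
        analytic = 2 * np.pi * rg ** 2 * (1 - np.cos(theta))
        assert m_ref.total_area == pytest.approx(analytic, rel=0.01)


class TestAreaRatio:
    def test_rigid_motion_unity(self, sphere_cap):
        R = Rotation.from_euler("zyx", [30, 10, -20], degrees=True).as_matrix()
        ref, load = build_mesh(sphere_cap, sphere_cap @ R.T + [1.0, -2.0, 0.5])
        f = area_ratio(ref, load)
        assert np.abs(f.per_face_ratio[f.valid] - 1.0).max() < 1e-12

    def test_uniform_scale_square_law(self, sphere_cap):
        for k in (1.01, 0.97, 1.25):
            ref, load = build_mesh(sphere_cap, k * sphere_cap)
            f = area_ratio(ref, load)
            assert np.allclose(f.per_face_ratio[f.valid], k ** 2, rtol=1e-12)

    def test_conservation_identity(self, sphere_cap):
        """Total mesh area ratio equals the area-weighted mean of face ratios."""
        rng = np.random.default_rng(8)
        load_pts = sphere_cap * (1 + 0.01 * rng.standard_normal((len(sphere_cap), 1)))
        ref, load = build_mesh(sphere_cap, load_pts)
        f = area_ratio(ref, load)
        w = f.face_areas_ref[f.valid]
        weighted = float((f.per_face_ratio[f.valid] * w).sum() / w.sum())
        assert weighted == pytest.approx(total_area_ratio(ref, load), rel=1e-12)

    def test_connectivity_mismatch_raises(self, sphere_cap):
        ref, load = build_mesh(sphere_cap, sphere_cap)
        other = SurfaceMesh(load.vertices, load.faces[::-1], "loaded")
        with pytest.raises(ValueError, match="connectivity"):
            area_ratio(ref, other)


def test_fit_sphere_recovers_center_radius(sphere_cap):
    center, radius = fit_sphere(sphere_cap + [1.0, 2.0, -3.0])
    assert np.allclose(center, [1.0, 2.0, -3.0], atol=1e-8)
    assert radius == pytest.approx(12.0, abs=1e-8)


class TestRegionalize:
    def make_field(self, ratios=None):
        spec = SceneSpec()
        verts, faces = _annulus_mesh(spec)
        ref = SurfaceMesh(verts, faces, "reference", "synthetic")
        f = area_ratio(ref, ref)
        if ratios is not None:
            f.per_face_ratio = ratios
        return spec, f

    def test_uniform_ones(self):
        spec, f = self.make_field()
        df = regionalize(f, scene_region_spec(spec))
        assert len(df) == 6
        assert np.allclose(df["mean"], 1.0)
        assert np.allclose(df["sd"], 0.0, atol=1e-12)
        assert np.allclose(df["mad_from_unity"], 0.0, atol=1e-12)

    def test_constructed_band_recovered_exactly(self, tether_scene):
        spec, _, gt = tether_scene
        ratios = np.ones(len(gt.faces))
        nasal = gt.sector_band_mask(0.0, (0.0, 1.0))
        ratios[nasal] = 0.977
        ref = SurfaceMesh(gt.vertices_ref, gt.faces, "reference", "synthetic")
        f = area_ratio(ref, ref)
        f.per_face_ratio = ratios
        df = regionalize(f, scene_region_spec(spec)).set_index("region")
        assert df.loc["nasal_0-1mm", "mean"] == pytest.approx(0.977, abs=1e-3)
        for reg in ("nasal_1-2mm", "superior_0-1mm", "temporal_0-1mm"):
            assert df.loc[reg, "mean"] == pytest.approx(1.0, abs=1e-3)

    def test_partition_disjoint(self):
        """No face is counted in more than one sector x annulus region."""
        spec, f = self.make_field()
        rs = scene_region_spec(spec)
        from tetherdic.surface import _surface_coords, _wrap

        s, phi = _surface_coords(f, rs)
        half = np.deg2rad(rs.sector_angle / 2)
        count = np.zeros(len(s), dtype=int)
        for az in rs.sector_azimuths.values():
            for lo, hi in rs.annuli:
                count += ((np.abs(_wrap(phi - np.deg2rad(az))) <= half)
                          & (s >= lo) & (s < hi)).astype(int)
        assert count.max() <= 1
        df = regionalize(f, rs)
        assert df["n_faces"].sum() == int((count == 1).sum())

    def test_empty_region_flagged(self):
        spec, f = self.make_field()
        rs = scene_region_spec(spec)
        rs.annuli = ((0.0, 1.0), (10.0, 11.0))   # second band beyond the mesh
        df = regionalize(f, rs)
        assert df[df["band_mm"] == (10.0, 11.0)]["empty"].all()


class TestMadFromUnity:
    def test_cases(self):
        assert mad_from_unity(np.ones(10)) == 0.0
        assert mad_from_unity(np.array([0.98, 1.02])) == pytest.approx(0.02)
        with pytest.raises(ValueError):
            mad_from_unity(np.array([]))

    def test_tether_nasal_band_near_paper_effect_size(self, tether_gt_field):
        spec, f = tether_gt_field
        rs = scene_region_spec(spec)
        df = regionalize(f, rs).set_index("region")
        assert df.loc["nasal_0-1mm", "mad_from_unity"] == pytest.approx(0.023, abs=0.004)


class TestStripProfile:
    def test_uniform_flat(self):
        spec = SceneSpec()
        verts, faces = _annulus_mesh(spec)
        ref = SurfaceMesh(verts, faces, "reference", "synthetic")
        f = area_ratio(ref, ref)
        prof = strip_profile(f, scene_region_spec(spec), "nasal", strip_width=0.3)
        assert np.allclose(prof["mean"], 1.0, atol=1e-12)

    def test_inflation_flat_at_k_squared(self):
        spec = SceneSpec()
        verts, faces = _annulus_mesh(spec)
        ref = SurfaceMesh(verts, faces, "reference", "synthetic")
        load = SurfaceMesh(1.01 * verts, faces, "loaded", "synthetic")
        f = area_ratio(ref, load)
        for d in ("nasal", "superior", "temporal"):
            prof = strip_profile(f, scene_region_spec(spec), d, strip_width=0.3)
            assert np.allclose(prof["mean"], 1.01 ** 2, rtol=1e-9)

    def test_tether_profile_shape(self, tether_gt_field):
        """Nasal profile dips below 1 inside ~1.2 mm and recovers beyond 2 mm."""
        spec, f = tether_gt_field
        prof = strip_profile(f, scene_region_spec(spec), "nasal",
                             strip_width=0.3).set_index("distance_mm")
        near = prof.loc[(prof.index > 0.15) & (prof.index <= 1.2), "mean"]
        far = prof.loc[prof.index >= 2.5, "mean"]
        assert near.min() < 0.98
        assert np.abs(far - 1.0).max() < 2e-3

    def test_unknown_direction_raises(self, tether_gt_field):
        spec, f = tether_gt_field
        with pytest.raises(ValueError):
            strip_profile(f, scene_region_spec(spec), "inferior")


class TestHeatmapRepeat:
    def test_identical_runs_zero_difference(self, tether_gt_field):
        spec, f = tether_gt_field
        rs = scene_region_spec(spec)
        assert repeat_difference(f, f, rs) == 0.0

    def test_heatmap_renders_png(self, tether_gt_field, tmp_path):
        spec, f = tether_gt_field
        out = tmp_path / "map.png"
        heatmap(f, path=str(out))
        assert out.exists() and out.stat().st_size > 0


class TestMeshIO:
    def test_fem_csv_roundtrip(self, tmp_path, sphere_cap):
        ref, load = build_mesh(sphere_cap, 1.02 * sphere_cap)
        tdio.write_fem_surface(ref, tmp_path / "nodes_ref.csv", tmp_path / "elems.csv")
        tdio.write_fem_surface(load, tmp_path / "nodes_load.csv")
        r2, l2 = tdio.read_fem_surface(tmp_path / "nodes_ref.csv",
                                       tmp_path / "nodes_load.csv",
                                       tmp_path / "elems.csv")
        assert np.allclose(r2.vertices, ref.vertices)
        assert np.array_equal(r2.faces, ref.faces)
        f = area_ratio(r2, l2)
        assert np.allclose(f.per_face_ratio[f.valid], 1.02 ** 2, rtol=1e-9)

    def test_ply_roundtrip(self, tmp_path, sphere_cap):
        ref, _ = build_mesh(sphere_cap, sphere_cap)
        tdio.write_mesh_ply(ref, tmp_path / "m.ply")
        back = tdio.read_mesh_ply(tmp_path / "m.ply")
        assert np.allclose(back.vertices, ref.vertices, atol=1e-6)
        assert np.array_equal(back.faces, ref.faces)
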