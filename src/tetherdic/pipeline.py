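"""End-to-end measurement pipeline on synthetic scenes.

Chains the full chain a bench experiment would run: calibrate both
cameras against a cylinder target (DLT), stereo-match the reference
images across cameras, track each camera from reference to deformed
state, triangulate both states, mesh the reconstructed points, and
compute the per-face surface-area-ratio field with regional statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .calib import CameraPair, dlt_calibrate, triangulate_many
from .cameras import PinholeCamera
from .dic import (DicParams, RoiGrid, correlate, estimate_global_shift,
                  matches_to_arrays, stereo_match)
from .surface import (AreaRatioField, RegionSpec, SurfaceMesh, area_ratio,
                      build_mesh)
from .synthgen import (SceneSpec, make_cylinder_target,
                       make_translation_standard)


def calibrate_rig(cameras: list[PinholeCamera], noise_sigma_px: float = 0.05,
                  seed: int = 0, **target_kwargs) -> tuple[CameraPair, dict]:
    """Calibrate a two-camera rig from a synthetic cylinder target.

    The default 0.05 px feature-localization noise emulates subpixel
    target detection. Returns the calibrated pair and a report holding the
    per-camera RMS reprojection error and the pair's 3D reconstruction RMS
    error (mm) measured by triangulating the (noisy) target projections
    back against the exact 3D coordinates.
    """
    target_kwargs.setdefault("axial_extent", 12.0)
    target_kwargs.setdefault("arc_deg", 66.0)
    target_kwargs.setdefault("center_z", -0.7)
    tgt = make_cylinder_target(cameras[:2], noise_sigma_px=noise_sigma_px,
                               seed=seed, **target_kwargs)
    cams = []
    for cam in cameras[:2]:
        cams.append(dlt_calibrate(tgt.points3d, tgt.noisy_projections[cam.name],
                                  image_size=cam.image_size, name=cam.name))
    pair = CameraPair(cams[0], cams[1])
    recon, _ = triangulate_many(pair, tgt.noisy_projections[cameras[0].name],
                                tgt.noisy_projections[cameras[1].name])
    err = np.linalg.norm(recon - tgt.points3d, axis=1)
    rms3d = float(np.sqrt(np.mean(err ** 2)))
    for c in cams:
        c.mse_3d = rms3d
    report = {"rms_reprojection_px": {c.name: c.rms_reprojection for c in cams},
              "rms_3d_mm": rms3d, "n_points": len(tgt.points3d)}
    return pair, report


def roi_from_projections(projections: np.ndarray, subset_size: int = 21,
                         grid_step: int = 8, pad_px: float = 4.0) -> RoiGrid:
    """Circular ROI polygon covering a set of projected points."""
    c = projections.mean(axis=0)
    radius = float(np.max(np.linalg.norm(projections - c, axis=1))) + pad_px
    ang = np.linspace(0.0, 2.0 * np.pi, 72, endpoint=False)
    poly = c + radius * np.column_stack([np.cos(ang), np.sin(ang)])
    return RoiGrid(poly, grid_step=grid_step, subset_size=subset_size)


@dataclass
class SceneMeasurement:
    """Everything the pipeline reconstructed from one scene."""

    mesh_ref: SurfaceMesh
    mesh_def: SurfaceMesh
    field: AreaRatioField
    points_ref: np.ndarray
    points_def: np.ndarray
    n_grid: int
    n_matched: int
    region_spec: RegionSpec | None = None
    info: dict = dataclass_field(default_factory=dict)


def measure_scene(images: dict, pair: CameraPair, roi: RoiGrid,
                  stereo_params: DicParams | None = None,
                  track_params: DicParams | None = None,
                  cam_names: tuple[str, str] | None = None) -> SceneMeasurement:
    """Run stereo DIC on rendered reference/deformed image pairs.

    ``images`` is ``{cam_name: {"reference": ..., "deformed": ...}}`` for
    exactly two cameras. Grid points are stereo-matched across cameras in
    the reference state, tracked through time in each camera, and both
    states triangulated with the shared correspondence.
    """
    names = cam_names or tuple(images.keys())
    if len(names) != 2:
        raise ValueError("need exactly two cameras")
    a, b = names
    stereo_params = stereo_params or DicParams(search_radius=40)
    track_params = track_params or DicParams(search_radius=12)

    st = stereo_match(images[a]["reference"], images[b]["reference"], roi,
                      stereo_params, pair=pair)
    st_arr = matches_to_arrays(st)
    ok = st_arr["ok"]
    pa_ref, pb_ref = st_arr["ref"][ok], st_arr["def"][ok]

    # coarse bulk motion per camera seeds the temporal search windows
    init_a = estimate_global_shift(images[a]["reference"], images[a]["deformed"])
    init_b = estimate_global_shift(images[b]["reference"], images[b]["deformed"])
    tr_a = correlate(images[a]["reference"], images[a]["deformed"], roi,
                     track_params, init_offsets=init_a, centers=pa_ref)
    tr_b = correlate(images[b]["reference"], images[b]["deformed"], roi,
                     track_params, init_offsets=init_b, centers=pb_ref)
    ta, tb = matches_to_arrays(tr_a), matches_to_arrays(tr_b)
    keep = ta["ok"] & tb["ok"]

    ref3d, _ = triangulate_many(pair, pa_ref[keep], pb_ref[keep])
    def3d, _ = triangulate_many(pair, ta["def"][keep], tb["def"][keep])

    # displacement-field consistency filter: a match that passed the score
    # cutoff can still be spurious (e.g. its true counterpart left the frame);
    # reject points whose displacement deviates grossly from the local median
    if len(ref3d) >= 10:
        from scipy.spatial import cKDTree

        disp = def3d - ref3d
        _, idx = cKDTree(ref3d).query(ref3d, k=min(9, len(ref3d)))
        med = np.median(disp[idx[:, 1:]], axis=1)
        dev = np.linalg.norm(disp - med, axis=1)
        good = dev <= max(0.02, 10.0 * float(np.median(dev)))
        ref3d, def3d = ref3d[good], def3d[good]

    mesh_ref, mesh_def = build_mesh(ref3d, def3d, provenance="dic")
    field = area_ratio(mesh_ref, mesh_def)
    return SceneMeasurement(mesh_ref, mesh_def, field, ref3d, def3d,
                            n_grid=len(st), n_matched=int(keep.sum()),
                            info={"stereo_ok": int(ok.sum())})


def scene_region_spec(spec: SceneSpec) -> RegionSpec:
    """Region layout for a synthetic globe scene (pole on +z, nasal +x)."""
    return RegionSpec(sheath_center=np.array([0.0, 0.0, spec.globe_radius]),
                      sheath_boundary_radius=spec.sheath_margin_arc,
                      nasal_direction=np.array([1.0, 0.0, 0.0]))


def measure_speckle_scene(spec: SceneSpec, pair: CameraPair | None = None,
                          grid_step: int = 8,
                          stereo_params: DicParams | None = None,
                          track_params: DicParams | None = None) -> SceneMeasurement:
    """Render a scene and measure it end-to-end (images in, field out)."""
    from .synthgen import render_speckle_scene

    images, gt = render_speckle_scene(spec)
    if pair is None:
        pair, _ = calibrate_rig(spec.camera_poses)
    name_a = spec.camera_poses[0].name
    roi = roi_from_projections(gt.projections[name_a]["reference"],
                               grid_step=grid_step)
    meas = measure_scene(images, pair, roi, stereo_params, track_params,
                         cam_names=(name_a, spec.camera_poses[1].name))
    meas.region_spec = scene_region_spec(spec)
    meas.info["ground_truth"] = gt
    return meas


def run_translation_standard(cameras: list[PinholeCamera],
                             directions=("normal", "tangential"),
                             magnitudes=(0.5, 1.0, 1.5, 2.0),
                             pair: CameraPair | None = None,
                             plane_z: float = 12.0, seed: int = 0,
                             grid_step: int = 12) -> pd.DataFrame:
    """Vernier translation-standard validation through the full pipeline.

    Normal translations move the patterned plane along +z (toward the
    cameras), tangential along +x. Per direction and magnitude, reports
    the mean measured displacement magnitude, its error against truth, and
    the mean surface area ratio (ideal: exactly the magnitude, and 1).
    Correlation failures reduce n_matched but are not fatal.
    """
    if pair is None:
        pair, _ = calibrate_rig(cameras)
    rows = []
    for direction in directions:
        vec_unit = np.array([0.0, 0.0, 1.0]) if direction == "normal" \
            else np.array([1.0, 0.0, 0.0])
        for mag in magnitudes:
            images, truth = make_translation_standard(
                cameras, tuple(mag * vec_unit), plane_z=plane_z, seed=seed)
            name_a = cameras[0].name
            uv = cameras[0].project(truth["points_ref"])
            inside = cameras[0].in_view(truth["points_ref"], margin=30)
            roi = roi_from_projections(uv[inside], grid_step=grid_step, pad_px=-10)
            meas = measure_scene(images, pair, roi,
                                 stereo_params=DicParams(search_radius=20),
                                 track_params=DicParams(search_radius=12),
                                 cam_names=(name_a, cameras[1].name))
            disp = meas.points_def - meas.points_ref
            mags = np.linalg.norm(disp, axis=1)
            r = meas.field.per_face_ratio[meas.field.valid]
            w = meas.field.face_areas_ref[meas.field.valid]
            rows.append(dict(direction=direction, magnitude_mm=mag,
                             measured_mm=float(np.mean(mags)),
                             error_mm=float(abs(np.mean(mags) - mag)),
                             area_ratio_mean=float((r * w).sum() / w.sum()),
                             area_ratio_mean_unweighted=float(np.mean(r)),
                             n_matched=meas.n_matched))
    return pd.DataFrame(rows)
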