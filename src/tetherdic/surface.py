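"""Triangulated-surface reconstruction and surface-area-ratio metrics.

The deformation metric is the per-triangle ratio of loaded to unloaded
face area. Unlike surface strain, it needs no thin-shell assumption (the
sclera thickens/thins under adduction tethering, which invalidates
membrane strain from surface data), and it obeys two exact laws used as
oracles throughout: rigid motion gives ratio 1 per face, uniform scaling
by k gives k^2 per face.

Regional statistics follow the layout used for the posterior sclera: three
fan-shaped sectors of 30 deg central angle centered on the nasal, superior
and temporal directions, each split into annular bands 0-1 mm and 1-2 mm
of geodesic distance from the optic-nerve sheath margin, plus narrow
strips along each direction for distance profiles. Because the meshes in
scope are near-spherical caps, geodesic distances are evaluated on a
least-squares sphere fitted to the reference mesh (the chord/geodesic
difference is second-order at 1-2 mm on a 12 mm globe).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd


@dataclass
class SurfaceMesh:
    """Triangulated surface; same vertex index = same material point across states."""

    vertices: np.ndarray
    faces: np.ndarray
    state: str = "reference"          # {reference, loaded}
    provenance: str = "synthetic"     # {dic, fem, synthetic}

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")

    def face_areas(self) -> np.ndarray:
        e1 = self.vertices[self.faces[:, 1]] - self.vertices[self.faces[:, 0]]
        e2 = self.vertices[self.faces[:, 2]] - self.vertices[self.faces[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    @property
    def total_area(self) -> float:
        return float(self.face_areas().sum())


@dataclass
class AreaRatioField:
    """Per-face loaded/reference area ratios on the reference mesh."""

    per_face_ratio: np.ndarray
    face_centroids: np.ndarray
    face_areas_ref: np.ndarray
    valid: np.ndarray                   # faces with nonzero reference area
    mesh: SurfaceMesh | None = None
    region_labels: np.ndarray | None = None


def build_mesh(points_ref: np.ndarray, points_def: np.ndarray,
               provenance: str = "dic", min_angle_deg: float = 5.0,
               min_area_frac: float = 0.05) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Mesh corresponding reference/deformed point sets with one connectivity.

    The reference points are parameterized on their two principal axes and
    Delaunay-triangulated there; the identical connectivity is applied to
    the deformed points (index i is the same material point in both).
    Degenerate faces are dropped, as are slivers (minimum angle below
    ``min_angle_deg`` or area below ``min_area_frac`` of the median) that
    Delaunay produces along irregular region boundaries - their tiny
    reference areas would otherwise make the ratio field arbitrarily
    noisy. Set both thresholds to 0 to keep every face.
    """
    from scipy.spatial import Delaunay, QhullError

    ref = np.atleast_2d(np.asarray(points_ref, dtype=float))
    dfp = np.atleast_2d(np.asarray(points_def, dtype=float))
    if ref.shape != dfp.shape:
        raise ValueError("point sets must correspond one-to-one")
    if len(ref) < 3:
        raise ValueError("need at least 3 points to mesh")
    centered = ref - ref.mean(axis=0)
    _, svals, Vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1e-300):
        raise ValueError("degenerate (collinear) point cloud")
    uv = centered @ Vt[:2].T
    try:
        tri = Delaunay(uv)
    except QhullError as e:      # pragma: no cover - guarded above
        raise ValueError(f"meshing failed: {e}") from e
    mesh_ref = SurfaceMesh(ref, tri.simplices, "reference", provenance)
    areas = mesh_ref.face_areas()
    keep = areas > 1e-9
    if min_area_frac > 0 and np.any(keep):
        keep &= areas > min_area_frac * np.median(areas[keep])
    if min_angle_deg > 0:
        tris = ref[tri.simplices]
        e = np.stack([tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 1],
                      tris[:, 0] - tris[:, 2]])
        ln = np.linalg.norm(e, axis=2)
        min_ang = np.full(len(tri.simplices), np.pi)
        for i in range(3):
            a, b = e[i], -e[(i + 2) % 3]
            cosang = np.einsum("ij,ij->i", a, b) / np.maximum(
                ln[i] * ln[(i + 2) % 3], 1e-300)
            min_ang = np.minimum(min_ang, np.arccos(np.clip(cosang, -1, 1)))
        keep &= min_ang >= np.deg2rad(min_angle_deg)
    faces = tri.simplices[keep]
    return (SurfaceMesh(ref, faces, "reference", provenance),
            SurfaceMesh(dfp, faces, "loaded", provenance))


def area_ratio(reference: SurfaceMesh, loaded: SurfaceMesh) -> AreaRatioField:
    """Per-face loaded/reference area ratio field.

    Requires identical connectivity; faces with reference area below
    1e-12 mm^2 are excluded (marked invalid), not silently divided.
    """
    if reference.faces.shape != loaded.faces.shape or \
            not np.array_equal(reference.faces, loaded.faces):
        raise ValueError("meshes must share connectivity")
    a_ref = reference.face_areas()
    a_load = loaded.face_areas()
    valid = a_ref > 1e-12
    ratio = np.full(len(a_ref), np.nan)
    ratio[valid] = a_load[valid] / a_ref[valid]
    return AreaRatioField(ratio, reference.face_centroids(), a_ref, valid,
                          mesh=reference)


def total_area_ratio(reference: SurfaceMesh, loaded: SurfaceMesh) -> float:
    return loaded.total_area / reference.total_area


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere through a point cloud -> (center, radius)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.sum(pts ** 2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


@dataclass
class RegionSpec:
    """Layout of the analyzed scleral regions around the sheath margin.

    ``sheath_center`` is the surface point at the middle of the ON
    junction; ``sheath_boundary_radius`` the geodesic (arc) radius of the
    sheath margin from that point. ``nasal_direction`` fixes azimuth 0 on
    the surface; superior/temporal default to 90/180 deg. Distances of
    faces are geodesic arc lengths from the margin on the sphere fitted to
    the reference mesh.
    """

    sheath_center: np.ndarray
    sheath_boundary_radius: float
    nasal_direction: np.ndarray = dataclass_field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    sector_azimuths: dict = dataclass_field(
        default_factory=lambda: {"nasal": 0.0, "superior": 90.0, "temporal": 180.0})
    sector_angle: float = 30.0
    annuli: tuple = ((0.0, 1.0), (1.0, 2.0))
    strip_width: float = 0.1
    sphere_center: np.ndarray | None = None
    sphere_radius: float | None = None

    def __post_init__(self) -> None:
        self.sheath_center = np.asarray(self.sheath_center, dtype=float)
        self.nasal_direction = np.asarray(self.nasal_direction, dtype=float)
        if self.sector_angle <= 0:
            raise ValueError("sector_angle must be positive")
        bands = sorted(self.annuli)
        for (a0, a1), (b0, b1) in zip(bands, bands[1:]):
            if a1 > b0:
                raise ValueError("annuli must be non-overlapping and ordered")


def _surface_coords(field: AreaRatioField, spec: RegionSpec
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(arc distance from sheath margin, azimuth rad) per face centroid."""
    if spec.sphere_center is None or spec.sphere_radius is None:
        if field.mesh is None:
            raise ValueError("need a reference mesh or an explicit sphere")
        center, radius = fit_sphere(field.mesh.vertices)
        spec.sphere_center, spec.sphere_radius = center, radius
    c, rho = spec.sphere_center, spec.sphere_radius
    axis = spec.sheath_center - c
    axis = axis / np.linalg.norm(axis)
    e1 = spec.nasal_direction - (spec.nasal_direction @ axis) * axis
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    d = field.face_centroids - c
    dn = d / np.linalg.norm(d, axis=1, keepdims=True)
    ang = np.arccos(np.clip(dn @ axis, -1.0, 1.0))
    s = rho * ang - spec.sheath_boundary_radius
    phi = np.arctan2(dn @ e2, dn @ e1)
    return s, phi


def _wrap(dphi: np.ndarray) -> np.ndarray:
    return np.arctan2(np.sin(dphi), np.cos(dphi))


def regionalize(field: AreaRatioField, spec: RegionSpec) -> pd.DataFrame:
    """Summary statistics per sector x annulus.

    Columns: region, sector, band_mm, n_faces, mean, sd, area_weighted_mean,
    mad_from_unity. Face means are unweighted by default; the area-weighted
    mean is reported alongside. Empty regions are flagged (n_faces 0, NaN
    stats) rather than dropped silently. The sector/annulus partition is
    disjoint by construction (each face belongs to at most one region).
    """
    s, phi = _surface_coords(field, spec)
    half = np.deg2rad(spec.sector_angle / 2.0)
    rows = []
    for sector, az in spec.sector_azimuths.items():
        dphi = np.abs(_wrap(phi - np.deg2rad(az)))
        for lo, hi in spec.annuli:
            mask = (dphi <= half) & (s >= lo) & (s < hi) & field.valid
            r = field.per_face_ratio[mask]
            a = field.face_areas_ref[mask]
            if len(r):
                rows.append(dict(region=f"{sector}_{lo:g}-{hi:g}mm", sector=sector,
                                 band_mm=(lo, hi), n_faces=len(r),
                                 mean=float(r.mean()),
                                 sd=float(r.std(ddof=1)) if len(r) > 1 else 0.0,
                                 area_weighted_mean=float((r * a).sum() / a.sum()),
                                 mad_from_unity=float(np.abs(r - 1.0).mean()),
                                 empty=False))
            else:
                rows.append(dict(region=f"{sector}_{lo:g}-{hi:g}mm", sector=sector,
                                 band_mm=(lo, hi), n_faces=0, mean=np.nan,
                                 sd=np.nan, area_weighted_mean=np.nan,
                                 mad_from_unity=np.nan, empty=True))
    return pd.DataFrame(rows)


def mad_from_unity(ratios: np.ndarray) -> float:
    """Mean absolute difference of area ratios from 1 over a face set."""
    r = np.asarray(ratios, dtype=float)
    r = r[np.isfinite(r)]
    if len(r) == 0:
        raise ValueError("empty region")
    return float(np.abs(r - 1.0).mean())


def strip_profile(field: AreaRatioField, spec: RegionSpec, direction: str,
                  max_distance: float = 4.0,
                  strip_width: float | None = None) -> pd.DataFrame:
    """Ratio vs geodesic distance along a narrow directional strip.

    Faces whose centroids lie within ``strip_width/2`` of the meridian at
    the chosen azimuth are binned at the strip resolution (bin centers at
    0, w, 2w, ...; edge ties fall to the lower bin). Returns columns
    distance_mm, mean, sd, n_faces.
    """
    if direction not in spec.sector_azimuths:
        raise ValueError(f"unknown direction {direction!r}")
    w = spec.strip_width if strip_width is None else strip_width
    s, phi = _surface_coords(field, spec)
    rho = spec.sphere_radius
    arc = s + spec.sheath_boundary_radius
    dphi = _wrap(phi - np.deg2rad(spec.sector_azimuths[direction]))
    # perpendicular geodesic distance from the meridian great circle
    perp = rho * np.arcsin(np.abs(np.clip(np.sin(arc / rho) * np.sin(dphi), -1, 1)))
    mask = (perp <= w / 2.0) & (np.abs(dphi) < np.pi / 2) & field.valid \
        & (s >= -w / 2.0) & (s <= max_distance)
    if not np.any(mask):
        raise ValueError(f"no faces in the {direction} strip")
    bins = np.floor(s[mask] / w + 0.5 - 1e-12).astype(int)
    df = pd.DataFrame({"bin": bins, "ratio": field.per_face_ratio[mask]})
    out = df.groupby("bin")["ratio"].agg(["mean", "std", "count"]).reset_index()
    out["distance_mm"] = out["bin"] * w
    return out.rename(columns={"std": "sd", "count": "n_faces"})[
        ["distance_mm", "mean", "sd", "n_faces"]]


def heatmap(field: AreaRatioField, spec: RegionSpec | None = None,
            camera=None, path: str | None = None, vmin: float = 0.95,
            vmax: float = 1.05, cmap: str = "RdBu_r"):
    """Color-mapped area-ratio field on the projected mesh.

    With ``camera`` (anything with a ``project`` method) the mesh is drawn
    in image coordinates; otherwise on its two principal in-plane axes.
    Returns the matplotlib figure; saves a PNG when ``path`` is given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mesh = field.mesh
    if camera is not None:
        uv = camera.project(mesh.vertices)
    else:
        centered = mesh.vertices - mesh.vertices.mean(axis=0)
        _, _, Vt = np.linalg.svd(centered, full_matrices=False)
        uv = centered @ Vt[:2].T
    fig, ax = plt.subplots(figsize=(5, 4.2))
    tpc = ax.tripcolor(uv[:, 0], uv[:, 1], mesh.faces,
                       facecolors=np.where(field.valid, field.per_face_ratio, np.nan),
                       vmin=vmin, vmax=vmax, cmap=cmap)
    fig.colorbar(tpc, ax=ax, label="surface area ratio")
    ax.set_aspect("equal")
    ax.set_title("loaded / reference face area")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def repeat_difference(field_a: AreaRatioField, field_b: AreaRatioField,
                      spec: RegionSpec, ds: float = 0.25,
                      dphi_deg: float = 10.0, max_distance: float = 3.0) -> float:
    """Mean absolute difference between two runs' heat maps.

    The two fields (possibly on different meshes) are binned on a common
    (distance, azimuth) grid around the sheath and compared bin-wise over
    bins populated in both.
    """
    maps = []
    for f in (field_a, field_b):
        sp = RegionSpec(spec.sheath_center.copy(), spec.sheath_boundary_radius,
                        spec.nasal_direction.copy(), dict(spec.sector_azimuths))
        s, phi = _surface_coords(f, sp)
        m = f.valid & (s >= 0) & (s < max_distance)
        i = np.floor(s[m] / ds).astype(int)
        j = np.floor((np.degrees(phi[m]) % 360.0) / dphi_deg).astype(int)
        df = pd.DataFrame({"i": i, "j": j, "r": f.per_face_ratio[m]})
        maps.append(df.groupby(["i", "j"])["r"].mean())
    both = pd.concat(maps, axis=1, join="inner")
    if both.empty:
        raise ValueError("no common bins between the two fields")
    return float(np.abs(both.iloc[:, 0] - both.iloc[:, 1]).mean())
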