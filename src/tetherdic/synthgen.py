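"""Synthetic-data generation with exact ground truth.

Everything downstream (DLT calibration, subset DIC, surface area-ratio
fields, tensile fitting) is exercised against scenes built here: a
speckle-patterned spherical cap representing the posterior sclera around
the optic-nerve (ON) sheath, viewed by a two-camera pinhole rig, under
one of three prescribed deformations:

* rigid translation - every face area ratio is exactly 1;
* inflation about the globe center by scale k - every ratio is exactly k^2;
* tether - a tangential (meridional) displacement with Gaussian decay away
  from the sheath margin, windowed in azimuth around the nasal direction,
  with amplitude calibrated so the mean face area ratio in the nasal
  0-1 mm annulus equals a requested value (default 0.977, the compression
  observed adjacent to the sheath during incremental adduction).

The surface frame puts the imaged pole on +z, with azimuth measured from
+x; nasal/superior/temporal are azimuths 0/90/180 deg. All lengths mm,
images float grayscale in [0, 1]. A single integer seed fixes every
stochastic draw, so identical specs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.optimize import brentq

from .cameras import PinholeCamera
from .tensile import StressStrainCurve


# --------------------------------------------------------------------------
# deformations

@dataclass
class RigidTranslation:
    vector: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def apply(self, points: np.ndarray, spec: "SceneSpec") -> np.ndarray:
        return points + np.asarray(self.vector, dtype=float)


@dataclass
class Inflation:
    """Uniform radial scaling about the globe center (IOP-like inflation)."""

    scale: float = 1.01

    def apply(self, points: np.ndarray, spec: "SceneSpec") -> np.ndarray:
        if self.scale <= 0:
            raise ValueError("inflation scale must be positive")
        return self.scale * points


@dataclass
class Tether:
    """Localized nasal compression mimicking ON-sheath traction.

    Points are displaced along their meridian, away from the sheath
    margin, by ``amplitude * exp(-dphi^2/(2*sphi^2)) * exp(-s^2/(2*ss^2))``
    where s is arc distance from the margin and dphi the wrapped azimuth
    offset from ``direction_deg``. The kernel sigma is ``decay_mm / 2`` so
    the field effectively vanishes beyond twice the decay length. The
    amplitude is calibrated numerically (not a free dial) so the mean face
    area ratio over the nasal 30 deg sector, 0-1 mm annulus, equals
    ``nasal_ratio``.
    """

    nasal_ratio: float = 0.977
    decay_mm: float = 1.0
    direction_deg: float = 0.0
    azimuth_sigma_deg: float = 30.0
    amplitude_mm: float | None = None  # filled by calibration

    def displace_arc(self, s: np.ndarray, phi: np.ndarray) -> np.ndarray:
        if self.amplitude_mm is None:
            raise RuntimeError("tether amplitude not calibrated yet")
        sigma_s = self.decay_mm / 2.0
        dphi = np.arctan2(np.sin(phi - np.deg2rad(self.direction_deg)),
                          np.cos(phi - np.deg2rad(self.direction_deg)))
        w = np.exp(-dphi ** 2 / (2.0 * np.deg2rad(self.azimuth_sigma_deg) ** 2))
        return self.amplitude_mm * w * np.exp(-s ** 2 / (2.0 * sigma_s ** 2))

    def apply(self, points: np.ndarray, spec: "SceneSpec") -> np.ndarray:
        rg = spec.globe_radius
        x, y, z = points.T
        theta = np.arccos(np.clip(z / rg, -1.0, 1.0))
        phi = np.arctan2(y, x)
        t = rg * theta
        s = t - spec.sheath_margin_arc
        t_new = t + self.displace_arc(s, phi)
        th = t_new / rg
        return rg * np.column_stack([np.sin(th) * np.cos(phi),
                                     np.sin(th) * np.sin(phi),
                                     np.cos(th)])


Deformation = RigidTranslation | Inflation | Tether


# --------------------------------------------------------------------------
# scene specification

def default_stereo_rig(image_size: tuple[int, int] = (512, 512),
                       focal_px: float = 1600.0,
                       baseline_mm: float = 10.0,
                       standoff_mm: float = 48.0,
                       pole_mm: float = 12.0) -> list[PinholeCamera]:
    """Two converging cameras above the imaged pole of the globe."""
    half = baseline_mm / 2.0
    target = np.array([0.0, 0.0, pole_mm])
    z = pole_mm + standoff_mm
    return [PinholeCamera.looking_at((-half, 0.0, z), target, focal_px,
                                     image_size, name="cam_a"),
            PinholeCamera.looking_at((half, 0.0, z), target, focal_px,
                                     image_size, name="cam_b")]


@dataclass
class SceneSpec:
    """Recipe for one speckle scene (geometry, cameras, deformation, seed)."""

    globe_radius: float = 12.0
    sheath_outer_radius: float = 3.2
    speckle_density: float = 40.0        # dots per mm^2
    dot_radius_mean: float = 0.05        # mm
    camera_poses: list[PinholeCamera] = dataclass_field(default_factory=default_stereo_rig)
    deformation: Deformation = dataclass_field(default_factory=RigidTranslation)
    noise_sigma: float = 0.005           # image-intensity units
    seed: int = 0
    mesh_extent_mm: float = 4.0          # ground-truth annulus width beyond margin
    mesh_ds_mm: float = 0.2
    mesh_nphi: int = 180
    background: float = 0.85

    def __post_init__(self) -> None:
        if not self.globe_radius > self.sheath_outer_radius > 0:
            raise ValueError("need globe_radius > sheath_outer_radius > 0")
        if self.speckle_density <= 0:
            raise ValueError("speckle density must be positive")
        if len(self.camera_poses) < 2:
            raise ValueError("need at least two cameras")

    @property
    def sheath_margin_arc(self) -> float:
        """Geodesic distance pole -> sheath margin on the globe surface."""
        return self.globe_radius * float(
            np.arcsin(self.sheath_outer_radius / self.globe_radius))


@dataclass
class GroundTruth:
    """Exact correspondence and per-face area ratios for one scene."""

    vertices_ref: np.ndarray
    vertices_def: np.ndarray
    faces: np.ndarray
    per_face_ratio: np.ndarray
    face_arc_s: np.ndarray               # centroid arc distance from sheath margin
    face_azimuth: np.ndarray             # centroid azimuth, radians
    projections: dict                    # {cam: {"reference": (N,2), "deformed": (N,2)}}
    meta: dict = dataclass_field(default_factory=dict)

    def sector_band_mask(self, direction_deg: float, band: tuple[float, float],
                         half_angle_deg: float = 15.0) -> np.ndarray:
        dphi = np.arctan2(np.sin(self.face_azimuth - np.deg2rad(direction_deg)),
                          np.cos(self.face_azimuth - np.deg2rad(direction_deg)))
        return ((np.abs(dphi) <= np.deg2rad(half_angle_deg))
                & (self.face_arc_s >= band[0]) & (self.face_arc_s < band[1]))


def _annulus_mesh(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Structured polar mesh of the scleral annulus outside the sheath margin."""
    rg = spec.globe_radius
    t = spec.sheath_margin_arc + np.arange(
        0.0, spec.mesh_extent_mm + spec.mesh_ds_mm / 2, spec.mesh_ds_mm)
    phi = np.linspace(0.0, 2.0 * np.pi, spec.mesh_nphi, endpoint=False)
    T, PHI = np.meshgrid(t, phi, indexing="ij")
    th = T / rg
    verts = rg * np.column_stack([(np.sin(th) * np.cos(PHI)).ravel(),
                                  (np.sin(th) * np.sin(PHI)).ravel(),
                                  np.cos(th).ravel()])
    nt, nphi = T.shape
    faces = []
    for i in range(nt - 1):
        for j in range(nphi):
            a = i * nphi + j
            b = i * nphi + (j + 1) % nphi
            c = (i + 1) * nphi + j
            d = (i + 1) * nphi + (j + 1) % nphi
            faces.append((a, b, d))
            faces.append((a, d, c))
    return verts, np.asarray(faces, dtype=np.int64)


def _tri_areas(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    e1 = verts[faces[:, 1]] - verts[faces[:, 0]]
    e2 = verts[faces[:, 2]] - verts[faces[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def calibrate_tether_amplitude(spec: SceneSpec, tether: Tether) -> float:
    """Solve for the displacement amplitude hitting the nasal-annulus target.

    The mean per-face area ratio over the 30 deg nasal sector, 0-1 mm from
    the sheath margin, is computed on the scene's ground-truth mesh and
    the amplitude bracketed by scalar root finding.
    """
    verts, faces = _annulus_mesh(spec)
    a_ref = _tri_areas(verts, faces)
    cent = verts[faces].mean(axis=1)
    theta = np.arccos(np.clip(cent[:, 2] / spec.globe_radius, -1.0, 1.0))
    s = spec.globe_radius * theta - spec.sheath_margin_arc
    phi = np.arctan2(cent[:, 1], cent[:, 0])
    dphi = np.arctan2(np.sin(phi - np.deg2rad(tether.direction_deg)),
                      np.cos(phi - np.deg2rad(tether.direction_deg)))
    mask = (np.abs(dphi) <= np.deg2rad(15.0)) & (s >= 0.0) & (s < 1.0)

    def mean_ratio(amplitude: float) -> float:
        trial = Tether(tether.nasal_ratio, tether.decay_mm, tether.direction_deg,
                       tether.azimuth_sigma_deg, amplitude_mm=amplitude)
        a_def = _tri_areas(trial.apply(verts, spec), faces)
        return float(np.mean(a_def[mask] / a_ref[mask]))

    return float(brentq(lambda a: mean_ratio(a) - tether.nasal_ratio,
                        0.0, 0.5, xtol=1e-8))


# --------------------------------------------------------------------------
# speckle rendering

def _sample_cap_points(rng: np.random.Generator, rg: float, t_lo: float,
                       t_hi: float, density: float) -> np.ndarray:
    """Uniform-by-area random points on the spherical band t in [t_lo, t_hi]."""
    c_lo, c_hi = np.cos(t_hi / rg), np.cos(t_lo / rg)  # cos decreasing in t
    area = 2.0 * np.pi * rg ** 2 * (c_hi - c_lo)
    n = rng.poisson(density * area)
    z = rng.uniform(c_lo, c_hi, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - z ** 2)
    return rg * np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), z])


def render_points(camera: PinholeCamera, points: np.ndarray, radii_mm: np.ndarray,
                  amplitudes: np.ndarray, background: float = 0.85) -> np.ndarray:
    """Render anti-aliased Gaussian dots at projected 3D points."""
    w, h = camera.image_size
    img = np.full((h, w), background, dtype=np.float64)
    depth = camera.depths(points)
    ok = depth > 0
    uv = camera.project(points[ok])
    sig = radii_mm[ok] * camera.focal_px / depth[ok]
    amp = amplitudes[ok]
    for (u, v), s, a in zip(uv, sig, amp):
        r = int(np.ceil(3.0 * s))
        x0, x1 = int(np.floor(u)) - r, int(np.floor(u)) + r + 1
        y0, y1 = int(np.floor(v)) - r, int(np.floor(v)) + r + 1
        if x1 <= 0 or y1 <= 0 or x0 >= w or y0 >= h:
            continue
        x0c, x1c, y0c, y1c = max(x0, 0), min(x1, w), max(y0, 0), min(y1, h)
        xs = np.arange(x0c, x1c)
        ys = np.arange(y0c, y1c)
        gx = np.exp(-(xs - u) ** 2 / (2.0 * s ** 2))
        gy = np.exp(-(ys - v) ** 2 / (2.0 * s ** 2))
        img[y0c:y1c, x0c:x1c] += a * gy[:, None] * gx[None, :]
    return img


def render_speckle_scene(spec: SceneSpec) -> tuple[dict, GroundTruth]:
    """Render reference/deformed speckle images and exact ground truth.

    Returns ``images[cam_name][state]`` (float arrays in [0, 1]) and a
    GroundTruth carrying the annulus mesh in both states, per-face area
    ratios, and per-camera vertex projections. Raises if the imaged pole
    is outside any camera's field of view.
    """
    deformation = spec.deformation
    if isinstance(deformation, Tether) and deformation.amplitude_mm is None:
        deformation.amplitude_mm = calibrate_tether_amplitude(spec, deformation)

    pole = np.array([[0.0, 0.0, spec.globe_radius]])
    for cam in spec.camera_poses:
        if cam.depths(pole)[0] <= 0:
            raise ValueError(f"{cam.name}: globe pole behind camera")
        if not cam.in_view(pole)[0]:
            raise ValueError(f"{cam.name}: globe pole outside field of view")

    # speckles extend slightly beyond the ground-truth annulus so that DIC
    # subsets near its rim have full texture support
    seq = np.random.SeedSequence(spec.seed)
    rng_dots, *noise_seqs = [np.random.default_rng(s) for s in seq.spawn(
        1 + 2 * len(spec.camera_poses))]
    t_lo = spec.sheath_margin_arc
    t_hi = spec.sheath_margin_arc + spec.mesh_extent_mm + 0.8
    dots = _sample_cap_points(rng_dots, spec.globe_radius, t_lo, t_hi,
                              spec.speckle_density)
    radii = spec.dot_radius_mean * rng_dots.lognormal(0.0, 0.2, len(dots))
    amps = -rng_dots.uniform(0.35, 0.75, len(dots))  # dark iron dust on pale sclera
    dots_def = deformation.apply(dots, spec)

    verts_ref, faces = _annulus_mesh(spec)
    verts_def = deformation.apply(verts_ref, spec)
    a_ref = _tri_areas(verts_ref, faces)
    a_def = _tri_areas(verts_def, faces)
    cent = verts_ref[faces].mean(axis=1)
    theta = np.arccos(np.clip(cent[:, 2] / spec.globe_radius, -1.0, 1.0))
    face_s = spec.globe_radius * theta - spec.sheath_margin_arc
    face_phi = np.arctan2(cent[:, 1], cent[:, 0])

    images: dict = {}
    projections: dict = {}
    k = 0
    for cam in spec.camera_poses:
        imgs = {}
        for state, pts in (("reference", dots), ("deformed", dots_def)):
            img = render_points(cam, pts, radii, amps, spec.background)
            if spec.noise_sigma > 0:
                img = img + noise_seqs[k].normal(0.0, spec.noise_sigma, img.shape)
            k += 1
            imgs[state] = np.clip(img, 0.0, 1.0)
        images[cam.name] = imgs
        projections[cam.name] = {"reference": cam.project(verts_ref),
                                 "deformed": cam.project(verts_def)}

    gt = GroundTruth(verts_ref, verts_def, faces, a_def / a_ref, face_s,
                     face_phi, projections,
                     meta={"deformation": type(deformation).__name__,
                           "spec_seed": spec.seed})
    if isinstance(deformation, Tether):
        gt.meta["tether_amplitude_mm"] = deformation.amplitude_mm
    return images, gt


# --------------------------------------------------------------------------
# calibration target

@dataclass
class CylinderTarget:
    """Feature points on a cylinder of known diameter, with projections."""

    points3d: np.ndarray
    projections: dict        # {cam: (N,2) exact}
    noisy_projections: dict  # {cam: (N,2) with Gaussian px noise}
    diameter: float
    noise_sigma_px: float


def make_cylinder_target(cameras: list[PinholeCamera], diameter: float = 25.4,
                         n_axial: int = 9, n_circ: int = 9,
                         axial_extent: float = 16.0, arc_deg: float = 80.0,
                         noise_sigma_px: float = 0.0, seed: int = 0,
                         center_z: float = 0.0) -> CylinderTarget:
    """Grid of pattern features on a cylinder of eye-like diameter.

    The cylinder axis runs along x at height ``center_z`` with the imaged
    arc facing +z (toward the cameras). Exact pinhole projections and a
    noisy copy are returned per camera; fewer than 6 features visible in
    any camera raises, and fewer than 20 in the first pair raises too.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    radius = diameter / 2.0
    xs = np.linspace(-axial_extent / 2, axial_extent / 2, n_axial)
    angs = np.deg2rad(np.linspace(-arc_deg / 2, arc_deg / 2, n_circ))
    X, A = np.meshgrid(xs, angs, indexing="ij")
    pts = np.column_stack([X.ravel(), radius * np.sin(A).ravel(),
                           center_z + radius * np.cos(A).ravel()])
    rng = np.random.default_rng(seed)
    projections, noisy = {}, {}
    visible = np.ones(len(pts), dtype=bool)
    for cam in cameras:
        visible &= cam.in_view(pts, margin=2.0)
    if visible.sum() < 6:
        raise ValueError("insufficient calibration features: fewer than 6 "
                         "points visible in every camera")
    if len(cameras) >= 2 and visible.sum() < 20:
        raise ValueError(f"only {visible.sum()} features visible in the pair; "
                         "need at least 20")
    pts = pts[visible]
    for cam in cameras:
        uv = cam.project(pts)
        projections[cam.name] = uv
        noisy[cam.name] = uv + rng.normal(0.0, noise_sigma_px, uv.shape)
    return CylinderTarget(pts, projections, noisy, diameter, noise_sigma_px)


# --------------------------------------------------------------------------
# planar translation standard

def make_translation_standard(cameras: list[PinholeCamera],
                              translation: tuple[float, float, float],
                              extent_mm: float = 14.0, plane_z: float = 12.0,
                              density: float = 40.0, dot_radius: float = 0.05,
                              noise_sigma: float = 0.005, seed: int = 0,
                              background: float = 0.85) -> tuple[dict, dict]:
    """Randomly patterned plane on a vernier stage, translated rigidly.

    Emulates the sheet-of-paper displacement standard: the plane sits at
    ``z = plane_z`` (where the globe pole normally is) and is translated
    by ``translation`` between states. Returns images per camera per state
    and a ground-truth dict with the exact dot positions in both states.
    """
    seq = np.random.SeedSequence(seed)
    rng, *noise_seqs = [np.random.default_rng(s) for s in seq.spawn(
        1 + 2 * len(cameras))]
    n = rng.poisson(density * extent_mm ** 2)
    xy = rng.uniform(-extent_mm / 2, extent_mm / 2, (n, 2))
    pts = np.column_stack([xy, np.full(n, plane_z)])
    radii = dot_radius * rng.lognormal(0.0, 0.2, n)
    amps = -rng.uniform(0.35, 0.75, n)
    pts_def = pts + np.asarray(translation, dtype=float)

    images: dict = {}
    k = 0
    for cam in cameras:
        imgs = {}
        for state, p in (("reference", pts), ("deformed", pts_def)):
            img = render_points(cam, p, radii, amps, background)
            if noise_sigma > 0:
                img = img + noise_seqs[k].normal(0.0, noise_sigma, img.shape)
            k += 1
            imgs[state] = np.clip(img, 0.0, 1.0)
        images[cam.name] = imgs
    truth = {"points_ref": pts, "points_def": pts_def,
             "translation": np.asarray(translation, dtype=float)}
    return images, truth


# --------------------------------------------------------------------------
# tensile curves

SHEATH_DEFAULTS = dict(gamma_low=1.2, gamma_high=2.5, breakpoint_strain=0.034,
                       scale=2.15)


def synth_tensile(region_label: str = "ON_sheath", gamma_low: float = 1.2,
                  gamma_high: float = 2.5, breakpoint_strain: float = 0.034,
                  scale: float = 2.15, noise_sigma: float = 0.0,
                  n_samples: int = 160, seed: int = 0,
                  strain_min: float = 0.002, strain_max: float = 0.12) -> StressStrainCurve:
    """Piecewise power-law stress-strain curve with a log-log breakpoint.

    The noiseless backbone is sigma = scale * eps^gamma_low below the
    breakpoint and continues continuously with exponent gamma_high above,
    i.e. log sigma vs log eps is exactly piecewise linear with the stated
    break. Multiplicative Gaussian noise (sd ``noise_sigma``) perturbs
    stress only. ``gamma_low == gamma_high`` degenerates to a single
    power law.
    """
    if gamma_low <= 0 or gamma_high <= 0:
        raise ValueError("exponents must be positive")
    if not 0 < breakpoint_strain < strain_max:
        raise ValueError("breakpoint must lie inside the strain range")
    if strain_min <= 0:
        raise ValueError("strains must be positive")
    eps = np.linspace(strain_min, strain_max, n_samples)
    sigma = np.where(
        eps <= breakpoint_strain,
        scale * eps ** gamma_low,
        scale * breakpoint_strain ** (gamma_low - gamma_high) * eps ** gamma_high)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        sigma = sigma * (1.0 + rng.normal(0.0, noise_sigma, len(sigma)))
        sigma = np.maximum(sigma, 1e-9)
    return StressStrainCurve(eps, sigma, region_label, meta={
        "gamma_low": gamma_low, "gamma_high": gamma_high,
        "breakpoint_strain": breakpoint_strain, "scale": scale,
        "noise_sigma": noise_sigma, "seed": seed})
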