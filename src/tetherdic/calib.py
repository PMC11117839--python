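"""Direct linear transformation (DLT) calibration and stereo triangulation.

Each camera is modeled by the classic 11-parameter DLT mapping a 3D point
X to pixel coordinates

    u = (L1 x + L2 y + L3 z + L4) / (L9 x + L10 y + L11 z + 1)
    v = (L5 x + L6 y + L7 z + L8) / (L9 x + L10 y + L11 z + 1),

estimated from known 3D <-> 2D correspondences by homogeneous least
squares with Hartley-style coordinate normalization for conditioning.
Two calibrated cameras triangulate a 3D point by linear least-squares
intersection of the two DLT rays; no bundle adjustment is performed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np


class CalibrationError(ValueError):
    """Degenerate or rank-deficient calibration configuration."""


@dataclass
class CameraDLT:
    """One calibrated camera: 11 DLT parameters (L12 fixed at 1)."""

    L: np.ndarray
    image_size: tuple[int, int] = (512, 512)
    rms_reprojection: float = float("nan")
    mse_3d: float = float("nan")         # filled after pair validation, mm
    name: str = "cam"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float).ravel()
        if self.L.shape != (11,):
            raise ValueError("DLT parameter vector must have 11 entries")

    @property
    def P(self) -> np.ndarray:
        """3x4 homogeneous projection matrix with P[2,3] = 1."""
        return np.append(self.L, 1.0).reshape(3, 4)

    def project(self, points3d: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points3d, dtype=float))
        Xh = np.column_stack([pts, np.ones(len(pts))])
        q = Xh @ self.P.T
        if np.any(q[:, 2] == 0):
            raise ValueError("point on the camera plane (zero denominator)")
        return q[:, :2] / q[:, 2:3]

    def to_json(self) -> str:
        return json.dumps({"L": self.L.tolist(), "image_size": list(self.image_size),
                           "rms_reprojection": self.rms_reprojection,
                           "mse_3d": self.mse_3d, "name": self.name})

    @classmethod
    def from_json(cls, s: str) -> "CameraDLT":
        d = json.loads(s)
        cam = cls(np.array(d["L"]), tuple(d["image_size"]), name=d.get("name", "cam"))
        cam.rms_reprojection = d.get("rms_reprojection", float("nan"))
        cam.mse_3d = d.get("mse_3d", float("nan"))
        return cam


@dataclass
class CameraPair:
    """Two cameras calibrated against the same target frame."""

    cam_a: CameraDLT
    cam_b: CameraDLT
    residual_threshold_px: float = 1.0   # match-rejection default

    def __post_init__(self) -> None:
        if np.allclose(self.cam_a.L, self.cam_b.L, rtol=1e-9, atol=1e-9):
            raise ValueError("identical cameras: zero baseline cannot triangulate")


def _normalizer_2d(pts: np.ndarray) -> np.ndarray:
    c = pts.mean(axis=0)
    scale = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - c, axis=1)), 1e-12)
    T = np.diag([scale, scale, 1.0])
    T[:2, 2] = -scale * c
    return T


def _normalizer_3d(pts: np.ndarray) -> np.ndarray:
    c = pts.mean(axis=0)
    scale = np.sqrt(3.0) / max(np.mean(np.linalg.norm(pts - c, axis=1)), 1e-12)
    U = np.diag([scale, scale, scale, 1.0])
    U[:3, 3] = -scale * c
    return U


def dlt_calibrate(points3d: np.ndarray, points2d: np.ndarray,
                  image_size: tuple[int, int] = (512, 512),
                  name: str = "cam", condition_limit: float = 1e8) -> CameraDLT:
    """Estimate the 11 DLT parameters from >= 6 non-coplanar correspondences.

    Homogeneous least squares (SVD) on normalized coordinates; the raw
    projection matrix is rescaled so its last entry is 1. A coplanar or
    otherwise deficient configuration raises CalibrationError carrying the
    design-matrix condition number.
    """
    X = np.atleast_2d(np.asarray(points3d, dtype=float))
    x = np.atleast_2d(np.asarray(points2d, dtype=float))
    if len(X) != len(x):
        raise ValueError("3D and 2D point counts differ")
    if len(X) < 6:
        raise CalibrationError(f"need at least 6 correspondences, got {len(X)}")

    U = _normalizer_3d(X)
    T = _normalizer_2d(x)
    Xn = (np.column_stack([X, np.ones(len(X))]) @ U.T)
    xn = (np.column_stack([x, np.ones(len(x))]) @ T.T)[:, :2]

    A = np.zeros((2 * len(X), 12))
    A[0::2, 0:4] = Xn
    A[0::2, 8:12] = -xn[:, 0:1] * Xn
    A[1::2, 4:8] = Xn
    A[1::2, 8:12] = -xn[:, 1:2] * Xn

    _, svals, Vt = np.linalg.svd(A)
    cond = svals[0] / max(svals[-2], 1e-300)
    if cond > condition_limit:
        raise CalibrationError(
            f"rank-deficient calibration (coplanar points?): "
            f"condition number {cond:.3g} exceeds {condition_limit:.3g}")
    Pn = Vt[-1].reshape(3, 4)
    P = np.linalg.inv(T) @ Pn @ U
    if abs(P[2, 3]) < 1e-12:
        raise CalibrationError("degenerate solution: cannot fix L12 = 1")
    P = P / P[2, 3]

    cam = CameraDLT(P.ravel()[:11], image_size, name=name,
                    meta={"condition_number": float(cond), "n_points": len(X)})
    resid = cam.project(X) - x
    cam.rms_reprojection = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return cam


def triangulate(pair: CameraPair, pt_a: np.ndarray, pt_b: np.ndarray,
                warn_condition: float = 1e6) -> tuple[np.ndarray, float]:
    """Linear two-view intersection of the DLT rays of one match.

    Returns the 3D point (mm) and the RMS reprojection residual (px).
    Near-parallel rays trigger an ill-conditioning warning.
    """
    pts, resid = triangulate_many(pair, np.atleast_2d(pt_a), np.atleast_2d(pt_b),
                                  warn_condition=warn_condition)
    return pts[0], float(resid[0])


def triangulate_many(pair: CameraPair, pts_a: np.ndarray, pts_b: np.ndarray,
                     warn_condition: float = 1e6) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized triangulation of matched pixel coordinates (N, 2) x 2."""
    Pa, Pb = pair.cam_a.P, pair.cam_b.P
    pts_a = np.atleast_2d(np.asarray(pts_a, dtype=float))
    pts_b = np.atleast_2d(np.asarray(pts_b, dtype=float))
    n = len(pts_a)
    out = np.empty((n, 3))
    resid = np.empty(n)
    warned = False
    for i in range(n):
        rows, rhs = [], []
        for P, (u, v) in ((Pa, pts_a[i]), (Pb, pts_b[i])):
            rows.append(P[0, :3] - u * P[2, :3])
            rhs.append(u * P[2, 3] - P[0, 3])
            rows.append(P[1, :3] - v * P[2, :3])
            rhs.append(v * P[2, 3] - P[1, 3])
        A = np.asarray(rows)
        b = np.asarray(rhs)
        sol, _, _, sv = np.linalg.lstsq(A, b, rcond=None)
        if not warned and sv[-1] > 0 and sv[0] / sv[-1] > warn_condition:
            warnings.warn("near-parallel rays: triangulation ill-conditioned")
            warned = True
        out[i] = sol
        ra = pair.cam_a.project(sol) - pts_a[i]
        rb = pair.cam_b.project(sol) - pts_b[i]
        resid[i] = np.sqrt(np.mean(np.concatenate([ra.ravel(), rb.ravel()]) ** 2))
    return out, resid


def propagate_displacement_error(per_point_mse_mm: float) -> float:
    """Displacement RMS error from per-point positional RMS error.

    A displacement is the difference of two independent, equally noisy
    positions, so its RMS error is the per-point error times sqrt(2)
    (e.g. 0.010 mm -> 0.0141 mm).
    """
    if per_point_mse_mm < 0:
        raise ValueError("error must be non-negative")
    return per_point_mse_mm * float(np.sqrt(2.0))


def validate_translation_standard(cameras, directions=("normal", "tangential"),
                                  magnitudes=(0.5, 1.0, 1.5, 2.0), **kwargs):
    """Run the vernier translation-standard check through the full pipeline.

    For each direction and magnitude a randomly patterned planar standard
    is rendered, measured by DIC + triangulation, and the recovered mean
    displacement and surface area ratio are compared with truth. Delegates
    to :func:`tetherdic.pipeline.run_translation_standard`.
    """
    from .pipeline import run_translation_standard
    return run_translation_standard(cameras, directions=directions,
                                    magnitudes=magnitudes, **kwargs)
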