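"""Ideal pinhole camera model.

Used by the synthetic-scene generator to project 3D surface points into
image coordinates, and by tests as the exact forward model that DLT
calibration must recover. Lengths are mm, image coordinates px.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def look_at_rotation(position: np.ndarray, target: np.ndarray,
                     up: np.ndarray = (0.0, 1.0, 0.0)) -> np.ndarray:
    """World->camera rotation with the optical axis (+z_cam) toward *target*."""
    position = np.asarray(position, dtype=float)
    z = np.asarray(target, dtype=float) - position
    nz = np.linalg.norm(z)
    if nz == 0:
        raise ValueError("camera position coincides with target")
    z = z / nz
    up = np.asarray(up, dtype=float)
    x = np.cross(up, z)
    if np.linalg.norm(x) < 1e-12:  # up parallel to axis: pick another up
        up = np.array([1.0, 0.0, 0.0])
        x = np.cross(up, z)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return np.vstack([x, y, z])


@dataclass
class PinholeCamera:
    """Distortion-free pinhole camera.

    Attributes
    ----------
    position : (3,) camera center in world frame, mm.
    rotation : (3, 3) world->camera rotation; rows are the camera axes.
    focal_px : focal length expressed in pixels.
    principal_point : (cx, cy) px.
    image_size : (width, height) px.
    """

    position: np.ndarray
    rotation: np.ndarray
    focal_px: float
    principal_point: tuple[float, float]
    image_size: tuple[int, int] = (512, 512)
    name: str = field(default="cam")

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if min(self.image_size) < 256:
            raise ValueError("image size must be at least 256 px")

    @classmethod
    def looking_at(cls, position, target, focal_px, image_size=(512, 512),
                   name="cam", up=(0.0, 1.0, 0.0)) -> "PinholeCamera":
        rot = look_at_rotation(np.asarray(position, float), np.asarray(target, float), up)
        cx = (image_size[0] - 1) / 2.0
        cy = (image_size[1] - 1) / 2.0
        return cls(np.asarray(position, float), rot, float(focal_px),
                   (cx, cy), tuple(image_size), name)

    @property
    def projection_matrix(self) -> np.ndarray:
        """3x4 homogeneous projection matrix K [R | -R C]."""
        K = np.array([[self.focal_px, 0.0, self.principal_point[0]],
                      [0.0, self.focal_px, self.principal_point[1]],
                      [0.0, 0.0, 1.0]])
        Rt = np.hstack([self.rotation, -self.rotation @ self.position[:, None]])
        return K @ Rt

    def depths(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.position) @ self.rotation[2]

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project (N, 3) world points to (N, 2) pixel coordinates.

        Raises if any point lies at or behind the camera plane.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cam = (pts - self.position) @ self.rotation.T
        if np.any(cam[:, 2] <= 0):
            raise ValueError("point at or behind the camera")
        u = self.focal_px * cam[:, 0] / cam[:, 2] + self.principal_point[0]
        v = self.focal_px * cam[:, 1] / cam[:, 2] + self.principal_point[1]
        return np.column_stack([u, v])

    def in_view(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cam = (pts - self.position) @ self.rotation.T
        ok = cam[:, 2] > 0
        uv = np.full((len(pts), 2), np.nan)
        uv[ok, 0] = self.focal_px * cam[ok, 0] / cam[ok, 2] + self.principal_point[0]
        uv[ok, 1] = self.focal_px * cam[ok, 1] / cam[ok, 2] + self.principal_point[1]
        w, h = self.image_size
        ok &= (uv[:, 0] >= margin) & (uv[:, 0] <= w - 1 - margin)
        ok &= (uv[:, 1] >= margin) & (uv[:, 1] <= h - 1 - margin)
        return ok
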