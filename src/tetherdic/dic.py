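"""Subset-based 2D digital image correlation (DIC).

Each point of a region-of-interest grid is matched from one grayscale
image to another by zero-normalized cross-correlation (ZNCC): an integer
search over a window locates the correlation peak, which is then refined
to subpixel precision by maximizing ZNCC over a continuously interpolated
(cubic-spline) deformed subset. ZNCC is invariant to per-image affine
intensity changes (gain/offset), which makes the score a meaningful match
quality in [-1, 1].

The same machinery serves temporal matching (reference vs deformed state
of one camera) and cross-camera stereo matching; for stereo, matches can
additionally be rejected on their post-triangulation residual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.ndimage import map_coordinates, spline_filter
from scipy.optimize import minimize
from skimage.feature import match_template

from .calib import CameraPair, triangulate_many


@dataclass
class RoiGrid:
    """Polygonal region of interest sampled on a square grid.

    ``exclusions`` are optional polygons (e.g. an occluded or textureless
    patch) whose interior grid points are dropped.
    """

    polygon: np.ndarray          # (M, 2) image coords (u, v)
    grid_step: int = 5
    subset_size: int = 21
    exclusions: list = None

    def __post_init__(self) -> None:
        self.polygon = np.atleast_2d(np.asarray(self.polygon, dtype=float))
        if self.subset_size < 11 or self.subset_size % 2 == 0:
            raise ValueError("subset_size must be odd and >= 11 px")
        if self.grid_step < 1:
            raise ValueError("grid_step must be >= 1 px")
        if self.exclusions is None:
            self.exclusions = []

    def grid_points(self) -> np.ndarray:
        """Grid points (u, v) inside the polygon and outside all exclusions."""
        lo = np.floor(self.polygon.min(axis=0))
        hi = np.ceil(self.polygon.max(axis=0))
        us = np.arange(lo[0], hi[0] + 1, self.grid_step)
        vs = np.arange(lo[1], hi[1] + 1, self.grid_step)
        U, V = np.meshgrid(us, vs)
        pts = np.column_stack([U.ravel(), V.ravel()])
        inside = MplPath(self.polygon).contains_points(pts)
        for ex in self.exclusions:
            inside &= ~MplPath(np.atleast_2d(np.asarray(ex, float))
                               ).contains_points(pts)
        return pts[inside]


@dataclass
class DicParams:
    """Matching parameters (artifact defaults, all configurable)."""

    search_radius: int = 15
    score_cutoff: float = 0.8
    contrast_floor: float = 0.01     # min std of subset intensities
    refine: bool = True
    max_refine_shift: float = 1.5    # px around the integer peak


@dataclass
class SubsetMatch:
    """One grid point matched (or not) between two images."""

    ref_center: np.ndarray
    def_center: np.ndarray
    score: float
    status: str = "ok"
    reason: str | None = None

    @property
    def displacement(self) -> np.ndarray:
        return self.def_center - self.ref_center


def zncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-normalized cross-correlation of two equal-shape subsets."""
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        return 0.0
    return float(a @ b / (na * nb))


def _sample_subset(filtered: np.ndarray, center_uv: np.ndarray, half: int) -> np.ndarray:
    """Subset of size (2*half+1)^2 centered at a (possibly subpixel) point."""
    off = np.arange(-half, half + 1, dtype=float)
    V, U = np.meshgrid(center_uv[1] + off, center_uv[0] + off, indexing="ij")
    return map_coordinates(filtered, [V, U], order=3, prefilter=False,
                           mode="nearest")


def correlate(ref_image: np.ndarray, def_image: np.ndarray, roi: RoiGrid,
              params: DicParams = DicParams(),
              init_offsets: np.ndarray | None = None,
              centers: np.ndarray | None = None) -> list[SubsetMatch]:
    """Match every ROI grid point from ref_image into def_image.

    ``init_offsets`` seeds the integer search per point (one row per grid
    point, or a single (2,) vector); ``centers`` overrides the ROI grid
    with explicit, possibly subpixel, reference centers. Deterministic:
    no randomness anywhere. Rejected matches carry a reason code among
    {low_contrast, out_of_bounds, out_of_range, low_score}.
    """
    if ref_image.shape != def_image.shape:
        raise ValueError("images must have the same shape")
    pts = roi.grid_points() if centers is None else np.atleast_2d(centers)
    half = roi.subset_size // 2
    R = params.search_radius
    h, w = ref_image.shape

    if init_offsets is None:
        inits = np.zeros((len(pts), 2))
    else:
        inits = np.broadcast_to(np.asarray(init_offsets, dtype=float),
                                (len(pts), 2)).copy()

    ref_f = spline_filter(np.asarray(ref_image, dtype=float), order=3)
    def_f = spline_filter(np.asarray(def_image, dtype=float), order=3)
    def_raw = np.asarray(def_image, dtype=float)

    matches: list[SubsetMatch] = []
    for p, o in zip(pts, inits):
        if not (half <= p[0] <= w - 1 - half and half <= p[1] <= h - 1 - half):
            matches.append(SubsetMatch(p, p + o, 0.0, "rejected", "out_of_bounds"))
            continue
        template = _sample_subset(ref_f, p, half)
        if template.std() < params.contrast_floor:
            matches.append(SubsetMatch(p, p + o, 0.0, "rejected", "low_contrast"))
            continue

        q0 = np.rint(p + o).astype(int)
        x0, x1 = q0[0] - half - R, q0[0] + half + R + 1
        y0, y1 = q0[1] - half - R, q0[1] + half + R + 1
        x0c, x1c, y0c, y1c = max(x0, 0), min(x1, w), max(y0, 0), min(y1, h)
        window = def_raw[y0c:y1c, x0c:x1c]
        if window.shape[0] < 2 * half + 1 or window.shape[1] < 2 * half + 1:
            matches.append(SubsetMatch(p, p + o, 0.0, "rejected", "out_of_bounds"))
            continue
        corr = match_template(window, template)
        iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
        # peak on the search border means the true displacement may be outside
        if (iy in (0, corr.shape[0] - 1) or ix in (0, corr.shape[1] - 1)):
            matches.append(SubsetMatch(p, p + o, float(corr[iy, ix]),
                                       "rejected", "out_of_range"))
            continue
        q_int = np.array([x0c + ix + half, y0c + iy + half], dtype=float)
        score = float(corr[iy, ix])

        q = q_int
        if params.refine:
            lim = params.max_refine_shift

            def neg_score(d):
                if np.any(np.abs(d) > lim):
                    return 1.0
                return -zncc(template, _sample_subset(def_f, q_int + d, half))

            res = minimize(neg_score, np.zeros(2), method="Nelder-Mead",
                           options={"xatol": 1e-3, "fatol": 1e-8, "maxiter": 200})
            if -res.fun >= score:     # keep refinement only if it improved
                q = q_int + res.x
                score = float(-res.fun)

        if score < params.score_cutoff:
            matches.append(SubsetMatch(p, q, score, "rejected", "low_score"))
        else:
            matches.append(SubsetMatch(p, q, score))
    return matches


def stereo_match(image_a: np.ndarray, image_b: np.ndarray, roi: RoiGrid,
                 params: DicParams = DicParams(),
                 pair: CameraPair | None = None,
                 init_offsets: np.ndarray | None = None,
                 centers: np.ndarray | None = None) -> list[SubsetMatch]:
    """Cross-camera subset matching, suitable for triangulation.

    If a calibrated ``pair`` is supplied, each accepted match is
    triangulated and rejected when its reprojection residual exceeds the
    pair's threshold (reason code ``high_residual``).
    """
    matches = correlate(image_a, image_b, roi, params, init_offsets, centers)
    if pair is not None:
        ok = [m for m in matches if m.status == "ok"]
        if ok:
            pa = np.array([m.ref_center for m in ok])
            pb = np.array([m.def_center for m in ok])
            _, resid = triangulate_many(pair, pa, pb)
            for m, r in zip(ok, resid):
                if r > pair.residual_threshold_px:
                    m.status, m.reason = "rejected", "high_residual"
    return matches


def estimate_global_shift(ref_image: np.ndarray, def_image: np.ndarray) -> np.ndarray:
    """Coarse whole-image shift (u, v) by phase correlation.

    Used to seed the integer subset search so that large bulk motions
    (e.g. millimetre stage translations) need only a small per-subset
    search window.
    """
    from skimage.registration import phase_cross_correlation

    shift, *_ = phase_cross_correlation(ref_image, def_image, upsample_factor=4)
    est = np.array([-shift[1], -shift[0]])  # (row, col) -> (u, v) of ref->def
    # guard against spurious peaks (e.g. pure scale change has no global
    # shift): keep the estimate only if it improves whole-image correlation
    r = np.rint(est).astype(int)
    rolled = np.roll(def_image, (-r[1], -r[0]), axis=(0, 1))
    if zncc(np.asarray(ref_image, float), np.asarray(rolled, float)) <= \
            zncc(np.asarray(ref_image, float), np.asarray(def_image, float)):
        return np.zeros(2)
    return est


def matches_to_arrays(matches: Sequence[SubsetMatch]) -> dict:
    """Stack a match list into arrays (ok subset only in 'mask')."""
    ref = np.array([m.ref_center for m in matches])
    dfc = np.array([m.def_center for m in matches])
    score = np.array([m.score for m in matches])
    ok = np.array([m.status == "ok" for m in matches])
    return {"ref": ref, "def": dfc, "score": score, "ok": ok}
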