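"""Uniaxial tensile-curve analysis for ocular tissues.

Converts force-elongation records to engineering stress-strain, fits
polynomial curves to extract tangent moduli at requested strains, and
detects the toe-region end of strain-stiffening tissue (notably the optic
nerve sheath) by bilinear regression in log-log coordinates: two ordinary
least-squares lines in (log strain, log stress) minimizing total squared
error, the transition strain being the abscissa of their intersection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

REGIONS = ("anterior", "equatorial", "posterior", "peripapillary", "ON", "ON_sheath")


@dataclass
class TensileRecord:
    """Raw uniaxial record: force (N) and grip separation (mm) samples.

    ``gauge_length_0`` is the grip separation at the 0.02 N preload; it is
    the reference length for engineering strain, which shifts all derived
    moduli and is therefore stated explicitly rather than inferred.
    """

    force_n: np.ndarray
    length_mm: np.ndarray
    width_mm: float
    thickness_mm: float
    gauge_length_0: float
    region_label: str = "posterior"
    preload_n: float = 0.02
    sample_rate_hz: float = 5.0

    def __post_init__(self) -> None:
        self.force_n = np.asarray(self.force_n, dtype=float)
        self.length_mm = np.asarray(self.length_mm, dtype=float)
        if self.width_mm <= 0 or self.thickness_mm <= 0:
            raise ValueError("cross-section dimensions must be positive")
        if self.gauge_length_0 <= 0:
            raise ValueError("gauge length must be positive")
        if self.force_n.shape != self.length_mm.shape:
            raise ValueError("force and length must have equal length")


@dataclass
class StressStrainCurve:
    """Engineering stress-strain samples for one tissue strip."""

    strain: np.ndarray
    stress_mpa: np.ndarray
    region_label: str = "posterior"
    rupture_index: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress_mpa = np.asarray(self.stress_mpa, dtype=float)
        if self.strain.shape != self.stress_mpa.shape:
            raise ValueError("strain and stress must have equal length")

    def __len__(self) -> int:
        return len(self.strain)


@dataclass
class BilinearFit:
    """Result of the bilinear log-log regression."""

    transition_strain: float
    slope_low: float
    slope_high: float
    intercept_low: float
    intercept_high: float
    r2_low: float
    r2_high: float
    sse_total: float
    break_index: int
    degenerate: bool = False
    out_of_range: bool = False

    def to_json(self) -> str:
        return json.dumps({k: getattr(self, k) for k in (
            "transition_strain", "slope_low", "slope_high", "intercept_low",
            "intercept_high", "r2_low", "r2_high", "sse_total", "break_index",
            "degenerate", "out_of_range")})


def to_stress_strain(rec: TensileRecord) -> StressStrainCurve:
    """Engineering stress-strain from a force-elongation record.

    strain = (L - L0)/L0 with L0 the grip separation at preload;
    stress = F / (width * thickness). Samples after peak force (rupture)
    are truncated. The preload itself is not subtracted: stress at zero
    strain equals preload/(w*t).
    """
    area = rec.width_mm * rec.thickness_mm
    strain = (rec.length_mm - rec.gauge_length_0) / rec.gauge_length_0
    stress = rec.force_n / area  # N/mm^2 == MPa
    i_rupture = int(np.argmax(rec.force_n))
    keep = slice(0, i_rupture + 1)
    return StressStrainCurve(strain[keep], stress[keep], rec.region_label,
                             rupture_index=i_rupture,
                             meta={"preload_stress_mpa": rec.preload_n / area})


def _poly_fit_best(strain: np.ndarray, stress: np.ndarray,
                   order_range: Sequence[int]) -> tuple[np.polynomial.Polynomial, int, float]:
    """Best polynomial by adjusted R^2 over the order range."""
    n = len(strain)
    best = None
    for order in order_range:
        if n <= order + 1:
            continue
        p = np.polynomial.Polynomial.fit(strain, stress, order)
        resid = stress - p(strain)
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((stress - stress.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - order - 1)
        if best is None or r2_adj > best[2]:
            best = (p, order, r2_adj)
    if best is None:
        raise ValueError("too few samples for requested polynomial orders")
    return best


def fit_tangent_moduli(curve: StressStrainCurve,
                       strain_points: Sequence[float] = (0.03, 0.06, 0.07),
                       order_range: Sequence[int] = (3, 4, 5),
                       order: int | None = None) -> dict:
    """Tangent moduli dsigma/deps (MPa) at requested strains.

    A polynomial of order 3-5 (chosen by adjusted R^2, or forced via
    ``order``) is fitted to the curve and differentiated analytically.
    Strain points beyond the sampled range are flagged, not extrapolated.
    """
    if order is not None:
        p, used_order, r2_adj = _poly_fit_best(curve.strain, curve.stress_mpa, [order])
    else:
        p, used_order, r2_adj = _poly_fit_best(curve.strain, curve.stress_mpa, order_range)
    dp = p.deriv()
    lo, hi = curve.strain.min(), curve.strain.max()
    moduli, flags = {}, {}
    for eps in strain_points:
        inside = lo <= eps <= hi
        moduli[eps] = float(dp(eps)) if inside else float("nan")
        flags[eps] = "ok" if inside else "outside_data_range"
    return {"moduli_mpa": moduli, "flags": flags, "order": used_order,
            "r2_adj": r2_adj, "polynomial": p}


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, SSE, R^2 of an ordinary least-squares line."""
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sse = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0
    return float(coef[0]), float(coef[1]), sse, r2


def bilinear_loglog(curve: StressStrainCurve, min_segment: int = 4,
                    slope_tol: float = 1e-2) -> BilinearFit:
    """Toe-region transition by exhaustive bilinear log-log regression.

    Every interior breakpoint leaving at least ``min_segment`` samples per
    segment is tried; the two lines are fitted independently and the split
    with minimal total SSE wins. The transition strain is the abscissa of
    the two lines' intersection mapped back from log space. Slopes within
    ``slope_tol`` of each other flag the fit as degenerate (a single power
    law fits the whole record).
    """
    mask = (curve.strain > 0) & (curve.stress_mpa > 0)
    x = np.log(curve.strain[mask])
    y = np.log(curve.stress_mpa[mask])
    n = len(x)
    if n < 2 * min_segment:
        raise ValueError(f"need at least {2 * min_segment} positive samples, got {n}")

    best = None
    for k in range(min_segment, n - min_segment + 1):
        g1, b1, sse1, r21 = _ols_line(x[:k], y[:k])
        g2, b2, sse2, r22 = _ols_line(x[k:], y[k:])
        sse = sse1 + sse2
        if best is None or sse < best[0]:
            best = (sse, k, g1, b1, r21, g2, b2, r22)
    sse, k, g1, b1, r21, g2, b2, r22 = best

    degenerate = abs(g2 - g1) < slope_tol
    if degenerate:
        transition = float("nan")
        out_of_range = True
    else:
        log_t = (b1 - b2) / (g2 - g1)
        transition = float(np.exp(log_t))
        out_of_range = not (curve.strain[mask].min() <= transition
                            <= curve.strain[mask].max())
    return BilinearFit(transition, g1, g2, b1, b2, r21, r22, sse, k,
                       degenerate=degenerate, out_of_range=out_of_range)
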