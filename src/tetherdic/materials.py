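"""Hyperelastic representation of tissue stress-strain behavior.

Incompressible reduced-polynomial strain energy
``W = sum_i C_i0 (I1bar - 3)^i`` fitted to uniaxial engineering
stress-strain data, plus the 5% pre-stretch translation used to model
baseline optic-nerve/sheath tension at the adduction tethering threshold,
and construction of a lamina-cribrosa curve as the pointwise average of
the optic-nerve and peripapillary-sclera curves.

For incompressible uniaxial extension with stretch lambda = 1 + eps the
nominal (engineering) stress is

    P(lambda) = 2 (lambda - lambda^-2) * sum_i i C_i0 (I1bar - 3)^(i-1),

with I1bar = lambda^2 + 2/lambda. P is linear in the coefficients, so the
fit is an ordinary least-squares problem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .tensile import StressStrainCurve

DEFAULT_ORDERS = {"anterior": 2, "equatorial": 2, "posterior": 2,
                  "peripapillary": 2, "ON": 1, "ON_sheath": 1,
                  "lamina_cribrosa": 1}


@dataclass
class ReducedPolynomialModel:
    """Reduced-polynomial hyperelastic model of order N (1..3).

    ``coefficients[i]`` is C_(i+1)0 in MPa. The Poisson ratio (0.495,
    near-incompressible) is carried as metadata for downstream FEM use;
    the uniaxial response itself assumes full incompressibility.
    """

    order: int
    coefficients: np.ndarray
    region_label: str = ""
    poisson: float = 0.495
    r2: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not 1 <= self.order <= 3:
            raise ValueError("order must be 1..3")
        if len(self.coefficients) != self.order:
            raise ValueError("need one C_i0 per order")

    @property
    def c10(self) -> float:
        return float(self.coefficients[0])

    @property
    def small_strain_modulus(self) -> float:
        """E = 3*mu with mu = 2*C_10 (incompressible small-strain limit)."""
        return 6.0 * self.c10

    def to_json(self) -> str:
        return json.dumps({"region": self.region_label, "order": self.order,
                           "C_i0_mpa": self.coefficients.tolist(),
                           "poisson": self.poisson, "r2": self.r2})

    @classmethod
    def from_json(cls, s: str) -> "ReducedPolynomialModel":
        d = json.loads(s)
        m = cls(d["order"], np.array(d["C_i0_mpa"]), d.get("region", ""),
                d.get("poisson", 0.495))
        m.r2 = d.get("r2", float("nan"))
        return m


def _stress_basis(strain: np.ndarray, order: int) -> np.ndarray:
    """Design matrix: column i is dP/dC_(i+1)0 at each strain."""
    lam = 1.0 + np.asarray(strain, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("strain must exceed -1")
    i1 = lam ** 2 + 2.0 / lam
    kin = 2.0 * (lam - lam ** -2)
    cols = [kin * (i + 1) * (i1 - 3.0) ** i for i in range(order)]
    return np.column_stack(cols)


def uniaxial_nominal_stress(model: ReducedPolynomialModel, strain) -> np.ndarray:
    """Nominal uniaxial stress (MPa) at engineering strain(s)."""
    strain = np.asarray(strain, dtype=float)
    out = _stress_basis(np.atleast_1d(strain), model.order) @ model.coefficients
    return out if strain.ndim else float(out[0])


def fit_reduced_polynomial(curve: StressStrainCurve, order: int = 2) -> ReducedPolynomialModel:
    """Least-squares reduced-polynomial fit to uniaxial data.

    Deterministic linear solve; raises if the leading coefficient C_10
    comes out non-positive (non-physical shear modulus).
    """
    if not 1 <= order <= 3:
        raise ValueError("order must be 1..3")
    A = _stress_basis(curve.strain, order)
    coef, *_ = np.linalg.lstsq(A, curve.stress_mpa, rcond=None)
    resid = curve.stress_mpa - A @ coef
    ss_tot = float(np.sum((curve.stress_mpa - curve.stress_mpa.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    if coef[0] <= 0:
        raise ValueError(f"fit failed: C_10 = {coef[0]:.4g} MPa <= 0 "
                         f"(r2 = {r2:.3f}); data may not be strain-stiffening")
    model = ReducedPolynomialModel(order, coef, curve.region_label)
    model.r2 = r2
    return model


@dataclass
class PrestretchSpec:
    """Strain-axis translation emulating baseline tension (default 5%)."""

    shift: float = 0.05

    def __post_init__(self) -> None:
        if self.shift < 0:
            raise ValueError("shift must be non-negative")


def apply_prestretch(curve: StressStrainCurve,
                     spec: PrestretchSpec | float = PrestretchSpec()) -> StressStrainCurve:
    """Translate the curve along the strain axis by ``spec.shift``.

    Stresses are unchanged: the tissue at nominal zero strain then already
    carries the stress formerly reached at the shift strain.
    """
    if not isinstance(spec, PrestretchSpec):
        spec = PrestretchSpec(float(spec))
    return StressStrainCurve(curve.strain + spec.shift, curve.stress_mpa.copy(),
                             curve.region_label, curve.rupture_index,
                             dict(curve.meta, prestretch=spec.shift))


def lamina_curve(on: StressStrainCurve, pps: StressStrainCurve,
                 n_grid: int = 200) -> StressStrainCurve:
    """Lamina-cribrosa curve: pointwise stress average of ON and PPS.

    Both curves are linearly interpolated onto a uniform grid spanning the
    intersection of their strain ranges.
    """
    lo = max(on.strain.min(), pps.strain.min())
    hi = min(on.strain.max(), pps.strain.max())
    if hi <= lo:
        raise ValueError("strain ranges do not overlap")
    grid = np.linspace(lo, hi, n_grid)
    s_on = np.interp(grid, on.strain, on.stress_mpa)
    s_pps = np.interp(grid, pps.strain, pps.stress_mpa)
    return StressStrainCurve(grid, 0.5 * (s_on + s_pps), "lamina_cribrosa")
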