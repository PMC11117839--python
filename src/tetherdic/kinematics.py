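"""Adduction-tethering kinematics of the globe and optic nerve.

Geometry is expressed in a right-handed globe-centered frame: for a right
eye, nasal = +x, superior = +y, anterior = +z (left eyes are handled by
mirroring x). Adduction is a rotation about the superior (+y) axis that
carries the cornea nasally. The optic-nerve (ON) junction sits on the
posterior globe, offset from the posterior pole by the fovea-disc angle;
the orbital apex (or, on the bench, the virtual apex realised by the ON
gripper) lies posterior-nasally.

Angles are degrees at every public interface and radians internally;
lengths are mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEG = np.pi / 180.0


@dataclass
class GlobeTetherGeometry:
    """Per-specimen globe/ON geometry.

    ``r`` globe radius; ``R`` globe-center-to-gripper distance; ``chi``
    offset angle between the ON junction and the gripper; ``phi`` azimuth
    of the ON junction. Defaults for the virtual orbital apex follow
    average orbital dimensions: apex 41 mm from the globe center, 22 deg
    off the sagittal plane, with a 17 deg fovea-disc angle.
    """

    r: float = 12.0
    R: float = 41.0
    chi: float = 10.0
    phi: float = 0.0
    apex_distance: float = 41.0
    apex_angle: float = 22.0
    fovea_disc_angle: float = 17.0
    on_length_mm: float = float("nan")
    sinuosity: float = 0.03

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("globe radius must be positive")
        if self.R <= self.r:
            raise ValueError("gripper distance R must exceed globe radius r")

    @property
    def junction(self) -> np.ndarray:
        """ON junction position: posterior pole rotated nasally by the fovea-disc angle."""
        a = self.fovea_disc_angle * DEG
        return self.r * np.array([np.sin(a), 0.0, -np.cos(a)])

    @property
    def apex(self) -> np.ndarray:
        """Virtual orbital apex position."""
        a = self.apex_angle * DEG
        return self.apex_distance * np.array([np.sin(a), 0.0, -np.cos(a)])

    @classmethod
    def from_specimen(cls, transverse_diameter_mm: float, on_length_mm: float,
                      **kw) -> "GlobeTetherGeometry":
        g = cls(r=transverse_diameter_mm / 2.0, on_length_mm=on_length_mm, **kw)
        return g


@dataclass
class AdductionScenario:
    """Loading protocol: incremental adduction and IOP steps."""

    start_angle: float = 26.0
    end_angle: float = 32.0
    iop_reference: float = 15.0
    iop_elevated: float = 30.0

    def __post_init__(self) -> None:
        if self.end_angle <= self.start_angle:
            raise ValueError("end_angle must exceed start_angle")


def on_length(g: GlobeTetherGeometry, extra_angle: float = 0.0) -> float:
    """Straight ON length by the law of cosines.

    sqrt(r^2 + R^2 - 2 r R cos(chi + extra_angle)), where ``extra_angle``
    is either the eye rotation theta or the gripper arc travel psi (deg).
    """
    ang = g.chi + extra_angle
    if not 0.0 <= ang < 180.0:
        raise ValueError(f"chi + angle = {ang} deg outside [0, 180)")
    return float(np.sqrt(g.r ** 2 + g.R ** 2
                         - 2.0 * g.r * g.R * np.cos(ang * DEG)))


def _rot_y(angle_deg: float) -> np.ndarray:
    c, s = np.cos(angle_deg * DEG), np.sin(angle_deg * DEG)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot2(angle_deg: float) -> np.ndarray:
    c, s = np.cos(angle_deg * DEG), np.sin(angle_deg * DEG)
    return np.array([[c, -s], [s, c]])


def equivalence_check(g: GlobeTetherGeometry, theta: float, psi: float,
                      tol: float = 1e-12) -> tuple[bool, float, float, float]:
    """Compare rotating the eye by theta with moving the gripper by psi.

    Both configurations are built explicitly in the plane containing the
    globe center, junction, and gripper (not via the closed form): the eye
    rotation carries the junction away from the gripper; the gripper
    rotation carries the gripper away from the junction. Returns
    (equivalent within tol, |L_eye - L_gripper|, L_eye, L_gripper).
    """
    junction = np.array([g.r, 0.0])
    gripper = g.R * np.array([np.cos(g.chi * DEG), np.sin(g.chi * DEG)])
    j_rot = _rot2(-theta) @ junction           # eye rotation: junction recedes
    l_eye = float(np.linalg.norm(gripper - j_rot))
    grip_rot = _rot2(psi) @ gripper            # gripper travels along its arc
    l_grip = float(np.linalg.norm(grip_rot - junction))
    diff = abs(l_eye - l_grip)
    return diff < tol, diff, l_eye, l_grip


def place_virtual_apex(g: GlobeTetherGeometry, measured_on_length: float) -> np.ndarray:
    """Initial gripper tip on the junction->apex line at the measured ON length.

    Raises if the ON is longer than the junction-apex distance (the nerve
    would be slack and the straight-line placement invalid).
    """
    j, a = g.junction, g.apex
    d = float(np.linalg.norm(a - j))
    if measured_on_length > d:
        raise ValueError(f"ON length {measured_on_length:.2f} mm exceeds "
                         f"junction-apex distance {d:.2f} mm: slack nerve")
    if measured_on_length == 0:
        warnings.warn("zero ON length: gripper placed at the junction")
    return j + (measured_on_length / d) * (a - j)


def apex_junction_distance(g: GlobeTetherGeometry, adduction_deg: float) -> float:
    """Distance from the (fixed) orbital apex to the junction rotated by adduction."""
    return float(np.linalg.norm(g.apex - _rot_y(adduction_deg) @ g.junction))


def extension_proportion(g: GlobeTetherGeometry,
                         scenario: AdductionScenario = AdductionScenario()) -> float:
    """Fractional increase of the apex-junction distance over the scenario.

    (d(end) - d(start)) / d(start) with the eye rotating about its center
    and the apex fixed; the actual ON is stretched by this proportion
    because it is straight under tethering.
    """
    d0 = apex_junction_distance(g, scenario.start_angle)
    d1 = apex_junction_distance(g, scenario.end_angle)
    return (d1 - d0) / d0


def strain_from_elongation(elongation_pct: float, sinuosity_pct: float,
                           convention: str = "chord") -> float:
    """ON strain (percent) from path elongation after spending sinuosity slack.

    The default chord-referenced convention subtracts percentages directly
    (e.g. 6.6% elongation with 3% sinuosity gives 3.6% strain), floored at
    zero. ``convention="ratio"`` instead references strain to the slack
    length: 100*((1+e/100)/(1+s/100) - 1).
    """
    if elongation_pct < 0 or sinuosity_pct < 0:
        raise ValueError("elongation and sinuosity must be non-negative")
    if convention == "chord":
        return max(elongation_pct - sinuosity_pct, 0.0)
    if convention == "ratio":
        return max(100.0 * ((1.0 + elongation_pct / 100.0)
                            / (1.0 + sinuosity_pct / 100.0) - 1.0), 0.0)
    raise ValueError(f"unknown convention {convention!r}")
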