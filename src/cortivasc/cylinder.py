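"""Infinite-cylinder susceptibility field model.

Large veins are modelled as infinitely long cylinders filled with
paramagnetic (deoxygenated) blood inside diamagnetic tissue.  The static
field perturbation they create has the classical closed form: outside the
cylinder the angular frequency offset is

    dw_extra = k * (dchi * w0) * (R/r)**2 * cos(2*phi) * sin(nu)**2

and inside (intravascular)

    dw_intra = k * (dchi * w0) * (3*cos(nu)**2 - 1)

where ``nu`` is the tilt of the cylinder axis against B0, ``R`` the cylinder
radius, ``r`` the perpendicular distance of the observation point from the
axis (valid for r >= R), and ``phi`` the polar angle of the observation
point in the plane perpendicular to the axis.  The susceptibility
difference ``dchi`` and the Larmor frequency ``w0`` enter only as a
product, kept here as a single configurable scale; the dimensionless
prefactor ``k`` is a convention (1/2 in the standard derivation) and all
downstream statistics of this package are ratios that cancel it.

For a pial vein hugging the cortical surface the tilt relates to the
cortical orientation angle as ``nu = 90 deg - theta_b0``, so the
extravascular fluctuation amplitude follows cos^2(theta_b0) — the law the
phantom's GRE-like contrast injects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CylinderGeometry",
    "FieldObservation",
    "SusceptibilityScale",
    "extravascular_offset",
    "intravascular_offset",
    "orientation_amplitude",
    "fold_tilt",
    "tilt_from_axis",
]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class CylinderGeometry:
    """An infinite cylinder: radius (mm), unit axis vector, a point on the axis."""

    radius_mm: float
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError(f"cylinder radius must be positive, got {self.radius_mm}")
        norm = float(np.linalg.norm(self.axis))
        if abs(norm - 1.0) > _UNIT_TOL:
            raise ValueError(f"axis must be a unit vector (|axis| = {norm})")


@dataclass(frozen=True)
class FieldObservation:
    """Observation point in cylinder coordinates.

    distance_mm: perpendicular distance r from the axis.
    polar_angle_rad: phi in the plane perpendicular to the axis.
    tilt_rad: nu, angle between the axis and B0 (folded to [0, pi/2]).
    """

    distance_mm: float
    polar_angle_rad: float
    tilt_rad: float


@dataclass(frozen=True)
class SusceptibilityScale:
    """The product dchi*w0 (rad/s) and the dimensionless convention factor k."""

    delta_chi_omega0: float = 1.0
    geometry_constant_k: float = 0.5

    def __post_init__(self) -> None:
        if self.delta_chi_omega0 < 0:
            raise ValueError("delta_chi_omega0 must be non-negative")


def fold_tilt(nu_rad):
    """Fold a tilt angle into [0, pi/2]; both offsets are even in cos^2."""
    return np.arccos(np.abs(np.cos(nu_rad)))


def tilt_from_axis(axis, b0_axis) -> float:
    """Tilt nu (radians, in [0, pi/2]) between a cylinder axis and B0."""
    a = np.asarray(axis, dtype=float)
    b = np.asarray(b0_axis, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector has no direction")
    c = np.clip(abs(float(a @ b) / (na * nb)), 0.0, 1.0)
    return float(np.arccos(c))


def extravascular_offset(
    scale: SusceptibilityScale,
    geom: CylinderGeometry,
    obs: FieldObservation | None = None,
    *,
    distance_mm=None,
    polar_angle_rad=None,
    tilt_rad=None,
):
    """Extravascular angular frequency offset (rad/s) at an observation point.

    Accepts either a :class:`FieldObservation` or array-valued keyword
    coordinates for vectorised evaluation.  Raises for points inside the
    cylinder, where the extravascular formula does not apply.
    """
    if obs is not None:
        distance_mm = obs.distance_mm
        polar_angle_rad = obs.polar_angle_rad
        tilt_rad = obs.tilt_rad
    r = np.asarray(distance_mm, dtype=float)
    phi = np.asarray(polar_angle_rad, dtype=float)
    nu = fold_tilt(np.asarray(tilt_rad, dtype=float))
    if np.any(r < geom.radius_mm):
        raise ValueError(
            f"extravascular field requested at r < R ({float(np.min(r)):g} mm "
            f"< {geom.radius_mm:g} mm); formula is only valid outside the cylinder"
        )
    out = (
        scale.geometry_constant_k
        * scale.delta_chi_omega0
        * (geom.radius_mm / r) ** 2
        * np.cos(2.0 * phi)
        * np.sin(nu) ** 2
    )
    return out if out.ndim else float(out)


def intravascular_offset(scale: SusceptibilityScale, tilt_rad):
    """Intravascular angular frequency offset (rad/s); independent of r and phi.

    Vanishes at the magic angle nu = arccos(1/sqrt(3)) ~ 54.74 deg.
    """
    nu = fold_tilt(np.asarray(tilt_rad, dtype=float))
    out = scale.geometry_constant_k * scale.delta_chi_omega0 * (3.0 * np.cos(nu) ** 2 - 1.0)
    return out if out.ndim else float(out)


def orientation_amplitude(theta_b0_deg):
    """Unit-free fluctuation gain cos^2(theta_b0) for a pial vein.

    With the vein tangent to the cortical surface, nu = 90 deg - theta_b0,
    so the extravascular sin^2(nu) envelope equals cos^2(theta_b0):
    maximal (1) where the surface normal is parallel to B0 and zero where
    it is perpendicular.
    """
    theta = np.asarray(theta_b0_deg, dtype=float)
    if np.any((theta < 0) | (theta > 90)):
        raise ValueError("theta_b0 must lie in [0, 90] degrees")
    out = np.cos(np.deg2rad(theta)) ** 2
    return out if out.ndim else float(out)
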