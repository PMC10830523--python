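"""Analytic hydrodynamics of a rectangular microchannel with a slightly sagging lid.

The microfluidic shear assay calibrates the drag force on a wall-attached
spherical particle from the volumetric flow rate.  The laminar velocity
profile in a rectangular duct is the classic odd-harmonic Fourier series;
two dimensionless corrections enter the force:

* ``C1`` accounts for the parabolic sag of the channel lid, which raises the
  center velocity at fixed flow rate.  It is the ratio of pressure drops of
  the sagging and the nominal rectangular channel and reduces to
  ``(h0 / h_eff)**3`` in the wide-channel limit.
* ``C2`` accounts for the wall-modified flow around the particle itself.  It
  was obtained once from resolved lattice-Boltzmann simulations and is
  adopted here as the constant 1.618.

All quantities are SI internally (m, s, Pa·s, m^3/s, N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "C2_DEFAULT",
    "ChannelGeometry",
    "FluidProperties",
    "ForceCalibration",
    "SimUnitScaling",
    "pressure_drop_rect",
    "velocity_profile_rect",
    "velocity_profile_2d",
    "velocity_profile_parabolic",
    "effective_height",
    "correction_c1",
    "correction_c1_from_heights",
    "drag_force",
    "flow_rate_for_force",
    "motor_velocity",
    "to_sim_units",
    "nu_sim_for_flow",
    "cross_section_flow",
]

#: Wall/finite-size drag correction from the resolved-particle flow study.
C2_DEFAULT = 1.618

# Series truncation: sum odd n until the last term's relative contribution is
# below SERIES_RTOL, hard cap at N_MAX.  Hyperbolic arguments beyond
# OVERFLOW_ARG use their asymptotic limits (tanh -> 1, cosh ratio -> exp).
SERIES_RTOL = 1e-12
N_MAX = 9999
OVERFLOW_ARG = 700.0


class GeometryError(ValueError):
    """Invalid channel geometry or a point outside the channel."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular channel with an optional parabolic lid, h(y) = h0 + a*y + b*y^2.

    Parameters
    ----------
    length, width, h0 : float
        Channel length, width and center height in meters.
    alpha : float
        Linear lid-slope coefficient (dimensionless).
    beta : float
        Lid curvature coefficient (1/m).  Negative values describe a lid
        that sags toward the side walls.
    """

    length: float
    width: float
    h0: float
    alpha: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0 or self.h0 <= 0:
            raise GeometryError("channel dimensions must be positive")
        y = np.linspace(-self.width / 2, self.width / 2, 201)
        if np.any(self.height(y) <= 0):
            raise GeometryError("channel height must stay positive across the width")

    def height(self, y):
        """Local channel height h(y) in meters."""
        return self.h0 + self.alpha * y + self.beta * y**2

    @property
    def is_rectangular(self) -> bool:
        return self.alpha == 0.0 and self.beta == 0.0


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: density (kg/m^3), dynamic viscosity (Pa s)."""

    rho: float
    eta: float
    temperature_c: float | None = None

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.eta <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity (m^2/s)."""
        return self.eta / self.rho


@dataclass(frozen=True)
class SimUnitScaling:
    """SI <-> lattice-unit velocity conversion, fixed by matching particle radius
    and kinematic viscosity between the two unit systems."""

    r_sim: float
    nu_sim: float
    r_si: float
    nu_si: float

    def __post_init__(self) -> None:
        if min(self.r_sim, self.nu_sim, self.r_si, self.nu_si) <= 0:
            raise ValueError("all scaling fields must be positive")

    @property
    def lattice_spacing(self) -> float:
        """Physical size of one lattice unit (m)."""
        return self.r_si / self.r_sim

    @property
    def velocity_factor(self) -> float:
        """Multiply an SI velocity by this to obtain lattice units."""
        return (self.nu_sim * self.r_si) / (self.nu_si * self.r_sim)


@dataclass
class ForceCalibration:
    """Calibration record tying a target drag force to a flow rate and motor speed."""

    r: float
    c1: float = 1.0
    c2: float = C2_DEFAULT
    force: float = 0.0
    flow_rate: float = 0.0
    r_piston: float = 0.0
    v_motor: float = 0.0
    extras: dict = field(default_factory=dict)


def _require_rect(geom: ChannelGeometry) -> None:
    if not geom.is_rectangular:
        raise GeometryError("this profile requires a rectangular channel (alpha = beta = 0)")


def _bracket(w: float, h: float) -> float:
    """Finite-width bracket of the duct pressure-flow relation:
    1 - sum_{n odd} 192 h / (n^5 pi^5 w) * tanh(n pi w / 2h)."""
    total = 0.0
    pref = 192.0 * h / (math.pi**5 * w)
    for n in range(1, N_MAX + 1, 2):
        arg = n * math.pi * w / (2.0 * h)
        t = 1.0 if arg > OVERFLOW_ARG else math.tanh(arg)
        term = pref * t / n**5
        total += term
        if term < SERIES_RTOL * total:
            break
    return 1.0 - total


def pressure_drop_rect(flow_rate: float, geom: ChannelGeometry, fluid: FluidProperties) -> float:
    """Pressure drop (Pa) along a rectangular channel at volumetric flow rate Q (m^3/s)."""
    _require_rect(geom)
    if flow_rate < 0:
        raise ValueError("flow rate must be non-negative")
    return _pressure_drop_wh(flow_rate, geom.width, geom.h0, geom.length, fluid.eta)


def _pressure_drop_wh(q: float, w: float, h: float, length: float, eta: float) -> float:
    return 12.0 * eta * length * q / (w * h**3) / _bracket(w, h)


def _cosh_ratio(a: float, b: float) -> float:
    """cosh(a)/cosh(b) for 0 <= a <= b, safe against overflow."""
    if b <= OVERFLOW_ARG:
        return math.cosh(a) / math.cosh(b)
    # cosh(x) = exp(x) (1 + exp(-2x)) / 2 for large x
    if a > OVERFLOW_ARG:
        return math.exp(a - b)
    return 2.0 * math.cosh(a) * math.exp(-b)


def _series_profile(y: float, z: float, w: float, h: float, dp: float,
                    length: float, eta: float) -> float:
    if not (-w / 2 <= y <= w / 2) or not (0 <= z <= h):
        raise GeometryError("point outside the channel cross-section")
    pref = 4.0 * h**2 * dp / (math.pi**3 * eta * length)
    total = 0.0
    ay = abs(y)
    for n in range(1, N_MAX + 1, 2):
        ratio = _cosh_ratio(n * math.pi * ay / h, n * math.pi * w / (2.0 * h))
        term = (1.0 - ratio) * math.sin(n * math.pi * z / h) / n**3
        total += term
        if abs(term) < SERIES_RTOL * abs(total) and total != 0.0:
            break
    return pref * total


def velocity_profile_rect(y: float, z: float, flow_rate: float,
                          geom: ChannelGeometry, fluid: FluidProperties) -> float:
    """Axial velocity (m/s) of the rectangular-duct series profile at (y, z)."""
    _require_rect(geom)
    dp = pressure_drop_rect(flow_rate, geom, fluid)
    return _series_profile(y, z, geom.width, geom.h0, dp, geom.length, fluid.eta)


def velocity_profile_2d(z: float, flow_rate: float, geom: ChannelGeometry,
                        fluid: FluidProperties) -> float:
    """Infinite-width (2D) Poiseuille approximation v(z) = 6 Q z (h - z) / (w h^3)."""
    h = geom.h0
    if not (0 <= z <= h):
        raise GeometryError("z outside the channel height")
    return 6.0 * flow_rate * z * (h - z) / (geom.width * h**3)


def effective_height(geom: ChannelGeometry) -> float:
    """Cubic-mean height of the sagging channel, h_eff = ((1/w) int h(y)^3 dy)^(1/3).

    Closed form of the width-averaged cube of h(y) = h0 + a y + b y^2.
    """
    h0, a, b, w = geom.h0, geom.alpha, geom.beta, geom.width
    mean_cube = (
        h0**3
        + 0.25 * h0**2 * b * w**2
        + 0.25 * h0 * a**2 * w**2
        + 3.0 / 80.0 * h0 * b**2 * w**4
        + 3.0 / 80.0 * a**2 * b * w**4
        + 1.0 / 448.0 * b**3 * w**6
    )
    return mean_cube ** (1.0 / 3.0)


def correction_c1_from_heights(h0: float, h_eff: float) -> float:
    """Lid-sag force correction in the wide-channel limit, C1 = h0^3 / h_eff^3."""
    if h0 <= 0 or h_eff <= 0:
        raise GeometryError("heights must be positive")
    return (h0 / h_eff) ** 3


def correction_c1(geom: ChannelGeometry, *, exact: bool = False,
                  fluid: FluidProperties | None = None) -> float:
    """Force correction for the parabolic lid.

    By default uses the wide-channel closed form ``(h0 / h_eff)**3``, which is
    what the calibration applied in practice.  With ``exact=True`` the full
    pressure-drop ratio of the series relation is evaluated instead (the flow
    rate cancels, so the fluid drops out as well; a unit fluid is used).
    """
    h_eff = effective_height(geom)
    if not exact:
        return correction_c1_from_heights(geom.h0, h_eff)
    eta, length, q = 1.0, 1.0, 1.0
    dp_par = _pressure_drop_wh(q, geom.width, h_eff, length, eta)
    dp_rect = _pressure_drop_wh(q, geom.width, geom.h0, length, eta)
    return dp_par / dp_rect


def velocity_profile_parabolic(y: float, z: float, flow_rate: float,
                               geom: ChannelGeometry, fluid: FluidProperties) -> float:
    """Series profile of the sagging channel: local height h(y), pressure drop from h_eff.

    Reduces exactly to :func:`velocity_profile_rect` when alpha = beta = 0.
    """
    if not (-geom.width / 2 <= y <= geom.width / 2):
        raise GeometryError("y outside the channel width")
    h_local = float(geom.height(y))
    if not (0 <= z <= h_local):
        raise GeometryError("z outside the local channel height")
    h_eff = effective_height(geom)
    dp_par = _pressure_drop_wh(flow_rate, geom.width, h_eff, geom.length, fluid.eta)
    return _series_profile(y, z, geom.width, h_local, dp_par, geom.length, fluid.eta)


def drag_force(flow_rate: float, geom: ChannelGeometry, fluid: FluidProperties,
               r: float, c1: float = 1.0, c2: float = C2_DEFAULT) -> float:
    """Calibrated drag force (N) on a wall-attached sphere of radius r:

    F = 36 C1 C2 pi eta Q r^2 (h0 - r) / (w h0^3)

    Stokes drag evaluated at the sphere-center height of the 2D profile, with
    the lid-sag (C1) and wall (C2) corrections.  Exactly linear in Q.
    """
    h = geom.h0
    if not (0 < r < h / 2):
        raise GeometryError("particle radius must satisfy 0 < r < h0/2")
    return 36.0 * c1 * c2 * math.pi * fluid.eta * flow_rate * r**2 * (h - r) / (geom.width * h**3)


def flow_rate_for_force(force_target: float, geom: ChannelGeometry, fluid: FluidProperties,
                        r: float, c1: float = 1.0, c2: float = C2_DEFAULT) -> float:
    """Flow rate (m^3/s) producing a given drag force; closed-form inversion of the
    linear F(Q) relation."""
    if force_target < 0:
        raise ValueError("target force must be non-negative")
    unit_force = drag_force(1.0, geom, fluid, r, c1, c2)
    return force_target / unit_force


def motor_velocity(flow_rate: float, r_piston: float) -> float:
    """Syringe-pump motor velocity v_m = Q / (pi r_piston^2)."""
    if r_piston <= 0:
        raise ValueError("piston radius must be positive")
    return flow_rate / (math.pi * r_piston**2)


def to_sim_units(v_si: float, scaling: SimUnitScaling) -> float:
    """Convert an SI velocity to lattice units: v_sim = (nu_sim r_SI)/(nu_SI r_sim) v_SI."""
    return scaling.velocity_factor * v_si


def nu_sim_for_flow(flow_rate: float, *, flow_rate_ref: float, nu_sim_ref: float = 1.0) -> float:
    """Lattice kinematic viscosity keeping the lattice velocity fixed across flow rates.

    The SI velocity is linear in Q, so holding v_sim constant requires
    nu_sim proportional to 1/Q: nu_sim = nu_sim_ref * Q_ref / Q.
    """
    if flow_rate <= 0 or flow_rate_ref <= 0:
        raise ValueError("flow rates must be positive")
    return nu_sim_ref * flow_rate_ref / flow_rate


def cross_section_flow(geom: ChannelGeometry, fluid: FluidProperties, flow_rate: float,
                       n_y: int = 96, n_z: int = 64, n_terms: int = 1201) -> float:
    """Numerically integrate the rectangular series profile over the cross-section.

    Gauss-Legendre in both directions with a vectorized series evaluation;
    used to validate that the profile reproduces the imposed flow rate.
    """
    _require_rect(geom)
    w, h = geom.width, geom.h0
    dp = pressure_drop_rect(flow_rate, geom, fluid)
    ys, wy = np.polynomial.legendre.leggauss(n_y)
    zs, wz = np.polynomial.legendre.leggauss(n_z)
    ys = 0.5 * w * ys  # map [-1, 1] -> [-w/2, w/2]
    zs = 0.5 * h * (zs + 1.0)
    ns = np.arange(1, n_terms + 1, 2, dtype=float)
    arg_y = ns[:, None] * math.pi * np.abs(ys)[None, :] / h
    arg_w = ns * math.pi * w / (2.0 * h)
    # cosh(a)/cosh(b) = exp(a-b) (1 + e^-2a) / (1 + e^-2b): no overflow, a <= b
    ratio = np.exp(arg_y - arg_w[:, None]) * (1.0 + np.exp(-2 * arg_y)) \
        / (1.0 + np.exp(-2 * arg_w[:, None]))
    sin_z = np.sin(ns[:, None] * math.pi * zs[None, :] / h)
    profile = np.einsum("n,ny,nz->yz", 1.0 / ns**3, 1.0 - ratio, sin_z)
    profile *= 4.0 * h**2 * dp / (math.pi**3 * fluid.eta * geom.length)
    total = wy @ profile @ wz
    return float(total * 0.25 * w * h)
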