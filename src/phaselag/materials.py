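"""Nanoprobe geometry, materials, and derived magnetic/hydrodynamic quantities.

The probes modelled here are flat elliptical multilayer cylinders (plasmonic
Au faces, TiO₂ spacers, one soft-magnetic NiFe layer) released into a fluid.
Their rotational response is governed by three derived quantities:

* the magnetic moment ``m = M_s · V_mag`` of the thin NiFe layer,
* the shape-anisotropy field ``H_K`` that pins the magnetization to the
  long axis, and
* the hydrodynamic volume ``V_hydro`` that sets the rotational drag
  (enlarged relative to the geometric volume by surface coatings and, in an
  assay, by bound analyte).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Literal, Sequence

from scipy.special import elliprd

from .constants import MU_0, volumetric_magnetization

__all__ = [
    "Environment",
    "MagneticMaterial",
    "LayerRole",
    "Layer",
    "LayerStack",
    "Nanoprobe",
    "default_five_layer_stack",
    "demag_factors_ellipsoid",
    "demag_difference_ellipsoid",
    "anisotropy_constant",
    "anisotropy_field",
    "hydrodynamic_volume",
    "magnetic_moment",
]

logger = logging.getLogger(__name__)

# Permalloy density; configurable per material, this is the package default.
NIFE_DENSITY_G_CM3 = 8.7
ROOM_TEMPERATURE_K = 293.15


@dataclass(frozen=True)
class Environment:
    """Fluid environment of the rotating probe.

    Attributes
    ----------
    viscosity_Pa_s : dynamic viscosity η in Pa·s (water ≈ 1e-3).
    temperature_K : absolute temperature in K.
    """

    viscosity_Pa_s: float = 1.0e-3
    temperature_K: float = ROOM_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.viscosity_Pa_s <= 0:
            raise ValueError(f"viscosity must be > 0, got {self.viscosity_Pa_s}")
        if self.temperature_K <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature_K}")


@dataclass(frozen=True)
class MagneticMaterial:
    """Soft-magnetic layer material.

    ``M_s`` is derived from the specific saturation moment (emu/g) and the
    mass density; 88 emu/g with ρ = 8.7 g/cm³ gives the permalloy default
    M_s ≈ 7.66e5 A/m.
    """

    name: str = "NiFe"
    sigma_s_emu_g: float = 88.0
    density_g_cm3: float = NIFE_DENSITY_G_CM3

    def __post_init__(self) -> None:
        if self.sigma_s_emu_g < 0:
            raise ValueError("sigma_s must be >= 0")
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be > 0")

    @property
    def M_s_A_m(self) -> float:
        """Volumetric saturation magnetization in A/m."""
        return volumetric_magnetization(self.sigma_s_emu_g, self.density_g_cm3)


class LayerRole(str, Enum):
    PLASMONIC = "plasmonic"
    MAGNETIC = "magnetic"
    DIELECTRIC = "dielectric"
    SACRIFICIAL = "sacrificial"


@dataclass(frozen=True)
class Layer:
    role: LayerRole
    material: str
    thickness_nm: float

    def __post_init__(self) -> None:
        if self.thickness_nm <= 0:
            raise ValueError(
                f"layer thickness must be > 0, got {self.thickness_nm} nm "
                f"({self.material})"
            )


@dataclass(frozen=True)
class LayerStack:
    """Ordered stack of deposited layers, bottom to top."""

    layers: tuple[Layer, ...]

    def __post_init__(self) -> None:
        n_mag = sum(1 for l in self.layers if l.role is LayerRole.MAGNETIC)
        if n_mag != 1:
            raise ValueError(f"stack must contain exactly one magnetic layer, found {n_mag}")

    @property
    def total_thickness_nm(self) -> float:
        return sum(l.thickness_nm for l in self.layers)

    @property
    def magnetic_thickness_nm(self) -> float:
        return next(l.thickness_nm for l in self.layers if l.role is LayerRole.MAGNETIC)


def default_five_layer_stack(
    nife_nm: float = 7.0, total_nm: float = 60.0, spacer_nm: float = 10.0
) -> LayerStack:
    """Au / TiO₂ / NiFe / TiO₂ / Au stack with symmetric gold faces.

    The two Au faces absorb whatever thickness remains after the NiFe layer
    and the two TiO₂ oxidation-barrier spacers.
    """
    au_nm = (total_nm - nife_nm - 2 * spacer_nm) / 2
    if au_nm <= 0:
        raise ValueError("total thickness too small for the requested inner layers")
    return LayerStack(
        layers=(
            Layer(LayerRole.PLASMONIC, "Au", au_nm),
            Layer(LayerRole.DIELECTRIC, "TiO2", spacer_nm),
            Layer(LayerRole.MAGNETIC, "NiFe", nife_nm),
            Layer(LayerRole.DIELECTRIC, "TiO2", spacer_nm),
            Layer(LayerRole.PLASMONIC, "Au", au_nm),
        )
    )


def demag_factors_ellipsoid(a: float, b: float, c: float) -> tuple[float, float, float]:
    """Demagnetizing factors (N_a, N_b, N_c) of a general ellipsoid.

    Semi-axes ``a, b, c`` in any common unit.  Uses the closed form in terms
    of the Carlson symmetric integral R_D,

        N_a = (a·b·c / 3) · R_D(b², c², a²),

    which is the standard elliptic-integral expression.  The three factors
    sum to 1.
    """
    if min(a, b, c) <= 0:
        raise ValueError(f"semi-axes must be > 0, got {(a, b, c)}")
    # Rescale to unit magnitude for numerical conditioning.
    s = max(a, b, c)
    a, b, c = a / s, b / s, c / s
    pref = a * b * c / 3.0
    na = pref * float(elliprd(b * b, c * c, a * a))
    nb = pref * float(elliprd(a * a, c * c, b * b))
    nc = pref * float(elliprd(a * a, b * b, c * c))
    return na, nb, nc


def demag_difference_ellipsoid(a: float, b: float, t: float) -> float:
    """ΔN = N_short − N_long for an ellipsoid approximating a flat ellipse.

    Parameters are the in-plane semi-axes ``a ≥ b`` and the full thickness
    ``t``; the ellipsoid has semi-axes (a, b, t/2).  ΔN > 0 whenever a > b,
    i.e. the long axis is the easy axis.
    """
    if not (a >= b > 0) or t <= 0:
        raise ValueError(f"require a >= b > 0 and t > 0, got a={a}, b={b}, t={t}")
    na, nb, _ = demag_factors_ellipsoid(a, b, t / 2.0)
    return nb - na


def anisotropy_constant(delta_N: float, M_s: float) -> float:
    """Shape-anisotropy constant K = ½·μ0·ΔN·M_s² in J/m³.

    Equivalent to the Gaussian-unit form K = 2π·M²·ΔN (erg/cm³) after
    unit conversion.
    """
    if delta_N < 0:
        raise ValueError("delta_N must be >= 0")
    if M_s <= 0:
        raise ValueError("M_s must be > 0")
    return 0.5 * MU_0 * delta_N * M_s * M_s


def anisotropy_field(K: float, M_s: float) -> float:
    """Anisotropy field H_K = 2K/(μ0·M_s) in A/m (= ΔN·M_s)."""
    if M_s <= 0:
        raise ValueError("M_s must be > 0")
    return 2.0 * K / (MU_0 * M_s)


def _elliptic_cylinder_volume(a: float, b: float, t: float) -> float:
    return math.pi * a * b * t


@dataclass(frozen=True)
class Nanoprobe:
    """A single elliptical multilayer nanoprobe.

    Dimensions are full axes/thicknesses in metres; the magnetically active
    layer is a thin slab of ``material`` with thickness ``magnetic_thickness_m``.

    ``hydro_scale`` enlarges the hydrodynamic envelope relative to the bare
    geometry; it is applied to the *linear* dimensions by default (volume
    scales with its cube), with a ``hydro_scale_mode='volume'`` switch for
    the direct volume-factor reading.  ``shell_m`` is the thickness of a
    uniformly bound analyte layer; it grows each hydrodynamic semi-axis by
    ``shell_m`` (and the thickness by ``2·shell_m``) before the envelope
    scaling and does not alter any magnetic property.

    ``mu0_Hk_T``: measured anisotropy field in tesla.  If ``None`` it is
    derived from the ellipsoid demagnetizing factors of the magnetic layer —
    a crude approximation for a 7 nm elliptical slab, hence a logged warning.
    """

    long_axis_m: float = 400e-9
    short_axis_m: float = 200e-9
    thickness_m: float = 60e-9
    magnetic_thickness_m: float = 7e-9
    material: MagneticMaterial = field(default_factory=MagneticMaterial)
    stack: LayerStack | None = None
    hydro_scale: float = 3.0
    hydro_scale_mode: Literal["linear", "volume"] = "linear"
    mu0_Hk_T: float | None = 30e-3
    shell_m: float = 0.0

    def __post_init__(self) -> None:
        if not (self.long_axis_m >= self.short_axis_m > 0):
            raise ValueError("require long_axis >= short_axis > 0")
        if not (self.thickness_m >= self.magnetic_thickness_m > 0):
            raise ValueError("require thickness >= magnetic_thickness > 0")
        if self.hydro_scale < 1:
            raise ValueError(f"hydro_scale must be >= 1, got {self.hydro_scale}")
        if self.shell_m < 0:
            raise ValueError("shell thickness must be >= 0")
        if self.mu0_Hk_T is not None and self.mu0_Hk_T <= 0:
            raise ValueError("mu0_Hk_T must be > 0 when set")

    # -- geometry ---------------------------------------------------------
    @property
    def a_m(self) -> float:
        """In-plane long semi-axis."""
        return self.long_axis_m / 2.0

    @property
    def b_m(self) -> float:
        """In-plane short semi-axis."""
        return self.short_axis_m / 2.0

    @property
    def magnetic_volume_m3(self) -> float:
        return _elliptic_cylinder_volume(self.a_m, self.b_m, self.magnetic_thickness_m)

    @property
    def hydrodynamic_volume_m3(self) -> float:
        return hydrodynamic_volume(self)

    # -- magnetics --------------------------------------------------------
    @property
    def moment_A_m2(self) -> float:
        return magnetic_moment(self, self.material)

    @property
    def demag_difference(self) -> float:
        """ΔN of the ellipsoid with semi-axes (a, b, t_mag/2)."""
        return demag_difference_ellipsoid(self.a_m, self.b_m, self.magnetic_thickness_m)

    @property
    def anisotropy_field_T(self) -> float:
        """μ0·H_K in tesla; measured value takes precedence over geometry."""
        if self.mu0_Hk_T is not None:
            return self.mu0_Hk_T
        hk = MU_0 * self.demag_difference * self.material.M_s_A_m
        logger.warning(
            "anisotropy field derived from ellipsoid demagnetizing factors "
            "(mu0_Hk = %.3g mT); the ellipsoid approximation of a thin "
            "elliptical slab is crude — prefer a measured value",
            hk * 1e3,
        )
        return hk

    def with_shell(self, shell_m: float) -> "Nanoprobe":
        """Return a copy carrying a bound-analyte shell of given thickness."""
        if shell_m < 0:
            raise ValueError("shell thickness must be >= 0")
        return replace(self, shell_m=shell_m)


def magnetic_moment(probe: Nanoprobe, mat: MagneticMaterial | None = None) -> float:
    """Magnetic moment m = M_s·V_mag of the probe's magnetic layer, A·m²."""
    mat = mat if mat is not None else probe.material
    return mat.M_s_A_m * probe.magnetic_volume_m3


def hydrodynamic_volume(probe: Nanoprobe) -> float:
    """Hydrodynamic volume in m³.

    The bare envelope is the elliptical cylinder π·a·b·t grown by any bound
    shell (δ on each semi-axis, 2δ on the thickness).  ``hydro_scale`` then
    multiplies the linear dimensions (default) or the volume directly.
    """
    d = probe.shell_m
    v = _elliptic_cylinder_volume(
        probe.a_m + d, probe.b_m + d, probe.thickness_m + 2 * d
    )
    if probe.hydro_scale_mode == "volume":
        return probe.hydro_scale * v
    return probe.hydro_scale**3 * v
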