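"""Physical constants and unit conversions.

All internal computation is SI.  The literature on single-domain magnetics
mixes Gaussian-CGS expressions (moments in emu, fields in Oe/mT-as-induction)
with SI-flavoured values, so explicit conversion helpers live here and are
used at every boundary where a CGS-style quantity enters.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "K_B",
    "MU_0",
    "emu_per_cm3_to_A_per_m",
    "A_per_m_to_emu_per_cm3",
    "volumetric_magnetization",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA values used throughout the package."""

    k_B: float = 1.380649e-23  # Boltzmann constant, J/K (exact, SI 2019)
    mu_0: float = 1.25663706212e-6  # vacuum permeability, T·m/A


CONSTANTS = PhysicalConstants()
K_B = CONSTANTS.k_B
MU_0 = CONSTANTS.mu_0

# 1 emu/cm^3 == 1e3 A/m
_EMU_CM3_TO_A_M = 1.0e3


def emu_per_cm3_to_A_per_m(m_cgs: float) -> float:
    """Convert volumetric magnetization from emu/cm³ to A/m."""
    return m_cgs * _EMU_CM3_TO_A_M


def A_per_m_to_emu_per_cm3(m_si: float) -> float:
    """Inverse of :func:`emu_per_cm3_to_A_per_m`."""
    return m_si / _EMU_CM3_TO_A_M


def volumetric_magnetization(sigma_s_emu_g: float, density_g_cm3: float) -> float:
    """Saturation magnetization M_s in A/m from the specific moment.

    Parameters
    ----------
    sigma_s_emu_g
        Specific saturation moment in emu/g (equivalently A·m²/kg).
    density_g_cm3
        Mass density in g/cm³.

    Returns
    -------
    float
        Volumetric saturation magnetization ``M_s = σ_s·ρ·10³`` in A/m.
    """
    if sigma_s_emu_g < 0:
        raise ValueError(f"specific moment must be >= 0, got {sigma_s_emu_g}")
    if density_g_cm3 <= 0:
        raise ValueError(f"density must be > 0, got {density_g_cm3}")
    return emu_per_cm3_to_A_per_m(sigma_s_emu_g * density_g_cm3)
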