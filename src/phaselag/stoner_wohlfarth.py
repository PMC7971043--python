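"""Single-domain Stoner–Wohlfarth energetics.

A quasi-single-domain elliptical probe carries a magnetization that prefers
the in-plane long (easy) axis through shape anisotropy.  Under an applied
field at angle ``φ`` to the easy axis the reduced energy per unit K·V is

    e(ϑ) = sin²ϑ − 2·h·cos(φ − ϑ),      h = H / H_K,

with ``ϑ`` the magnetization–easy-axis angle.  Setting de/dϑ = 0 with the
viscous-lag decomposition φ = ϑ + α gives the equilibrium condition
sin(2ϑ) = 2·h·sin(α).  When the field point leaves the astroid the energy
minimum disappears and the magnetization switches irreversibly — during
fluid rotation this drives the probe into an erratic (flagged) regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "SWState",
    "sw_energy",
    "equilibrium_theta",
    "astroid_switching_field",
    "hysteresis_loop",
    "rotational_instability_check",
]


def _wrap_pi(x: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    y = math.fmod(x + math.pi, 2.0 * math.pi)
    if y <= 0.0:
        y += 2.0 * math.pi
    return y - math.pi


@dataclass(frozen=True)
class SWState:
    """One quasi-static magnetization state of a probe under load.

    Angles in radians, wrapped into (-pi, pi]; ``phi = theta + alpha`` holds
    whenever the state is stable.
    """

    h: float
    phi: float
    theta: float
    alpha: float
    stability: Literal["stable", "unstable", "switched"]

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("reduced field h must be >= 0")
        for name in ("phi", "theta", "alpha"):
            v = getattr(self, name)
            if not (-math.pi < v <= math.pi + 1e-12):
                raise ValueError(f"{name}={v} not in (-pi, pi]")
        if self.stability == "stable":
            if abs(_wrap_pi(self.phi - self.theta - self.alpha)) > 1e-9:
                raise ValueError("stable state must satisfy phi = theta + alpha")


def sw_energy(theta, phi, h):
    """Reduced energy e(ϑ) = sin²ϑ − 2h·cos(φ−ϑ) and its first two derivatives.

    The arbitrary offset E0 is fixed to zero; only derivatives matter for
    equilibria and stability.  Accepts scalars or arrays; returns
    ``(e, de_dtheta, d2e_dtheta2)``.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(np.asarray(h) < 0):
        raise ValueError("reduced field h must be >= 0")
    e = np.sin(theta) ** 2 - 2.0 * h * np.cos(phi - theta)
    de = np.sin(2.0 * theta) - 2.0 * h * np.sin(phi - theta)
    d2e = 2.0 * np.cos(2.0 * theta) + 2.0 * h * np.cos(phi - theta)
    if e.ndim == 0:
        return float(e), float(de), float(d2e)
    return e, de, d2e


def equilibrium_theta(alpha: float, h: float) -> tuple[float, bool]:
    """Stable-branch magnetization angle ϑ solving sin(2ϑ) = 2h·sin(α).

    Returns ``(theta, stable)``.  The stable pre-switching branch is
    ϑ ∈ [−π/4, π/4]; when |2h·sinα| ≥ 1 no such equilibrium exists (the
    transverse load exceeds the anisotropy restoring torque) and the state
    is flagged unstable with ϑ = ±π/4.  The marginal case is flagged
    unstable too: an unsaturated or thermally agitated probe switches
    before the ideal threshold, so the conservative call is the safe one.
    """
    if h < 0:
        raise ValueError("reduced field h must be >= 0")
    s = 2.0 * h * math.sin(alpha)
    if abs(s) >= 1.0:
        return math.copysign(math.pi / 4.0, s), False
    return 0.5 * math.asin(s), True


def astroid_switching_field(psi: float) -> float:
    """Reduced switching field h_sw at field angle ψ to the easy axis.

    Solves the simultaneous instability conditions
    ``h·sinφ = sin³ϑ`` and ``h·cosφ = −cos³ϑ`` (vanishing first and second
    energy derivative), whose locus is the classical astroid

        h_sw(ψ) = (cos^{2/3}ψ + sin^{2/3}ψ)^{−3/2}.

    Minimum 1/2 at ψ = 45°, maximum 1 along the principal axes.
    """
    psi = abs(_wrap_pi(psi))
    if psi > math.pi / 2.0:  # astroid is symmetric under psi -> pi - psi
        psi = math.pi - psi
    c, s = math.cos(psi), math.sin(psi)
    if c < 1e-15:  # cos(pi/2) is not exactly zero in floating point
        c = 0.0
    if s < 1e-15:
        s = 0.0
    return (c ** (2.0 / 3.0) + s ** (2.0 / 3.0)) ** (-1.5)


def rotational_instability_check(phi: float, h: float) -> bool:
    """True iff the reduced field point (h, φ) lies on or outside the astroid.

    ``phi`` is the instantaneous field angle to the easy axis.  The boundary
    is closed: a probe driven exactly to the astroid switches.
    """
    if h < 0:
        raise ValueError("reduced field h must be >= 0")
    return h >= astroid_switching_field(phi) - 1e-15


def _monotone_runs(h: np.ndarray) -> list[slice]:
    """Split a sweep into maximal monotone runs; reject jittery sweeps."""
    if h.size < 2:
        return [slice(0, h.size)]
    d = np.diff(h)
    if np.any(d == 0):
        raise ValueError("hysteresis sweep contains repeated field values")
    sign = np.sign(d)
    turns = np.nonzero(sign[1:] != sign[:-1])[0] + 1
    starts = [0, *(int(t) for t in turns)]
    stops = [*(int(t) + 1 for t in turns), h.size]
    runs = [slice(lo, hi) for lo, hi in zip(starts, stops)]
    if len(runs) > 1 and any(r.stop - r.start < 3 for r in runs):
        raise ValueError("sweep segments must be monotone (direction flips every sample)")
    return runs


def hysteresis_loop(
    axis: Literal["easy", "hard"], h_values: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Idealized single-domain loop: reduced magnetization projection M∥/M_s.

    Easy axis: square loop, irreversible switching at |h| = 1, full
    remanence.  Hard axis: reversible linear branch M∥/M_s = clamp(h, −1, 1)
    saturating at the anisotropy field (zero remanence, closed loop).
    """
    h = np.asarray(h_values, dtype=float)
    if axis not in ("easy", "hard"):
        raise ValueError(f"axis must be 'easy' or 'hard', got {axis!r}")
    _monotone_runs(h)  # validates sweep structure
    if axis == "hard":
        return np.clip(h, -1.0, 1.0)
    m = np.empty_like(h)
    state = 1.0 if h[0] >= 0 else -1.0
    for i, hi in enumerate(h):
        if state > 0 and hi <= -1.0:
            state = -1.0
        elif state < 0 and hi >= 1.0:
            state = 1.0
        m[i] = state
    return m
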