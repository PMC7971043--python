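"""Rotational dynamics of magnetic nanoprobes in a rotating field.

This is the heart of the signal model.  A probe suspended in fluid follows a
field rotating at angular frequency ω, but lags behind:

* the **viscous lag** α between magnetization and field comes from the
  Debye rotational-relaxation picture with the Langevin saturation factor,

      tan α = ω · 2τ_B / (2 + ξ·L(ξ)),   ξ = m·B/(k_B·T),
      τ_B = 3·η·V_hydro/(k_B·T);

* the **internal angle** ϑ between magnetization and the particle's easy
  axis follows quasi-statically from Stoner–Wohlfarth equilibrium,
  sin 2ϑ = 2(H/H_K)·sin α;

* the **measured lag** of the optical (long) axis is φ = ϑ + α.

Below the critical frequency ω_c = m·B/(6·η·V_hydro) the rotation is
synchronous (constant lag); above it the probe slips periodically and
advances at a mean rate below ω.  A time-domain integrator of the torque
balance, with optional rotational diffusion, provides an independent route
to the same steady state and covers the asynchronous regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .constants import K_B
from .materials import Environment, Nanoprobe
from .stoner_wohlfarth import equilibrium_theta

__all__ = [
    "OperatingPoint",
    "PhaseState",
    "RotationTrajectory",
    "brownian_time",
    "langevin",
    "thermal_field_parameter",
    "viscous_lag",
    "measured_phase_lag",
    "critical_frequency",
    "simulate_rotation",
    "phase_lag_curve",
    "phase_lag_model",
    "fit_phase_curve",
]

Regime = Literal["synchronous", "asynchronous", "sw_unstable"]


@dataclass(frozen=True)
class OperatingPoint:
    """Drive condition: rotating-field amplitude and angular frequency."""

    angular_frequency_rad_s: float
    field_T: float

    def __post_init__(self) -> None:
        if self.angular_frequency_rad_s < 0:
            raise ValueError("angular frequency must be >= 0")
        if self.field_T <= 0:
            raise ValueError("field amplitude must be > 0")

    @classmethod
    def from_frequency(cls, frequency_Hz: float, field_T: float) -> "OperatingPoint":
        return cls(2.0 * math.pi * frequency_Hz, field_T)

    @property
    def frequency_Hz(self) -> float:
        return self.angular_frequency_rad_s / (2.0 * math.pi)


@dataclass(frozen=True)
class PhaseState:
    """Resolved lag angles of one probe at one operating point (radians)."""

    tau_B_s: float
    xi: float
    alpha_rad: float
    theta_rad: float
    phi_rad: float
    regime: Regime

    def __post_init__(self) -> None:
        if self.tau_B_s <= 0:
            raise ValueError("tau_B must be > 0")
        if self.xi < 0:
            raise ValueError("xi must be >= 0")


def brownian_time(env: Environment, V_hydro_m3: float) -> float:
    """Brownian rotational relaxation time τ_B = 3·η·V_hydro/(k_B·T) in s."""
    if V_hydro_m3 <= 0:
        raise ValueError("hydrodynamic volume must be > 0")
    return 3.0 * env.viscosity_Pa_s * V_hydro_m3 / (K_B * env.temperature_K)


def langevin(xi):
    """Langevin function L(ξ) = coth ξ − 1/ξ, numerically stable at both ends.

    Series ξ/3 − ξ³/45 below ξ = 1e-3; 1 − 1/ξ above ξ = 40 (coth is 1 to
    double precision there).  Accepts scalars or arrays, ξ ≥ 0.
    """
    x = np.asarray(xi, dtype=float)
    if np.any(x < 0):
        raise ValueError("xi must be >= 0")
    out = np.empty_like(x)
    small = x < 1e-3
    large = x > 40.0
    mid = ~(small | large)
    xs = x[small]
    out[small] = xs / 3.0 - xs**3 / 45.0
    with np.errstate(over="ignore"):
        xm = x[mid]
        out[mid] = 1.0 / np.tanh(xm) - 1.0 / xm
    out[large] = 1.0 - 1.0 / x[large]
    return float(out) if out.ndim == 0 else out


def thermal_field_parameter(
    op: OperatingPoint, probe: Nanoprobe, env: Environment
) -> float:
    """ξ = m·B/(k_B·T): Zeeman energy over thermal energy."""
    return probe.moment_A_m2 * op.field_T / (K_B * env.temperature_K)


def viscous_lag(op: OperatingPoint, probe: Nanoprobe, env: Environment) -> float:
    """Viscous (Debye) lag α = arctan(2ωτ_B / (2 + ξ·L(ξ))) ∈ [0, π/2)."""
    tau = brownian_time(env, probe.hydrodynamic_volume_m3)
    xi = thermal_field_parameter(op, probe, env)
    return math.atan(
        2.0 * op.angular_frequency_rad_s * tau / (2.0 + xi * langevin(xi))
    )


def critical_frequency(probe: Nanoprobe, env: Environment, field_T: float) -> float:
    """Deterministic critical angular frequency ω_c = m·B/(6·η·V_hydro), rad/s.

    This is the torque-balance limit: the maximum magnetic torque m·B (at
    lag π/2) against the rotational drag 6·η·V_hydro·ω.  Beyond ω_c no
    synchronous solution exists.  Note the thermal (Debye) lag formula never
    reaches π/2 at finite ω; the synchronous/asynchronous transition is a
    property of the deterministic balance, which the Debye expression
    approaches when ξ ≫ 1.
    """
    if field_T <= 0:
        raise ValueError("field must be > 0")
    return (
        probe.moment_A_m2
        * field_T
        / (6.0 * env.viscosity_Pa_s * probe.hydrodynamic_volume_m3)
    )


def measured_phase_lag(
    op: OperatingPoint, probe: Nanoprobe, env: Environment
) -> PhaseState:
    """Measured optical-axis lag φ = ϑ + α at one operating point.

    α comes from the thermal Debye balance, ϑ from quasi-static
    Stoner–Wohlfarth equilibrium at reduced field h = B/(μ0·H_K).  The
    regime is ``sw_unstable`` if the transverse load exceeds the astroid
    limit, ``asynchronous`` if ω exceeds the deterministic critical
    frequency, else ``synchronous``.
    """
    tau = brownian_time(env, probe.hydrodynamic_volume_m3)
    xi = thermal_field_parameter(op, probe, env)
    alpha = math.atan(2.0 * op.angular_frequency_rad_s * tau / (2.0 + xi * langevin(xi)))
    h = op.field_T / probe.anisotropy_field_T
    theta, stable = equilibrium_theta(alpha, h)
    regime: Regime
    if not stable:
        regime = "sw_unstable"
    elif op.angular_frequency_rad_s > critical_frequency(probe, env, op.field_T):
        regime = "asynchronous"
    else:
        regime = "synchronous"
    return PhaseState(
        tau_B_s=tau,
        xi=xi,
        alpha_rad=alpha,
        theta_rad=theta,
        phi_rad=theta + alpha,
        regime=regime,
    )


def phase_lag_curve(
    probe: Nanoprobe,
    env: Environment,
    field_T: float,
    frequencies_Hz: Sequence[float] | np.ndarray,
) -> pd.DataFrame:
    """Lag curve over a frequency grid: columns (frequency_Hz, alpha_rad,
    theta_rad, phi_rad, regime), plus a ``near_critical`` flag where the
    drive exceeds 95 % of the deterministic critical frequency."""
    f = np.asarray(frequencies_Hz, dtype=float)
    if f.size == 0 or np.any(f < 0) or np.any(np.diff(f) <= 0) and f.size > 1:
        raise ValueError("frequency grid must be positive and strictly ascending")
    f_c = critical_frequency(probe, env, field_T) / (2.0 * math.pi)
    rows = []
    for fi in f:
        st = measured_phase_lag(OperatingPoint.from_frequency(fi, field_T), probe, env)
        rows.append(
            {
                "frequency_Hz": fi,
                "alpha_rad": st.alpha_rad,
                "theta_rad": st.theta_rad,
                "phi_rad": st.phi_rad,
                "regime": st.regime,
                "near_critical": fi >= 0.95 * f_c,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Time-domain simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RotationTrajectory:
    """Sampled particle-orientation trajectory and its steady-state summary.

    ``theta_p`` is the unwrapped particle (easy-axis) angle, ``theta_H`` the
    field angle ω·t.  ``steady_state_lag_rad`` is the circular mean of the
    wrapped lag over the second half of the run — meaningful in the
    synchronous regime; in the asynchronous regime the mean rotation rate
    is the informative quantity.
    """

    t_s: np.ndarray
    theta_p_rad: np.ndarray
    theta_H_rad: np.ndarray
    steady_state_lag_rad: float
    final_lag_rad: float
    mean_rotation_rate_rad_s: float
    regime: Regime


def _solve_alpha_quasistatic(lag: float, h: float, alpha0: float) -> tuple[float, bool]:
    """Solve α + ϑ(α) = lag for the magnetization lag α (quasi-static SW).

    ϑ(α) = ½·arcsin(2h·sinα).  Fixed-point iteration with warm start; the
    map is a contraction whenever |2h·sinα| < 1 with margin.  Returns
    (alpha, stable); stable=False when the astroid load limit is hit.
    """
    alpha = alpha0
    for _ in range(60):
        s = 2.0 * h * math.sin(alpha)
        if abs(s) >= 1.0:
            return alpha, False
        new = lag - 0.5 * math.asin(s)
        if abs(new - alpha) < 1e-12:
            return new, True
        alpha = new
    return alpha, True


def simulate_rotation(
    probe: Nanoprobe,
    env: Environment,
    op: OperatingPoint,
    duration_s: float,
    dt_s: float,
    mode: Literal["rigid_dipole", "sw_quasistatic"] = "rigid_dipole",
    noise: bool = False,
    seed: int | None = None,
    theta0_rad: float = 0.0,
) -> RotationTrajectory:
    """Integrate the overdamped torque balance of a single probe.

        6·η·V_hydro · dθ_p/dt = m·B · sin(θ_H(t) − θ_m(t)) [+ thermal torque]

    with θ_H = ω·t, and θ_m = θ_p (``rigid_dipole``) or θ_p + ϑ with the
    internal angle at instantaneous Stoner–Wohlfarth equilibrium
    (``sw_quasistatic``).  Thermal rotational diffusion (coefficient
    D = k_B·T/(6·η·V_hydro)) enters as an Euler–Maruyama noise term with a
    fixed seed.  No inertia: the motion is strictly overdamped.

    Raises if the time step does not resolve the drive (dt ≤ 2π/(50ω)) or
    the run covers fewer than 20 drive periods.
    """
    omega = op.angular_frequency_rad_s
    if dt_s <= 0 or duration_s <= 0:
        raise ValueError("duration and dt must be > 0")
    if omega > 0:
        if dt_s > 2.0 * math.pi / (50.0 * omega):
            raise ValueError(
                f"dt={dt_s:g} s too coarse for drive at {omega:g} rad/s "
                f"(need dt <= {2.0 * math.pi / (50.0 * omega):g} s)"
            )
        if duration_s < 20.0 * 2.0 * math.pi / omega:
            raise ValueError("duration must cover at least 20 drive periods")

    omega_c = critical_frequency(probe, env, op.field_T)
    h = op.field_T / probe.anisotropy_field_T
    n = int(round(duration_s / dt_s))
    t = np.arange(n + 1) * dt_s
    theta_p = np.empty(n + 1)
    theta_p[0] = theta0_rad

    noise_amp = 0.0
    normals = None
    if noise:
        D = K_B * env.temperature_K / (
            6.0 * env.viscosity_Pa_s * probe.hydrodynamic_volume_m3
        )
        noise_amp = math.sqrt(2.0 * D * dt_s)
        rng = np.random.default_rng(seed)
        normals = rng.standard_normal(n)

    sw = mode == "sw_quasistatic"
    if mode not in ("rigid_dipole", "sw_quasistatic"):
        raise ValueError(f"unknown mode {mode!r}")

    regime: Regime = "synchronous"
    alpha_prev = 0.0
    th = theta_p[0]
    sin = math.sin
    for i in range(n):
        lag = omega * t[i] - th
        if sw:
            alpha, stable = _solve_alpha_quasistatic(lag, h, alpha_prev)
            if not stable:
                regime = "sw_unstable"
            alpha_prev = alpha
            drive = omega_c * sin(alpha)
        else:
            drive = omega_c * sin(lag)
        th = th + drive * dt_s
        if normals is not None:
            th += noise_amp * normals[i]
        theta_p[i + 1] = th

    theta_H = omega * t
    half = (n + 1) // 2
    lag_arr = theta_H[half:] - theta_p[half:]
    # circular mean of the wrapped lag (robust to 2π slips in the async regime)
    steady = math.atan2(np.mean(np.sin(lag_arr)), np.mean(np.cos(lag_arr)))
    final_lag = float(theta_H[-1] - theta_p[-1])
    if t[-1] > t[half]:
        mean_rate = float((theta_p[-1] - theta_p[half]) / (t[-1] - t[half]))
    else:
        mean_rate = 0.0
    if regime != "sw_unstable" and omega > 0 and mean_rate < 0.99 * omega:
        regime = "asynchronous"
    return RotationTrajectory(
        t_s=t,
        theta_p_rad=theta_p,
        theta_H_rad=theta_H,
        steady_state_lag_rad=float(steady),
        final_lag_rad=final_lag,
        mean_rotation_rate_rad_s=mean_rate,
        regime=regime,
    )


# ---------------------------------------------------------------------------
# Curve fitting (parameter recovery from measured lag curves)
# ---------------------------------------------------------------------------


def phase_lag_model(f_Hz, tau_B_s, xi, h):
    """Measured lag φ(f) for given τ_B, ξ and reduced field h (vectorized).

    The forward model behind :func:`measured_phase_lag`, parameterized
    directly by the quantities a lag-curve fit can constrain.
    """
    f = np.asarray(f_Hz, dtype=float)
    omega = 2.0 * math.pi * f
    alpha = np.arctan(2.0 * omega * tau_B_s / (2.0 + xi * langevin(xi)))
    s = np.clip(2.0 * h * np.sin(alpha), -1.0, 1.0)
    theta = 0.5 * np.arcsin(s)
    return alpha + theta


def fit_phase_curve(
    f_Hz: np.ndarray,
    phi_rad: np.ndarray,
    xi: float,
    h: float,
    tau_B_guess_s: float = 1e-2,
    vary_xi: bool = False,
):
    """Recover τ_B (optionally ξ) from a measured (f, φ) lag curve.

    Least-squares fit of :func:`phase_lag_model`; ξ and h default to fixed
    known values since a single lag curve constrains them only weakly.
    Returns the lmfit result; the recovered time is
    ``result.params['tau_B_s'].value``.
    """
    import lmfit

    model = lmfit.Model(phase_lag_model, independent_vars=["f_Hz"])
    params = model.make_params(
        tau_B_s={"value": tau_B_guess_s, "min": 1e-8},
        xi={"value": xi, "vary": vary_xi, "min": 0.0},
        h={"value": h, "vary": False},
    )
    return model.fit(np.asarray(phi_rad, float), params, f_Hz=np.asarray(f_Hz, float))
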