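"""End-to-end homogeneous immunoassay model.

Analyte molecules captured on a probe's surface build up a hydrodynamic
shell: the hydrodynamic volume grows, the Brownian time τ_B grows with it,
and the measured phase lag φ increases.  The assay observable is the lag
difference Δφ(c) = φ(c) − φ(0) between the analyte sample and a
zero-analyte reference, measured at a fixed synchronous operating point.

Binding is modelled as equilibrium Langmuir coverage — the endpoint shell
thickness is δ(c) = δ_max·c/(c + K_d) — because the readout is an endpoint
phase lag, not a kinetic trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .detection import (
    OPTICAL_OFFSET_RAD,
    ensemble_signal,
    lockin_extract_phase,
    synthesize_trace,
)
from .dynamics import OperatingPoint, measured_phase_lag
from .materials import Environment, Nanoprobe

__all__ = [
    "BindingModel",
    "AssayResult",
    "shell_thickness",
    "bound_probe",
    "dose_response",
    "viscosity_sensitivity",
    "run_assay",
    "fit_dose_response",
    "wrap_phase_difference",
]


@dataclass(frozen=True)
class BindingModel:
    """Equilibrium analyte-binding model.

    ``K_d_M`` — dissociation constant in mol/L; ``delta_max_m`` — shell
    thickness at full coverage (of order one protein layer, ~10 nm).
    """

    K_d_M: float = 1e-9
    delta_max_m: float = 10e-9

    def __post_init__(self) -> None:
        if self.K_d_M <= 0:
            raise ValueError("K_d must be > 0")
        if self.delta_max_m < 0:
            raise ValueError("delta_max must be >= 0")


def shell_thickness(c_analyte_M, model: BindingModel):
    """Bound-layer thickness δ(c) = δ_max·c/(c + K_d); vectorized, c ≥ 0."""
    c = np.asarray(c_analyte_M, dtype=float)
    if np.any(c < 0):
        raise ValueError("analyte concentration must be >= 0")
    out = model.delta_max_m * c / (c + model.K_d_M)
    return float(out) if out.ndim == 0 else out


def bound_probe(probe: Nanoprobe, delta_m: float) -> Nanoprobe:
    """Probe with a uniform analyte shell of thickness δ on every face.

    Only the hydrodynamic envelope changes; moment and anisotropy field are
    untouched (the bound protein is non-magnetic).
    """
    return probe.with_shell(delta_m)


def wrap_phase_difference(dphi_rad: float) -> float:
    """Wrap a lag difference into (−π/2, π/2] (lags live modulo π)."""
    return -((-dphi_rad + math.pi / 2.0) % math.pi - math.pi / 2.0)


@dataclass(frozen=True)
class AssayResult:
    """Dose–response table: lag and lag difference per concentration."""

    concentrations_M: np.ndarray
    phi_rad: np.ndarray
    dphi_rad: np.ndarray
    dphi_sd_rad: np.ndarray
    regime: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "c_molar": self.concentrations_M,
                "phi_rad": self.phi_rad,
                "dphi_rad": self.dphi_rad,
                "dphi_sd_rad": self.dphi_sd_rad,
                "regime": list(self.regime),
            }
        )


def dose_response(
    probe: Nanoprobe,
    env: Environment,
    op: OperatingPoint,
    model: BindingModel,
    concentrations_M: Sequence[float] | np.ndarray,
) -> AssayResult:
    """Noise-free dose–response through the full physical chain.

    binding → shell → V_hydro → τ_B → (Debye α, SW ϑ) → φ; Δφ is taken
    against c = 0 with the same probe and operating point.  Rows where the
    operating point leaves the synchronous regime are flagged, never
    dropped: an asynchronous lag reading is not a valid assay point.
    """
    c = np.asarray(concentrations_M, dtype=float)
    if np.any(c < 0):
        raise ValueError("analyte concentration must be >= 0")
    ref = measured_phase_lag(op, bound_probe(probe, 0.0), env)
    phi = np.empty_like(c)
    regimes = []
    for i, ci in enumerate(c):
        st = measured_phase_lag(op, bound_probe(probe, shell_thickness(ci, model)), env)
        phi[i] = st.phi_rad
        regimes.append(st.regime)
    dphi = phi - ref.phi_rad
    return AssayResult(
        concentrations_M=c,
        phi_rad=phi,
        dphi_rad=dphi,
        dphi_sd_rad=np.zeros_like(c),
        regime=tuple(regimes),
    )


def viscosity_sensitivity(
    probe: Nanoprobe,
    env: Environment,
    op: OperatingPoint,
    rel_eta_step: float = 1e-3,
) -> float:
    """Logarithmic sensitivity (Δφ/φ)/(Δη/η) of the lag to viscosity.

    Central finite difference through the full model.  In the small-lag
    regime φ ∝ η so the ratio is 1; it falls toward 0 as the lag
    approaches π/2 (the arctan saturates), which is why a lag assay is
    most viscosity-robust near its critical point.
    """
    if rel_eta_step <= 0:
        raise ValueError("perturbation must be > 0")
    phi0 = measured_phase_lag(op, probe, env).phi_rad
    if phi0 == 0:
        raise ValueError("zero lag at this operating point; sensitivity undefined")
    states = []
    for sgn in (+1.0, -1.0):
        env_p = Environment(
            viscosity_Pa_s=env.viscosity_Pa_s * (1.0 + sgn * rel_eta_step),
            temperature_K=env.temperature_K,
        )
        states.append(measured_phase_lag(op, probe, env_p).phi_rad)
    dphi = (states[0] - states[1]) / 2.0
    return (dphi / phi0) / rel_eta_step


def run_assay(config, output_dir=None):
    """Run the full synthetic assay defined by a :class:`~phaselag.config.RunConfig`.

    Chain per concentration: sample the probe population once (seeded),
    grow each particle's shell to the Langmuir equilibrium, compute every
    particle's lag, form the coherent 2f ensemble signal, synthesize a
    noisy detector trace per bootstrap seed, demodulate it, and report the
    seed-mean lag with its standard deviation.  Δφ is referenced to the
    c = 0 row extracted with identical window settings, so the constant
    optical offset cancels exactly.

    Returns ``(AssayResult, summary dict)``; writes CSV/JSON artifacts when
    ``output_dir`` is given (see :mod:`phaselag.cli`).
    """
    from .config import RunConfig  # deferred: config imports domain types
    from .synthetic import PopulationSpec, sample_population

    if not isinstance(config, RunConfig):
        config = RunConfig.model_validate(config)

    probe = config.probe.to_probe()
    env = config.environment.to_environment()
    op = config.field.to_operating_point()
    binding = config.binding.to_model()
    pop = sample_population(
        PopulationSpec(
            probe=probe,
            lateral_cv=config.population.lateral_cv,
            thickness_cv=config.population.thickness_cv,
            count=config.population.count,
            seed=config.seed,
            correlated_axes=config.population.correlated_axes,
        )
    )
    offset = OPTICAL_OFFSET_RAD if config.assay.optical_offset_90deg else 0.0
    tr = config.trace

    concentrations = np.asarray(config.assay.concentrations_M, dtype=float)
    phi_hat = np.empty_like(concentrations)
    phi_sd = np.empty_like(concentrations)
    regimes = []
    attenuations = []
    per_c_records = []
    for i, c in enumerate(concentrations):
        delta = shell_thickness(float(c), binding)
        states = [measured_phase_lag(op, bound_probe(p, delta), env) for p in pop]
        phases = np.array([s.phi_rad for s in states])
        worst = "synchronous"
        for s in states:
            if s.regime == "sw_unstable":
                worst = "sw_unstable"
                break
            if s.regime == "asynchronous":
                worst = "asynchronous"
        regimes.append(worst)
        ens = ensemble_signal(phases + offset)
        attenuations.append(ens.attenuation)
        amp = tr.amplitude * ens.attenuation
        estimates = []
        for k in range(config.assay.n_seeds):
            trace = synthesize_trace(
                phi_rad=ens.resultant_phase_rad,
                frequency_Hz=op.frequency_Hz,
                amplitude=amp,
                offset=tr.offset,
                noise_sigma=tr.noise_sigma,
                sampling_rate_Hz=tr.sampling_rate_Hz,
                duration_s=tr.duration_s,
                seed=config.seed * 100003 + 1009 * i + k,
            )
            estimates.append(lockin_extract_phase(trace).phi_rad)
        # circular mean modulo pi (2phi circular statistics)
        z = np.mean(np.exp(2j * np.asarray(estimates)))
        phi_hat[i] = (0.5 * np.angle(z)) % math.pi
        phi_sd[i] = float(np.std([wrap_phase_difference(e - phi_hat[i]) for e in estimates]))
        per_c_records.append(
            {
                "c_molar": float(c),
                "shell_nm": delta * 1e9,
                "ensemble_attenuation": ens.attenuation,
                "true_phi_ensemble_rad": ens.resultant_phase_rad,
            }
        )

    dphi = np.array(
        [wrap_phase_difference(p - phi_hat[0]) for p in phi_hat]
    )
    result = AssayResult(
        concentrations_M=concentrations,
        phi_rad=phi_hat,
        dphi_rad=dphi,
        dphi_sd_rad=phi_sd,
        regime=tuple(regimes),
    )
    summary = {
        "seed": config.seed,
        "n_particles": config.population.count,
        "n_seeds": config.assay.n_seeds,
        "optical_offset_90deg": bool(config.assay.optical_offset_90deg),
        "ensemble_attenuation": attenuations,
        "per_concentration": per_c_records,
        "resolved_config": config.model_dump(),
    }
    if output_dir is not None:
        _write_assay_artifacts(output_dir, result, summary)
    return result, summary


def _write_assay_artifacts(output_dir, result: AssayResult, summary: dict) -> None:
    import json
    from pathlib import Path

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(out / "dose_response.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)


def fit_dose_response(
    concentrations_M: np.ndarray,
    dphi_rad: np.ndarray,
    probe: Nanoprobe,
    env: Environment,
    op: OperatingPoint,
    K_d_guess_M: float = 1e-9,
    delta_max_guess_m: float = 5e-9,
):
    """Recover (K_d, δ_max) from a measured Δφ(c) curve.

    Least-squares fit of the full forward chain (Langmuir shell → τ_B →
    Debye+SW lag difference); K_d is fitted on a log scale since it spans
    decades.  Returns the lmfit result with parameters ``log10_Kd_M`` and
    ``delta_max_m``.
    """
    import lmfit

    c = np.asarray(concentrations_M, dtype=float)
    y = np.asarray(dphi_rad, dtype=float)

    def forward(c_M, log10_Kd_M, delta_max_m):
        model = BindingModel(K_d_M=10.0**log10_Kd_M, delta_max_m=delta_max_m)
        res = dose_response(probe, env, op, model, c_M)
        return res.dphi_rad

    model = lmfit.Model(forward, independent_vars=["c_M"])
    params = model.make_params(
        log10_Kd_M={"value": math.log10(K_d_guess_M), "min": -15.0, "max": -3.0},
        delta_max_m={"value": delta_max_guess_m, "min": 0.0, "max": 100e-9},
    )
    return model.fit(y, params, c_M=c)
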