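"""Synthetic inputs with the statistical structure of the real system.

The nanoimprint process produces near-monodisperse particles; the residual
lateral size variation is Gaussian with a standard deviation of about 3 %.
A single scale factor is drawn per particle for both in-plane axes by
default (imprint/etch fluctuations affect the whole ellipse, preserving the
aspect ratio); an independent-axis mode is available.  Every generator is
deterministic under its seed, so fixture sets regenerate bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .detection import synthesize_trace
from .materials import Nanoprobe

__all__ = [
    "PopulationSpec",
    "TraceSpec",
    "sample_population",
    "population_table",
    "generate_assay_dataset",
]

_MAX_CV = 0.3  # beyond this the Gaussian model of the imprint process is unphysical


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a probe population draw."""

    probe: Nanoprobe = field(default_factory=Nanoprobe)
    lateral_cv: float = 0.03
    thickness_cv: float = 0.0
    count: int = 1000
    seed: int = 0
    correlated_axes: bool = True

    def __post_init__(self) -> None:
        if self.lateral_cv < 0 or self.thickness_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.lateral_cv >= _MAX_CV or self.thickness_cv >= _MAX_CV:
            raise ValueError(
                f"CV >= {_MAX_CV} is unphysical for the imprint process"
            )
        if self.count < 1:
            raise ValueError("count must be >= 1")


def sample_population(spec: PopulationSpec) -> list[Nanoprobe]:
    """Draw a population of probes with Gaussian size dispersion.

    Lateral axes are scaled by one factor ~N(1, CV) per particle
    (aspect-ratio preserving) or by independent per-axis factors when
    ``correlated_axes`` is off.  Thickness dispersion (default zero) scales
    the stack and magnetic layer together.  Derived quantities — moment,
    hydrodynamic volume, anisotropy field — follow automatically from each
    particle's geometry.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.count
    if spec.correlated_axes:
        g_long = g_short = rng.normal(1.0, spec.lateral_cv, size=n)
    else:
        g_long = rng.normal(1.0, spec.lateral_cv, size=n)
        g_short = rng.normal(1.0, spec.lateral_cv, size=n)
    g_t = (
        rng.normal(1.0, spec.thickness_cv, size=n)
        if spec.thickness_cv > 0
        else np.ones(n)
    )
    p0 = spec.probe
    out = []
    for i in range(n):
        gl = float(g_long[i])
        gs = float(g_short[i])
        gt = float(g_t[i])
        long_m, short_m = p0.long_axis_m * gl, p0.short_axis_m * gs
        if short_m > long_m:  # uncorrelated draws can invert the aspect ratio
            long_m, short_m = short_m, long_m
        out.append(
            replace(
                p0,
                long_axis_m=long_m,
                short_axis_m=short_m,
                thickness_m=p0.thickness_m * gt,
                magnetic_thickness_m=p0.magnetic_thickness_m * gt,
            )
        )
    return out


def population_table(population: Sequence[Nanoprobe]) -> pd.DataFrame:
    """Tabulate per-particle geometry and derived magnetics (CSV-ready)."""
    return pd.DataFrame(
        {
            "long_axis_nm": [p.long_axis_m * 1e9 for p in population],
            "short_axis_nm": [p.short_axis_m * 1e9 for p in population],
            "thickness_nm": [p.thickness_m * 1e9 for p in population],
            "moment_A_m2": [p.moment_A_m2 for p in population],
            "V_hydro_m3": [p.hydrodynamic_volume_m3 for p in population],
            "mu0_Hk_mT": [p.anisotropy_field_T * 1e3 for p in population],
        }
    )


@dataclass(frozen=True)
class TraceSpec:
    """Detector-trace synthesis parameters for fixture generation."""

    frequency_Hz: float = 500.0
    field_T: float = 10e-3
    amplitude: float = 4.5
    offset: float = 0.0
    noise_sigma: float = 0.0
    sampling_rate_Hz: float = 100e3
    duration_s: float = 0.2
    seed: int = 0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def generate_assay_dataset(
    population_spec: PopulationSpec,
    binding_model,
    concentrations_M: Sequence[float],
    trace_spec: TraceSpec,
    output_dir,
    overwrite: bool = False,
) -> dict:
    """Write a complete on-disk assay fixture set with ground truth.

    Per concentration: a two-column detector/reference trace CSV and a JSON
    sidecar holding the per-particle lags, the ensemble truth and the shell
    thickness.  A manifest lists every file with its SHA-256 checksum so
    bit-identical regeneration is verifiable.  Refuses to touch an existing
    populated directory unless ``overwrite`` is set.
    """
    from .assay import bound_probe, shell_thickness
    from .detection import ensemble_signal
    from .dynamics import OperatingPoint, measured_phase_lag
    from .materials import Environment

    out = Path(output_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    env = Environment()
    op = OperatingPoint.from_frequency(trace_spec.frequency_Hz, trace_spec.field_T)
    population = sample_population(population_spec)
    population_table(population).to_csv(out / "population.csv", index=False)

    files = ["population.csv"]
    for i, c in enumerate(concentrations_M):
        delta = float(shell_thickness(float(c), binding_model))
        phases = np.array(
            [
                measured_phase_lag(op, bound_probe(p, delta), env).phi_rad
                for p in population
            ]
        )
        ens = ensemble_signal(phases)
        trace = synthesize_trace(
            phi_rad=ens.resultant_phase_rad,
            frequency_Hz=trace_spec.frequency_Hz,
            amplitude=trace_spec.amplitude * ens.attenuation,
            offset=trace_spec.offset,
            noise_sigma=trace_spec.noise_sigma,
            sampling_rate_Hz=trace_spec.sampling_rate_Hz,
            duration_s=trace_spec.duration_s,
            seed=trace_spec.seed + i,
        )
        stem = f"trace_c{i:02d}"
        pd.DataFrame(
            {"t_s": trace.time_s, "signal": trace.signal, "reference": trace.reference}
        ).to_csv(out / f"{stem}.csv", index=False)
        sidecar = {
            "c_molar": float(c),
            "shell_m": delta,
            "per_particle_phi_rad": phases.tolist(),
            "ensemble_phi_rad": ens.resultant_phase_rad,
            "ensemble_attenuation": ens.attenuation,
            "trace_metadata": {
                k: v for k, v in trace.metadata.items() if k != "seed"
            }
            | {"seed": trace_spec.seed + i},
        }
        with open(out / f"{stem}.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
        files += [f"{stem}.csv", f"{stem}.json"]

    manifest = {
        "population_seed": population_spec.seed,
        "trace_seed": trace_spec.seed,
        "files": {name: _sha256(out / name) for name in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
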