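"""Run configuration: schema-validated, unit-suffixed, YAML/JSON-loadable.

Every physical quantity carries its unit in the key name; unknown keys are
rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .assay import BindingModel
from .dynamics import OperatingPoint
from .materials import Environment, MagneticMaterial, Nanoprobe

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MaterialConfig(_Strict):
    name: str = "NiFe"
    sigma_s_emu_g: float = Field(88.0, ge=0)
    density_g_cm3: float = Field(8.7, gt=0)

    def to_material(self) -> MagneticMaterial:
        return MagneticMaterial(self.name, self.sigma_s_emu_g, self.density_g_cm3)


class ProbeConfig(_Strict):
    long_axis_nm: float = Field(400.0, gt=0)
    short_axis_nm: float = Field(200.0, gt=0)
    thickness_nm: float = Field(60.0, gt=0)
    magnetic_thickness_nm: float = Field(7.0, gt=0)
    hydro_scale: float = Field(3.0, ge=1)
    hydro_scale_mode: Literal["linear", "volume"] = "linear"
    mu0_Hk_mT: float | None = Field(30.0, gt=0)
    material: MaterialConfig = MaterialConfig()

    def to_probe(self) -> Nanoprobe:
        return Nanoprobe(
            long_axis_m=self.long_axis_nm * 1e-9,
            short_axis_m=self.short_axis_nm * 1e-9,
            thickness_m=self.thickness_nm * 1e-9,
            magnetic_thickness_m=self.magnetic_thickness_nm * 1e-9,
            material=self.material.to_material(),
            hydro_scale=self.hydro_scale,
            hydro_scale_mode=self.hydro_scale_mode,
            mu0_Hk_T=None if self.mu0_Hk_mT is None else self.mu0_Hk_mT * 1e-3,
        )


class EnvironmentConfig(_Strict):
    viscosity_Pa_s: float = Field(1.0e-3, gt=0)
    temperature_K: float = Field(293.15, gt=0)

    def to_environment(self) -> Environment:
        return Environment(self.viscosity_Pa_s, self.temperature_K)


class FieldConfig(_Strict):
    frequency_Hz: float = Field(500.0, ge=0)
    field_mT: float = Field(10.0, gt=0)

    def to_operating_point(self) -> OperatingPoint:
        return OperatingPoint.from_frequency(self.frequency_Hz, self.field_mT * 1e-3)


class PopulationConfig(_Strict):
    lateral_cv: float = Field(0.03, ge=0, lt=0.3)
    thickness_cv: float = Field(0.0, ge=0, lt=0.3)
    count: int = Field(200, ge=1)
    correlated_axes: bool = True


class BindingConfig(_Strict):
    K_d_M: float = Field(1e-9, gt=0)
    delta_max_nm: float = Field(10.0, ge=0)

    def to_model(self) -> BindingModel:
        return BindingModel(K_d_M=self.K_d_M, delta_max_m=self.delta_max_nm * 1e-9)


class TraceConfig(_Strict):
    amplitude: float = Field(4.5, gt=0)  # longitudinal/transversal Q_ext contrast
    offset: float = 0.0
    noise_sigma: float = Field(0.45, ge=0)
    sampling_rate_Hz: float = Field(100e3, gt=0)
    duration_s: float = Field(0.2, gt=0)


class AssayConfig(_Strict):
    concentrations_M: list[float] = Field(
        default_factory=lambda: [0.0, 1e-10, 3e-10, 1e-9, 3e-9, 1e-8]
    )
    n_seeds: int = Field(20, ge=1)
    optical_offset_90deg: bool = True


class RunConfig(_Strict):
    """Full, reproducible description of one run."""

    probe: ProbeConfig = ProbeConfig()
    environment: EnvironmentConfig = EnvironmentConfig()
    field: FieldConfig = FieldConfig()
    population: PopulationConfig = PopulationConfig()
    binding: BindingConfig = BindingConfig()
    trace: TraceConfig = TraceConfig()
    assay: AssayConfig = AssayConfig()
    seed: int = 0
    verbosity: int = Field(0, ge=0, le=2)


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration; missing blocks take defaults."""
    p = Path(path)
    text = p.read_text()
    data = json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.model_validate(data or {})
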