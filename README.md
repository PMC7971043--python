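# phaselag

Physics model and synthetic-assay pipeline for **rotating-field phase-lag
biosensing** with anisotropic magneto-plasmonic nanoprobes.

In a homogeneous (no-wash) immunoassay of this kind, elliptical multilayer
nanoprobes suspended in the sample are rotated in-plane by a magnetic field
and watched in transmission with polarized light. Target molecules captured
on the probe surface enlarge its hydrodynamic volume, increasing the
rotational drag — the probe's orientation lags further behind the field,
and that **phase lag is the assay signal**. The package is written for
people designing or analysing such readouts: it predicts the lag from probe
geometry and fluid properties, simulates the detector signal, and provides
estimators that recover physical parameters from measured lag curves and
dose–response data.

## Model

Three coupled pieces produce the measured lag φ of the optical (long) axis
behind a field of amplitude B = μ₀H rotating at angular frequency ω:

- **Viscous/Brownian lag** (Debye relaxation with Langevin saturation):

  tan α = ω·2τ_B/(2 + ξ·L(ξ)),  ξ = mB/k_BT,  τ_B = 3ηV_hydro/k_BT

- **Internal Stoner–Wohlfarth angle** of the magnetization against the
  shape-anisotropy easy axis (anisotropy field H_K):

  sin 2ϑ = 2(H/H_K)·sin α,  with instability beyond the switching astroid
  h_sw(ψ) = (cos²ᐟ³ψ + sin²ᐟ³ψ)⁻³ᐟ²

- **Measured lag** φ = ϑ + α, read out at twice the drive frequency
  (frequency-doubled optical signal, so φ is defined modulo π) by
  second-harmonic lock-in demodulation.

Synchronous rotation is lost at the critical frequency
ω_c = mB/(6ηV_hydro), where the steady lag reaches π/2; a seeded
time-domain simulator of the overdamped torque balance (with optional
rotational diffusion) covers both regimes. Binding enters as an equilibrium
Langmuir shell δ(c) = δ_max·c/(c + K_d) that grows V_hydro only. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import math
from phaselag import (
    Nanoprobe, Environment, OperatingPoint, BindingModel,
    brownian_time, critical_frequency, measured_phase_lag, dose_response,
)

probe, env = Nanoprobe(), Environment()        # 400x200 nm probe in water
op = OperatingPoint.from_frequency(500.0, 10e-3)  # 500 Hz, 10 mT

tau = brownian_time(env, probe.hydrodynamic_volume_m3)
f_c = critical_frequency(probe, env, 10e-3) / (2 * math.pi)
state = measured_phase_lag(op, probe, env)
print(f"tau_B           = {tau*1e3:.1f} ms")
print(f"critical freq   = {f_c:.0f} Hz")
print(f"phi (measured)  = {math.degrees(state.phi_rad):.1f} deg  [{state.regime}]")

res = dose_response(probe, env, op, BindingModel(K_d_M=1e-9, delta_max_m=10e-9),
                    [0.0, 1e-10, 1e-9, 1e-8])
for c, dphi in zip(res.concentrations_M, res.dphi_rad):
    print(f"c = {c:.0e} M  ->  dphi = {math.degrees(dphi):5.2f} deg")
```

prints

```
tau_B           = 75.4 ms
critical freq   = 878 Hz
phi (measured)  = 39.3 deg  [synchronous]
c = 0e+00 M  ->  dphi =  0.00 deg
c = 1e-10 M  ->  dphi =  1.41 deg
c = 1e-09 M  ->  dphi =  7.68 deg
c = 1e-08 M  ->  dphi = 13.70 deg
```

The default probe rotates synchronously at 500 Hz with a 39.3° lag
(29.6° viscous + 9.6° internal); binding a 1 nM-affinity analyte shifts the
lag by up to ~14° at saturation — the dose–response curve the assay reads.

A CLI covers the same ground from a shell, driven by a YAML/JSON config
with unit-suffixed keys:

```
phaselag phase-curve --fmin 10 --fmax 2000 --points 100 --out curve.csv
phaselag sw --mode astroid --out astroid.csv
phaselag assay --out assay_run/            # full synthetic immunoassay
phaselag fixtures --out dataset/           # traces + ground-truth sidecars
```

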