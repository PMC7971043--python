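# Methods

## Physical model

The package models a homogeneous (no-wash) immunoassay readout in which
anisotropic magneto-plasmonic nanoprobes — flat elliptical multilayer
cylinders, nominally 400 × 200 nm with a 7 nm NiFe layer inside a 60 nm
Au/TiO₂/NiFe/TiO₂/Au stack — are rotated in-plane by a magnetic field of
amplitude μ₀H and angular frequency ω, and observed in transmission with
polarized light. Three coupled pieces produce the observable.

**Viscous (Brownian) lag α.** The magnetization trails the rotating field by
the Debye rotational-relaxation angle

    tan α = ω · 2τ_B / (2 + ξ·L(ξ)),
    ξ = m·B / (k_B·T),   L(ξ) = coth ξ − 1/ξ,   τ_B = 3·η·V_hydro / (k_B·T),

with m the probe moment, B = μ₀H, η the fluid viscosity and V_hydro the
hydrodynamic volume. The Langevin factor ξ·L(ξ) suppresses thermal agitation
at high field; for the reference probe at 10 mT, ξ ≈ 832, so the expression
is within a fraction of a percent of the zero-temperature torque balance.

**Internal Stoner–Wohlfarth angle ϑ.** The probe is treated as
quasi-single-domain with uniaxial shape anisotropy along the long axis
(anisotropy field μ₀H_K, measured ≈ 30 mT). Under the transverse load set by
α, the magnetization rotates off the easy axis to the stable equilibrium of
the reduced energy e(ϑ) = sin²ϑ − 2h·cos(φ − ϑ):

    sin 2ϑ = 2·h·sin α,    h = H/H_K,    ϑ ∈ [−π/4, π/4].

When |2h·sin α| ≥ 1 the easy-axis minimum is gone (the field point crosses
the switching astroid h_sw(ψ) = (cos^{2/3}ψ + sin^{2/3}ψ)^{−3/2}) and the
state is flagged `sw_unstable`; post-switch motion is not simulated. The
marginal equality is flagged unstable deliberately: unsaturated or thermally
agitated probes switch before the ideal threshold.

**Measured lag.** The optical principal axis reports φ = ϑ + α. Because the
transmission signal is invariant under a 180° flip of the particle, the
detector modulates at 2ω and φ is identifiable only modulo π.

**Synchronous/asynchronous transition.** The deterministic torque balance
6ηV_hydro·dθ/dt = mB·sin(ωt − θ) has a synchronous solution only up to

    ω_c = m·B / (6·η·V_hydro),

where the steady lag reaches π/2 (877.5 Hz for the reference probe at
10 mT). Above ω_c the probe slips periodically and advances at a mean rate
below ω. Note the thermal Debye arctan never reaches π/2 at finite ω; the
critical frequency is a property of the deterministic balance, which the
Debye formula approaches at ξ ≫ 1. The package reports both and the
time-domain simulator (Euler–Maruyama, fixed step, optional rotational
diffusion D = k_BT/6ηV_hydro, explicit seed) provides the independent route
used in the tests.

**Assay chain.** Analyte binding is equilibrium Langmuir: shell thickness
δ(c) = δ_max·c/(c + K_d), grown uniformly on all faces before the
hydrodynamic envelope scaling. The shell enters only V_hydro; moment and
anisotropy are untouched. The observable is Δφ(c) = φ(c) − φ(0) against a
zero-analyte reference measured with identical lock-in settings, which makes
the constant 90° optical offset of the instrument geometry cancel exactly.

## Parameters and defaults

| parameter | default | why |
|---|---|---|
| probe axes / stack | 400×200 nm, 60 nm, 7 nm NiFe | reference fabrication geometry |
| σ_s (NiFe) | 88 emu/g | measured specific moment |
| ρ (NiFe) | 8.7 g/cm³ | permalloy handbook value; configurable |
| μ₀H_K | 30 mT (user-set) | measured hard-axis saturation; the ellipsoid-derived fallback (≈ 19 mT for this geometry) is crude for a 7 nm slab and logs a warning |
| hydro factor | 3 on linear dimensions (V ×27) | "dimensions" read geometrically; places f_c ≈ 878 Hz at 10 mT, near the instrument's 900 Hz operating point; a `volume` mode (×3) is available |
| η, T | 1.0 mPa·s, 293.15 K | water at room temperature |
| operating point | 500 Hz, 10 mT | mid-curve on the synchronous branch for the nominal probe at every dose (f_c stays above 500 Hz up to full shell); the instrument's 900 Hz / 5 mT point is asynchronous for this probe model and is therefore not the default |
| lateral size CV | 3 % Gaussian, one scale factor for both axes | imprint-process dispersion; independent-axis mode by flag |
| K_d, δ_max | 1 nM, 10 nm | free synthetic parameters (no reported values); typical antibody affinity and ~one protein layer |
| Q_ext amplitude | 4.5 | longitudinal/transversal extinction contrast of the 5-layer stack, entering only as the trace amplitude |
| trace noise σ | 0.45 (SNR 10) | baseline detector noise for recovery studies |

## Numerical choices

- SI units throughout; the CGS-style anisotropy constant 2πM²ΔN is
  implemented as K = ½μ₀ΔN·M², and ξ uses B = μ₀H.
- Demagnetizing factors of the general ellipsoid via the Carlson R_D
  elliptic integral (axes normalized first); factors sum to 1 to < 1e-9.
- L(ξ): series ξ/3 − ξ³/45 below 1e-3, coth form in between, 1 − 1/ξ above
  40.
- Simulator step: dt ≤ 2π/(50ω) enforced; runs must cover ≥ 20 drive
  periods. Steady lag = circular mean of the wrapped lag over the second
  half; asynchronous regime declared when the mean rotation rate over the
  second half falls below 0.99ω. In the quasi-static SW mode the
  magnetization lag solves α + ϑ(α) = θ_H − θ_p by warm-started fixed-point
  iteration (a contraction for h < 0.5).
- Lock-in: trim to integer drive periods, rectangular window (drive
  frequency exactly known), φ̂ = ½·atan2(Y, X) reported in [0, π);
  quality = coherent fraction of AC power, flagged below 0.05.
- Lag differences are wrapped into (−π/2, π/2]; seed-bootstrap uncertainty
  (default 20 seeds) reported as a standard deviation.
- Fits use lmfit least squares; K_d is fitted as log₁₀K_d since it spans
  decades; ξ and h are held at known values when fitting τ_B (a single lag
  curve constrains them only weakly).

## What the synthetic data does and does not emulate

The generator reproduces: Gaussian lateral size dispersion (aspect-ratio
preserving by default), frequency-doubled traces with additive Gaussian
detector noise, Langmuir endpoint binding, and seeded bit-identical
regeneration. It does not emulate: binding kinetics, particle
agglomeration or interparticle stray fields, the wavelength-resolved
plasmonic spectrum (the extinction contrast is a single amplitude
parameter), multi-domain or vortex magnetization states, shape-dependent
drag corrections beyond the isotropic 6ηV_hydro form, or the reproducible
but unexplained sub-100 Hz lag anomaly seen in experiments. Passing tests
therefore validate the stated physical model and its estimators on data
drawn from that same model family — not instrument-specific artefacts.

A consequence of the model worth flagging: with one scale factor for both
lateral axes and fixed thickness, V_hydro/m — hence the deterministic lag —
is independent of lateral size, so the 3 % lateral CV produces only a tiny
lag dispersion (σ_φ ≈ 0.002° at the reference point, via the thermal ξ
correction). Ensemble dephasing from size dispersion becomes significant
only through thickness variation, uncorrelated axes (via shape anisotropy),
or operation near the critical frequency.

## Problem sizes

Test and verification runs use: simulator steps of 1–4 µs over 0.05–1.5 s
(the critical-point run needs ~0.4 s of simulated time for the slow
algebraic approach to π/2); 100-seed noise ensembles; 40-point lag curves;
populations of 50–10 000 particles; 20-seed assay bootstraps over six
concentrations. These sizes keep every statistical check comfortably
resolved while the full suite runs in well under a minute.

## Known limitations

- The quasi-static SW coupling assumes the magnetization equilibrates
  instantly on the fluid-rotation timescale; no Landau–Lifshitz dynamics.
- The ellipsoid demagnetizing approximation of a thin elliptical cylinder
  underestimates the measured anisotropy field by ~1.6×; the measured value
  should be supplied whenever available.
- No absolute limit of detection is claimed: the noise floor is a synthetic
  parameter, not an instrument model.
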