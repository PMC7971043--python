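"""Brownian/viscous lag, the coupled lag solver, and the rotation simulator."""

import math
from dataclasses import replace

import numpy as np
import pytest

from phaselag import (
    Environment,
    Nanoprobe,
    OperatingPoint,
    brownian_time,
    critical_frequency,
    fit_phase_curve,
    langevin,
    measured_phase_lag,
    phase_lag_curve,
    simulate_rotation,
    thermal_field_parameter,
    viscous_lag,
)
from phaselag.dynamics import phase_lag_model


class TestBrownianTime:
    def test_reference_value(self, probe, env):
        # 3·η·V/(k_B·T) with V = 27x the 400x200x60 nm envelope
        tau = brownian_time(env, probe.hydrodynamic_volume_m3)
        assert tau == pytest.approx(7.55e-2, rel=2e-3)

    def test_linear_in_viscosity_inverse_in_temperature(self, probe, env):
        V = probe.hydrodynamic_volume_m3
        tau = brownian_time(env, V)
        thick = Environment(viscosity_Pa_s=2 * env.viscosity_Pa_s, temperature_K=env.temperature_K)
        hot = Environment(viscosity_Pa_s=env.viscosity_Pa_s, temperature_K=2 * env.temperature_K)
        assert brownian_time(thick, V) == pytest.approx(2 * tau, rel=1e-12)
        assert brownian_time(hot, V) == pytest.approx(tau / 2, rel=1e-12)


class TestLangevin:
    def test_limits_and_reference_point(self):
        assert langevin(0.0) == 0.0
        assert langevin(1.0) == pytest.approx(1.0 / math.tanh(1.0) - 1.0, rel=1e-12)
        assert langevin(1e6) == pytest.approx(1.0, abs=1e-5)

    def test_monotone_increasing_and_continuous_at_branch_points(self):
        x = np.concatenate(
            [np.linspace(0, 2e-3, 100), np.linspace(0.01, 39.9, 100), np.linspace(39.9, 60, 50)]
        )
        y = langevin(x)
        assert np.all(np.diff(y) >= 0)
        # branch seams: series vs direct, direct vs asymptotic (the points
        # straddling each seam differ by 2e-9 in argument, hence ~dL/dx*2e-9)
        assert langevin(1e-3 - 1e-9) == pytest.approx(langevin(1e-3 + 1e-9), abs=1e-9)
        assert langevin(40.0 - 1e-9) == pytest.approx(langevin(40.0 + 1e-9), abs=1e-11)

    def test_negative_argument_rejected(self):
        with pytest.raises(ValueError):
            langevin(-0.1)


class TestViscousLag:
    def test_zero_frequency_zero_lag(self, probe, env):
        assert viscous_lag(OperatingPoint(0.0, 10e-3), probe, env) == 0.0

    def test_small_field_reduces_to_debye_limit(self, probe, env):
        # xi -> 0: tan(alpha) -> omega * tau_B
        op = OperatingPoint.from_frequency(1.0, 1e-12)
        tau = brownian_time(env, probe.hydrodynamic_volume_m3)
        assert math.tan(viscous_lag(op, probe, env)) == pytest.approx(
            op.angular_frequency_rad_s * tau, rel=1e-6
        )

    def test_reference_operating_point(self, probe, env, op500):
        # 500 Hz at 10 mT: xi ~ 832, tan(alpha) ~ 0.569
        assert thermal_field_parameter(op500, probe, env) == pytest.approx(832.0, rel=5e-3)
        alpha = viscous_lag(op500, probe, env)
        assert math.tan(alpha) == pytest.approx(0.569, rel=2e-3)
        assert math.degrees(alpha) == pytest.approx(29.6, abs=0.1)

    def test_large_xi_matches_deterministic_torque_balance(self, probe, env):
        """Thermal (Debye+Langevin) lag must reduce to the zero-temperature
        torque balance sin(alpha) = omega/omega_c when xi >> 1."""
        omega_c = critical_frequency(probe, env, 10e-3)
        for frac in (0.02, 0.05, 0.1):
            op = OperatingPoint(frac * omega_c, 10e-3)
            assert thermal_field_parameter(op, probe, env) > 100
            tan_thermal = math.tan(viscous_lag(op, probe, env))
            tan_det = math.tan(math.asin(frac))
            assert tan_thermal == pytest.approx(tan_det, rel=0.02)


class TestMeasuredPhaseLag:
    def test_rigid_dipole_limit(self, rigid_probe, env, op500):
        st = measured_phase_lag(op500, rigid_probe, env)
        assert st.theta_rad == pytest.approx(0.0, abs=1e-6)
        assert st.phi_rad == pytest.approx(st.alpha_rad, abs=1e-6)

    def test_reference_point_decomposition(self, probe, env, op500):
        st = measured_phase_lag(op500, probe, env)
        assert math.degrees(st.alpha_rad) == pytest.approx(29.6, abs=0.1)
        assert math.degrees(st.theta_rad) == pytest.approx(9.6, abs=0.1)
        assert math.degrees(st.phi_rad) == pytest.approx(39.2, abs=0.15)
        assert st.phi_rad == st.theta_rad + st.alpha_rad
        assert st.regime == "synchronous"

    def test_lag_curve_monotone_and_consistent(self, probe, env):
        df = phase_lag_curve(probe, env, 10e-3, np.linspace(10, 2000, 60))
        assert np.all(np.diff(df["phi_rad"]) > 0)
        assert np.all(np.diff(df["alpha_rad"]) > 0)
        np.testing.assert_allclose(
            df["phi_rad"], df["alpha_rad"] + df["theta_rad"], atol=1e-14
        )
        assert df["near_critical"].iloc[-1]  # 2000 Hz is beyond f_c ~ 878 Hz

    def test_higher_field_shifts_curve_to_higher_frequency(self, probe, env):
        f = np.linspace(10, 800, 40)
        low = phase_lag_curve(probe, env, 5e-3, f)["phi_rad"].to_numpy()
        high = phase_lag_curve(probe, env, 10e-3, f)["phi_rad"].to_numpy()
        assert np.all(low >= high)


class TestCriticalFrequency:
    def test_reference_value(self, probe, env):
        wc = critical_frequency(probe, env, 10e-3)
        assert wc == pytest.approx(5.5e3, rel=0.01)
        assert wc / (2 * math.pi) == pytest.approx(880.0, rel=0.01)

    def test_linear_in_field(self, probe, env):
        assert critical_frequency(probe, env, 20e-3) == pytest.approx(
            2 * critical_frequency(probe, env, 10e-3), rel=1e-12
        )


class TestSimulator:
    def test_static_field_relaxation(self, probe, env):
        op = OperatingPoint(0.0, 10e-3)
        traj = simulate_rotation(
            probe, env, op, duration_s=0.02, dt_s=2e-6, theta0_rad=1.0
        )
        assert abs(traj.theta_p_rad[-1]) < 1e-6
        assert traj.final_lag_rad == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("frac", [0.3, 0.5, 0.9])
    def test_synchronous_lag_matches_algebraic_balance(self, probe, env, frac):
        wc = critical_frequency(probe, env, 10e-3)
        op = OperatingPoint(frac * wc, 10e-3)
        traj = simulate_rotation(probe, env, op, duration_s=0.1, dt_s=1e-6)
        assert traj.regime == "synchronous"
        assert traj.steady_state_lag_rad == pytest.approx(math.asin(frac), abs=1e-3)

    def test_asynchronous_slipping_above_critical(self, probe, env):
        wc = critical_frequency(probe, env, 10e-3)
        op = OperatingPoint(1.2 * wc, 10e-3)
        traj = simulate_rotation(probe, env, op, duration_s=0.2, dt_s=2e-6)
        assert traj.regime == "asynchronous"
        # forward on average, but slower than the drive
        assert 0.0 < traj.mean_rotation_rate_rad_s < 1.2 * wc

    def test_quasistatic_sw_adds_internal_angle(self, probe, env):
        wc = critical_frequency(probe, env, 10e-3)
        op = OperatingPoint(0.5 * wc, 10e-3)
        traj = simulate_rotation(probe, env, op, duration_s=0.1, dt_s=1e-6, mode="sw_quasistatic")
        alpha = math.asin(0.5)
        h = 10e-3 / probe.anisotropy_field_T
        theta = 0.5 * math.asin(2 * h * math.sin(alpha))
        assert traj.steady_state_lag_rad == pytest.approx(alpha + theta, abs=1e-3)

    def test_step_halving_convergence(self, probe, env):
        """First-order convergence of the transient trajectory under step
        halving (the steady state itself is insensitive to dt)."""
        wc = critical_frequency(probe, env, 10e-3)
        op = OperatingPoint(0.6 * wc, 10e-3)

        def theta_at(dt):
            traj = simulate_rotation(
                probe, env, op, duration_s=0.05, dt_s=dt, theta0_rad=1.0
            )
            i = int(round(0.001 / dt))  # mid-transient sample at t = 1 ms
            return traj.theta_p_rad[i]

        ref = theta_at(2.5e-7)
        e_coarse = abs(theta_at(4e-6) - ref)
        e_fine = abs(theta_at(2e-6) - ref)
        assert e_fine < 0.7 * e_coarse
        assert e_fine < 1e-2

    def test_noise_ensemble_mean_recovers_deterministic_lag(self, probe, env):
        wc = critical_frequency(probe, env, 10e-3)
        op = OperatingPoint(0.5 * wc, 10e-3)
        lags = np.array(
            [
                simulate_rotation(
                    probe, env, op, duration_s=0.05, dt_s=4e-6, noise=True, seed=s
                ).steady_state_lag_rad
                for s in range(100)
            ]
        )
        se = lags.std(ddof=1) / math.sqrt(len(lags))
        assert abs(lags.mean() - math.asin(0.5)) < 3 * max(se, 1e-6)

    def test_coarse_step_rejected(self, probe, env, op500):
        with pytest.raises(ValueError, match="too coarse"):
            simulate_rotation(probe, env, op500, duration_s=0.1, dt_s=1e-3)

    def test_short_run_rejected(self, probe, env, op500):
        with pytest.raises(ValueError, match="20 drive periods"):
            simulate_rotation(probe, env, op500, duration_s=0.01, dt_s=1e-6)


class TestParameterRecovery:
    def _curve(self, probe, env, field_T=10e-3, n=40):
        f = np.linspace(50.0, 2000.0, n)
        phi = phase_lag_curve(probe, env, field_T, f)["phi_rad"].to_numpy()
        return f, phi

    def test_tau_b_recovered_noise_free(self, probe, env, op500):
        f, phi = self._curve(probe, env)
        xi = thermal_field_parameter(op500, probe, env)
        h = 10e-3 / probe.anisotropy_field_T
        res = fit_phase_curve(f, phi, xi=xi, h=h)
        truth = brownian_time(env, probe.hydrodynamic_volume_m3)
        assert res.params["tau_B_s"].value == pytest.approx(truth, rel=0.01)

    def test_tau_b_recovered_with_phase_noise(self, probe, env, op500, rng):
        f, phi = self._curve(probe, env)
        noisy = phi + rng.normal(0.0, math.radians(2.0), size=phi.size)
        xi = thermal_field_parameter(op500, probe, env)
        h = 10e-3 / probe.anisotropy_field_T
        res = fit_phase_curve(f, noisy, xi=xi, h=h)
        truth = brownian_time(env, probe.hydrodynamic_volume_m3)
        assert res.params["tau_B_s"].value == pytest.approx(truth, rel=0.10)

    def test_model_function_matches_solver(self, probe, env):
        f = np.linspace(50, 1500, 20)
        tau = brownian_time(env, probe.hydrodynamic_volume_m3)
        op = OperatingPoint.from_frequency(1.0, 10e-3)  # xi is frequency-independent
        xi = thermal_field_parameter(op, probe, env)
        h = 10e-3 / probe.anisotropy_field_T
        direct = phase_lag_curve(probe, env, 10e-3, f)["phi_rad"].to_numpy()
        np.testing.assert_allclose(phase_lag_model(f, tau, xi, h), direct, atol=1e-12)
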