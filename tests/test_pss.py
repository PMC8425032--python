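"""Pre-steady-state isolation, charge integration, Boltzmann fit, turnover."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import FARADAY, GAS_CONSTANT, oracle_boltzmann_fraction
from symportfit import (
    ChargeMovement,
    SolutionCondition,
    StepProtocol,
    ValidationError,
    fit_boltzmann,
    integrate_charge,
    isolate_pss_currents,
    simulate_step_sweeps,
    turnover_number,
)
from symportfit.kinetics import FitError
from symportfit.pss import charge_voltage_analysis
from symportfit.simulate import boltzmann_charge_fraction, pss_tau


def oracle_delta_q(preset, vt, vhold=-50.0):
    return preset.Qmax * (
        oracle_boltzmann_fraction(vt, preset.V05, preset.z, preset.temperature)
        - oracle_boltzmann_fraction(vhold, preset.V05, preset.z, preset.temperature)
    )


class TestIntegrateCharge:
    def test_rectangular_pulse(self):
        t = np.arange(0.0, 10.0 + 0.05, 0.1)
        q = integrate_charge(t, np.full(t.size, -100.0))
        assert q == pytest.approx(-1.0, rel=1e-12)

    def test_exponential_equals_a_tau(self):
        tau, a = 10.0, -100.0
        t = np.arange(0.0, 10 * tau + 0.05, 0.1)
        q = integrate_charge(t, a * np.exp(-t / tau))
        assert q == pytest.approx(a * tau * 1e-3, rel=1e-3)

    def test_refinement_stability(self):
        tau, a = 10.0, -100.0
        coarse = np.arange(0.0, 100.0 + 0.05, 0.1)
        fine = np.arange(0.0, 100.0 + 0.025, 0.05)
        q1 = integrate_charge(coarse, a * np.exp(-coarse / tau))
        q2 = integrate_charge(fine, a * np.exp(-fine / tau))
        assert abs(q1 - q2) < 1e-4 * abs(q1)

    def test_nonuniform_sampling_rejected(self):
        with pytest.raises(ValidationError):
            integrate_charge(np.array([0.0, 1.0, 3.0]), np.array([1.0, 1.0, 1.0]))


class TestIsolation:
    def test_null_transporter_charge_near_zero(self, preset):
        null = dataclasses.replace(preset, Qmax=1e-9)
        protocol = StepProtocol(step_voltages=(-150.0,))
        (sweep,) = simulate_step_sweeps(
            null, protocol, SolutionCondition(pH=5.5), seed=0, noise_sd=0.0
        )
        iso = isolate_pss_currents(sweep)
        assert abs(integrate_charge(iso.time, iso.current)) < 0.02

    @pytest.mark.parametrize("vt", [-150.0, -90.0, 30.0])
    def test_noiseless_tau_slow_matches_preset(self, preset, vt):
        protocol = StepProtocol(step_voltages=(vt,))
        (sweep,) = simulate_step_sweeps(
            preset, protocol, SolutionCondition(pH=5.5), seed=0, noise_sd=0.0
        )
        iso = isolate_pss_currents(sweep)
        assert iso.tau_slow == pytest.approx(pss_tau(preset, vt), rel=0.02)

    def test_end_to_end_charge_matches_boltzmann_within_one_percent(self, preset):
        protocol = StepProtocol()
        sweeps = simulate_step_sweeps(
            preset, protocol, SolutionCondition(pH=5.5), seed=0, noise_sd=0.0
        )
        for m in charge_voltage_analysis(sweeps):
            expected = oracle_delta_q(preset, m.voltage)
            if abs(expected) < 1e-6:
                assert abs(m.charge) < 0.02
            else:
                assert m.charge == pytest.approx(expected, rel=0.01)

    def test_saturating_sugar_suppresses_charge(self, preset):
        """At saturating arabinose the transient charge shrinks by the
        preset suppression factor."""
        protocol = StepProtocol(step_voltages=(-150.0,))
        buffer_cond = SolutionCondition(pH=5.5)
        sat = SolutionCondition(pH=5.5, sugar_name="l-arabinose", sugar_concentration=100.0)
        (b,) = simulate_step_sweeps(preset, protocol, buffer_cond, seed=0, noise_sd=0.0)
        (s,) = simulate_step_sweeps(preset, protocol, sat, seed=0, noise_sd=0.0)
        qb = integrate_charge(*_iso_xy(b))
        qs = integrate_charge(*_iso_xy(s))
        occ = 100.0 / (100.0 + preset.sugars["l-arabinose"].Km)
        assert qs / qb == pytest.approx(1 - preset.pss_sugar_suppression * occ, rel=0.05)

    def test_template_subtraction_recovers_suppressed_fraction(self, preset):
        protocol = StepProtocol(step_voltages=(-150.0,))
        buffer_cond = SolutionCondition(pH=5.5)
        sat = SolutionCondition(pH=5.5, sugar_name="l-arabinose", sugar_concentration=100.0)
        (b,) = simulate_step_sweeps(preset, protocol, buffer_cond, seed=0, noise_sd=0.0)
        (s,) = simulate_step_sweeps(preset, protocol, sat, seed=0, noise_sd=0.0)
        iso = isolate_pss_currents(b, method="template_subtraction", template=s)
        occ = 100.0 / (100.0 + preset.sugars["l-arabinose"].Km)
        expected = oracle_delta_q(preset, -150.0) * preset.pss_sugar_suppression * occ
        assert integrate_charge(iso.time, iso.current) == pytest.approx(expected, rel=0.02)

    def test_template_requires_matching_voltage(self, preset):
        protocol_a = StepProtocol(step_voltages=(-150.0,))
        protocol_b = StepProtocol(step_voltages=(-90.0,))
        (a,) = simulate_step_sweeps(preset, protocol_a, SolutionCondition(pH=5.5), 0, noise_sd=0.0)
        (b,) = simulate_step_sweeps(preset, protocol_b, SolutionCondition(pH=5.5), 0, noise_sd=0.0)
        with pytest.raises(ValidationError):
            isolate_pss_currents(a, method="template_subtraction", template=b)


def _iso_xy(sweep):
    iso = isolate_pss_currents(sweep)
    return iso.time, iso.current


class TestBoltzmannFit:
    T = 293.15

    def _points(self, qhyp=-4.0, qmax=5.897, z=1.0, v05=-20.0, voltages=None):
        voltages = voltages if voltages is not None else np.arange(-150.0, 51.0, 20.0)
        qs = qhyp + qmax * np.array(
            [oracle_boltzmann_fraction(v, v05, z, self.T) for v in voltages]
        )
        return [ChargeMovement(voltage=v, charge=q) for v, q in zip(voltages, qs)]

    def test_thermal_voltage_point(self):
        """One RT/F above the midpoint the occupancy is 1/(1+e) ~ 0.2689."""
        rt_over_f = 1000.0 * GAS_CONSTANT * self.T / FARADAY  # ~25.26 mV
        frac = boltzmann_charge_fraction(-20.0 + rt_over_f, -20.0, 1.0, self.T)
        assert frac == pytest.approx(1.0 / (1.0 + math.e), rel=1e-9)
        assert frac == pytest.approx(0.2689, abs=1e-4)

    def test_midpoint_is_half_occupancy(self):
        fit = fit_boltzmann(self._points(), temperature=self.T)
        mid = fit.Qhyp + fit.Qmax * oracle_boltzmann_fraction(fit.V05, fit.V05, fit.z, self.T)
        assert mid == pytest.approx(fit.Qhyp + fit.Qmax / 2, rel=1e-9)

    def test_noiseless_parameter_recovery(self):
        fit = fit_boltzmann(self._points(), temperature=self.T)
        assert fit.Qhyp == pytest.approx(-4.0, rel=1e-4)
        assert fit.Qmax == pytest.approx(5.897, rel=1e-4)
        assert fit.z == pytest.approx(1.0, rel=1e-4)
        assert fit.V05 == pytest.approx(-20.0, rel=1e-4)
        assert fit.Qdep == pytest.approx(fit.Qhyp + fit.Qmax)

    def test_negative_orientation_reported(self):
        fit = fit_boltzmann(self._points(z=-1.0), temperature=self.T)
        assert fit.z == pytest.approx(-1.0, rel=1e-3)
        assert fit.Qmax == pytest.approx(5.897, rel=1e-3)

    def test_one_sided_voltages_ill_conditioned(self):
        points = self._points(voltages=np.array([20.0, 25.0, 30.0, 35.0, 40.0, 45.0]))
        with pytest.raises(FitError):
            fit_boltzmann(points, temperature=self.T)

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            fit_boltzmann(self._points()[:4], temperature=self.T)


class TestTurnover:
    def test_zero_imax(self):
        assert turnover_number(0.0, 5.897).turnover == 0.0

    def test_published_arabinose_ratio(self):
        result = turnover_number(-355.0, 5.897, sugar="l-arabinose")
        assert result.turnover == pytest.approx(60.2, abs=0.05)

    def test_published_xylose_ratio_consistent(self):
        result = turnover_number(-72.3, 5.897, sugar="d-xylose")
        assert result.turnover == pytest.approx(12.26, abs=0.01)
        assert result.turnover == pytest.approx(12.3, abs=0.05)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_under_expression_scaling(self, c):
        base = turnover_number(-355.0, 5.897)
        scaled = turnover_number(-355.0 * c, 5.897 * c)
        assert scaled.turnover == pytest.approx(base.turnover, rel=1e-9)

    def test_zero_qmax_rejected(self):
        with pytest.raises(ZeroDivisionError):
            turnover_number(-355.0, 0.0)
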