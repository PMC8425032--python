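"""Simulator oracle equivalence, determinism and design arithmetic."""

import dataclasses
import math

import numpy as np
import pytest

from conftest import (
    FARADAY,
    GAS_CONSTANT,
    oracle_boltzmann_fraction,
    oracle_steady_state,
    oracle_transport_current,
)
from symportfit import (
    PerfusionSchedule,
    SolutionCondition,
    StepProtocol,
    ValidationError,
    simulate_cp_table,
    simulate_perfusion_trace,
    simulate_step_sweeps,
    simulate_uptake_counts,
)
from symportfit.qpcr import expression_level, log2_fold_change


def oracle_sweep_current(preset, protocol, condition, vt):
    """Fully independent closed-form evaluation of a noiseless sweep."""
    dt = protocol.sampling_interval
    n = int(round((protocol.pre_duration + protocol.step_duration + protocol.post_duration) / dt)) + 1
    t = np.arange(n) * dt
    onset = protocol.pre_duration
    offset = onset + protocol.step_duration
    vh = protocol.hold_voltage
    sugar, conc = condition.sugar_name, condition.sugar_concentration

    def dq(v_from, v_to):
        q = preset.Qmax * (
            oracle_boltzmann_fraction(v_to, preset.V05, preset.z, preset.temperature)
            - oracle_boltzmann_fraction(v_from, preset.V05, preset.z, preset.temperature)
        )
        if sugar is not None and conc > 0:
            occ = conc / (conc + preset.sugars[sugar].Km)
            q *= 1.0 - preset.pss_sugar_suppression * occ
        return q

    def tau(v):
        x = preset.z * FARADAY * (v - preset.V05) * 1e-3 / (2 * GAS_CONSTANT * preset.temperature)
        return preset.tau0 / math.cosh(x)

    def transients(trel, v_from, v_to):
        out = np.zeros_like(trel)
        dv = v_to - v_from
        if dv:
            out += preset.Cm * dv / preset.tau_cap * np.exp(-trel / preset.tau_cap)
        out += 1000.0 * dq(v_from, v_to) / tau(v_to) * np.exp(-trel / tau(v_to))
        return out

    cur = np.full(n, oracle_steady_state(preset, vh, condition.pH, sugar, conc))
    on = (t >= onset) & (t < offset)
    cur[on] = oracle_steady_state(preset, vt, condition.pH, sugar, conc) + transients(
        t[on] - onset, vh, vt
    )
    post = t >= offset
    cur[post] = oracle_steady_state(preset, vh, condition.pH, sugar, conc) + transients(
        t[post] - offset, vt, vh
    )
    return t, cur


class TestStepSweeps:
    @pytest.mark.parametrize("vt", [-150.0, -90.0, 10.0])
    @pytest.mark.parametrize("with_sugar", [False, True])
    def test_noiseless_matches_closed_form_everywhere(self, preset, vt, with_sugar):
        cond = (
            SolutionCondition(pH=5.5, sugar_name="l-arabinose", sugar_concentration=5.0)
            if with_sugar
            else SolutionCondition(pH=5.5)
        )
        protocol = StepProtocol(step_voltages=(vt,))
        (sweep,) = simulate_step_sweeps(preset, protocol, cond, seed=0, noise_sd=0.0)
        t, expected = oracle_sweep_current(preset, protocol, cond, vt)
        np.testing.assert_array_equal(sweep.time, t)
        np.testing.assert_allclose(sweep.current, expected, atol=1e-6)

    def test_null_model_silent_after_capacitive_settling(self, preset):
        null = dataclasses.replace(preset, Qmax=1e-12, leak_conductance=0.0)
        protocol = StepProtocol(step_voltages=(-150.0,))
        (sweep,) = simulate_step_sweeps(
            null, protocol, SolutionCondition(pH=5.5), seed=0, noise_sd=0.0
        )
        cap_amplitude = abs(null.Cm * (-100.0) / null.tau_cap)
        settle = sweep.step_onset + 5 * null.tau_cap
        late = sweep.current[(sweep.time > settle) & (sweep.time < sweep.step_offset)]
        assert np.max(np.abs(late)) < 0.01 * cap_amplitude

    def test_late_window_mean_equals_steady_state(self, preset, arabinose_5mm):
        protocol = StepProtocol(step_voltages=(-50.0,))
        (sweep,) = simulate_step_sweeps(preset, protocol, arabinose_5mm, seed=0, noise_sd=0.0)
        sl = sweep.step_slice()
        late = sweep.current[sl][-500:]
        expected = oracle_steady_state(preset, -50.0, 5.5, "l-arabinose", 5.0)
        assert np.mean(late) == pytest.approx(expected, abs=0.1)

    def test_same_seed_bit_identical(self, preset, default_protocol, arabinose_5mm):
        a = simulate_step_sweeps(preset, default_protocol, arabinose_5mm, seed=11)
        b = simulate_step_sweeps(preset, default_protocol, arabinose_5mm, seed=11)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.current, y.current)

    def test_unknown_sugar_rejected_before_simulation(self, preset, default_protocol):
        cond = SolutionCondition(pH=5.5, sugar_name="sucrose", sugar_concentration=5.0)
        with pytest.raises(ValidationError):
            simulate_step_sweeps(preset, default_protocol, cond, seed=0)

    @pytest.mark.parametrize("vt", [-150.0, -90.0, 30.0])
    def test_on_transient_integrates_to_boltzmann_charge(self, preset, vt):
        """Integrated PSS transient over the ON step equals the Boltzmann dQ."""
        protocol = StepProtocol(step_voltages=(vt,))
        cond = SolutionCondition(pH=5.5)
        (sweep,) = simulate_step_sweeps(preset, protocol, cond, seed=0, noise_sd=0.0)
        sl = sweep.step_slice()
        t = sweep.time[sl] - sweep.step_onset
        y = sweep.current[sl].copy()
        # remove leak/steady level and the known capacitive component
        y -= oracle_steady_state(preset, vt, 5.5)
        dv = vt - protocol.hold_voltage
        y -= preset.Cm * dv / preset.tau_cap * np.exp(-t / preset.tau_cap)
        q = np.trapezoid(y, t) * 1e-3
        expected = preset.Qmax * (
            oracle_boltzmann_fraction(vt, preset.V05, preset.z, preset.temperature)
            - oracle_boltzmann_fraction(-50.0, preset.V05, preset.z, preset.temperature)
        )
        assert q == pytest.approx(expected, rel=0.01)

    def test_expression_scaling_leaves_turnover_invariant(self, preset):
        """Doubling Imax_ref and Qmax together mimics higher expression; the
        implied turnover |Imax|/|Qmax| must not change."""
        scaled = dataclasses.replace(
            preset,
            Qmax=2 * preset.Qmax,
            sugars={
                name: dataclasses.replace(p, Imax_ref=2 * p.Imax_ref)
                for name, p in preset.sugars.items()
            },
        )
        for p in (preset, scaled):
            ratio = abs(p.sugars["l-arabinose"].Imax_ref) / p.Qmax
            assert ratio == pytest.approx(
                abs(preset.sugars["l-arabinose"].Imax_ref) / preset.Qmax, rel=1e-12
            )
        # and the simulated transporter-borne signal scales accordingly
        protocol = StepProtocol(step_voltages=(-90.0,))
        cond = SolutionCondition(pH=5.5, sugar_name="l-arabinose", sugar_concentration=5.0)
        (base,) = simulate_step_sweeps(preset, protocol, cond, seed=0, noise_sd=0.0)
        (double,) = simulate_step_sweeps(scaled, protocol, cond, seed=0, noise_sd=0.0)
        sl = base.step_slice()
        leak = oracle_steady_state(preset, -90.0, 5.5)
        trel = base.time[sl] - base.step_onset
        cap = preset.Cm * (-40.0) / preset.tau_cap * np.exp(-trel / preset.tau_cap)
        np.testing.assert_allclose(
            double.current[sl] - leak - cap,
            2 * (base.current[sl] - leak - cap),
            atol=1e-8,
        )


class TestPerfusion:
    def test_single_buffer_segment_is_flat_leak(self, preset):
        schedule = PerfusionSchedule(segments=((10.0, SolutionCondition(pH=5.5)),))
        trace = simulate_perfusion_trace(preset, schedule, seed=0, noise_sd=0.0)
        leak = oracle_steady_state(preset, -50.0, 5.5)
        np.testing.assert_allclose(trace.current, leak, atol=1e-9)

    def test_arabinose_plateau_matches_printed_kinetics(self, preset):
        """pH 7.4 -> pH 5.5 -> 5 mM arabinose reaches ~ -355*5/(5+0.207) nA of
        sugar-induced current once the bath has exchanged."""
        ara = SolutionCondition(pH=5.5, sugar_name="l-arabinose", sugar_concentration=5.0)
        schedule = PerfusionSchedule(
            segments=(
                (20.0, SolutionCondition(pH=7.4)),
                (20.0, SolutionCondition(pH=5.5)),
                (20.0, ara),
            ),
            exchange_tau=2.0,
        )
        trace = simulate_perfusion_trace(preset, schedule, seed=0, noise_sd=0.0)
        leak = oracle_steady_state(preset, -50.0, 5.5)
        plateau = trace.current[-10:].mean() - leak
        assert plateau == pytest.approx(-355.0 * 5.0 / 5.207, rel=0.01)

    def test_washout_restores_baseline(self, preset):
        ara = SolutionCondition(pH=5.5, sugar_name="l-arabinose", sugar_concentration=5.0)
        buffer = SolutionCondition(pH=5.5)
        schedule = PerfusionSchedule(
            segments=((10.0, buffer), (10.0, ara), (15.0, buffer)), exchange_tau=2.0
        )
        trace = simulate_perfusion_trace(preset, schedule, seed=0, noise_sd=0.0)
        baseline = trace.current[0]
        # 15 s washout > 5 * exchange_tau
        assert abs(trace.current[-1] - baseline) < 0.01 * abs(
            oracle_transport_current(preset, -50.0, 5.5, "l-arabinose", 5.0)
        )


class TestUptakeCounts:
    DESIGN = [(0.167, 2.0, 1.6, 300.0, 1)]

    def test_zero_vmax_counts_are_blanks(self):
        samples = simulate_uptake_counts(
            0.0, 0.102, self.DESIGN, blank_mean=100.0, seed=1, noiseless=True
        )
        assert all(s.cpm == 100.0 and s.blank_cpm == 100.0 for s in samples)

    def test_half_saturation_exact(self):
        samples = simulate_uptake_counts(
            1.0, 0.5, [(0.5, 2.0, 1.0, 100.0, 1)], blank_mean=0.0, seed=1, noiseless=True
        )
        # S = Km: net cpm = 0.5 * Vmax * od_to_cdw * od * t * sa
        assert samples[0].cpm == pytest.approx(0.5 * 1.0 * 0.252 * 1.0 * 2.0 * 100.0)

    def test_published_design_net_counts(self):
        """Vmax=1.49, Km=0.102, S=0.167 mM, 1.6 OD, 2 min, 300 cpm/nmol -> ~223.8 net cpm."""
        samples = simulate_uptake_counts(
            1.49, 0.102, self.DESIGN, blank_mean=100.0, seed=1, noiseless=True
        )
        net = samples[0].cpm - samples[0].blank_cpm
        assert net == pytest.approx(1.49 * (0.167 / 0.269) * 0.252 * 1.6 * 2.0 * 300.0, rel=1e-6)
        assert net == pytest.approx(223.8, abs=0.2)

    def test_determinism_and_poisson_noise(self):
        a = simulate_uptake_counts(1.49, 0.102, self.DESIGN, 100.0, seed=5)
        b = simulate_uptake_counts(1.49, 0.102, self.DESIGN, 100.0, seed=5)
        assert [s.cpm for s in a] == [s.cpm for s in b]
        assert all(float(s.cpm).is_integer() for s in a)

    def test_negative_design_rejected(self):
        with pytest.raises(ValidationError):
            simulate_uptake_counts(1.0, 0.1, [(-1.0, 2, 1, 100, 1)], 100.0, seed=1)


class TestCpTable:
    def test_sd_zero_level_one_equals_reference_mean(self):
        (rec,) = simulate_cp_table({"cond": 1.0}, [20.0, 22.0], sd=0.0, seed=1)
        assert rec.target_cp == pytest.approx(21.0)

    def test_designed_fold_change_recovered(self):
        records = simulate_cp_table(
            {"ara": 2.0**8.12, "glc": 1.0}, [20.0, 22.0], sd=0.0, seed=1
        )
        by = {r.condition: expression_level(r) for r in records}
        assert log2_fold_change(by["ara"], by["glc"]) == pytest.approx(8.12, abs=1e-12)

    def test_same_seed_identical(self):
        a = simulate_cp_table({"x": 2.0}, [20.0], sd=0.4, seed=9, replicates=3)
        b = simulate_cp_table({"x": 2.0}, [20.0], sd=0.4, seed=9, replicates=3)
        assert [(r.target_cp, tuple(r.reference_cps)) for r in a] == [
            (r.target_cp, tuple(r.reference_cps)) for r in b
        ]

    def test_nonpositive_level_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cp_table({"x": 0.0}, [20.0], sd=0.0, seed=1)
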