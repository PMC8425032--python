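"""Synthetic TEVC, perfusion, uptake-count and qPCR data generators.

No raw recordings are deposited for the Trire2_104072 oocyte experiments,
so this module is the stand-in data source for the whole analysis chain.
A simulated voltage-step sweep is the sum of four components:

* ohmic leak,  g_leak * (V - E_leak);
* a capacitive settling transient, amplitude Cm*dV/tau_cap decaying with
  tau_cap, carrying total charge Cm*dV;
* a pre-steady-state (PSS) transient of the empty transporter: total charge
  dQ = Q(Vt) - Q(Vhold) from the two-state Boltzmann charge distribution,
  relaxing mono-exponentially with the bell-shaped
  tau(V) = tau0 / cosh(zF(V - V05)/(2RT)), and suppressed by sugar in
  proportion to Michaelis–Menten site occupancy;
* the steady-state symport current
  Imax_ref * scale(V) * [S]/([S]+Km) * hill([H+]) with the proton Hill
  factor normalized to 1 at the preset's reference pH, so Imax_ref is the
  saturating-sugar current at the reference voltage and pH.

Gaussian current noise (i.i.d. per sample) is added last.  Every stochastic
output is a pure function of its inputs and the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import FARADAY, GAS_CONSTANT
from .trace_model import (
    CpRecord,
    SolutionCondition,
    SweepTrace,
    TransporterPreset,
    UptakeSample,
    ValidationError,
)

__all__ = [
    "StepProtocol",
    "PerfusionSchedule",
    "steady_state_current",
    "transport_current",
    "boltzmann_charge_fraction",
    "pss_tau",
    "simulate_step_sweeps",
    "simulate_perfusion_trace",
    "simulate_uptake_counts",
    "simulate_cp_table",
]

DEFAULT_STEP_VOLTAGES = tuple(float(v) for v in range(-150, 51, 20))


@dataclass(frozen=True)
class StepProtocol:
    """Voltage-step protocol: hold, then 200 ms steps over a voltage range."""

    hold_voltage: float = -50.0  # mV
    step_voltages: tuple[float, ...] = DEFAULT_STEP_VOLTAGES
    step_duration: float = 200.0  # ms
    pre_duration: float = 20.0  # ms at hold before the step
    post_duration: float = 50.0  # ms at hold after the step
    sampling_interval: float = 0.1  # ms

    def __post_init__(self) -> None:
        if self.step_duration <= 0:
            raise ValidationError("step_duration must be > 0")
        if not self.step_voltages:
            raise ValidationError("step_voltages must be non-empty")
        if self.sampling_interval <= 0:
            raise ValidationError("sampling_interval must be > 0")


@dataclass(frozen=True)
class PerfusionSchedule:
    """Ordered bath-exchange schedule at a fixed holding potential."""

    segments: tuple[tuple[float, SolutionCondition], ...]  # (duration s, solution)
    exchange_tau: float = 2.0  # s, bath-exchange relaxation time
    sampling_interval: float = 10.0  # ms

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("schedule needs at least one segment")
        if any(d <= 0 for d, _ in self.segments):
            raise ValidationError("segment durations must be > 0")
        if self.exchange_tau <= 0:
            raise ValidationError("exchange_tau must be > 0")


# ---------------------------------------------------------------------------
# closed-form model pieces
# ---------------------------------------------------------------------------


def _hill_factor(preset: TransporterPreset, pH: float) -> float:
    """Proton activation, normalized to 1 at the preset reference pH."""

    def h(conc_nM: float) -> float:
        cn = conc_nM**preset.hill_n_H
        return cn / (cn + preset.K05_H**preset.hill_n_H)

    return h(10.0 ** (9.0 - pH)) / h(10.0 ** (9.0 - preset.reference_pH))


def transport_current(
    preset: TransporterPreset, voltage: float, condition: SolutionCondition
) -> float:
    """Steady-state sugar-induced symport current in nA (0 without sugar)."""
    if condition.sugar_name is None or condition.sugar_concentration == 0.0:
        return 0.0
    params = preset.sugar(condition.sugar_name)
    s = condition.sugar_concentration
    occupancy = s / (s + params.Km)
    return (
        params.Imax_ref
        * preset.voltage_scale(voltage)
        * occupancy
        * _hill_factor(preset, condition.pH)
    )


def _leak(preset: TransporterPreset, voltage: float) -> float:
    return preset.leak_conductance * (voltage - preset.leak_reversal)


def steady_state_current(
    preset: TransporterPreset, voltage: float, condition: SolutionCondition
) -> float:
    """Total steady-state current (leak + transport) in nA."""
    return _leak(preset, voltage) + transport_current(preset, voltage, condition)


def boltzmann_charge_fraction(
    voltage: float, V05: float, z: float, temperature: float
) -> float:
    """Mobile-charge occupancy (Q - Qhyp)/Qmax = 1/(1 + exp[zF(V-V05)/RT])."""
    x = z * FARADAY * (voltage - V05) * 1e-3 / (GAS_CONSTANT * temperature)
    return 1.0 / (1.0 + math.exp(x))


def pss_tau(preset: TransporterPreset, voltage: float) -> float:
    """Bell-shaped PSS relaxation time tau0/cosh(zF(V-V05)/(2RT)), in ms."""
    x = (
        preset.z
        * FARADAY
        * (voltage - preset.V05)
        * 1e-3
        / (2.0 * GAS_CONSTANT * preset.temperature)
    )
    return preset.tau0 / math.cosh(x)


def _pss_delta_q(
    preset: TransporterPreset, v_from: float, v_to: float, condition: SolutionCondition
) -> float:
    """Charge moved by a step v_from -> v_to, in nC, including sugar suppression."""
    dq = preset.Qmax * (
        boltzmann_charge_fraction(v_to, preset.V05, preset.z, preset.temperature)
        - boltzmann_charge_fraction(v_from, preset.V05, preset.z, preset.temperature)
    )
    if condition.sugar_name is not None and condition.sugar_concentration > 0:
        params = preset.sugar(condition.sugar_name)
        occupancy = condition.sugar_concentration / (
            condition.sugar_concentration + params.Km
        )
        dq *= 1.0 - preset.pss_sugar_suppression * occupancy
    return dq


def _step_transients(
    t: np.ndarray,
    preset: TransporterPreset,
    v_from: float,
    v_to: float,
    condition: SolutionCondition,
) -> np.ndarray:
    """Capacitive plus PSS relaxation currents after a jump at t=0 (t in ms, >= 0)."""
    dv = v_to - v_from
    out = np.zeros_like(t)
    if dv != 0.0:
        # nF*mV/ms = nA; total capacitive charge Cm*dV (pC) = 1e-3*Cm*dV nC
        out += (preset.Cm * dv / preset.tau_cap) * np.exp(-t / preset.tau_cap)
    dq = _pss_delta_q(preset, v_from, v_to, condition)
    if dq != 0.0:
        tau = pss_tau(preset, v_to)
        # nC/ms = uA, hence the factor 1000 to express the current in nA
        out += 1000.0 * (dq / tau) * np.exp(-t / tau)
    return out


# ---------------------------------------------------------------------------
# sweep simulators
# ---------------------------------------------------------------------------


def simulate_step_sweeps(
    preset: TransporterPreset,
    protocol: StepProtocol,
    condition: SolutionCondition,
    seed: int,
    oocyte_id: str = "sim",
    noise_sd: Optional[float] = None,
) -> list[SweepTrace]:
    """Simulate one sweep per protocol step voltage.

    ``noise_sd`` overrides the preset's Gaussian current-noise standard
    deviation (pass 0 for a noiseless run).  The same
    (preset, protocol, condition, seed) always yields bit-identical traces.
    """
    if condition.sugar_name is not None:
        preset.sugar(condition.sugar_name)  # fail early on unknown sugar
    sd = preset.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    dt = protocol.sampling_interval
    total = protocol.pre_duration + protocol.step_duration + protocol.post_duration
    n = int(round(total / dt)) + 1
    t = np.arange(n) * dt
    onset = protocol.pre_duration
    offset = protocol.pre_duration + protocol.step_duration
    vh = protocol.hold_voltage

    sweeps = []
    for vt in protocol.step_voltages:
        current = np.full(n, steady_state_current(preset, vh, condition))
        on = t >= onset
        current[on] = steady_state_current(preset, vt, condition)
        current[on] += _step_transients(t[on] - onset, preset, vh, vt, condition)
        post = t >= offset
        current[post] = steady_state_current(preset, vh, condition)
        current[post] += _step_transients(t[post] - offset, preset, vt, vh, condition)
        if sd > 0:
            current = current + rng.normal(0.0, sd, size=n)
        sweeps.append(
            SweepTrace(
                time=t.copy(),
                current=current,
                sampling_interval=dt,
                hold_voltage=vh,
                step_voltage=vt,
                step_onset=onset,
                step_offset=offset,
                solution=condition,
                oocyte_id=oocyte_id,
                seed=seed,
            )
        )
    return sweeps


def simulate_perfusion_trace(
    preset: TransporterPreset,
    schedule: PerfusionSchedule,
    hold_voltage: float = -50.0,
    seed: int = 0,
    oocyte_id: str = "sim",
    noise_sd: Optional[float] = None,
) -> SweepTrace:
    """Simulate a continuous recording at a fixed hold during bath exchanges.

    The current starts at the steady state of the first segment and relaxes
    exponentially (time constant ``exchange_tau``) toward each subsequent
    segment's steady state, emulating finite bath exchange.
    """
    sd = preset.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    dt = schedule.sampling_interval
    tau_ms = schedule.exchange_tau * 1000.0
    total_ms = sum(d for d, _ in schedule.segments) * 1000.0
    n = int(round(total_ms / dt)) + 1
    t = np.arange(n) * dt
    current = np.empty(n)

    level = steady_state_current(preset, hold_voltage, schedule.segments[0][1])
    seg_start = 0.0
    for duration_s, cond in schedule.segments:
        target = steady_state_current(preset, hold_voltage, cond)
        seg_end = seg_start + duration_s * 1000.0
        mask = (t >= seg_start - 1e-9) & (t < seg_end)
        current[mask] = target + (level - target) * np.exp(-(t[mask] - seg_start) / tau_ms)
        level = target + (level - target) * math.exp(-(seg_end - seg_start) / tau_ms)
        seg_start = seg_end
    current[-1] = level
    if sd > 0:
        current = current + rng.normal(0.0, sd, size=n)
    last_cond = schedule.segments[-1][1]
    return SweepTrace(
        time=t,
        current=current,
        sampling_interval=dt,
        hold_voltage=hold_voltage,
        step_voltage=hold_voltage,
        step_onset=0.0,
        step_offset=float(t[-1]),
        solution=last_cond,
        oocyte_id=oocyte_id,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# uptake-count and qPCR simulators
# ---------------------------------------------------------------------------


def simulate_uptake_counts(
    true_Vmax: float,
    true_Km: float,
    design: Sequence[tuple[float, float, float, float, int]],
    blank_mean: float,
    seed: int,
    od_to_cdw: float = 0.252,
    pH: float = 6.5,
    sugar_name: str = "l-arabinose",
    strain: str = "strain",
    noiseless: bool = False,
) -> list[UptakeSample]:
    """Simulate scintillation counts for a zero-trans uptake assay.

    ``design`` rows are (concentration mM, reaction time min, OD units,
    specific activity cpm/nmol, replicates).  The expected net signal per
    sample is ``Vmax*S/(S+Km) * od_to_cdw * od * time * sa`` cpm; observed
    counts add a Poisson blank (unspecific filter binding) and Poisson
    counting noise on the signal.  Each sample also carries an independently
    drawn blank measurement for subtraction.  With ``noiseless=True`` counts
    equal their expectations exactly.
    """
    if not design:
        raise ValidationError("design must be non-empty")
    if true_Vmax < 0 or true_Km <= 0 or blank_mean < 0:
        raise ValidationError("Vmax and blank_mean must be >= 0 and Km > 0")
    rng = np.random.default_rng(seed)
    samples = []
    for conc, time_min, od, sa, reps in design:
        if min(conc, time_min, od, sa) < 0 or reps < 1:
            raise ValidationError("design values must be non-negative, replicates >= 1")
        cond = SolutionCondition(pH=pH, sugar_name=sugar_name, sugar_concentration=conc)
        net = true_Vmax * conc / (conc + true_Km) * od_to_cdw * od * time_min * sa
        for _ in range(int(reps)):
            if noiseless:
                cpm, blank = blank_mean + net, blank_mean
            else:
                cpm = float(rng.poisson(blank_mean) + rng.poisson(net))
                blank = float(rng.poisson(blank_mean))
            samples.append(
                UptakeSample(
                    cpm=cpm,
                    blank_cpm=blank,
                    reaction_time=time_min,
                    od_units=od,
                    specific_activity=sa,
                    condition=cond,
                    strain=strain,
                )
            )
    return samples


def simulate_cp_table(
    design: dict[str, float],
    reference_cp_means: Sequence[float],
    sd: float,
    seed: int,
    strain: str = "parental",
    replicates: int = 1,
) -> list[CpRecord]:
    """Simulate qPCR crossing points for given true expression levels.

    ``design`` maps condition label -> true expression level (2**-dCp).
    Reference-gene Cp values are drawn around their stated means with
    Gaussian sd; the target Cp is the reference mean minus log2(level) plus
    Gaussian noise.  sd=0 reproduces the design exactly.
    """
    if not reference_cp_means:
        raise ValidationError("at least one reference gene mean is required")
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for condition, level in design.items():
        if level <= 0:
            raise ValidationError(f"expression level for {condition!r} must be > 0")
        for _ in range(int(replicates)):
            refs = [m + rng.normal(0.0, sd) if sd > 0 else m for m in reference_cp_means]
            target = float(np.mean(refs)) - math.log2(level)
            if sd > 0:
                target += rng.normal(0.0, sd)
            records.append(
                CpRecord(
                    target_cp=target,
                    reference_cps=refs,
                    condition=condition,
                    strain=strain,
                )
            )
    return records
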