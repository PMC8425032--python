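"""End-to-end recovery experiments for the packaged Trire2_104072 presets.

Each function here runs a complete simulated experiment — generate sweeps
or counts from a ground-truth preset, push them through the analysis chain
— and returns the fitted constants.  :func:`reproduce_all` bundles the
whole characterization: substrate kinetics for L-arabinose and D-xylose,
proton (Hill) kinetics, the pre-steady-state charge/turnover pipeline,
yeast uptake kinetics and the qPCR fold-change round trip.

Experiments use three independent simulated oocytes (or assay runs), i.e.
three seeds, matching the replication of a typical TEVC characterization.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import qpcr
from .kinetics import fit_hill, fit_michaelis_menten
from .pss import charge_voltage_analysis, fit_boltzmann, turnover_number
from .simulate import (
    StepProtocol,
    simulate_cp_table,
    simulate_step_sweeps,
    simulate_uptake_counts,
)
from .trace_model import (
    BoltzmannFit,
    HillFit,
    MMFit,
    SolutionCondition,
    TransporterPreset,
    UptakePreset,
    get_preset,
    get_uptake_preset,
)
from .traceproc import build_iv_curve
from .uptake import fit_uptake_kinetics

__all__ = [
    "ARABINOSE_CONCENTRATIONS",
    "XYLOSE_CONCENTRATIONS",
    "PH_SERIES",
    "UPTAKE_CONCENTRATIONS",
    "sugar_kinetics_experiment",
    "proton_kinetics_experiment",
    "charge_movement_experiment",
    "uptake_kinetics_experiment",
    "qpcr_roundtrip",
    "reproduce_all",
]

# concentration series of the simulated experiments (mM); both bracket the
# respective Km by more than an order of magnitude on each side
ARABINOSE_CONCENTRATIONS = (0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0)
XYLOSE_CONCENTRATIONS = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0)
PH_SERIES = (5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0, 8.5, 9.0)
# uptake assay design: L-arabinose mM, 2 min reactions, 1.6 OD, 300 cpm/nmol
UPTAKE_CONCENTRATIONS = (0.02, 0.05, 0.1, 0.2, 0.5, 1.0)

_MOD = 2**31 - 1


def _subseed(seed: int, k: int) -> int:
    """Distinct deterministic child seed for the k-th simulation of a run."""
    return (seed * 1000003 + 7919 * k + 1) % _MOD


def sugar_kinetics_experiment(
    sugar: str,
    concentrations: Sequence[float],
    seed: int,
    preset: Optional[TransporterPreset] = None,
    pH: float = 5.5,
    voltage: float = -50.0,
) -> MMFit:
    """One simulated oocyte concentration series at a fixed voltage -> MM fit.

    For every concentration a sugar sweep and a sugar-free (buffer) sweep
    are simulated at the clamped voltage, buffer-subtracted, and the
    steady-state currents fitted to the Michaelis–Menten model.
    """
    preset = preset or get_preset()
    protocol = StepProtocol(hold_voltage=voltage, step_voltages=(voltage,))
    currents = []
    for k, conc in enumerate(concentrations):
        sugar_cond = SolutionCondition(pH=pH, sugar_name=sugar, sugar_concentration=conc)
        buffer_cond = SolutionCondition(pH=pH)
        sugar_sweeps = simulate_step_sweeps(
            preset, protocol, sugar_cond, seed=_subseed(seed, 2 * k)
        )
        buffer_sweeps = simulate_step_sweeps(
            preset, protocol, buffer_cond, seed=_subseed(seed, 2 * k + 1)
        )
        iv = build_iv_curve(sugar_sweeps, buffer_sweeps)
        currents.append(iv.current_at(voltage))
    return fit_michaelis_menten(np.asarray(concentrations), np.asarray(currents))


def proton_kinetics_experiment(
    seed: int,
    preset: Optional[TransporterPreset] = None,
    sugar: str = "l-arabinose",
    sugar_concentration: float = 5.0,
    ph_values: Sequence[float] = PH_SERIES,
    voltage: float = -50.0,
) -> HillFit:
    """One simulated pH series at saturating sugar -> Hill fit in [H+]."""
    preset = preset or get_preset()
    protocol = StepProtocol(hold_voltage=voltage, step_voltages=(voltage,))
    protons, currents = [], []
    for k, ph in enumerate(ph_values):
        sugar_cond = SolutionCondition(
            pH=ph, sugar_name=sugar, sugar_concentration=sugar_concentration
        )
        buffer_cond = SolutionCondition(pH=ph)
        sugar_sweeps = simulate_step_sweeps(
            preset, protocol, sugar_cond, seed=_subseed(seed, 1000 + 2 * k)
        )
        buffer_sweeps = simulate_step_sweeps(
            preset, protocol, buffer_cond, seed=_subseed(seed, 1000 + 2 * k + 1)
        )
        iv = build_iv_curve(sugar_sweeps, buffer_sweeps)
        protons.append(sugar_cond.proton_concentration)
        currents.append(iv.current_at(voltage))
    return fit_hill(np.asarray(protons), np.asarray(currents))


def charge_movement_experiment(
    seed: int,
    preset: Optional[TransporterPreset] = None,
    pH: float = 5.5,
) -> BoltzmannFit:
    """One simulated sugar-free step protocol -> PSS isolation -> Boltzmann fit."""
    preset = preset or get_preset()
    protocol = StepProtocol()
    condition = SolutionCondition(pH=pH)
    sweeps = simulate_step_sweeps(preset, protocol, condition, seed=_subseed(seed, 5000))
    movements = charge_voltage_analysis(sweeps)
    return fit_boltzmann(movements, temperature=preset.temperature)


def uptake_kinetics_experiment(
    seed: int,
    preset: Optional[UptakePreset] = None,
    concentrations: Sequence[float] = UPTAKE_CONCENTRATIONS,
    replicates: int = 3,
    reaction_time: float = 2.0,
    od_units: float = 1.6,
    specific_activity: float = 300.0,
    blank_mean: float = 100.0,
) -> MMFit:
    """One simulated scintillation assay -> rates -> MM fit (Vmax, Km)."""
    preset = preset or get_uptake_preset()
    design = [
        (c, reaction_time, od_units, specific_activity, replicates)
        for c in concentrations
    ]
    samples = simulate_uptake_counts(
        true_Vmax=preset.Vmax,
        true_Km=preset.Km,
        design=design,
        blank_mean=blank_mean,
        seed=_subseed(seed, 9000),
        od_to_cdw=preset.od_to_cdw,
        pH=preset.pH,
    )
    fit, _ = fit_uptake_kinetics(samples, od_to_cdw=preset.od_to_cdw)
    return fit


def qpcr_roundtrip(designed_log2_fc: float = 8.12) -> float:
    """Noise-free ddCp round trip: simulate Cp values encoding a designed
    log2 fold-change between inducing and repressing carbon sources and
    recover it through the expression analysis."""
    records = simulate_cp_table(
        design={"l-arabinose": 2.0**designed_log2_fc, "d-glucose": 1.0},
        reference_cp_means=(20.0, 22.0),
        sd=0.0,
        seed=0,
    )
    by_cond = {r.condition: qpcr.expression_level(r) for r in records}
    return qpcr.log2_fold_change(by_cond["l-arabinose"], by_cond["d-glucose"])


def reproduce_all(seed: int = 1, n_oocytes: int = 3) -> dict[str, float]:
    """Full recovery suite over ``n_oocytes`` independent seeds.

    Returns mean fitted constants keyed by quantity:

    * ``Km_arabinose_mM``, ``Imax_arabinose_nA`` — oocyte MM kinetics,
    * ``Km_xylose_mM``, ``Imax_xylose_nA``,
    * ``K05_proton_nM``, ``hill_n_proton``,
    * ``Qmax_nC``, ``turnover_arabinose_per_s``, ``turnover_xylose_per_s``
      (per-seed pairing of Imax with Qmax, then averaged),
    * ``uptake_Km_mM``, ``uptake_Vmax_nmol_per_mg_min``,
    * ``qpcr_log2_fc``.
    """
    seeds = [(seed + i) % _MOD for i in range(n_oocytes)]
    ara = [sugar_kinetics_experiment("l-arabinose", ARABINOSE_CONCENTRATIONS, s) for s in seeds]
    xyl = [sugar_kinetics_experiment("d-xylose", XYLOSE_CONCENTRATIONS, s) for s in seeds]
    hill = [proton_kinetics_experiment(s) for s in seeds]
    boltz = [charge_movement_experiment(s) for s in seeds]
    upt = [uptake_kinetics_experiment(s) for s in seeds]

    turnover_ara = [
        turnover_number(a.Imax, b.Qmax, sugar="l-arabinose").turnover
        for a, b in zip(ara, boltz)
    ]
    turnover_xyl = [
        turnover_number(x.Imax, b.Qmax, sugar="d-xylose").turnover
        for x, b in zip(xyl, boltz)
    ]
    mean = lambda xs: float(np.mean(xs))
    return {
        "Km_arabinose_mM": mean([f.Km for f in ara]),
        "Imax_arabinose_nA": mean([f.Imax for f in ara]),
        "Km_xylose_mM": mean([f.Km for f in xyl]),
        "Imax_xylose_nA": mean([f.Imax for f in xyl]),
        "K05_proton_nM": mean([f.K05 for f in hill]),
        "hill_n_proton": mean([f.hill_n for f in hill]),
        "Qmax_nC": mean([abs(f.Qmax) for f in boltz]),
        "turnover_arabinose_per_s": mean(turnover_ara),
        "turnover_xylose_per_s": mean(turnover_xyl),
        "uptake_Km_mM": mean([f.Km for f in upt]),
        "uptake_Vmax_nmol_per_mg_min": mean([f.Imax for f in upt]),
        "qpcr_log2_fc": qpcr_roundtrip(),
    }
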