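"""Radiotracer zero-trans uptake analysis.

Rates come straight from scintillation counts:

    rate_per_OD  = (cpm - blank_cpm) / (time * OD * specific_activity)
    rate_per_CDW = rate_per_OD / 0.252  [mg cell dry weight per OD unit]

in nmol min^-1 OD^-1 and nmol min^-1 mg_CDW^-1.  Negative net counts
(sample below blank) are clamped to zero and flagged — uptake is physically
non-negative and blanks measure unspecific binding of the sugar to the cell
surface.  Kinetics are Michaelis–Menten fits to replicate-averaged rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import OD_TO_CDW_DEFAULT
from .kinetics import fit_michaelis_menten
from .trace_model import MMFit, UptakeRate, UptakeSample, ValidationError

__all__ = [
    "compute_uptake_rate",
    "specific_uptake_rate",
    "inhibition_percent",
    "LinearityReport",
    "fit_uptake_kinetics",
]


def compute_uptake_rate(
    sample: UptakeSample, od_to_cdw: float = OD_TO_CDW_DEFAULT
) -> UptakeRate:
    """Uptake rate of one sample, per OD unit and per mg cell dry weight."""
    if od_to_cdw <= 0:
        raise ValidationError("od_to_cdw must be > 0")
    if sample.od_units <= 0:
        raise ValidationError("od_units must be > 0 to compute a rate")
    net = sample.cpm - sample.blank_cpm
    clamped = net < 0
    if clamped:
        warnings.warn(
            f"net counts negative ({net:.1f} cpm); clamped to 0", stacklevel=2
        )
        net = 0.0
    per_od = net / (sample.reaction_time * sample.od_units * sample.specific_activity)
    return UptakeRate(
        rate_per_od=per_od,
        rate_per_cdw=per_od / od_to_cdw,
        od_to_cdw=od_to_cdw,
        clamped=clamped,
    )


def specific_uptake_rate(strain_rate: UptakeRate, control_rate: UptakeRate) -> UptakeRate:
    """Strain rate minus empty-plasmid control rate (may be negative, flagged)."""
    if strain_rate.od_to_cdw != control_rate.od_to_cdw:
        raise ValidationError("strain and control rates use different OD->CDW factors")
    per_od = strain_rate.rate_per_od - control_rate.rate_per_od
    return UptakeRate(
        rate_per_od=per_od,
        rate_per_cdw=per_od / strain_rate.od_to_cdw,
        od_to_cdw=strain_rate.od_to_cdw,
        clamped=per_od < 0,
    )


def inhibition_percent(rate_without: float, rate_with: float) -> float:
    """Percent inhibition by a competing sugar: 100*(1 - rate_with/rate_without)."""
    if rate_without <= 0:
        raise ValidationError("uninhibited rate must be > 0")
    return 100.0 * (1.0 - rate_with / rate_without)


@dataclass
class LinearityReport:
    """Two-timepoint linearity check per concentration.

    ``ratio`` is rate(t2)/rate(t1); concentrations where it deviates from 1
    by more than ``tolerance`` are flagged as outside the linear range.
    """

    concentrations: list[float] = field(default_factory=list)
    ratios: list[float] = field(default_factory=list)
    flagged: list[float] = field(default_factory=list)
    tolerance: float = 0.20


def fit_uptake_kinetics(
    samples: Sequence[UptakeSample],
    od_to_cdw: float = OD_TO_CDW_DEFAULT,
    linearity_pairs: Optional[Sequence[tuple[UptakeSample, UptakeSample]]] = None,
    linearity_tolerance: float = 0.20,
) -> tuple[MMFit, LinearityReport]:
    """Michaelis–Menten fit of uptake rates versus substrate concentration.

    Technical replicates (same concentration) are averaged before the fit,
    so the fitted ``Imax`` is Vmax in nmol min^-1 mg_CDW^-1 and ``Km`` in
    mM.  Optional ``linearity_pairs`` are (earlier, later) timepoint samples
    at matched concentrations; their rate ratio should be ~1 if uptake is
    still in the initial-rate regime.
    """
    if not samples:
        raise ValidationError("no uptake samples supplied")
    by_conc: dict[float, list[float]] = {}
    for s in samples:
        rate = compute_uptake_rate(s, od_to_cdw=od_to_cdw)
        by_conc.setdefault(s.condition.sugar_concentration, []).append(rate.rate_per_cdw)
    concs = np.array(sorted(by_conc))
    rates = np.array([np.mean(by_conc[c]) for c in concs])
    fit = fit_michaelis_menten(concs, rates)

    report = LinearityReport(tolerance=linearity_tolerance)
    for first, second in linearity_pairs or ():
        if first.condition.sugar_concentration != second.condition.sugar_concentration:
            raise ValidationError("linearity pair concentrations differ")
        r1 = compute_uptake_rate(first, od_to_cdw=od_to_cdw).rate_per_cdw
        r2 = compute_uptake_rate(second, od_to_cdw=od_to_cdw).rate_per_cdw
        if r1 <= 0:
            raise ValidationError("first-timepoint rate must be > 0 for linearity check")
        ratio = r2 / r1
        conc = first.condition.sugar_concentration
        report.concentrations.append(conc)
        report.ratios.append(ratio)
        if abs(ratio - 1.0) > linearity_tolerance:
            report.flagged.append(conc)
    return fit, report
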