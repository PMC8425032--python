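"""Steady-state extraction, buffer subtraction and current normalization.

Raw sweeps become I–V curves in three steps: average the late, settled part
of each step to a steady-state current; subtract the sugar-free (buffer)
current from the sugar current voltage by voltage; optionally normalize to
the most negative current at the reference voltage of the experiment.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .trace_model import IVCurve, SweepTrace, ValidationError

__all__ = [
    "PairingError",
    "NormalizationError",
    "extract_steady_state",
    "build_iv_curve",
    "normalize_currents",
]

DEFAULT_WINDOW_FRACTION = 0.75  # start of the default steady-state window within the step


class PairingError(ValidationError):
    """Sugar and buffer sweep collections do not cover the same voltages."""


class NormalizationError(ValidationError):
    """No valid (strictly negative) reference current for normalization."""


def extract_steady_state(
    sweep: SweepTrace, window: Optional[tuple[float, float]] = None
) -> tuple[float, float]:
    """Mean current over a late window of the step, with its sample SD.

    ``window`` is (start, end) in ms relative to the step onset.  The
    default covers the final quarter of the step (the last 50 ms of a
    200 ms step), well past capacitive settling.  Returns
    ``(mean_nA, sd_nA)``; the SD is a stability diagnostic.
    """
    duration = sweep.step_offset - sweep.step_onset
    if window is None:
        window = (DEFAULT_WINDOW_FRACTION * duration, duration)
    start, end = window
    if not (0.0 <= start < end <= duration + 1e-9):
        raise ValidationError(
            f"window {window} must lie within the step (0, {duration}) ms"
        )
    t0 = sweep.step_onset + start
    t1 = sweep.step_onset + end
    # half-open on the right when the window ends at the step offset: that
    # sample already belongs to the post-step epoch
    if end >= duration - 1e-9:
        mask = (sweep.time >= t0 - 1e-9) & (sweep.time < t1 - 1e-9)
    else:
        mask = (sweep.time >= t0 - 1e-9) & (sweep.time <= t1 + 1e-9)
    values = sweep.current[mask]
    if values.size < 2:
        raise ValidationError("steady-state window contains fewer than 2 samples")
    return float(values.mean()), float(values.std(ddof=1))


def _steady_states_by_voltage(
    sweeps: Sequence[SweepTrace], window: Optional[tuple[float, float]]
) -> dict[float, float]:
    by_v: dict[float, list[float]] = {}
    for sweep in sweeps:
        mean, _ = extract_steady_state(sweep, window)
        by_v.setdefault(float(sweep.step_voltage), []).append(mean)
    # replicate sweeps at one voltage are averaged
    return {v: float(np.mean(vals)) for v, vals in by_v.items()}


def build_iv_curve(
    sugar_sweeps: Sequence[SweepTrace],
    buffer_sweeps: Sequence[SweepTrace],
    window: Optional[tuple[float, float]] = None,
) -> IVCurve:
    """Buffer-subtracted I–V curve: I_sugar(V) - I_buffer(V), ascending in V.

    Both collections must cover exactly the same step voltages; a mismatch
    raises :class:`PairingError` listing the unmatched voltages.
    """
    if not sugar_sweeps or not buffer_sweeps:
        raise ValidationError("both sweep collections must be non-empty")
    sugar = _steady_states_by_voltage(sugar_sweeps, window)
    buffer = _steady_states_by_voltage(buffer_sweeps, window)
    if set(sugar) != set(buffer):
        only_sugar = sorted(set(sugar) - set(buffer))
        only_buffer = sorted(set(buffer) - set(sugar))
        raise PairingError(
            f"voltage sets differ: sugar-only {only_sugar}, buffer-only {only_buffer}"
        )
    voltages = np.array(sorted(sugar))
    currents = np.array([sugar[v] - buffer[v] for v in voltages])
    return IVCurve(
        voltages=voltages,
        currents=currents,
        condition=sugar_sweeps[0].solution,
        oocyte_id=sugar_sweeps[0].oocyte_id,
    )


def normalize_currents(
    currents: Sequence[float], reference: Optional[float] = None
) -> np.ndarray:
    """Divide currents by the most negative (largest inward) current.

    ``reference`` defaults to min(currents) and must be strictly negative —
    the convention divides by the highest negative current obtained at the
    reference voltage during the experiment, so the reference maps to 1.0.
    """
    currents = np.asarray(currents, dtype=float)
    if reference is None:
        if currents.size == 0:
            raise NormalizationError("cannot normalize an empty current list")
        reference = float(currents.min())
    if reference >= 0:
        raise NormalizationError(
            f"reference current must be strictly negative (inward), got {reference}"
        )
    return currents / reference
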