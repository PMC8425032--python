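"""Pre-steady-state (PSS) charge-movement analysis.

After a voltage jump, an electrogenic transporter without substrate shows a
transient current from voltage-driven movement of the empty carrier's
charged binding site, on top of the much faster capacitive settling of the
membrane.  The pipeline here: isolate the slow transient from each sweep
(default: biexponential component separation, the fast component being
membrane capacitance), integrate it to the charge transfer Q(V), fit the
charge–voltage relation

    (Q - Qhyp)/Qmax = 1 / (1 + exp[zF(V - V05)/RT])

and combine Qmax with a saturating current Imax into the turnover number
|Imax|/|Qmax| (nA/nC = s^-1), i.e. transport cycles per carrier per second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import lmfit
import numpy as np
from scipy import optimize

from .constants import DEFAULT_TEMPERATURE, FARADAY, GAS_CONSTANT
from .kinetics import FitError
from .trace_model import (
    BoltzmannFit,
    ChargeMovement,
    SweepTrace,
    TurnoverResult,
    ValidationError,
)

__all__ = [
    "PssIsolation",
    "isolate_pss_currents",
    "integrate_charge",
    "charge_movement",
    "charge_voltage_analysis",
    "fit_boltzmann",
    "turnover_number",
]

TAU_SEPARATION_MIN = 3.0  # below this tau_slow/tau_fast ratio, isolation is dubious


@dataclass
class PssIsolation:
    """Isolated PSS transient: time (ms, relative to step onset) and current (nA)."""

    time: np.ndarray
    current: np.ndarray
    tau_fast: Optional[float]
    tau_slow: Optional[float]
    residual_rms: float
    warning: Optional[str] = None


@dataclass
class _BiexpResult:
    a_fast: float
    tau_fast: float
    a_slow: float
    tau_slow: float
    i_ss: float
    residual_rms: float
    success: bool


def _fit_biexponential(t: np.ndarray, y: np.ndarray) -> _BiexpResult:
    """Least-squares biexponential-plus-offset fit of an ON-step segment.

    Time constants are fitted on a log scale (tau_slow = tau_fast * ratio
    with ratio > 1, guaranteeing the ordering) and the trust-region solver
    is restarted from several initial time-constant splits: the capacitive
    and transporter amplitudes can differ by an order of magnitude, which
    leaves shallow local minima around merged time constants.
    """
    i_ss0 = float(np.mean(y[int(0.9 * y.size):]))
    a0 = float(y[0] - i_ss0)

    def residual(theta):
        a_f, log_tf, a_s, log_ratio, i_ss = theta
        tau_f = np.exp(log_tf)
        tau_s = tau_f * np.exp(log_ratio)
        return a_f * np.exp(-t / tau_f) + a_s * np.exp(-t / tau_s) + i_ss - y

    dt = float(t[1] - t[0])
    span = float(t[-1] - t[0])
    lower = [-np.inf, math.log(dt / 10.0), -np.inf, math.log(1.01), -np.inf]
    upper = [np.inf, math.log(10.0 * span), np.inf, math.log(1e4), np.inf]
    best = None
    for tf0, ratio0 in ((2 * dt, 10.0), (1.0, 15.0), (1.0, 40.0), (5.0, 8.0)):
        theta0 = np.array([0.9 * a0, math.log(tf0), 0.1 * a0, math.log(ratio0), i_ss0])
        try:
            res = optimize.least_squares(
                residual,
                theta0,
                bounds=(lower, upper),
                x_scale="jac",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=2000,
            )
        except ValueError:
            continue
        ss = float(np.sum(res.fun**2))
        if res.status > 0 and (best is None or ss < best[1]):
            best = (res, ss)
    if best is None:
        return _BiexpResult(math.nan, math.nan, math.nan, math.nan, math.nan, math.nan, False)
    res, ss = best
    a_f, log_tf, a_s, log_ratio, i_ss = res.x
    tau_f = float(np.exp(log_tf))
    tau_s = float(tau_f * np.exp(log_ratio))
    return _BiexpResult(
        a_fast=float(a_f),
        tau_fast=tau_f,
        a_slow=float(a_s),
        tau_slow=tau_s,
        i_ss=float(i_ss),
        residual_rms=float(np.sqrt(ss / t.size)),
        success=True,
    )


def isolate_pss_currents(
    sweep: SweepTrace,
    method: str = "biexponential",
    template: Optional[SweepTrace] = None,
    max_window_taus: float = 8.0,
) -> PssIsolation:
    """Extract the slow (transporter) transient from the ON step of a sweep.

    ``biexponential`` fits A_fast*exp(-t/tau_fast) + A_slow*exp(-t/tau_slow)
    + I_ss to the ON segment and returns the fitted slow component (from
    the step onset, out to ``max_window_taus`` slow time constants), free
    of the capacitive fast component and the steady-state offset.  When the
    two time constants are within a factor of 3 the result carries a
    warning in ``warning``.

    ``template_subtraction`` subtracts a saturating-sugar sweep recorded at
    the same voltage (``template``) after aligning the steady-state levels;
    it isolates the sugar-suppressible fraction of the transient.
    """
    sl = sweep.step_slice()
    t = sweep.time[sl] - sweep.step_onset
    y = sweep.current[sl]
    if t.size < 10:
        raise ValidationError("step segment too short for transient isolation")

    if method == "biexponential":
        result = _fit_biexponential(t, y)
        if not result.success:
            raise FitError(
                "biexponential transient fit failed",
                best={"tau_fast": result.tau_fast, "tau_slow": result.tau_slow},
            )
        ratio = result.tau_slow / result.tau_fast
        warning = None
        if ratio < TAU_SEPARATION_MIN:
            warning = (
                f"tau_slow/tau_fast = {ratio:.2f} < {TAU_SEPARATION_MIN}: "
                "fast and slow components poorly separable"
            )
        dt = float(t[1] - t[0])
        span = float(t[-1] - t[0])
        if not (dt / 10 < result.tau_fast < span and result.tau_slow < 100 * span):
            warning = (
                f"time constants at the edge of the observable range "
                f"(tau_fast={result.tau_fast:.3g} ms, tau_slow={result.tau_slow:.3g} ms); "
                "transient amplitude likely negligible"
            )
        end = min(float(t[-1]), max_window_taus * result.tau_slow)
        keep = t <= end + 1e-9
        slow = result.a_slow * np.exp(-t[keep] / result.tau_slow)
        return PssIsolation(
            time=t[keep],
            current=slow,
            tau_fast=result.tau_fast,
            tau_slow=result.tau_slow,
            residual_rms=result.residual_rms,
            warning=warning,
        )

    if method == "template_subtraction":
        if template is None:
            raise ValidationError("template_subtraction requires a saturating-sugar sweep")
        if not np.isclose(template.step_voltage, sweep.step_voltage):
            raise ValidationError("template sweep must be at the same step voltage")
        tsl = template.step_slice()
        ty = template.current[tsl]
        n = min(y.size, ty.size)
        diff = y[:n] - ty[:n]
        # steady-state alignment: difference of late-window means is removed
        tail = diff[int(0.75 * n):]
        diff = diff - float(tail.mean())
        return PssIsolation(
            time=t[:n],
            current=diff,
            tau_fast=None,
            tau_slow=None,
            residual_rms=float(tail.std(ddof=1)),
        )

    raise ValidationError(f"unknown isolation method {method!r}")


def integrate_charge(time: np.ndarray, current: np.ndarray) -> float:
    """Trapezoidal time integral of a current segment, in nC.

    nA x ms = 1e-3 nC, so a 100 nA current sustained for 10 ms carries 1 nC.
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    if time.size < 2 or time.shape != current.shape:
        raise ValidationError("segment must contain >= 2 (time, current) samples")
    dt = np.diff(time)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValidationError("segment must be uniformly sampled")
    return float(np.trapezoid(current, time)) * 1e-3


def charge_movement(
    sweep: SweepTrace,
    method: str = "biexponential",
    template: Optional[SweepTrace] = None,
) -> ChargeMovement:
    """Isolate and integrate one sweep's PSS transient into a charge point.

    A sweep whose step voltage equals the holding potential has no voltage
    jump and therefore moves no charge; it contributes Q = 0 exactly
    (fitting a transient to what is pure baseline noise would be
    meaningless).
    """
    if sweep.step_voltage == sweep.hold_voltage:
        return ChargeMovement(
            voltage=float(sweep.step_voltage),
            charge=0.0,
            warning="no voltage jump: charge transfer is identically zero",
        )
    iso = isolate_pss_currents(sweep, method=method, template=template)
    q = integrate_charge(iso.time, iso.current)
    return ChargeMovement(
        voltage=float(sweep.step_voltage),
        charge=q,
        tau_slow=iso.tau_slow,
        tau_fast=iso.tau_fast,
        isolation_residual=iso.residual_rms,
        warning=iso.warning,
    )


def charge_voltage_analysis(
    sweeps: Sequence[SweepTrace], method: str = "biexponential"
) -> list[ChargeMovement]:
    """Charge transfer Q(V) for a collection of step sweeps, sorted by voltage."""
    movements = [charge_movement(s, method=method) for s in sweeps]
    return sorted(movements, key=lambda m: m.voltage)


def fit_boltzmann(
    charges: Sequence[ChargeMovement],
    temperature: float = DEFAULT_TEMPERATURE,
) -> BoltzmannFit:
    """Fit the charge–voltage Boltzmann relation to Q(V) points.

    Charges may be referenced to any holding potential — the constant
    offset is absorbed by Qhyp.  Requires >= 5 voltages and data on both
    sides of the midpoint; both orientations of z are tried and the better
    least-squares minimum is kept.
    """
    if len(charges) < 5:
        raise ValidationError("need charge at >= 5 voltages to fit 4 parameters")
    v = np.array([c.voltage for c in charges], dtype=float)
    q = np.array([c.charge for c in charges], dtype=float)
    if temperature <= 0:
        raise ValidationError("temperature must be > 0 K")
    kT = GAS_CONSTANT * temperature

    def model(v, qhyp, qmax, z, v05):
        x = z * FARADAY * (v - v05) * 1e-3 / kT
        return qhyp + qmax / (1.0 + np.exp(np.clip(x, -500, 500)))

    mod = lmfit.Model(model)
    span = float(np.ptp(q)) or 1.0
    v_lo, v_hi = float(v.min()), float(v.max())
    v05_starts = np.quantile(v, (0.25, 0.5, 0.75))
    best = None
    # the 4-parameter sigmoid has shallow local minima (steep z, midpoint
    # pushed off the sampled range); restart over orientation, steepness
    # and midpoint and keep the best least-squares minimum
    for z0 in (0.5, 1.0, 2.0, -0.5, -1.0, -2.0):
        # with z > 0 charge decreases toward depolarized voltages
        qhyp0 = float(q[np.argmax(v)]) if z0 > 0 else float(q[np.argmin(v)])
        for v05_0 in v05_starts:
            params = mod.make_params(
                qhyp=qhyp0,
                qmax=span,
                z=dict(value=z0, min=-25.0, max=25.0),
                v05=dict(value=float(v05_0), min=v_lo - 100.0, max=v_hi + 100.0),
            )
            result = mod.fit(
                q, params, v=v, max_nfev=20000, fit_kws=dict(xtol=1e-10, ftol=1e-10)
            )
            ss = float(np.sum(result.residual**2))
            if result.success and (best is None or ss < best[1]):
                best = (result, ss)
    if best is None:
        raise FitError("Boltzmann fit did not converge from any start")
    result, ss = best
    v05 = float(result.params["v05"].value)
    if not (v.min() < v05 < v.max()):
        raise FitError(
            f"ill-conditioned Boltzmann fit: midpoint {v05:.1f} mV lies outside "
            f"the sampled voltage range [{v.min():.0f}, {v.max():.0f}] mV",
            best={k: float(p.value) for k, p in result.params.items()},
        )

    def se(name):
        return float(result.params[name].stderr or math.nan)

    qhyp = float(result.params["qhyp"].value)
    qmax = float(result.params["qmax"].value)
    z = float(result.params["z"].value)
    se_qhyp, se_qmax = se("qhyp"), se("qmax")
    if qmax < 0:
        # the sigmoid is invariant under (Qhyp, Qmax, z) -> (Qhyp + Qmax,
        # -Qmax, -z); canonicalize to Qmax > 0, z carries the orientation
        if result.covar is not None:
            names = result.var_names
            cov = result.covar[names.index("qhyp"), names.index("qmax")]
            se_qhyp = math.sqrt(max(se("qhyp") ** 2 + se("qmax") ** 2 + 2 * cov, 0.0))
        else:
            se_qhyp = math.nan
        qhyp, qmax, z = qhyp + qmax, -qmax, -z

    return BoltzmannFit(
        Qhyp=qhyp,
        Qmax=qmax,
        z=z,
        V05=v05,
        temperature=temperature,
        se_Qhyp=se_qhyp,
        se_Qmax=se_qmax,
        se_z=se("z"),
        se_V05=se("v05"),
        residual_ss=ss,
        converged=True,
    )


def turnover_number(
    Imax: float, Qmax: float, sugar: str = "l-arabinose", pH: float = 5.5
) -> TurnoverResult:
    """Transport cycles per carrier per second: |Imax| / |Qmax| (nA/nC = s^-1).

    ``Imax`` is the saturating current from an unnormalized Michaelis–Menten
    fit; ``Qmax`` the total mobile charge from a sugar-free Boltzmann fit at
    the same pH.
    """
    if Qmax == 0:
        raise ZeroDivisionError("Qmax must be nonzero to compute a turnover number")
    return TurnoverResult(
        turnover=abs(Imax) / abs(Qmax),
        Imax_used=Imax,
        Qmax_used=Qmax,
        sugar=sugar,
        pH=pH,
    )
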