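"""Nonlinear least-squares kinetics: Michaelis–Menten, Hill, selectivity stats.

Both saturation models are fitted by Levenberg–Marquardt least squares
(via lmfit); the contract is the least-squares minimum itself, not the
optimizer path, so any NLS routine reaching the same minimum is
equivalent.  Residuals are unweighted.  The Hill model is fitted in
log-concentration space internally (response = Imax / (1 + exp(n*(ln K05
- ln S)))) for conditioning over the decades-wide proton range, and
reported on the linear scale.

Standard errors come from the Jacobian-based covariance at the optimum.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .trace_model import (
    HillFit,
    IVCurve,
    MMFit,
    SolutionCondition,
    ValidationError,
)

__all__ = [
    "FitError",
    "fit_michaelis_menten",
    "fit_hill",
    "kinetics_by_voltage",
    "selectivity_anova",
]

_FIT_KWS = dict(xtol=1e-8, ftol=1e-8)
_MAX_NFEV = 5000


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries best-so-far parameters."""

    def __init__(self, message: str, best: Optional[Mapping[str, float]] = None):
        super().__init__(message)
        self.best = dict(best) if best else {}


def _check_responses(concentrations, responses, min_distinct: int):
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape or conc.ndim != 1:
        raise ValidationError("concentrations and responses must be equal-length 1-D")
    if len(np.unique(conc)) < min_distinct:
        raise ValidationError(
            f"need at least {min_distinct} distinct concentrations, "
            f"got {len(np.unique(conc))}"
        )
    if np.any(conc < 0):
        raise ValidationError("concentrations must be >= 0")
    nonzero = resp[resp != 0]
    if nonzero.size and not (np.all(nonzero > 0) or np.all(nonzero < 0)):
        raise ValidationError("responses must share one sign")
    return conc, resp


def _initial_guesses(conc: np.ndarray, resp: np.ndarray) -> tuple[float, float]:
    """Imax0 = 1.2x the extreme response; K0 = concentration nearest half-extreme."""
    extreme = resp[np.argmax(np.abs(resp))]
    imax0 = 1.2 * extreme if extreme != 0 else 1.0
    half = extreme / 2.0
    k0 = conc[np.argmin(np.abs(resp - half))]
    if k0 <= 0:
        k0 = float(np.median(conc[conc > 0])) if np.any(conc > 0) else 1.0
    return float(imax0), float(k0)


def fit_michaelis_menten(
    concentrations: Sequence[float], responses: Sequence[float]
) -> MMFit:
    """Fit response = Imax*[S]/([S] + Km) by unweighted least squares.

    Works equally for inward currents (negative nA) and uptake rates
    (non-negative); Km is scale-invariant under multiplication of all
    responses by a positive constant, so normalized and raw currents give
    the same Km.
    """
    conc, resp = _check_responses(concentrations, responses, min_distinct=3)
    imax0, km0 = _initial_guesses(conc, resp)

    def model(s, imax, km):
        return imax * s / (s + km)

    mod = lmfit.Model(model)
    params = mod.make_params(imax=imax0, km=dict(value=km0, min=1e-12))
    result = mod.fit(resp, params, s=conc, max_nfev=_MAX_NFEV, fit_kws=_FIT_KWS)
    km = float(result.params["km"].value)
    imax = float(result.params["imax"].value)
    converged = bool(result.success) and math.isfinite(km) and math.isfinite(imax)
    if not converged:
        raise FitError(
            f"Michaelis–Menten fit did not converge: {result.message}",
            best={"Km": km, "Imax": imax},
        )
    return MMFit(
        Km=km,
        Imax=imax,
        se_Km=float(result.params["km"].stderr or math.nan),
        se_Imax=float(result.params["imax"].stderr or math.nan),
        residual_ss=float(np.sum(result.residual**2)),
        converged=converged,
        n_points=int(conc.size),
    )


def fit_hill(
    proton_concentrations: Sequence[float], responses: Sequence[float]
) -> HillFit:
    """Fit response = Imax*[S]^n/([S]^n + K05^n) over proton concentration (nM).

    K05 is reported in nM; its pH equivalent is available as
    :attr:`HillFit.K05_pH` (pH = 9 - log10(K05)).  With n fixed near 1 the
    model reduces to Michaelis–Menten.
    """
    conc, resp = _check_responses(proton_concentrations, responses, min_distinct=4)
    if np.any(conc <= 0):
        raise ValidationError("proton concentrations must be > 0")
    imax0, k0 = _initial_guesses(conc, resp)
    log_conc = np.log(conc)

    def model(lns, imax, lnk05, n):
        return imax / (1.0 + np.exp(n * (lnk05 - lns)))

    mod = lmfit.Model(model)
    params = mod.make_params(
        imax=imax0,
        lnk05=math.log(k0),
        n=dict(value=1.0, min=1e-3, max=20.0),
    )
    result = mod.fit(resp, params, lns=log_conc, max_nfev=_MAX_NFEV, fit_kws=_FIT_KWS)
    k05 = float(np.exp(result.params["lnk05"].value))
    n = float(result.params["n"].value)
    imax = float(result.params["imax"].value)
    converged = bool(result.success) and all(map(math.isfinite, (k05, n, imax)))
    if not converged:
        raise FitError(
            f"Hill fit did not converge: {result.message}",
            best={"K05": k05, "hill_n": n, "Imax": imax},
        )
    se_lnk = result.params["lnk05"].stderr
    return HillFit(
        K05=k05,
        hill_n=n,
        Imax=imax,
        se_K05=float(k05 * se_lnk) if se_lnk else math.nan,  # delta method
        se_n=float(result.params["n"].stderr or math.nan),
        se_Imax=float(result.params["imax"].stderr or math.nan),
        residual_ss=float(np.sum(result.residual**2)),
        converged=converged,
        n_points=int(conc.size),
    )


def kinetics_by_voltage(
    iv_curves: Sequence[IVCurve], model: str = "mm"
) -> pd.DataFrame:
    """One saturation fit per voltage across a concentration series of I–V curves.

    Each input curve corresponds to one substrate concentration (``model
    ="mm"``, x = sugar mM) or one pH (``model="hill"``, x = [H+] nM); every
    concentration must be measured at every voltage.  Returns a table with
    one row per voltage, sorted by voltage.
    """
    if model not in ("mm", "hill"):
        raise ValidationError("model must be 'mm' or 'hill'")
    if not iv_curves:
        raise ValidationError("need at least one I-V curve")
    voltage_sets = [tuple(c.voltages.tolist()) for c in iv_curves]
    if len(set(voltage_sets)) != 1:
        gaps = sorted(set().union(*map(set, voltage_sets)) - set.intersection(*map(set, voltage_sets)))
        raise ValidationError(f"curves do not share a common voltage grid; unmatched: {gaps}")

    def xval(curve: IVCurve) -> float:
        if model == "mm":
            return curve.condition.sugar_concentration
        return curve.condition.proton_concentration

    xs = np.array([xval(c) for c in iv_curves])
    rows = []
    for j, v in enumerate(iv_curves[0].voltages):
        ys = np.array([c.currents[j] for c in iv_curves])
        if model == "mm":
            fit = fit_michaelis_menten(xs, ys)
            rows.append(
                dict(voltage=float(v), Km=fit.Km, Imax=fit.Imax,
                     se_Km=fit.se_Km, se_Imax=fit.se_Imax)
            )
        else:
            fit = fit_hill(xs, ys)
            rows.append(
                dict(voltage=float(v), K05=fit.K05, hill_n=fit.hill_n, Imax=fit.Imax,
                     se_K05=fit.se_K05, se_n=fit.se_n, se_Imax=fit.se_Imax)
            )
    return pd.DataFrame(rows).sort_values("voltage", ignore_index=True)


def selectivity_anova(
    groups: Mapping[str, Sequence[float]],
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus Tukey HSD across sugar (or strain) groups.

    Returns ``(F, p, tukey_table)`` where the table has one row per pair
    with the mean difference and the Tukey-adjusted p value.  Degenerate
    all-identical data yields F = 0, p = 1 and no significant pairs.
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 replicates")
        arrays[name] = arr

    flat = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[name] * arr.size for name, arr in arrays.items()])
    names = sorted(arrays)
    if np.ptp(flat) == 0.0:  # no variance anywhere: nothing to distinguish
        pairs = [
            dict(group1=a, group2=b, meandiff=0.0, p_adj=1.0, reject=False)
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        ]
        return 0.0, 1.0, pd.DataFrame(pairs)

    f_stat, p_value = stats.f_oneway(*arrays.values())
    tukey = pairwise_tukeyhsd(flat, labels)
    table = pd.DataFrame(
        data=tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    ).rename(columns={"p-adj": "p_adj"})
    table["p_adj"] = tukey.pvalues
    return float(f_stat), float(p_value), table
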