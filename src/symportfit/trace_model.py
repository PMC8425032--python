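"""Core data types and file I/O for voltage-clamp traces, uptake tables and Cp tables.

The package revolves around a handful of plain containers:

* :class:`SweepTrace` — one voltage-clamp recording epoch (time, current,
  step protocol metadata, solution condition),
* :class:`IVCurve` — buffer-subtracted sugar-induced steady-state current
  versus clamped voltage,
* fit-result records (:class:`MMFit`, :class:`HillFit`, :class:`BoltzmannFit`),
* :class:`UptakeSample` / :class:`UptakeRate` for radiotracer assays,
* :class:`CpRecord` for qPCR crossing points,
* :class:`TransporterPreset` — the ground-truth parameter set that drives
  the simulator.

Traces are stored in a plain-text CSV dialect: one block per sweep, each
block introduced by ``#key=value`` metadata lines followed by a
``time_ms,current_nA`` header and the samples.  The dialect is diffable and
round-trips byte-identically (floats are written with ``repr``, which is the
shortest exact decimal representation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, OD_TO_CDW_DEFAULT

__all__ = [
    "ValidationError",
    "TraceFormatError",
    "SolutionCondition",
    "SweepTrace",
    "IVCurve",
    "MMFit",
    "HillFit",
    "BoltzmannFit",
    "ChargeMovement",
    "TurnoverResult",
    "UptakeSample",
    "UptakeRate",
    "CpRecord",
    "SugarParams",
    "TransporterPreset",
    "UptakePreset",
    "get_preset",
    "get_uptake_preset",
    "read_trace",
    "write_trace",
    "read_uptake_table",
    "write_uptake_table",
    "read_cp_table",
    "write_cp_table",
]


class ValidationError(ValueError):
    """An input violates a documented invariant."""


class TraceFormatError(ValidationError):
    """A trace file does not conform to the trace-CSV dialect."""


# ---------------------------------------------------------------------------
# solution / sweep containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolutionCondition:
    """Bath solution: pH and (optionally) one sugar at a given concentration.

    ``proton_concentration`` is derived from pH on the nanomolar scale,
    [H+] = 10**(9 - pH) nM, so that pH 5.5 corresponds to ~3162 nM.
    """

    pH: float
    sugar_name: Optional[str] = None
    sugar_concentration: float = 0.0  # mM

    def __post_init__(self) -> None:
        if not math.isfinite(self.pH):
            raise ValidationError("pH must be finite")
        if self.sugar_concentration < 0:
            raise ValidationError("sugar_concentration must be >= 0")
        if self.sugar_name is None and self.sugar_concentration > 0:
            raise ValidationError("sugar_concentration > 0 requires a sugar_name")

    @property
    def proton_concentration(self) -> float:
        """[H+] in nM, exactly 10**(9 - pH)."""
        return 10.0 ** (9.0 - self.pH)

    @staticmethod
    def ph_from_proton(conc_nM: float) -> float:
        """Inverse of :attr:`proton_concentration`: pH = 9 - log10([H+]/nM)."""
        if conc_nM <= 0:
            raise ValidationError("proton concentration must be > 0")
        return 9.0 - math.log10(conc_nM)


@dataclass
class SweepTrace:
    """One voltage-clamp epoch: uniformly sampled current during a voltage step.

    Inward current is negative (transport currents are reported as negative
    nA).  ``step_voltage`` equals ``hold_voltage`` for perfusion traces,
    where the clamp never leaves the holding potential.
    """

    time: np.ndarray  # ms, uniform
    current: np.ndarray  # nA
    sampling_interval: float  # ms
    hold_voltage: float  # mV
    step_voltage: float  # mV
    step_onset: float  # ms
    step_offset: float  # ms
    solution: SolutionCondition
    oocyte_id: str = "sim"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValidationError("time must be a 1-D array with >= 2 samples")
        if self.current.shape != self.time.shape:
            raise ValidationError("current and time must have the same length")
        if not np.all(np.isfinite(self.current)):
            raise ValidationError("current must be finite everywhere")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValidationError("time must be strictly increasing")
        if not np.allclose(dt, self.sampling_interval, rtol=1e-6, atol=1e-9):
            raise ValidationError("time must be uniformly sampled at sampling_interval")
        if not (0.0 <= self.step_onset < self.step_offset <= self.time[-1] + 1e-9):
            raise ValidationError("step window must satisfy 0 <= onset < offset <= last time")

    def __len__(self) -> int:
        return int(self.time.size)

    def step_slice(self) -> slice:
        """Index slice covering samples in [step_onset, step_offset).

        The window is half-open: the sample at exactly ``step_offset``
        belongs to the post-step epoch (the clamp has already returned to
        the holding potential there).
        """
        i0 = int(np.searchsorted(self.time, self.step_onset - 1e-12))
        i1 = int(np.searchsorted(self.time, self.step_offset - 1e-12))
        return slice(i0, i1)


@dataclass
class IVCurve:
    """Sugar-induced steady-state current versus clamped voltage.

    Currents are buffer-subtracted (sugar minus sugar-free bath at each
    voltage).  ``normalized``, when present, is the current divided by the
    most negative current at the reference voltage; the reference maps to 1.
    """

    voltages: np.ndarray  # mV, ascending
    currents: np.ndarray  # nA
    condition: SolutionCondition
    normalized: Optional[np.ndarray] = None
    oocyte_id: str = "sim"

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.voltages.shape != self.currents.shape:
            raise ValidationError("voltages and currents must have equal length")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)
            if self.normalized.shape != self.voltages.shape:
                raise ValidationError("normalized must match voltages in length")

    def current_at(self, voltage: float) -> float:
        idx = np.flatnonzero(np.isclose(self.voltages, voltage))
        if idx.size == 0:
            raise ValidationError(f"no current recorded at {voltage} mV")
        return float(self.currents[idx[0]])


# ---------------------------------------------------------------------------
# fit-result records
# ---------------------------------------------------------------------------


@dataclass
class MMFit:
    """Michaelis–Menten estimates: response = Imax*[S]/([S]+Km)."""

    Km: float  # mM
    Imax: float  # nA, or Vmax in nmol min^-1 mg^-1 for uptake data
    se_Km: float
    se_Imax: float
    residual_ss: float
    converged: bool
    n_points: int

    def __post_init__(self) -> None:
        if self.converged and not (
            math.isfinite(self.Km) and math.isfinite(self.Imax) and self.Km > 0
        ):
            raise ValidationError("converged MM fit requires finite Imax and Km > 0")

    def predict(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.Imax * s / (s + self.Km)


@dataclass
class HillFit:
    """Hill estimates: response = Imax*[S]^n/([S]^n + K05^n), [S] in nM protons."""

    K05: float  # nM
    hill_n: float
    Imax: float
    se_K05: float
    se_n: float
    se_Imax: float
    residual_ss: float
    converged: bool
    n_points: int

    def __post_init__(self) -> None:
        if self.converged and not (self.K05 > 0 and self.hill_n > 0):
            raise ValidationError("converged Hill fit requires K05 > 0 and n > 0")

    @property
    def K05_pH(self) -> float:
        """Half-saturating proton concentration expressed as pH."""
        return SolutionCondition.ph_from_proton(self.K05)

    def predict(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        sn = s**self.hill_n
        return self.Imax * sn / (sn + self.K05**self.hill_n)


@dataclass
class BoltzmannFit:
    """Charge–voltage Boltzmann parameters.

    (Q - Qhyp)/Qmax = 1 / (1 + exp[zF(V - V05)/RT]); Qdep = Qhyp + Qmax.
    For z > 0 the charge approaches Qhyp at depolarized voltages; the fit
    accepts either sign of z and reports the orientation found.
    """

    Qhyp: float  # nC
    Qmax: float  # nC
    z: float
    V05: float  # mV
    temperature: float  # K
    se_Qhyp: float
    se_Qmax: float
    se_z: float
    se_V05: float
    residual_ss: float
    converged: bool

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0 K")

    @property
    def Qdep(self) -> float:
        return self.Qhyp + self.Qmax


@dataclass
class ChargeMovement:
    """Charge transferred at one step voltage, with isolation diagnostics."""

    voltage: float  # mV
    charge: float  # nC
    tau_slow: Optional[float] = None  # ms
    tau_fast: Optional[float] = None  # ms
    isolation_residual: float = float("nan")
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.charge):
            raise ValidationError("charge must be finite")
        if self.tau_slow is not None and self.tau_fast is not None:
            if not (self.tau_slow > self.tau_fast > 0):
                raise ValidationError("expected tau_slow > tau_fast > 0")


@dataclass(frozen=True)
class TurnoverResult:
    """Turnover number |Imax|/|Qmax| in s^-1 (nA/nC is exactly s^-1)."""

    turnover: float
    Imax_used: float  # nA
    Qmax_used: float  # nC
    sugar: str
    pH: float


# ---------------------------------------------------------------------------
# uptake and qPCR containers
# ---------------------------------------------------------------------------


@dataclass
class UptakeSample:
    """One scintillation measurement from a zero-trans uptake assay."""

    cpm: float
    blank_cpm: float
    reaction_time: float  # min
    od_units: float  # OD x mL of cells in the reaction
    specific_activity: float  # cpm per nmol
    condition: SolutionCondition
    strain: str = "strain"

    def __post_init__(self) -> None:
        for name in ("cpm", "blank_cpm", "reaction_time", "od_units", "specific_activity"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.specific_activity <= 0:
            raise ValidationError("specific_activity must be > 0")
        if self.reaction_time <= 0:
            raise ValidationError("reaction_time must be > 0")


@dataclass(frozen=True)
class UptakeRate:
    """Uptake rate per OD unit and per mg cell dry weight."""

    rate_per_od: float  # nmol min^-1 OD^-1
    rate_per_cdw: float  # nmol min^-1 mg_CDW^-1
    od_to_cdw: float = OD_TO_CDW_DEFAULT  # mg_CDW per OD
    clamped: bool = False  # True when negative net counts were clamped to zero


@dataclass
class CpRecord:
    """qPCR crossing points for one target gene under one condition."""

    target_cp: float
    reference_cps: Sequence[float]
    condition: str
    strain: str = "strain"

    def __post_init__(self) -> None:
        cps = [self.target_cp, *self.reference_cps]
        if not cps[1:]:
            raise ValidationError("at least one reference Cp is required")
        for cp in cps:
            if not (0.0 < cp < 50.0):
                raise ValidationError("Cp values must lie in (0, 50) cycles")


# ---------------------------------------------------------------------------
# ground-truth presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SugarParams:
    """Per-sugar transport parameters: affinity and saturating current."""

    Km: float  # mM
    Imax_ref: float  # nA at the reference voltage and reference pH

    def __post_init__(self) -> None:
        if self.Km <= 0:
            raise ValidationError("Km must be > 0")


@dataclass(frozen=True)
class TransporterPreset:
    """Ground-truth parameters for the TEVC simulator.

    ``Imax_ref`` of each sugar is the extrapolated saturating-sugar current
    at ``reference_voltage`` and ``reference_pH``; the voltage lookup table
    and the proton Hill factor scale it multiplicatively (both equal 1 at
    the reference condition).
    """

    name: str
    sugars: dict[str, SugarParams]
    imax_voltage_table: tuple[tuple[float, float], ...]  # (mV, scale), scale(-50) = 1
    K05_H: float  # nM
    hill_n_H: float
    Qmax: float  # nC
    V05: float  # mV
    z: float
    tau0: float = 20.0  # ms, peak pre-steady-state relaxation time
    tau_cap: float = 0.5  # ms, clamp/membrane capacitive settling
    Cm: float = 20.0  # nF
    leak_conductance: float = 0.5  # uS
    leak_reversal: float = -20.0  # mV
    noise_sd: float = 5.0  # nA
    pss_sugar_suppression: float = 0.8  # fraction at saturating sugar
    reference_voltage: float = -50.0  # mV
    reference_pH: float = 5.5
    temperature: float = DEFAULT_TEMPERATURE  # K

    def __post_init__(self) -> None:
        if min(self.Qmax, self.tau0, self.tau_cap) <= 0:
            raise ValidationError("Qmax, tau0 and tau_cap must be > 0")
        if any(scale <= 0 for _, scale in self.imax_voltage_table):
            raise ValidationError("voltage scale factors must be > 0")
        if not 0.0 <= self.pss_sugar_suppression <= 1.0:
            raise ValidationError("pss_sugar_suppression must lie in [0, 1]")

    def sugar(self, name: str) -> SugarParams:
        try:
            return self.sugars[name]
        except KeyError:
            raise ValidationError(
                f"sugar {name!r} not in preset {self.name!r}; "
                f"known: {sorted(self.sugars)}"
            ) from None

    def voltage_scale(self, voltage: float) -> float:
        """Piecewise-linear Imax scale factor; clamps outside the table range."""
        table = np.asarray(self.imax_voltage_table, dtype=float)
        return float(np.interp(voltage, table[:, 0], table[:, 1]))


@dataclass(frozen=True)
class UptakePreset:
    """Ground truth for the yeast radiotracer uptake simulator."""

    name: str
    Vmax: float  # nmol min^-1 mg_CDW^-1
    Km: float  # mM
    od_to_cdw: float = OD_TO_CDW_DEFAULT
    pH: float = 6.5

    def __post_init__(self) -> None:
        if self.Vmax < 0 or self.Km <= 0:
            raise ValidationError("Vmax must be >= 0 and Km > 0")


# Default oocyte preset for the T. reesei L-arabinose/H+ symporter
# Trire2_104072.  Substrate affinities, saturating currents and the proton
# K0.5 are the fitted constants from TEVC experiments at -50 mV / pH 5.5;
# the Hill coefficient is back-computed from the ~25% residual activity at
# pH 9; Qmax is back-computed from the published turnover numbers
# (|Imax|/turnover, consistent between the two substrates within 1%).
# V05, z, relaxation times, membrane and leak parameters are not published
# and carry representative oocyte values.
TRIRE2_104072 = TransporterPreset(
    name="trire2_104072",
    sugars={
        "l-arabinose": SugarParams(Km=0.207, Imax_ref=-355.0),
        "d-xylose": SugarParams(Km=9.16, Imax_ref=-72.3),
        "d-glucose": SugarParams(Km=5.0, Imax_ref=-15.0),
    },
    imax_voltage_table=((-150.0, 1.9), (-100.0, 1.45), (-50.0, 1.0), (0.0, 0.6), (50.0, 0.25)),
    K05_H=68.9,
    hill_n_H=0.26,
    Qmax=5.897,
    V05=-20.0,
    z=1.0,
)

TRIRE2_104072_YEAST = UptakePreset(
    name="trire2_104072_yeast", Vmax=1.49, Km=0.102, pH=6.5
)

_PRESETS: dict[str, TransporterPreset] = {TRIRE2_104072.name: TRIRE2_104072}
_UPTAKE_PRESETS: dict[str, UptakePreset] = {TRIRE2_104072_YEAST.name: TRIRE2_104072_YEAST}


def get_preset(name: str = "trire2_104072") -> TransporterPreset:
    """Look up a packaged oocyte preset by name."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValidationError(f"unknown preset {name!r}; known: {sorted(_PRESETS)}") from None


def get_uptake_preset(name: str = "trire2_104072_yeast") -> UptakePreset:
    """Look up a packaged yeast-uptake preset by name."""
    try:
        return _UPTAKE_PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown uptake preset {name!r}; known: {sorted(_UPTAKE_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# trace CSV dialect
# ---------------------------------------------------------------------------

_MAGIC = "# symportfit trace v1"
_COLUMNS = "time_ms,current_nA"


def _format_meta(sweep: SweepTrace) -> list[str]:
    cond = sweep.solution
    lines = [
        f"#sampling_interval_ms={float(sweep.sampling_interval)!r}",
        f"#hold_voltage_mV={float(sweep.hold_voltage)!r}",
        f"#step_voltage_mV={float(sweep.step_voltage)!r}",
        f"#step_onset_ms={float(sweep.step_onset)!r}",
        f"#step_offset_ms={float(sweep.step_offset)!r}",
        f"#pH={float(cond.pH)!r}",
        f"#sugar_name={cond.sugar_name if cond.sugar_name is not None else ''}",
        f"#sugar_concentration_mM={float(cond.sugar_concentration)!r}",
        f"#oocyte_id={sweep.oocyte_id}",
    ]
    if sweep.seed is not None:
        lines.append(f"#seed={sweep.seed}")
    return lines


def write_trace(traces: Iterable[SweepTrace], path: str | Path) -> Path:
    """Write sweeps in the canonical trace-CSV dialect.

    Output is deterministic: identical input produces byte-identical files.
    An empty collection yields a header-only file.
    """
    path = Path(path)
    chunks = [_MAGIC + "\n"]
    for sweep in traces:
        lines = _format_meta(sweep)
        lines.append(_COLUMNS)
        lines.extend(
            f"{float(t)!r},{float(i)!r}" for t, i in zip(sweep.time, sweep.current)
        )
        chunks.append("\n".join(lines) + "\n")
    path.write_text("\n".join(chunks) if len(chunks) > 1 else chunks[0])
    return path


def _parse_block(meta: dict[str, str], rows: list[str], lineno: int) -> SweepTrace:
    required = {
        "sampling_interval_ms",
        "hold_voltage_mV",
        "step_voltage_mV",
        "step_onset_ms",
        "step_offset_ms",
        "pH",
        "sugar_concentration_mM",
    }
    missing = required - meta.keys()
    if missing:
        raise TraceFormatError(
            f"block ending at line {lineno}: missing metadata {sorted(missing)}"
        )
    try:
        data = np.array([[float(v) for v in row.split(",")] for row in rows])
    except ValueError as exc:
        raise TraceFormatError(f"block ending at line {lineno}: bad sample row ({exc})") from None
    if data.ndim != 2 or data.shape[1] != 2:
        raise TraceFormatError(f"block ending at line {lineno}: expected two columns")
    sugar = meta.get("sugar_name", "") or None
    cond = SolutionCondition(
        pH=float(meta["pH"]),
        sugar_name=sugar,
        sugar_concentration=float(meta["sugar_concentration_mM"]),
    )
    seed = int(meta["seed"]) if "seed" in meta else None
    return SweepTrace(
        time=data[:, 0],
        current=data[:, 1],
        sampling_interval=float(meta["sampling_interval_ms"]),
        hold_voltage=float(meta["hold_voltage_mV"]),
        step_voltage=float(meta["step_voltage_mV"]),
        step_onset=float(meta["step_onset_ms"]),
        step_offset=float(meta["step_offset_ms"]),
        solution=cond,
        oocyte_id=meta.get("oocyte_id", "unknown"),
        seed=seed,
    )


def read_trace(path: str | Path) -> list[SweepTrace]:
    """Read a trace-CSV file written by :func:`write_trace`.

    Raises :class:`TraceFormatError` naming the offending line on malformed
    input, and :class:`ValidationError` if samples are not uniformly spaced.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise TraceFormatError(f"line 1: expected dialect header {_MAGIC!r}")
    sweeps: list[SweepTrace] = []
    meta: dict[str, str] = {}
    rows: list[str] = []
    in_data = False

    def flush(lineno: int) -> None:
        nonlocal meta, rows, in_data
        if meta or rows:
            if not rows:
                raise TraceFormatError(f"block ending at line {lineno}: no sample rows")
            sweeps.append(_parse_block(meta, rows, lineno))
        meta, rows, in_data = {}, [], False

    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line:
            flush(lineno)
            continue
        if line.startswith("#"):
            if in_data:
                flush(lineno)
            if "=" not in line:
                raise TraceFormatError(f"line {lineno}: metadata must be '#key=value'")
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
        elif line == _COLUMNS:
            in_data = True
        else:
            if not in_data:
                raise TraceFormatError(
                    f"line {lineno}: data row before '{_COLUMNS}' header"
                )
            rows.append(line)
    flush(len(lines) + 1)
    return sweeps


# ---------------------------------------------------------------------------
# uptake and Cp flat CSV tables
# ---------------------------------------------------------------------------

_UPTAKE_COLUMNS = [
    "cpm",
    "blank_cpm",
    "reaction_time_min",
    "od_units",
    "specific_activity_cpm_per_nmol",
    "pH",
    "sugar_name",
    "sugar_concentration_mM",
    "strain",
]


def write_uptake_table(samples: Iterable[UptakeSample], path: str | Path) -> Path:
    rows = [
        {
            "cpm": s.cpm,
            "blank_cpm": s.blank_cpm,
            "reaction_time_min": s.reaction_time,
            "od_units": s.od_units,
            "specific_activity_cpm_per_nmol": s.specific_activity,
            "pH": s.condition.pH,
            "sugar_name": s.condition.sugar_name or "",
            "sugar_concentration_mM": s.condition.sugar_concentration,
            "strain": s.strain,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=_UPTAKE_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_uptake_table(path: str | Path) -> list[UptakeSample]:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(_UPTAKE_COLUMNS) - set(df.columns)
    if missing:
        raise TraceFormatError(f"uptake table missing columns {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        cond = SolutionCondition(
            pH=float(row["pH"]),
            sugar_name=str(row["sugar_name"]) or None,
            sugar_concentration=float(row["sugar_concentration_mM"]),
        )
        samples.append(
            UptakeSample(
                cpm=float(row["cpm"]),
                blank_cpm=float(row["blank_cpm"]),
                reaction_time=float(row["reaction_time_min"]),
                od_units=float(row["od_units"]),
                specific_activity=float(row["specific_activity_cpm_per_nmol"]),
                condition=cond,
                strain=str(row["strain"]),
            )
        )
    return samples


_CP_COLUMNS = ["target_cp", "reference_cps", "condition", "strain"]


def write_cp_table(records: Iterable[CpRecord], path: str | Path) -> Path:
    rows = [
        {
            "target_cp": r.target_cp,
            "reference_cps": ";".join(repr(c) for c in r.reference_cps),
            "condition": r.condition,
            "strain": r.strain,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_CP_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_cp_table(path: str | Path) -> list[CpRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(_CP_COLUMNS) - set(df.columns)
    if missing:
        raise TraceFormatError(f"Cp table missing columns {sorted(missing)}")
    return [
        CpRecord(
            target_cp=float(row["target_cp"]),
            reference_cps=[float(v) for v in str(row["reference_cps"]).split(";")],
            condition=str(row["condition"]),
            strain=str(row["strain"]),
        )
        for _, row in df.iterrows()
    ]
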