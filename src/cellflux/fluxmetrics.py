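"""Extracellular-flux trace parsing and mito-stress-test metric extraction.

A plate run records, for each well, the oxygen consumption rate (OCR,
pmol O2/min) and extracellular acidification rate (ECAR, mpH/min) over a
series of measurement cycles, with serial injections partitioning the
cycles into phases:

    basal -> oligomycin (ATP-synthase block) -> FCCP (uncoupler)
          -> rotenone + antimycin A (complex I/III block) -> 2-DG

From the per-phase rate levels the standard mitochondrial and glycolytic
metrics are derived:

    ATP-linked OCR   = basal - post-oligomycin
    proton leak      = post-oligomycin - non-mitochondrial
    spare capacity   = maximal (post-FCCP) - basal
    non-mito OCR     = post-rotenone/antimycin minimum
    2-DG-sensitive   = non-mito - post-2-DG   (non-mitochondrial oxidases)

so that basal = ATP-linked + proton leak + non-mito holds exactly by
construction. Basal rates use the mean of the last cycles before the first
injection; inhibitor phases use the phase extremum (minimum for
inhibitions, maximum for the FCCP uncoupling), the convention of standard
mito-stress-test analysis. Wells whose basal OCR falls below a detection
limit (default 20 pmol/min) are flagged as failing QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "Injection",
    "InjectionSchedule",
    "FluxTrace",
    "WellMetrics",
    "MetricParams",
    "FluxParseError",
    "PhaseError",
    "parse_flux_csv",
    "write_flux_csv",
    "phase_level",
    "compute_metrics",
    "qc_detection_limit",
    "metrics_table",
]

#: Phase labels in assay order.
PHASES = ("basal", "post_om", "post_fccp", "post_rotaa", "post_2dg")

#: OCR phase statistic: minimum for inhibitions, maximum for uncoupling.
_OCR_EXTREMUM = {"post_om": "min", "post_fccp": "max", "post_rotaa": "min", "post_2dg": "min"}

#: Basal OCR floor (pmol/min) below which a measurement is unreliable.
DETECTION_LIMIT_PMOL_MIN = 20.0

_ROWS = "ABCDEFGH"
_VALID_WELLS = frozenset(f"{r}{c:02d}" for r in _ROWS for c in range(1, 13))


class FluxParseError(ValueError):
    """Malformed flux CSV (bad header, duplicates, non-monotone time)."""


class PhaseError(ValueError):
    """A requested phase is absent or too short."""


@dataclass(frozen=True)
class Injection:
    name: str  # phase label the injection starts, e.g. "post_om"
    compound: str
    concentration: str
    first_cycle: int  # 1-based index of the first cycle after the injection


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered injections plus cycle timing for one assay protocol.

    The default protocol runs 12 measurement cycles of 3 min with 2 min of
    mixing between measurements: 4 basal cycles, then 2 cycles after each
    of the four serial injections (1.5 uM oligomycin, 1 uM FCCP,
    1.25 uM rotenone + 2.5 uM antimycin A, 50 mM 2-deoxyglucose).
    """

    injections: tuple[Injection, ...] = (
        Injection("post_om", "oligomycin", "1.5 uM", 5),
        Injection("post_fccp", "FCCP", "1 uM", 7),
        Injection("post_rotaa", "rotenone+antimycin A", "1.25 uM + 2.5 uM", 9),
        Injection("post_2dg", "2-deoxyglucose", "50 mM", 11),
    )
    n_cycles: int = 12
    measure_min: float = 3.0
    mix_min: float = 2.0

    def __post_init__(self) -> None:
        firsts = [inj.first_cycle for inj in self.injections]
        if any(b <= a for a, b in zip(firsts, firsts[1:])):
            raise ValueError("injection first_cycle values must be strictly increasing")
        if firsts and (firsts[0] < 2 or firsts[-1] > self.n_cycles):
            raise ValueError("injections must fall inside the cycle range")

    @property
    def cycle_period_min(self) -> float:
        return self.measure_min + self.mix_min

    def phase_of(self, cycle: int) -> str:
        """Phase label of a 1-based cycle index."""
        if cycle < 1 or cycle > self.n_cycles:
            raise ValueError(f"cycle {cycle} outside schedule (1..{self.n_cycles})")
        label = "basal"
        for inj in self.injections:
            if cycle >= inj.first_cycle:
                label = inj.name
        return label

    def phase_labels(self) -> list[str]:
        return [self.phase_of(c) for c in range(1, self.n_cycles + 1)]

    def times_min(self) -> np.ndarray:
        """Nominal time of each measurement start, in minutes."""
        return np.arange(self.n_cycles, dtype=np.float64) * self.cycle_period_min

    def save(self, path: str | Path) -> None:
        lines = ["name,compound,concentration,first_cycle"]
        lines += [
            f"{i.name},{i.compound},{i.concentration},{i.first_cycle}" for i in self.injections
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path, n_cycles: int = 12) -> "InjectionSchedule":
        rows = Path(path).read_text().strip().splitlines()
        if rows[0].strip() != "name,compound,concentration,first_cycle":
            raise FluxParseError(f"bad schedule header: {rows[0]!r}")
        injections = []
        for row in rows[1:]:
            name, compound, conc, first = (x.strip() for x in row.split(","))
            injections.append(Injection(name, compound, conc, int(first)))
        return cls(injections=tuple(injections), n_cycles=n_cycles)


@dataclass
class FluxTrace:
    """Per-well OCR/ECAR time course with phase labels from the schedule."""

    well_id: str
    cycles: np.ndarray  # 1-based cycle indices, strictly increasing
    time_min: np.ndarray
    ocr: np.ndarray  # pmol O2 / min
    ecar: np.ndarray  # mpH / min
    phases: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.time_min = np.asarray(self.time_min, dtype=np.float64)
        self.ocr = np.asarray(self.ocr, dtype=np.float64)
        self.ecar = np.asarray(self.ecar, dtype=np.float64)
        if np.any(np.diff(self.cycles) <= 0):
            raise FluxParseError(f"well {self.well_id}: cycle indices not strictly increasing")
        if np.any(np.diff(self.time_min) <= 0):
            raise FluxParseError(f"well {self.well_id}: time not strictly increasing")
        if len(self.phases) != len(self.cycles):
            raise ValueError("phases must be labelled per cycle")

    def phase_values(self, phase: str, channel: str = "ocr") -> np.ndarray:
        data = self.ocr if channel == "ocr" else self.ecar
        mask = np.array([p == phase for p in self.phases])
        return data[mask]


@dataclass(frozen=True)
class WellMetrics:
    """Per-well flux metrics; ``None`` marks a phase absent from the run.

    The invariant ``basal_ocr == atp_linked + proton_leak + nonmito_ocr``
    holds exactly whenever all three terms are defined.
    """

    well_id: str
    basal_ocr: Optional[float] = None
    basal_ecar: Optional[float] = None
    post_om_ocr: Optional[float] = None
    post_om_ecar: Optional[float] = None
    max_ocr: Optional[float] = None
    nonmito_ocr: Optional[float] = None
    post_2dg_ocr: Optional[float] = None
    atp_linked: Optional[float] = None
    proton_leak: Optional[float] = None
    src: Optional[float] = None
    dg_sensitive_nonmito: Optional[float] = None
    om_ecar_response: Optional[float] = None
    basal_ocr_mito: Optional[float] = None  # basal corrected for non-mito OCR
    qc_pass: Optional[bool] = None


@dataclass(frozen=True)
class MetricParams:
    """Which cycles feed each metric (configurable; defaults are standard)."""

    k_last: int = 3  # cycles averaged for last-k means (capped at phase length)
    basal_statistic: str = "last_k_mean"


FLUX_HEADER = ["plate_id", "well", "cycle", "time_min", "ocr_pmol_min", "ecar_mph_min"]


def parse_flux_csv(path: str | Path, schedule: InjectionSchedule) -> list[FluxTrace]:
    """Parse a plate flux CSV into per-well traces, phase-labelled.

    Dialect: header ``plate_id,well,cycle,time_min,ocr_pmol_min,
    ecar_mph_min``, UTF-8, '.' decimal, one row per (well, cycle).
    Missing cycles are kept as gaps, never interpolated. Duplicate
    (well, cycle) pairs and non-monotone times are parse errors naming
    the offending well.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    if header.split(",") != FLUX_HEADER:
        raise FluxParseError(f"malformed header: {header!r}")
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str}, float_precision="round_trip")
    bad_wells = sorted(set(df["well"]) - _VALID_WELLS)
    if bad_wells:
        raise FluxParseError(f"invalid 96-well coordinates: {bad_wells}")
    dup = df.duplicated(subset=["well", "cycle"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FluxParseError(f"duplicate (well, cycle): ({row['well']}, {row['cycle']})")
    traces = []
    for well, g in df.groupby("well", sort=True):
        g = g.sort_values("cycle")
        if np.any(np.diff(g["time_min"].to_numpy()) <= 0):
            raise FluxParseError(f"well {well}: time_min not strictly increasing")
        cycles = g["cycle"].to_numpy(dtype=int)
        traces.append(
            FluxTrace(
                well_id=str(well),
                cycles=cycles,
                time_min=g["time_min"].to_numpy(),
                ocr=g["ocr_pmol_min"].to_numpy(),
                ecar=g["ecar_mph_min"].to_numpy(),
                phases=[schedule.phase_of(int(c)) for c in cycles],
            )
        )
    return traces


def write_flux_csv(
    traces: Iterable[FluxTrace], path: str | Path, plate_id: str = "plate1"
) -> None:
    """Write traces in the flux CSV dialect (the parser's exact inverse)."""
    rows = []
    for t in traces:
        for c, tm, o, e in zip(t.cycles, t.time_min, t.ocr, t.ecar):
            rows.append(
                {
                    "plate_id": plate_id,
                    "well": t.well_id,
                    "cycle": int(c),
                    "time_min": float(tm),
                    "ocr_pmol_min": float(o),
                    "ecar_mph_min": float(e),
                }
            )
    pd.DataFrame(rows, columns=FLUX_HEADER).to_csv(path, index=False)


def phase_level(
    trace: FluxTrace,
    phase: str,
    k: int = 3,
    statistic: str = "last_k_mean",
    channel: str = "ocr",
) -> float:
    """Summary rate of one phase.

    ``last_k_mean`` averages the final ``k`` cycles of the phase (default
    3); ``extremum`` takes the phase minimum for inhibition phases and the
    maximum for the FCCP phase.
    """
    values = trace.phase_values(phase, channel)
    if values.size == 0:
        raise PhaseError(f"well {trace.well_id}: phase {phase!r} absent")
    if statistic == "last_k_mean":
        if values.size < k:
            raise PhaseError(
                f"well {trace.well_id}: phase {phase!r} has {values.size} cycles, need {k}"
            )
        return float(values[-k:].mean())
    if statistic == "extremum":
        ext = _OCR_EXTREMUM.get(phase, "min")
        return float(values.max() if ext == "max" else values.min())
    raise ValueError(f"unknown statistic {statistic!r}")


def _maybe_level(trace, phase, channel, statistic, k):
    values = trace.phase_values(phase, channel)
    if values.size == 0:
        return None
    if statistic == "extremum":
        return phase_level(trace, phase, statistic="extremum", channel=channel)
    # last-k mean with k capped at the phase length (short post phases)
    return phase_level(trace, phase, k=min(k, values.size), channel=channel)


def compute_metrics(
    trace: FluxTrace,
    schedule: InjectionSchedule | None = None,
    params: MetricParams = MetricParams(),
) -> WellMetrics:
    """Extract all per-well metrics from one trace.

    Basal rates are last-k means of the pre-injection cycles; OCR in
    post-injection phases uses the phase extremum; ECAR metrics use last-k
    means throughout. Phases missing from the trace (e.g. a run stopped
    before 2-DG) yield ``None`` for their metrics and everything derived
    from them, never zeros.
    """
    if trace.phase_values("basal").size == 0:
        raise PhaseError(f"well {trace.well_id}: empty basal phase")
    basal_ocr = _maybe_level(trace, "basal", "ocr", params.basal_statistic, params.k_last)
    basal_ecar = _maybe_level(trace, "basal", "ecar", "last_k_mean", params.k_last)
    post_om_ocr = _maybe_level(trace, "post_om", "ocr", "extremum", params.k_last)
    post_om_ecar = _maybe_level(trace, "post_om", "ecar", "last_k_mean", params.k_last)
    max_ocr = _maybe_level(trace, "post_fccp", "ocr", "extremum", params.k_last)
    nonmito_ocr = _maybe_level(trace, "post_rotaa", "ocr", "extremum", params.k_last)
    post_2dg_ocr = _maybe_level(trace, "post_2dg", "ocr", "extremum", params.k_last)

    def sub(x, y):
        return None if x is None or y is None else x - y

    return WellMetrics(
        well_id=trace.well_id,
        basal_ocr=basal_ocr,
        basal_ecar=basal_ecar,
        post_om_ocr=post_om_ocr,
        post_om_ecar=post_om_ecar,
        max_ocr=max_ocr,
        nonmito_ocr=nonmito_ocr,
        post_2dg_ocr=post_2dg_ocr,
        atp_linked=sub(basal_ocr, post_om_ocr),
        proton_leak=sub(post_om_ocr, nonmito_ocr),
        src=sub(max_ocr, basal_ocr),
        dg_sensitive_nonmito=sub(nonmito_ocr, post_2dg_ocr),
        om_ecar_response=sub(post_om_ecar, basal_ecar),
        basal_ocr_mito=sub(basal_ocr, nonmito_ocr),
    )


def qc_detection_limit(
    metrics: WellMetrics, limit: float = DETECTION_LIMIT_PMOL_MIN
) -> WellMetrics:
    """Flag wells whose basal OCR clears the detection limit.

    The boundary is inclusive: a basal OCR exactly at the limit passes
    (values *below* the limit are the unreliable ones). Failing wells are
    retained in outputs but excluded from group statistics downstream.
    """
    if not limit > 0:
        raise ValueError("detection limit must be positive")
    passed = metrics.basal_ocr is not None and metrics.basal_ocr >= limit
    return replace(metrics, qc_pass=bool(passed))


def metrics_table(metrics: Sequence[WellMetrics]) -> pd.DataFrame:
    """All wells' metrics as one DataFrame (one row per well)."""
    cols = [
        "well_id",
        "basal_ocr",
        "basal_ecar",
        "post_om_ocr",
        "post_om_ecar",
        "max_ocr",
        "nonmito_ocr",
        "post_2dg_ocr",
        "atp_linked",
        "proton_leak",
        "src",
        "dg_sensitive_nonmito",
        "om_ecar_response",
        "basal_ocr_mito",
        "qc_pass",
    ]
    return pd.DataFrame(
        [{c: getattr(m, c) for c in cols} for m in metrics], columns=cols
    )
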