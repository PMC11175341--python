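"""Reading and writing eNose recordings, annotations and feature tables.

The instrument software writes one CSV per measurement day: a time column
followed by one resistance column per sensor. A day is then segmented into
per-sample measurement cycles according to a phase schedule (flush ``B``,
baseline ``A``, sample measurement ``C``), and sample annotations (day,
substance, concentration, replicate, blank flag) are joined onto the cycles.

The CSV dialect is declared, not sniffed: comma separator, a header row with
the time column first, decimal points only. Files using comma decimals are
rejected rather than silently misread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationMismatchError, FormatError

ANNOTATION_COLUMNS = ["day", "substance", "concentration_ppm", "replicate", "is_blank"]

#: Default three-phase schedule (label, duration in seconds): flush the
#: sensor and sample bottle (B), record the baseline (A), measure the
#: sample headspace (C). Durations are instrument configuration, not
#: physical constants.
DEFAULT_SCHEDULE: tuple[tuple[str, float], ...] = (("B", 30.0), ("A", 30.0), ("C", 30.0))


@dataclass(frozen=True)
class CSVDialect:
    """Declared layout of a day-recording CSV."""

    sep: str = ","
    time_column: str = "time"


@dataclass
class SensorTrace:
    """Resistance time series of one sensor.

    Timestamps are seconds, strictly increasing; resistances are ohms and
    must be strictly positive (a MOS sensor always has finite resistance).
    """

    sensor_id: str
    timestamps: np.ndarray
    resistances: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.resistances = np.asarray(self.resistances, dtype=float)
        if self.timestamps.size < 1:
            raise FormatError(f"sensor {self.sensor_id!r}: empty trace")
        if self.timestamps.size != self.resistances.size:
            raise FormatError(f"sensor {self.sensor_id!r}: timestamp/resistance length mismatch")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise FormatError(f"sensor {self.sensor_id!r}: timestamps not strictly increasing")
        if not np.all(self.resistances > 0):
            raise FormatError(f"sensor {self.sensor_id!r}: non-positive resistance values")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    def slice_time(self, start: float, end: float) -> "SensorTrace":
        """Return the sub-trace with ``start <= t < end``."""
        mask = (self.timestamps >= start) & (self.timestamps < end)
        return SensorTrace(self.sensor_id, self.timestamps[mask], self.resistances[mask])


@dataclass(frozen=True)
class SampleAnnotation:
    """Metadata of one measured sample."""

    day: int
    substance: str
    concentration: float
    replicate: int
    is_blank: bool

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise FormatError(f"negative concentration {self.concentration}")
        if self.is_blank != (self.concentration == 0.0):
            raise FormatError(
                f"is_blank={self.is_blank} inconsistent with concentration={self.concentration}"
            )


@dataclass
class MeasurementCycle:
    """One sample's phase-resolved multi-sensor traces plus its annotation."""

    cycle_id: str
    phase_traces: dict[str, list[SensorTrace]]
    annotation: SampleAnnotation | None = None

    def __post_init__(self) -> None:
        if "C" not in self.phase_traces:
            raise FormatError(f"cycle {self.cycle_id!r}: sample phase 'C' missing")
        id_sets = {
            phase: tuple(t.sensor_id for t in traces)
            for phase, traces in self.phase_traces.items()
        }
        reference = next(iter(id_sets.values()))
        for phase, ids in id_sets.items():
            if set(ids) != set(reference):
                raise FormatError(
                    f"cycle {self.cycle_id!r}: phase {phase!r} has a different sensor set"
                )

    @property
    def sensor_ids(self) -> list[str]:
        return [t.sensor_id for t in self.phase_traces["C"]]


@dataclass
class DayRecording:
    """All sensor traces of one measurement day, plus cycle boundaries."""

    day: int
    traces: list[SensorTrace]
    cycle_boundaries: list[tuple[float, float, str]] = field(default_factory=list)

    @property
    def sensor_ids(self) -> list[str]:
        return [t.sensor_id for t in self.traces]

    @property
    def n_points(self) -> int:
        return len(self.traces[0])


def load_day_recording(path: str | Path, dialect: CSVDialect = CSVDialect(), day: int = 0) -> DayRecording:
    """Read a day-recording CSV into one :class:`SensorTrace` per sensor column.

    Raises :class:`FormatError` when the time column is missing, any cell is
    non-numeric (including comma-decimal files), or time is non-monotone.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.sep)
    if dialect.time_column not in df.columns:
        raise FormatError(f"{path.name}: missing time column {dialect.time_column!r}")
    sensor_cols = [c for c in df.columns if c != dialect.time_column]
    if not sensor_cols:
        raise FormatError(f"{path.name}: no sensor columns")
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            raise FormatError(f"{path.name}: non-numeric values in column {col!r}")
        df[col] = values
    t = df[dialect.time_column].to_numpy(dtype=float)
    traces = [SensorTrace(str(col), t, df[col].to_numpy(dtype=float)) for col in sensor_cols]
    return DayRecording(day=day, traces=traces)


def write_day_recording(rec: DayRecording, path: str | Path, dialect: CSVDialect = CSVDialect()) -> None:
    """Write a recording back to the declared CSV dialect."""
    data = {dialect.time_column: rec.traces[0].timestamps}
    for trace in rec.traces:
        data[trace.sensor_id] = trace.resistances
    pd.DataFrame(data).to_csv(path, sep=dialect.sep, index=False)


def _annotation_from_row(row: pd.Series) -> SampleAnnotation:
    return SampleAnnotation(
        day=int(row["day"]),
        substance=str(row["substance"]),
        concentration=float(row["concentration_ppm"]),
        replicate=int(row["replicate"]),
        is_blank=bool(row["is_blank"]),
    )


def segment_cycles(
    rec: DayRecording,
    schedule: Sequence[tuple[str, float]] = DEFAULT_SCHEDULE,
    annotations: pd.DataFrame | None = None,
    strict: bool = False,
) -> list[MeasurementCycle]:
    """Cut a day recording into measurement cycles by tiling the phase schedule.

    Cycles are joined to ``annotations`` (rows for this day, in measurement
    order — the instrument measures ascending concentrations) unless the
    table carries an explicit ``cycle_id`` column, which then takes
    precedence. A trailing partial cycle is dropped with a warning, or
    raises in ``strict`` mode.
    """
    durations = [d for _, d in schedule]
    if any(d <= 0 for d in durations):
        raise FormatError("schedule durations must be positive")
    cycle_len = float(sum(durations))
    t = rec.traces[0].timestamps
    t0, t_last = float(t[0]), float(t[-1])
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    span = t_last - t0 + dt  # recording covers [t0, t_last + dt)
    n_full = int(np.floor(span / cycle_len + 1e-9))
    if span - n_full * cycle_len > dt / 2:
        if strict:
            raise FormatError("recording does not tile the schedule (trailing partial cycle)")
        warnings.warn("trailing partial cycle dropped", stacklevel=2)
    if n_full == 0:
        raise FormatError("recording shorter than one full cycle")

    cycles: list[MeasurementCycle] = []
    boundaries: list[tuple[float, float, str]] = []
    for k in range(n_full):
        start = t0 + k * cycle_len
        phase_traces: dict[str, list[SensorTrace]] = {}
        offset = 0.0
        for label, duration in schedule:
            lo, hi = start + offset, start + offset + duration
            phase_traces[label] = [tr.slice_time(lo, hi) for tr in rec.traces]
            boundaries.append((lo, hi, label))
            offset += duration
        cycles.append(MeasurementCycle(cycle_id=f"d{rec.day}c{k:03d}", phase_traces=phase_traces))
    rec.cycle_boundaries = boundaries

    if annotations is not None:
        ann = annotations[annotations["day"] == rec.day] if "day" in annotations else annotations
        if "cycle_id" in ann.columns and ann["cycle_id"].notna().all():
            by_id = ann.set_index("cycle_id")
            missing = [c.cycle_id for c in cycles if c.cycle_id not in by_id.index]
            if missing:
                raise AnnotationMismatchError(f"no annotation for cycles {missing}")
            for cycle in cycles:
                cycle.annotation = _annotation_from_row(by_id.loc[cycle.cycle_id])
        else:
            if len(ann) != len(cycles):
                raise AnnotationMismatchError(
                    f"day {rec.day}: {len(cycles)} cycles but {len(ann)} annotations"
                )
            for cycle, (_, row) in zip(cycles, ann.iterrows()):
                cycle.annotation = _annotation_from_row(row)
    return cycles


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation CSV and validate the blank flag."""
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation table missing columns {missing}")
    df["is_blank"] = df["is_blank"].astype(bool)
    bad = df[df["is_blank"] != (df["concentration_ppm"] == 0)]
    if len(bad):
        raise FormatError(f"is_blank inconsistent with concentration in rows {list(bad.index)}")
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
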