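"""Feature extraction and normalization for eNose measurement cycles.

One feature per sensor and sample is computed: the drift-corrected response

    R_{i,d} = (ybar_sample,i − ybar_base,i)
              − (1/n_d) Σ_j (ybar_ethanol,j − ybar_base,j)

where ``ybar_sample,i`` is the mean of the last ``n_points`` resistance
values of the sample phase (C), ``ybar_base,i`` the mean of the last
``n_points`` baseline values (phase A) immediately preceding it, and the sum
runs over day *d*'s ``n_d`` analyte-free ethanol reference measurements
(blanks). Subtracting the preceding baseline removes the slow baseline
level; subtracting the day's mean ethanol response removes additive
between-day drift exactly. Blanks are ordinary rows and receive their own
feature value.

Features are then z-score normalized per sensor (sample SD, N−1 divisor);
the normalization statistics are stored so held-out rows can be transformed
with training-set statistics and the transform can be inverted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingPhaseError
from .io import ANNOTATION_COLUMNS, MeasurementCycle


@dataclass(frozen=True)
class WindowSpec:
    """Number of trailing points used for phase means (plateau average)."""

    n_points: int = 10

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


@dataclass(frozen=True)
class Normalization:
    """Stored per-sensor z-scoring statistics (sample SD)."""

    means: pd.Series
    sds: pd.Series


@dataclass
class FeatureMatrix:
    """Samples × sensors table of features with aligned annotations.

    ``values`` is indexed by cycle id with one column per sensor;
    ``annotations`` shares the index and carries day, substance,
    concentration_ppm, replicate and is_blank.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    normalization: Normalization | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.annotations.index):
            raise ValueError("values and annotations must share the same index")

    @property
    def sensor_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def concentrations(self) -> np.ndarray:
        return self.annotations["concentration_ppm"].to_numpy(dtype=float)

    @property
    def is_blank(self) -> np.ndarray:
        return self.annotations["is_blank"].to_numpy(dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def blank_rows(self) -> pd.DataFrame:
        return self.values.loc[self.is_blank]


def phase_mean(cycle: MeasurementCycle, phase: str, window: WindowSpec = WindowSpec()) -> pd.Series:
    """Per-sensor mean of the last ``window.n_points`` values of a phase.

    Traces shorter than the window are averaged in full, with a warning.
    """
    if phase not in cycle.phase_traces:
        raise MissingPhaseError(f"cycle {cycle.cycle_id!r}: phase {phase!r} absent")
    means = {}
    for trace in cycle.phase_traces[phase]:
        n = min(window.n_points, len(trace))
        if n < window.n_points:
            warnings.warn(
                f"cycle {cycle.cycle_id!r} phase {phase!r} sensor {trace.sensor_id!r}: "
                f"only {n} points available for a {window.n_points}-point window",
                stacklevel=2,
            )
        means[trace.sensor_id] = float(np.mean(trace.resistances[-n:]))
    return pd.Series(means)


def extract_features(
    cycles: Sequence[MeasurementCycle],
    window: WindowSpec = WindowSpec(),
    baseline_phase: str = "A",
    sample_phase: str = "C",
) -> FeatureMatrix:
    """Compute the drift-corrected feature matrix from annotated cycles.

    Every day represented must contain at least one blank (ethanol
    reference) cycle; a day without blanks raises
    :class:`~enoselod.errors.ConfigurationError` naming the day.
    """
    if any(c.annotation is None for c in cycles):
        raise ConfigurationError("all cycles must carry annotations before feature extraction")

    raw = {}
    for cycle in cycles:
        sample = phase_mean(cycle, sample_phase, window)
        base = phase_mean(cycle, baseline_phase, window)
        raw[cycle.cycle_id] = sample - base
    values = pd.DataFrame(raw).T
    annotations = pd.DataFrame(
        {
            "day": [c.annotation.day for c in cycles],
            "substance": [c.annotation.substance for c in cycles],
            "concentration_ppm": [c.annotation.concentration for c in cycles],
            "replicate": [c.annotation.replicate for c in cycles],
            "is_blank": [c.annotation.is_blank for c in cycles],
        },
        index=values.index,
    )
    fm = FeatureMatrix(values=values, annotations=annotations)
    return subtract_ethanol_reference(fm)


def subtract_ethanol_reference(fm: FeatureMatrix) -> FeatureMatrix:
    """Subtract each day's mean blank response from every row of that day.

    This is the between-day drift correction: an additive per-(day, sensor)
    offset common to all cycles of a day cancels exactly. Blanks are
    corrected too (their residual spread is what remains after correction).
    """
    corrected = fm.values.copy()
    for day, idx in fm.annotations.groupby("day").groups.items():
        day_ann = fm.annotations.loc[idx]
        blank_idx = day_ann.index[day_ann["is_blank"]]
        if len(blank_idx) == 0:
            raise ConfigurationError(f"day {day} has no blank (ethanol reference) cycles")
        corrected.loc[idx] = fm.values.loc[idx] - fm.values.loc[blank_idx].mean(axis=0)
    return FeatureMatrix(values=corrected, annotations=fm.annotations.copy())


def zscore_normalize(fm: FeatureMatrix, on_zero_variance: str = "error") -> FeatureMatrix:
    """Z-score each sensor column to mean 0, sample SD 1.

    Statistics are computed over the full table (all days, blanks included)
    and stored for inverse transforms and for applying to held-out rows.
    Zero-variance sensors raise, or are dropped when
    ``on_zero_variance="drop"``.
    """
    means = fm.values.mean(axis=0)
    sds = fm.values.std(axis=0, ddof=1)
    dead = sds.index[(sds == 0) | sds.isna()].tolist()
    values = fm.values
    if dead:
        if on_zero_variance == "drop":
            warnings.warn(f"dropping zero-variance sensors: {dead}", stacklevel=2)
            values = values.drop(columns=dead)
            means = means.drop(dead)
            sds = sds.drop(dead)
        else:
            raise ConfigurationError(f"zero-variance sensors: {dead}")
    normalized = (values - means) / sds
    return FeatureMatrix(
        values=normalized,
        annotations=fm.annotations.copy(),
        normalization=Normalization(means=means, sds=sds),
    )


def apply_normalization(fm: FeatureMatrix, norm: Normalization) -> FeatureMatrix:
    """Transform rows with previously fitted statistics (held-out data)."""
    values = (fm.values[norm.means.index] - norm.means) / norm.sds
    return FeatureMatrix(values=values, annotations=fm.annotations.copy(), normalization=norm)


def inverse_normalization(fm: FeatureMatrix) -> FeatureMatrix:
    if fm.normalization is None:
        raise ValueError("feature matrix is not normalized")
    norm = fm.normalization
    values = fm.values * norm.sds + norm.means
    return FeatureMatrix(values=values, annotations=fm.annotations.copy())


def write_feature_table(fm: FeatureMatrix, path: str | Path) -> None:
    """Write annotations + features as CSV, normalization stats as a JSON sidecar."""
    path = Path(path)
    table = pd.concat([fm.annotations, fm.values], axis=1)
    table.index.name = "cycle_id"
    table.to_csv(path)
    if fm.normalization is not None:
        sidecar = path.with_suffix(path.suffix + ".norm.json")
        payload = {
            "means": {str(k): float(v) for k, v in fm.normalization.means.items()},
            "sds": {str(k): float(v) for k, v in fm.normalization.sds.items()},
        }
        sidecar.write_text(json.dumps(payload, indent=1))


def read_feature_table(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    table = pd.read_csv(path, index_col="cycle_id")
    annotations = table[ANNOTATION_COLUMNS].copy()
    annotations["is_blank"] = annotations["is_blank"].astype(bool)
    values = table.drop(columns=ANNOTATION_COLUMNS)
    norm = None
    sidecar = path.with_suffix(path.suffix + ".norm.json")
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        norm = Normalization(
            means=pd.Series(payload["means"], dtype=float),
            sds=pd.Series(payload["sds"], dtype=float),
        )
    return FeatureMatrix(values=values, annotations=annotations, normalization=norm)
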