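"""Domain types and CSV I/O for single-cell Ca2+ transient traces.

A trace is the fluorescence intensity of one region of interest (one cell)
recorded over time, in arbitrary fluorescence units (AU).  The default
sampling rate is 5 frames per second; recordings are typically 12-32 s.
Frame indices are 0-based throughout; duration-type quantities are reported
in seconds via ``dt = 1 / sampling_hz``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NORMAL = "normal"
ABNORMAL = "abnormal"
LABELS = (NORMAL, ABNORMAL)

#: Provenance of a peak/cell assessment.
ASSESSMENT_SOURCES = ("expert", "analytical", "svm")

#: The 14 per-peak variables, in canonical column order.
PEAK_FEATURE_NAMES = [
    "A_l", "A_r", "A_d", "D_l", "D_r",
    "Dy_max", "Dy_min", "D2y_max", "D2y_min", "R",
    "delta", "delta_l2Dymax", "delta_m2Dymin", "Peak_distance_median",
]

#: The 6 per-signal (cell) variables used by the cell-level classifier.
CELL_FEATURE_NAMES = [
    "analytical_cell_label", "svm_cell_label", "prop_abnormal",
    "var_A", "var_delta", "var_R",
]


def validate_label(label: str) -> str:
    """Normalise and validate a normal/abnormal label string."""
    value = str(label).strip().lower()
    if value not in LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    return value


@dataclass
class CalciumTrace:
    """One cell's fluorescence intensity time series.

    Parameters
    ----------
    cell_id:
        Identifier of the cell / region of interest.
    intensities:
        Fluorescence values in frame order (arbitrary units).
    sampling_hz:
        Frames per second (default 5).
    source_tag:
        Free-form provenance string (file of origin, generator settings, ...).
    """

    cell_id: str
    intensities: np.ndarray
    sampling_hz: float = 5.0
    source_tag: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError(
                f"trace {self.cell_id!r}: needs at least 2 frames in a 1-D series"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"trace {self.cell_id!r}: intensities must be finite")
        if not self.sampling_hz > 0:
            raise ValueError(f"trace {self.cell_id!r}: sampling_hz must be > 0")
        self.intensities = arr

    @property
    def n_frames(self) -> int:
        return int(self.intensities.size)

    @property
    def dt(self) -> float:
        """Seconds per frame."""
        return 1.0 / self.sampling_hz

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.dt


@dataclass(frozen=True)
class PeakBoundary:
    """Frame indices (0-based) of one detected transient: start, maximum, end."""

    left_idx: int
    max_idx: int
    right_idx: int

    def __post_init__(self) -> None:
        if not (self.left_idx < self.max_idx < self.right_idx):
            raise ValueError(
                f"peak boundary must satisfy left < max < right, "
                f"got ({self.left_idx}, {self.max_idx}, {self.right_idx})"
            )
        if self.left_idx < 0:
            raise ValueError("peak boundary indices must be non-negative")

    def check_on(self, trace: CalciumTrace) -> None:
        if self.right_idx >= trace.n_frames:
            raise ValueError(
                f"peak boundary {self} outside trace {trace.cell_id!r} "
                f"({trace.n_frames} frames)"
            )


@dataclass
class PeakFeatureVector:
    """The 14 quantified variables of one transient peak.

    Amplitudes are in AU, durations in seconds, derivatives in AU/s and
    AU/s^2, the area ``R`` in AU*s.  ``Dy_min`` and ``D2y_min`` are stored as
    absolute values.  ``delta`` (previous-maximum to current-maximum time) is
    NaN for the first peak of a signal; ``Peak_distance_median`` is the
    median of the defined deltas and is identical across a signal's peaks.
    """

    A_l: float
    A_r: float
    A_d: float
    D_l: float
    D_r: float
    Dy_max: float
    Dy_min: float
    D2y_max: float
    D2y_min: float
    R: float
    delta: float
    delta_l2Dymax: float
    delta_m2Dymin: float
    Peak_distance_median: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in PEAK_FEATURE_NAMES}

    @property
    def max_amplitude(self) -> float:
        """max(A_l, A_r) — the 'peak max amplitude' of the rule engine."""
        return max(self.A_l, self.A_r)

    @property
    def min_amplitude(self) -> float:
        return min(self.A_l, self.A_r)


@dataclass
class PeakAssessment:
    """A binary normal/abnormal call with its provenance."""

    label: str
    source: str
    rule: Optional[str] = None  # which analytical rule fired, if any

    def __post_init__(self) -> None:
        self.label = validate_label(self.label)
        if self.source not in ASSESSMENT_SOURCES:
            raise ValueError(
                f"unknown assessment source {self.source!r}; "
                f"expected one of {ASSESSMENT_SOURCES}"
            )

    @property
    def is_abnormal(self) -> bool:
        return self.label == ABNORMAL


@dataclass
class CellFeatureVector:
    """The 6 per-signal predictors of the cell-level classifier."""

    analytical_cell_label: float
    svm_cell_label: float
    prop_abnormal: float
    var_A: float
    var_delta: float
    var_R: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_abnormal <= 1.0:
            raise ValueError("prop_abnormal must lie in [0, 1]")
        for name in ("var_A", "var_delta", "var_R"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in CELL_FEATURE_NAMES}


@dataclass
class LabelTable:
    """Expert labels keyed by cell_id (cell level) or (cell_id, peak_index)."""

    level: str  # "peak" or "cell"
    labels: dict

    def __post_init__(self) -> None:
        if self.level not in ("peak", "cell"):
            raise ValueError(f"level must be 'peak' or 'cell', got {self.level!r}")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, key):
        return self.labels[key]

    @property
    def n_abnormal(self) -> int:
        return sum(1 for v in self.labels.values() if v == ABNORMAL)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_LONG_COLUMNS = {"cell_id", "frame", "intensity"}


def _read_csv(path) -> pd.DataFrame:
    try:
        # round_trip parsing keeps written floats bit-exact on re-read
        return pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"unparsable CSV file {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty CSV file {path}") from exc


def _coerce_intensity(series: pd.Series, path, column: str) -> pd.Series:
    """Convert to float; non-numeric text is a hard error naming the line."""
    numeric = pd.to_numeric(series, errors="coerce")
    bad = numeric.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: non-numeric intensity {series.iloc[row]!r} in column "
            f"{column!r} at data line {row + 2}"
        )
    return numeric


def read_traces(
    path,
    sampling_hz: float = 5.0,
    source_tag: Optional[str] = None,
) -> list[CalciumTrace]:
    """Read traces from CSV, auto-detecting layout by header.

    Long layout has columns ``cell_id, frame, intensity`` (one row per
    frame); wide layout has a leading frame column and one intensity column
    per cell.  Traces containing missing intensities are rejected with a
    logged warning; non-numeric text is a hard error naming the line.
    """
    df = _read_csv(path)
    tag = source_tag if source_tag is not None else str(path)
    lower = {c.strip().lower(): c for c in df.columns}
    traces: list[CalciumTrace] = []

    if _LONG_COLUMNS <= set(lower):
        df = df.rename(columns={lower[k]: k for k in _LONG_COLUMNS})
        df["intensity"] = _coerce_intensity(df["intensity"], path, "intensity")
        for cell_id, group in df.groupby("cell_id", sort=False):
            group = group.sort_values("frame", kind="stable")
            values = group["intensity"].to_numpy()
            if np.isnan(values).any():
                logger.warning(
                    "trace %r rejected: missing intensity values", cell_id
                )
                continue
            traces.append(CalciumTrace(str(cell_id), values, sampling_hz, tag))
    else:
        # wide layout: first column is the frame axis, the rest are cells
        if df.shape[1] < 2:
            raise ValueError(f"{path}: wide layout needs a frame column and "
                             "at least one cell column")
        frame_col = df.columns[0]
        order = np.argsort(df[frame_col].to_numpy(), kind="stable")
        for col in df.columns[1:]:
            values = _coerce_intensity(df[col], path, col).to_numpy()[order]
            if np.isnan(values).any():
                logger.warning("trace %r rejected: missing intensity values", col)
                continue
            traces.append(CalciumTrace(str(col), values, sampling_hz, tag))

    return traces


def write_traces(traces: Sequence[CalciumTrace], path, layout: str = "long") -> None:
    """Write traces to CSV (long by default); round-trips values exactly."""
    if layout == "long":
        frames = [
            pd.DataFrame(
                {
                    "cell_id": t.cell_id,
                    "frame": np.arange(t.n_frames),
                    "intensity": t.intensities,
                }
            )
            for t in traces
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    elif layout == "wide":
        n = {t.n_frames for t in traces}
        if len(n) > 1:
            raise ValueError("wide layout requires equal-length traces")
        data = {"frame": np.arange(n.pop())}
        for t in traces:
            data[t.cell_id] = t.intensities
        pd.DataFrame(data).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_labels(path, level: str) -> LabelTable:
    """Read an expert label table (``level`` = 'peak' or 'cell') from CSV.

    A peak table is keyed by (cell_id, peak_index), a cell table by cell_id.
    Labels are case-insensitive 'normal'/'abnormal'; anything else, and any
    duplicated key, is a hard error.
    """
    if level not in ("peak", "cell"):
        raise ValueError(f"level must be 'peak' or 'cell', got {level!r}")
    df = _read_csv(path)
    lower = {c.strip().lower(): c for c in df.columns}
    required = {"cell_id", "label"} | ({"peak_index"} if level == "peak" else set())
    missing = required - set(lower)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    labels: dict = {}
    for pos, (_, row) in enumerate(df.iterrows()):
        try:
            value = validate_label(row[lower["label"]])
        except ValueError as exc:
            raise ValueError(f"{path}: data line {pos + 2}: {exc}") from exc
        if level == "peak":
            key = (str(row[lower["cell_id"]]), int(row[lower["peak_index"]]))
        else:
            key = str(row[lower["cell_id"]])
        if key in labels:
            raise ValueError(f"{path}: duplicate key {key!r} at data line {pos + 2}")
        labels[key] = value
    return LabelTable(level, labels)
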