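"""Quantification of the 14 per-peak variables and feature standardization.

For a peak with boundary frames (left, max, right) on intensity y:

* ``A_l = y[max] - y[left]``, ``A_r = y[max] - y[right]``, ``A_d = A_l - A_r``
* ``D_l``, ``D_r``: rise and decay durations in seconds
* ``Dy_max``: maximum first derivative on the rise;
  ``Dy_min``: absolute minimum first derivative on the decay
* ``D2y_max`` / ``D2y_min``: the corresponding second-derivative extrema
  (``D2y_max`` side is configurable; default is the rising side)
* ``R``: trapezoidal area under the raw intensity curve over [left, right]
* ``delta``: time from the previous peak maximum to this one (NaN for the
  first peak); ``Peak_distance_median``: within-signal median of deltas
* ``delta_l2Dymax`` / ``delta_m2Dymin``: times from peak left to the Dy_max
  frame and from peak max to the Dy_min frame

Standardization is column-wise centering/scaling with training-set mean and
sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trace_model import (
    PEAK_FEATURE_NAMES,
    CalciumTrace,
    PeakBoundary,
    PeakFeatureVector,
)


def quantify_peak(
    trace: CalciumTrace,
    peak: PeakBoundary,
    prev_peak: Optional[PeakBoundary] = None,
    d2y_max_side: str = "left",
) -> PeakFeatureVector:
    """Quantify one peak; ``Peak_distance_median`` is left NaN (it is a
    signal-level quantity, filled by :func:`quantify_signal`)."""
    peak.check_on(trace)
    if d2y_max_side not in ("left", "right"):
        raise ValueError("d2y_max_side must be 'left' or 'right'")
    y = trace.intensities
    dt = trace.dt
    dy = np.gradient(y, dt)
    d2y = np.gradient(dy, dt)
    l, m, r = peak.left_idx, peak.max_idx, peak.right_idx

    a_l = float(y[m] - y[l])
    a_r = float(y[m] - y[r])
    rise_dy = dy[l : m + 1]
    fall_dy = dy[m : r + 1]
    i_dymax = l + int(np.argmax(rise_dy))
    i_dymin = m + int(np.argmin(fall_dy))

    if d2y_max_side == "left":
        d2y_max = float(np.max(d2y[l : m + 1]))
    else:
        d2y_max = float(np.max(d2y[m : r + 1]))

    delta = float((m - prev_peak.max_idx) * dt) if prev_peak is not None else float("nan")

    return PeakFeatureVector(
        A_l=a_l,
        A_r=a_r,
        A_d=a_l - a_r,
        D_l=(m - l) * dt,
        D_r=(r - m) * dt,
        Dy_max=float(np.max(rise_dy)),
        Dy_min=float(abs(np.min(fall_dy))),
        D2y_max=d2y_max,
        D2y_min=float(abs(np.min(d2y[m : r + 1]))),
        R=float(np.trapezoid(y[l : r + 1], dx=dt)),
        delta=delta,
        delta_l2Dymax=(i_dymax - l) * dt,
        delta_m2Dymin=(i_dymin - m) * dt,
        Peak_distance_median=float("nan"),
    )


def quantify_signal(
    trace: CalciumTrace,
    peaks: Sequence[PeakBoundary],
    d2y_max_side: str = "left",
) -> list[PeakFeatureVector]:
    """Quantify all peaks of a signal and fill ``Peak_distance_median``.

    Requires at least two peaks (single-peak signals should already have
    been excluded upstream).
    """
    if len(peaks) < 2:
        raise ValueError(
            f"signal {trace.cell_id!r}: quantification needs >= 2 peaks, "
            f"got {len(peaks)}"
        )
    vectors = [
        quantify_peak(trace, peak, peaks[i - 1] if i > 0 else None, d2y_max_side)
        for i, peak in enumerate(peaks)
    ]
    deltas = [v.delta for v in vectors[1:]]
    median = float(np.median(deltas))
    for v in vectors:
        v.Peak_distance_median = median
    return vectors


def features_frame(
    cell_id: str,
    vectors: Sequence[PeakFeatureVector],
    impute_first_delta: bool = True,
) -> pd.DataFrame:
    """Tabulate a signal's peak features, one row per peak.

    The first peak's undefined ``delta`` is imputed with the signal's
    ``Peak_distance_median`` when a complete matrix is required (the default;
    the analytical rule engine works from the vectors directly and never
    sees the imputed value).
    """
    rows = []
    for i, v in enumerate(vectors):
        row = {"cell_id": cell_id, "peak_index": i}
        row.update(v.as_dict())
        if impute_first_delta and np.isnan(row["delta"]):
            row["delta"] = row["Peak_distance_median"]
        rows.append(row)
    return pd.DataFrame(rows, columns=["cell_id", "peak_index"] + PEAK_FEATURE_NAMES)


@dataclass
class StandardizationStats:
    """Per-feature training mean and sample standard deviation."""

    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray


def fit_standardizer(
    frame: pd.DataFrame, feature_names: Optional[Sequence[str]] = None
) -> StandardizationStats:
    """Estimate centering/scaling statistics on a training feature matrix.

    A zero-variance column cannot be scaled and is reported as an error
    naming the offending columns.
    """
    names = list(feature_names) if feature_names is not None else list(frame.columns)
    X = frame[names].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(len(names))
    flagged = [name for name, s in zip(names, sd) if s == 0.0]
    if flagged:
        raise ValueError(f"zero-variance feature column(s): {flagged}")
    return StandardizationStats(names, mean, sd)


def apply_standardizer(
    stats: StandardizationStats, frame: pd.DataFrame
) -> pd.DataFrame:
    """Apply training statistics to a feature matrix (training or test)."""
    missing = [c for c in stats.feature_names if c not in frame.columns]
    if missing:
        raise ValueError(f"feature matrix lacks column(s): {missing}")
    out = frame.copy()
    X = out[stats.feature_names].to_numpy(dtype=float)
    out[stats.feature_names] = (X - stats.mean) / stats.sd
    return out
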