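"""Derivative-based transient peak detection.

Peaks are located by sequential screening of the first derivative of the
intensity trace: an upstroke crossing ``t_up`` opens a peak (peak left), the
first subsequent negative derivative brackets the maximum, and the first
subsequent positive derivative exceeding ``rt_up`` closes it (peak right) —
the small positive threshold steps over noisy fluctuations on the decay.
Two exclusion rules follow: a partial first peak (strongly asymmetric and of
near-background intensity) is dropped, as are noise peaks below a fraction
of the signal's largest amplitude.  Signals retaining fewer than two peaks
carry too little rhythm information and are excluded entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .trace_model import CalciumTrace, PeakBoundary

logger = logging.getLogger(__name__)


@dataclass
class DetectionConfig:
    """Thresholds of the sequential screening and the exclusion rules.

    ``t_up`` and ``rt_up`` are in AU/s at the default 5 Hz sampling
    convention (derivatives are per second, dt = 1/sampling_hz).
    """

    t_up: float = 30.0
    rt_up: float = 2.0
    first_peak_asym_frac: float = 0.50
    first_peak_intensity_floor: float = 5.0
    noise_amp_frac: float = 0.15
    min_peaks: int = 2

    def __post_init__(self) -> None:
        if not self.t_up > 0:
            raise ValueError("t_up must be > 0")
        if self.rt_up < 0:
            raise ValueError("rt_up must be >= 0")
        for name in ("first_peak_asym_frac", "noise_amp_frac"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.min_peaks < 1:
            raise ValueError("min_peaks must be >= 1")


@dataclass
class DerivativeSeries:
    """First or second derivative sampled at every frame of the trace."""

    values: np.ndarray
    order: int

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")


def first_derivative(trace: CalciumTrace) -> DerivativeSeries:
    """First derivative in AU/s: central differences at interior frames,
    one-sided differences at the two endpoints."""
    if trace.n_frames < 3:
        raise ValueError("derivative needs a trace of at least 3 frames")
    return DerivativeSeries(np.gradient(trace.intensities, trace.dt), order=1)


def second_derivative(trace: CalciumTrace) -> DerivativeSeries:
    """Second derivative: the first-derivative operator applied twice."""
    if trace.n_frames < 3:
        raise ValueError("derivative needs a trace of at least 3 frames")
    dy = np.gradient(trace.intensities, trace.dt)
    return DerivativeSeries(np.gradient(dy, trace.dt), order=2)


def _next_index(mask: np.ndarray, start: int) -> Optional[int]:
    """First index >= start where mask is True, or None."""
    hits = np.flatnonzero(mask[start:])
    return None if hits.size == 0 else int(start + hits[0])


def detect_peaks(trace: CalciumTrace, cfg: DetectionConfig | None = None) -> list[PeakBoundary]:
    """Sequentially screen the first derivative for peak boundaries.

    Scanning left to right from the current cursor: the first frame with
    derivative > ``t_up`` is peak left; the first later frame with a negative
    derivative brackets the maximum (taken as the intensity argmax between
    them, first occurrence on ties); the first later frame with derivative
    > ``rt_up`` is peak right, and the cursor jumps past it.  A trailing
    transient whose decay never re-crosses ``rt_up`` before the recording
    ends is truncated at the last frame; a trailing upstroke with no maximum
    is discarded.  Returned boundaries are ordered and non-overlapping.
    """
    cfg = cfg or DetectionConfig()
    if trace.n_frames < 3:
        raise ValueError("peak detection needs a trace of at least 3 frames")
    y = trace.intensities
    dy = first_derivative(trace).values
    n = trace.n_frames

    up = dy > cfg.t_up
    down = dy < 0.0
    close = dy > cfg.rt_up

    peaks: list[PeakBoundary] = []
    cursor = 0
    while cursor < n:
        left = _next_index(up, cursor)
        if left is None:
            break
        sign_change = _next_index(down, left + 1)
        if sign_change is None:
            break  # still rising at the end of the recording: partial upstroke
        # intensity maximum between the upstroke start and the sign change
        # (first occurrence on ties)
        max_idx = left + int(np.argmax(y[left : sign_change + 1]))
        if max_idx == left:
            # a one-frame upstroke: the central-difference crossing frame is
            # itself the maximum, so the transient started one frame earlier
            prev_right = peaks[-1].right_idx if peaks else -1
            if left - 1 > prev_right:
                left -= 1
            else:
                max_idx = left + 1 + int(np.argmax(y[left + 1 : sign_change + 1]))
        right = _next_index(close, sign_change + 1)
        if right is None:
            # recording ends before the next upstroke: truncate at last frame
            if n - 1 > max_idx:
                peaks.append(PeakBoundary(left, max_idx, n - 1))
            break
        peaks.append(PeakBoundary(left, max_idx, right))
        cursor = right + 1
    return peaks


def _amplitudes(trace: CalciumTrace, peak: PeakBoundary) -> tuple[float, float]:
    y = trace.intensities
    return (
        float(y[peak.max_idx] - y[peak.left_idx]),
        float(y[peak.max_idx] - y[peak.right_idx]),
    )


def filter_peaks(
    trace: CalciumTrace,
    peaks: Sequence[PeakBoundary],
    cfg: DetectionConfig | None = None,
) -> list[PeakBoundary]:
    """Apply the first-peak and noise-peak exclusion rules.

    The first peak is dropped iff it is asymmetric (left amplitude below
    ``first_peak_asym_frac`` of the right amplitude) AND its maximum
    intensity is below ``first_peak_intensity_floor`` — the signature of a
    transient already in progress when acquisition started.  Then any peak
    whose max(A_l, A_r) falls below ``noise_amp_frac`` of the largest
    pre-filter amplitude in the signal is dropped as noise.
    """
    cfg = cfg or DetectionConfig()
    if not peaks:
        return []
    for p in peaks:
        p.check_on(trace)
    amps = [max(_amplitudes(trace, p)) for p in peaks]
    pre_filter_max = max(amps)

    kept = list(zip(peaks, amps))
    a_l, a_r = _amplitudes(trace, peaks[0])
    max_intensity = trace.intensities[peaks[0].max_idx]
    if (a_l < cfg.first_peak_asym_frac * a_r
            and max_intensity < cfg.first_peak_intensity_floor):
        kept = kept[1:]

    return [
        p for p, amp in kept
        if amp >= cfg.noise_amp_frac * pre_filter_max
    ]


def apply_min_peak_filter(
    traces_with_peaks: Iterable[tuple[CalciumTrace, Sequence[PeakBoundary]]],
    cfg: DetectionConfig | None = None,
) -> tuple[list[tuple[CalciumTrace, list[PeakBoundary]]], list[tuple[str, str]]]:
    """Drop signals with fewer than ``min_peaks`` surviving peaks.

    Returns the retained (trace, peaks) pairs and a per-signal exclusion
    report of (cell_id, reason); exclusions are also logged.
    """
    cfg = cfg or DetectionConfig()
    retained: list[tuple[CalciumTrace, list[PeakBoundary]]] = []
    excluded: list[tuple[str, str]] = []
    for trace, peaks in traces_with_peaks:
        peaks = list(peaks)
        if len(peaks) < cfg.min_peaks:
            reason = (
                f"{len(peaks)} peak(s) after filtering, "
                f"minimum is {cfg.min_peaks}"
            )
            logger.info("signal %r excluded: %s", trace.cell_id, reason)
            excluded.append((trace.cell_id, reason))
        else:
            retained.append((trace, peaks))
    return retained, excluded


def detect_and_filter(
    trace: CalciumTrace, cfg: DetectionConfig | None = None
) -> list[PeakBoundary]:
    """Convenience: sequential screening followed by the exclusion rules."""
    cfg = cfg or DetectionConfig()
    return filter_peaks(trace, detect_peaks(trace, cfg), cfg)


def boundaries_frame(
    detections: Iterable[tuple[str, Sequence[PeakBoundary]]]
) -> pd.DataFrame:
    """Tabulate detections as (cell_id, peak_index, left_idx, max_idx, right_idx)."""
    rows = [
        {
            "cell_id": cell_id,
            "peak_index": i,
            "left_idx": p.left_idx,
            "max_idx": p.max_idx,
            "right_idx": p.right_idx,
        }
        for cell_id, peaks in detections
        for i, p in enumerate(peaks)
    ]
    return pd.DataFrame(
        rows, columns=["cell_id", "peak_index", "left_idx", "max_idx", "right_idx"]
    )


def plot_detection(trace: CalciumTrace, peaks: Sequence[PeakBoundary], path) -> None:
    """Overlay detected boundaries on the intensity trace and save to PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frames = np.arange(trace.n_frames)
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(frames, trace.intensities, color="tab:blue", lw=1)
    for p in peaks:
        ax.axvspan(p.left_idx, p.right_idx, color="tab:orange", alpha=0.15)
        ax.plot(p.max_idx, trace.intensities[p.max_idx], "v", color="tab:red")
    ax.set_xlabel("frame")
    ax.set_ylabel("fluorescence intensity (AU)")
    ax.set_title(trace.cell_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
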