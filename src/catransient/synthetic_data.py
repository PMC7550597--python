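"""Seeded generator of Ca2+-transient-like traces with ground truth.

Each signal is a baseline plus a slow drift, a quasi-periodic train of
transient templates (difference of exponentials: fast rise, slower decay)
and Gaussian noise.  Abnormal signals carry at least one injected defect,
each emulating a morphology an expert would flag and mapping onto one of the
analytical rules:

* ``small_amplitude``  — one or two transients scaled down (amplitude rules)
* ``asymmetric_decay`` — a transient with a much slower decay, leaving the
  signal elevated at the peak end (asymmetry rule)
* ``irregular_phase``  — one beat skipped, doubling an inter-peak interval
  (phase rule)
* ``baseline_oscillation`` — a diastolic oscillation over the whole signal
* ``spontaneous_release_bump`` — a small extra release between transients

Ground-truth labels are generative (they record what was injected); they are
never derived from the rule engine, so the rule engine and the classifiers
can be tested against them.  Cohorts are bit-reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .trace_model import ABNORMAL, NORMAL, CalciumTrace

DEFECT_NONE = "none"
DEFECT_SMALL_AMPLITUDE = "small_amplitude"
DEFECT_ASYMMETRIC_DECAY = "asymmetric_decay"
DEFECT_IRREGULAR_PHASE = "irregular_phase"
DEFECT_BASELINE_OSCILLATION = "baseline_oscillation"
DEFECT_SPONTANEOUS_BUMP = "spontaneous_release_bump"

DEFECTS = (
    DEFECT_SMALL_AMPLITUDE,
    DEFECT_ASYMMETRIC_DECAY,
    DEFECT_IRREGULAR_PHASE,
    DEFECT_BASELINE_OSCILLATION,
    DEFECT_SPONTANEOUS_BUMP,
)

#: seconds of decay room left between the last transient onset and the end
#: of the recording, so the final transient returns near the diastolic level
_ONSET_HEADROOM_S = 3.0

#: shape of a spontaneous-release bump (narrower and faster than a transient)
_BUMP_WIDTH_S = 0.12
_BUMP_MID_S = 0.6
_BUMP_DECAY_S = 0.35
#: position of a bump within its inter-transient gap
_BUMP_GAP_FRACTION = 0.75


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort.

    Defaults emulate 5 Hz recordings of 12-32 s with a ~2 s beat period
    (about 9-10 transients per signal), ~100 AU transients on a ~100 AU
    baseline, and an abnormal-cell probability of 0.6 split over the five
    defect types.
    """

    n_signals: int = 200
    duration_range: tuple[float, float] = (12.0, 32.0)
    sampling_hz: float = 5.0

    baseline: float = 100.0
    drift_amp: float = 1.0          # AU, slow sinusoidal baseline drift
    drift_freq_hz: float = 0.05

    amp_mean: float = 200.0         # AU
    amp_sd: float = 18.0
    upstroke_width: float = 0.12    # s, logistic upstroke time constant
    upstroke_mid: float = 0.9       # s, upstroke half-rise time after onset
    decay_tau: float = 0.45         # s

    period_mean: float = 2.8        # s between transient onsets
    period_jitter_sd: float = 0.08  # s, beat-to-beat within a signal
    period_between_sd: float = 0.15  # s, cell-to-cell spontaneous-rate spread

    p_small_amplitude: float = 0.15
    p_asymmetric_decay: float = 0.15
    p_irregular_phase: float = 0.15
    p_baseline_oscillation: float = 0.075
    p_spontaneous_bump: float = 0.075

    small_amp_factor: float = 0.30
    asym_decay_tau: float = 2.0     # s, slowed decay of the defective transient
    osc_amp: float = 20.0           # AU, diastolic oscillation
    osc_freq_hz: float = 0.6
    bump_amp_frac: float = 0.30     # of amp_mean

    noise_sd: float = 1.5           # AU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signals < 1:
            raise ValueError("n_signals must be >= 1")
        lo, hi = self.duration_range
        if not (0 < lo <= hi):
            raise ValueError("duration_range must be increasing and positive")
        for name in ("sampling_hz", "amp_mean", "upstroke_width",
                     "upstroke_mid", "decay_tau", "period_mean"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.upstroke_width >= self.decay_tau:
            raise ValueError("upstroke_width must be smaller than decay_tau "
                             "(rapid upstroke, slower decay)")
        if self.defect_probability > 1.0 + 1e-9:
            raise ValueError("defect probabilities must sum to <= 1")
        # at zero jitter the shortest recording must still carry >= 2 peaks
        n_min = 1 + math.floor((lo - _ONSET_HEADROOM_S - 1.2) / self.period_mean)
        if n_min < 2:
            raise ValueError(
                "configuration yields fewer than 2 transients per signal "
                "at zero jitter; lengthen duration_range or shorten period_mean"
            )

    @property
    def defect_probability(self) -> float:
        return (self.p_small_amplitude + self.p_asymmetric_decay
                + self.p_irregular_phase + self.p_baseline_oscillation
                + self.p_spontaneous_bump)


def clean_config(cfg: GeneratorConfig, **overrides) -> GeneratorConfig:
    """A copy with no noise, no drift and no injected defects."""
    return replace(
        cfg,
        noise_sd=0.0,
        drift_amp=0.0,
        p_small_amplitude=0.0,
        p_asymmetric_decay=0.0,
        p_irregular_phase=0.0,
        p_baseline_oscillation=0.0,
        p_spontaneous_bump=0.0,
        **overrides,
    )


def scale_defect_mix(cfg: GeneratorConfig, abnormal_frac: float) -> GeneratorConfig:
    """Rescale the defect probabilities to a given total abnormal fraction."""
    if not 0.0 <= abnormal_frac <= 1.0:
        raise ValueError("abnormal_frac must lie in [0, 1]")
    total = cfg.defect_probability
    if total == 0:
        raise ValueError("cannot rescale a zero defect mix")
    k = abnormal_frac / total
    return replace(
        cfg,
        p_small_amplitude=cfg.p_small_amplitude * k,
        p_asymmetric_decay=cfg.p_asymmetric_decay * k,
        p_irregular_phase=cfg.p_irregular_phase * k,
        p_baseline_oscillation=cfg.p_baseline_oscillation * k,
        p_spontaneous_bump=cfg.p_spontaneous_bump * k,
    )


@dataclass
class Cohort:
    """Generated traces plus per-peak and per-cell ground truth."""

    traces: list[CalciumTrace]
    peak_truth: pd.DataFrame   # cell_id, peak_index, onset_frame, max_idx, label, kind
    cell_truth: pd.DataFrame   # cell_id, label, defect
    config: GeneratorConfig

    def peak_truth_for(self, cell_id: str) -> pd.DataFrame:
        return self.peak_truth[self.peak_truth["cell_id"] == cell_id]


#: the decay is shut off smoothly this many decay constants after the peak,
#: so the fluorescence returns fully to the diastolic level between beats
_CUTOFF_AFTER_PEAK_TAUS = 1.8
_CUTOFF_WIDTH_S = 0.12


def _upstroke_peak_time(width: float, mid: float, decay_tau: float) -> float:
    """Stationary point of sigma((t-mid)/width) * exp(-t/decay_tau)."""
    sig_pk = 1.0 - width / decay_tau
    return mid + width * math.log(sig_pk / (1.0 - sig_pk))


@lru_cache(maxsize=64)
def _template_norm(width: float, mid: float, decay_tau: float) -> float:
    t_pk = _upstroke_peak_time(width, mid, decay_tau)
    grid = np.linspace(0.0, t_pk + 2.0 * decay_tau, 4001)
    return float(_template_raw(grid, width, mid, decay_tau).max())


def _template_raw(
    t: np.ndarray, width: float, mid: float, decay_tau: float
) -> np.ndarray:
    t_cut = (_upstroke_peak_time(width, mid, decay_tau)
             + _CUTOFF_AFTER_PEAK_TAUS * decay_tau)
    return (
        expit((t - mid) / width)
        * np.exp(-t / decay_tau)
        * expit((t_cut - t) / _CUTOFF_WIDTH_S)
    )


def _template(
    t: np.ndarray, amp: float, width: float, mid: float, decay_tau: float
) -> np.ndarray:
    """Transient template normalised so the peak value equals ``amp``.

    A logistic upstroke (real fluorescence upstrokes accelerate smoothly out
    of the diastolic level) multiplied by an exponential decay; the decay is
    smoothly terminated ~1.8 decay constants after the peak so the diastolic
    interval between beats is genuinely quiet rather than an endless tail.
    """
    out = np.zeros_like(t)
    mask = t >= 0
    out[mask] = _template_raw(t[mask], width, mid, decay_tau) * (
        amp / _template_norm(width, mid, decay_tau)
    )
    return out


def transient_time_to_peak(cfg: GeneratorConfig) -> float:
    """Seconds from transient onset to its maximum under the default shape."""
    return _upstroke_peak_time(cfg.upstroke_width, cfg.upstroke_mid, cfg.decay_tau)


def _choose_defect(rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    u = rng.random()
    edge = 0.0
    for name, p in (
        (DEFECT_SMALL_AMPLITUDE, cfg.p_small_amplitude),
        (DEFECT_ASYMMETRIC_DECAY, cfg.p_asymmetric_decay),
        (DEFECT_IRREGULAR_PHASE, cfg.p_irregular_phase),
        (DEFECT_BASELINE_OSCILLATION, cfg.p_baseline_oscillation),
        (DEFECT_SPONTANEOUS_BUMP, cfg.p_spontaneous_bump),
    ):
        edge += p
        if u < edge:
            return name
    return DEFECT_NONE


def _generate_signal(
    rng: np.random.Generator, cfg: GeneratorConfig, cell_id: str
) -> tuple[CalciumTrace, list[dict], str]:
    duration = rng.uniform(*cfg.duration_range)
    hz = cfg.sampling_hz
    n = int(round(duration * hz))
    t = np.arange(n) / hz
    defect = _choose_defect(rng, cfg)

    # each cell beats at its own spontaneous rate; keep the period inside a
    # band that preserves a quiet diastole before every upstroke
    period = float(np.clip(
        rng.normal(cfg.period_mean, cfg.period_between_sd),
        cfg.period_mean - 0.2, cfg.period_mean + 0.4,
    ))

    # quasi-periodic onset times; keep headroom for the rise and maximum
    gaps: list[float] = []
    onsets = [rng.uniform(0.6, 1.2)]
    while True:
        gap = max(period + rng.normal(0.0, cfg.period_jitter_sd), 0.5 * period)
        if onsets[-1] + gap >= duration - _ONSET_HEADROOM_S:
            break
        gaps.append(gap)
        onsets.append(onsets[-1] + gap)

    phase_target = -1
    if defect == DEFECT_IRREGULAR_PHASE:
        if len(onsets) >= 6:
            # pause: drop two consecutive interior transients, so the peak
            # after the gap arrives ~3 periods late (well past the 90%
            # deviation threshold even under jitter and frame quantisation)
            # while the within-signal median stays at one period
            j = int(rng.integers(1, len(onsets) - 2))
            del onsets[j : j + 2]
            phase_target = j
        else:
            # too few beats to express an irregular phase; inject a
            # small-amplitude defect instead
            defect = DEFECT_SMALL_AMPLITUDE

    n_peaks = len(onsets)
    amps = rng.normal(cfg.amp_mean, cfg.amp_sd, size=n_peaks)
    # normal transients have consistent amplitudes; keep them well clear of
    # the 50% amplitude rule so only injected defects cross it
    amps = np.maximum(amps, 0.55 * cfg.amp_mean)
    decay_taus = np.full(n_peaks, cfg.decay_tau)
    labels = [NORMAL] * n_peaks

    if defect == DEFECT_SMALL_AMPLITUDE:
        k = min(n_peaks, int(rng.integers(1, 3)))
        targets = rng.choice(n_peaks, size=k, replace=False)
        for idx in targets:
            amps[idx] = cfg.amp_mean * cfg.small_amp_factor
            labels[idx] = ABNORMAL
    elif defect == DEFECT_ASYMMETRIC_DECAY:
        k = min(n_peaks, int(rng.integers(1, 3)))
        targets = rng.choice(n_peaks, size=k, replace=False)
        for idx in targets:
            decay_taus[idx] = cfg.asym_decay_tau
            labels[idx] = ABNORMAL
    elif defect == DEFECT_IRREGULAR_PHASE and phase_target >= 0:
        labels[phase_target] = ABNORMAL
    elif defect == DEFECT_BASELINE_OSCILLATION:
        labels = [ABNORMAL] * n_peaks

    events = [
        {
            "time": float(onsets[i]),
            "amp": float(amps[i]),
            "width": cfg.upstroke_width,
            "mid": cfg.upstroke_mid,
            "decay_tau": float(decay_taus[i]),
            "label": labels[i],
            "kind": "transient",
        }
        for i in range(n_peaks)
    ]

    if defect == DEFECT_SPONTANEOUS_BUMP and n_peaks >= 2:
        k = min(n_peaks - 1, int(rng.integers(1, 3)))
        slots = rng.choice(n_peaks - 1, size=k, replace=False)
        for j in slots:
            gap = onsets[j + 1] - onsets[j]
            events.append(
                {
                    "time": float(onsets[j] + _BUMP_GAP_FRACTION * gap),
                    "amp": float(cfg.amp_mean * cfg.bump_amp_frac),
                    "width": _BUMP_WIDTH_S,
                    "mid": _BUMP_MID_S,
                    "decay_tau": _BUMP_DECAY_S,
                    "label": ABNORMAL,
                    "kind": "bump",
                }
            )
        events.sort(key=lambda e: e["time"])

    clean = np.full(n, cfg.baseline, dtype=float)
    if cfg.drift_amp > 0:
        clean += cfg.drift_amp * np.sin(
            2 * np.pi * cfg.drift_freq_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if defect == DEFECT_BASELINE_OSCILLATION:
        clean += cfg.osc_amp * np.sin(
            2 * np.pi * cfg.osc_freq_hz * t + rng.uniform(0, 2 * np.pi)
        )
    for e in events:
        clean += _template(t - e["time"], e["amp"], e["width"], e["mid"],
                           e["decay_tau"])

    # ground-truth maxima: argmax of the noiseless composite within each
    # inter-onset window, so they match what any detector can recover
    onset_frames = np.searchsorted(t, [e["time"] for e in events])
    for i, e in enumerate(events):
        start = int(onset_frames[i])
        stop = int(onset_frames[i + 1]) if i + 1 < len(events) else n
        e["onset_frame"] = start
        e["max_idx"] = start + int(np.argmax(clean[start:stop]))

    noisy = clean
    if cfg.noise_sd > 0:
        noisy = clean + rng.normal(0.0, cfg.noise_sd, size=n)

    trace = CalciumTrace(cell_id, noisy, hz, source_tag=f"synthetic:{defect}")
    return trace, events, defect


def generate_cohort(cfg: GeneratorConfig) -> Cohort:
    """Generate ``cfg.n_signals`` traces with ground truth, reproducibly
    from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    traces: list[CalciumTrace] = []
    peak_rows: list[dict] = []
    cell_rows: list[dict] = []
    for i in range(cfg.n_signals):
        cell_id = f"cell{i:04d}"
        trace, events, defect = _generate_signal(rng, cfg, cell_id)
        traces.append(trace)
        for j, e in enumerate(events):
            peak_rows.append(
                {
                    "cell_id": cell_id,
                    "peak_index": j,
                    "onset_frame": e["onset_frame"],
                    "max_idx": e["max_idx"],
                    "label": e["label"],
                    "kind": e["kind"],
                }
            )
        cell_rows.append(
            {
                "cell_id": cell_id,
                "label": ABNORMAL if defect != DEFECT_NONE else NORMAL,
                "defect": defect,
            }
        )
    return Cohort(
        traces=traces,
        peak_truth=pd.DataFrame(
            peak_rows,
            columns=["cell_id", "peak_index", "onset_frame", "max_idx",
                     "label", "kind"],
        ),
        cell_truth=pd.DataFrame(cell_rows, columns=["cell_id", "label", "defect"]),
        config=cfg,
    )


def label_detected_peaks(
    peak_truth: pd.DataFrame, boundaries: Sequence
) -> list[str]:
    """Emulate expert labelling of detected peaks against ground truth.

    Each detected boundary is matched to the planted event whose true
    maximum lies within [left, right] (nearest maximum on multiple matches)
    and inherits its label; a detection matching no planted event is a
    spurious, noise-born peak and is labelled abnormal.
    """
    truth_max = peak_truth["max_idx"].to_numpy()
    truth_label = peak_truth["label"].to_numpy()
    labels: list[str] = []
    for b in boundaries:
        inside = np.flatnonzero((truth_max >= b.left_idx) & (truth_max <= b.right_idx))
        if inside.size == 0:
            labels.append(ABNORMAL)
        else:
            nearest = inside[np.argmin(np.abs(truth_max[inside] - b.max_idx))]
            labels.append(str(truth_label[nearest]))
    return labels
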