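"""Rule-based ("analytical") peak and cell abnormality assessment.

The rule cascade evaluates a signal's peaks left to right.  With the peak
max/min amplitude defined as the larger/smaller of A_l and A_r:

1. The first peak is abnormal if its max amplitude is below ``amp_frac`` of
   the signal's mean max amplitude.
2. A later peak is abnormal if the preceding peak is abnormal and its max
   amplitude is below ``amp_frac`` of the signal mean, or if its max
   amplitude is below ``amp_frac`` of the most recent normal peak's — so a
   run of consecutive shrunken peaks is caught in full.
3. A peak of normal amplitude is abnormal if its min amplitude is below
   ``asym_frac`` of its max amplitude (asymmetric rise/decay, e.g. an
   incomplete return to the diastolic level).
4. A symmetric, amplitude-normal, non-first peak is abnormal if its peak
   distance ``delta`` deviates from the signal's median by more than
   ``phase_frac`` of that median (irregular phase).  A "literal" mode that
   instead flags ``delta > phase_frac * median`` is available.

A cell is abnormal iff at least one of its peaks is abnormal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

import numpy as np
import pandas as pd

from .trace_model import (
    ABNORMAL,
    NORMAL,
    PeakAssessment,
    PeakFeatureVector,
)

RULE_AMPLITUDE = "amplitude"
RULE_ASYMMETRY = "asymmetry"
RULE_PHASE = "irregular_phase"


@dataclass
class RuleConfig:
    amp_frac: float = 0.50
    asym_frac: float = 0.85
    phase_frac: float = 0.90
    phase_mode: str = "deviation"  # or "literal"

    def __post_init__(self) -> None:
        for name in ("amp_frac", "asym_frac", "phase_frac"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.phase_mode not in ("deviation", "literal"):
            raise ValueError("phase_mode must be 'deviation' or 'literal'")


def assess_peaks_analytical(
    signal_features: Sequence[PeakFeatureVector],
    cfg: RuleConfig | None = None,
) -> list[PeakAssessment]:
    """Run the rule cascade over one signal's peaks, left to right."""
    cfg = cfg or RuleConfig()
    if len(signal_features) < 2:
        raise ValueError("analytical assessment needs >= 2 peaks per signal")

    max_amps = [v.max_amplitude for v in signal_features]
    mean_max_amp = float(np.mean(max_amps))

    assessments: list[PeakAssessment] = []
    last_normal_amp: float | None = None
    for i, v in enumerate(signal_features):
        max_amp = v.max_amplitude
        min_amp = v.min_amplitude
        rule = None

        if i == 0:
            if max_amp < cfg.amp_frac * mean_max_amp:
                rule = RULE_AMPLITUDE
        else:
            preceding_abnormal = assessments[-1].is_abnormal
            if preceding_abnormal and max_amp < cfg.amp_frac * mean_max_amp:
                rule = RULE_AMPLITUDE
            elif (last_normal_amp is not None
                    and max_amp < cfg.amp_frac * last_normal_amp):
                rule = RULE_AMPLITUDE

        if rule is None and min_amp < cfg.asym_frac * max_amp:
            rule = RULE_ASYMMETRY

        if rule is None and i > 0 and not math.isnan(v.delta):
            median = v.Peak_distance_median
            if cfg.phase_mode == "deviation":
                irregular = abs(v.delta - median) > cfg.phase_frac * median
            else:
                irregular = v.delta > cfg.phase_frac * median
            if irregular:
                rule = RULE_PHASE

        label = ABNORMAL if rule is not None else NORMAL
        assessments.append(PeakAssessment(label, source="analytical", rule=rule))
        if label == NORMAL:
            last_normal_amp = max_amp
    return assessments


def assess_cell_analytical(
    peak_assessments: Sequence[PeakAssessment],
) -> PeakAssessment:
    """Cell label: abnormal iff the signal contains any abnormal peak."""
    if not peak_assessments:
        raise ValueError("cell assessment needs at least one assessed peak")
    label = ABNORMAL if any(a.is_abnormal for a in peak_assessments) else NORMAL
    return PeakAssessment(label, source="analytical")


def assessments_frame(
    assessments: Sequence[tuple[str, Sequence[PeakAssessment]]]
) -> pd.DataFrame:
    """Tabulate peak assessments as (cell_id, peak_index, label, fired_rule)."""
    rows = [
        {
            "cell_id": cell_id,
            "peak_index": i,
            "label": a.label,
            "fired_rule": a.rule or "",
        }
        for cell_id, items in assessments
        for i, a in enumerate(items)
    ]
    return pd.DataFrame(
        rows, columns=["cell_id", "peak_index", "label", "fired_rule"]
    )
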