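import numpy as np
import pandas as pd
import pytest

from catransient import (
    DetectionConfig,
    GeneratorConfig,
    RuleConfig,
    SVMConfig,
    generate_cohort,
)
from catransient.synthetic_data import clean_config
from catransient.trace_model import PEAK_FEATURE_NAMES, CalciumTrace


@pytest.fixture
def det_cfg():
    return DetectionConfig()


@pytest.fixture
def rule_cfg():
    return RuleConfig()


@pytest.fixture
def svm_cfg():
    return SVMConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A mixed 16-signal cohort with the default abnormality mix."""
    return generate_cohort(GeneratorConfig(n_signals=16, seed=3))


@pytest.fixture(scope="session")
def clean_cohort():
    """A defect-free, noise-free, drift-free 12-signal cohort."""
    return generate_cohort(clean_config(GeneratorConfig(n_signals=12, seed=9)))


def synthetic_feature_frame(rng, n_signals=12, peaks_per_signal=8, separation=3.0):
    """A labelled random peak-feature matrix with two linearly separated
    classes; abnormal rows are shifted along a few feature axes."""
    rows = []
    labels = []
    for i in range(n_signals):
        cell_id = f"s{i:03d}"
        for j in range(peaks_per_signal):
            x = rng.normal(0.0, 1.0, size=len(PEAK_FEATURE_NAMES))
            abnormal = rng.random() < 0.35
            if abnormal:
                x[:4] += separation
            row = {"cell_id": cell_id, "peak_index": j}
            row.update(dict(zip(PEAK_FEATURE_NAMES, x)))
            rows.append(row)
            labels.append("abnormal" if abnormal else "normal")
    frame = pd.DataFrame(rows, columns=["cell_id", "peak_index"] + PEAK_FEATURE_NAMES)
    return frame, np.array(labels)


@pytest.fixture
def feature_frame_factory():
    return synthetic_feature_frame


def triangle_trace(cell_id="tri", hz=1.0, amp=40.0, base=0.0, rise=4, fall=4,
                   pad=6):
    """A single triangular transient with flat padding on both sides."""
    up = np.linspace(base, base + amp, rise + 1)
    down = np.linspace(base + amp, base, fall + 1)[1:]
    y = np.concatenate([np.full(pad, base), up, down, np.full(pad, base)])
    return CalciumTrace(cell_id, y, sampling_hz=hz)
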