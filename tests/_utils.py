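"""Independent reference implementations (oracles) used by the tests.

These deliberately avoid the package's own code paths: derivatives are
computed with explicit loops, the peak screening with plain-Python scans,
and the AUC with the brute-force pairwise rank statistic.
"""

from __future__ import annotations

import math

import numpy as np

from catransient.trace_model import PeakFeatureVector


def naive_first_derivative(y, hz):
    """Loop-based central differences with one-sided endpoints, AU/s."""
    dt = 1.0 / hz
    n = len(y)
    dy = []
    for i in range(n):
        if i == 0:
            dy.append((y[1] - y[0]) / dt)
        elif i == n - 1:
            dy.append((y[n - 1] - y[n - 2]) / dt)
        else:
            dy.append((y[i + 1] - y[i - 1]) / (2.0 * dt))
    return dy


def oracle_detect_peaks(y, hz, t_up, rt_up):
    """Brute-force reference for the sequential screening.

    Enumerates candidate frames with list scans and greedily takes the
    leftmost valid (left, max, right) chain: left = first derivative
    > t_up from the cursor; the maximum is the intensity argmax up to the
    first negative-derivative frame (stepping the boundary one frame back
    when a one-frame upstroke makes the crossing frame itself the maximum);
    right = first derivative > rt_up after the sign change, else the last
    frame.  Returns (left, max, right) tuples.
    """
    y = list(y)
    dy = naive_first_derivative(y, hz)
    n = len(y)
    out = []
    cursor = 0
    while cursor < n:
        lefts = [i for i in range(cursor, n) if dy[i] > t_up]
        if not lefts:
            break
        left = lefts[0]
        signs = [j for j in range(left + 1, n) if dy[j] < 0.0]
        if not signs:
            break
        sign = signs[0]
        m = max(range(left, sign + 1), key=lambda k: (y[k], -k))
        if m == left:
            prev_right = out[-1][2] if out else -1
            if left - 1 > prev_right:
                left -= 1
            else:
                m = max(range(left + 1, sign + 1), key=lambda k: (y[k], -k))
        rights = [k for k in range(sign + 1, n) if dy[k] > rt_up]
        if rights:
            right = rights[0]
            out.append((left, m, right))
            cursor = right + 1
        else:
            if n - 1 > m:
                out.append((left, m, n - 1))
            break
    return out


def pairwise_auc(truth01, scores):
    """AUC as the probability a random abnormal outranks a random normal
    (ties counted half); O(n^2) enumeration."""
    truth01 = list(truth01)
    scores = list(scores)
    pos = [s for t, s in zip(truth01, scores) if t == 1]
    neg = [s for t, s in zip(truth01, scores) if t == 0]
    if not pos or not neg:
        raise ValueError("need both classes")
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def make_pfv(
    A_l=100.0,
    A_r=100.0,
    delta=2.0,
    median=2.0,
    **overrides,
) -> PeakFeatureVector:
    """A feature vector with plausible filler values for rule-level tests."""
    values = dict(
        A_l=A_l,
        A_r=A_r,
        A_d=A_l - A_r,
        D_l=0.8,
        D_r=1.2,
        Dy_max=300.0,
        Dy_min=250.0,
        D2y_max=900.0,
        D2y_min=800.0,
        R=200.0,
        delta=delta,
        delta_l2Dymax=0.4,
        delta_m2Dymin=0.4,
        Peak_distance_median=median,
    )
    values.update(overrides)
    return PeakFeatureVector(**values)


def random_trace_values(rng, n):
    """Random short traces that exercise the screening: a noisy baseline
    with a random number of planted ramps of varied steepness."""
    y = np.cumsum(rng.normal(0.0, 6.0, size=n))
    y += rng.normal(0.0, 2.0, size=n)
    for _ in range(rng.integers(0, 4)):
        start = int(rng.integers(0, n - 6))
        width = int(rng.integers(2, 6))
        height = float(rng.uniform(20.0, 180.0))
        stop = min(n, start + width)
        ramp = np.zeros(n)
        ramp[start:stop] = np.linspace(0.0, height, stop - start)
        ramp[stop:] = height * np.exp(-np.arange(n - stop) / rng.uniform(1.0, 6.0))
        y = y + ramp
    return y + 100.0
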