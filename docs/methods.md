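# Methods

## Signal model and detection procedure

A recording is a fluorescence intensity series y[0..n−1] for one cell,
sampled at `sampling_hz` (default 5 frames/s), in arbitrary units (AU).
Derivatives are computed per second (dt = 1/sampling_hz) with central
differences at interior frames and one-sided differences at the two
endpoints; the second derivative is the same operator applied twice.
Duration-type quantities are reported in seconds so that features remain
comparable across sampling rates; frame indices are 0-based.

Peak boundaries are found by sequential screening of the first derivative:

* **peak left** — the first frame after the cursor with dy > `t_up`
  (default 30 AU/s). The thresholds are calibrated to the per-second
  derivative convention at 5 Hz.
* **peak maximum** — the intensity argmax between peak left and the first
  frame with a negative derivative (first occurrence wins ties). When the
  upstroke is resolved by a single frame, the crossing frame itself can be
  the maximum; the boundary is then moved one frame back (the transient
  started before the threshold crossing), unless that frame already belongs
  to the previous peak, in which case the maximum is taken after the left
  frame. This keeps the invariant left < max < right in all cases.
* **peak right** — the first later frame with dy > `rt_up` (default
  2 AU/s; the small positive threshold steps over derivative fluctuations
  in the diastole). A trailing transient whose decay never re-crosses
  `rt_up` before the recording ends is truncated at the last frame; a
  trailing upstroke with no maximum is discarded as partial. With this
  rule the right boundary lands either in the quiet diastole or at the
  foot of the next upstroke — in both cases at a near-diastolic intensity,
  which is what the boundary-referenced amplitudes assume.

Two exclusion rules follow (in this order): the first peak is removed iff
it is strongly asymmetric (A_l < 50% of A_r) *and* its maximum intensity is
below 5 AU — the signature of a transient already in progress at
acquisition start in background-subtracted data; then any peak whose
max(A_l, A_r) is below 15% of the largest pre-filter amplitude in the
signal is removed as noise (max(A_l, A_r) is used because it is
conservative against dropping true peaks on drifting baselines). Signals
retaining fewer than `min_peaks` (default 2) peaks are excluded entirely,
with a per-signal reason in the log: a single peak carries no rhythm
information and its distance-based features are undefined.

## Peak variables

For a boundary (l, m, r) on intensity y with first/second derivatives
dy/d2y:

| variable | definition | units |
|---|---|---|
| A_l, A_r | y[m] − y[l], y[m] − y[r] | AU |
| A_d | A_l − A_r | AU |
| D_l, D_r | (m − l)·dt, (r − m)·dt | s |
| Dy_max | max dy on [l, m] | AU/s |
| Dy_min | \|min dy on [m, r]\| | AU/s |
| D2y_max | max d2y on [l, m] (side configurable) | AU/s² |
| D2y_min | \|min d2y on [m, r]\| | AU/s² |
| R | trapezoidal integral of y over [l, r] | AU·s |
| delta | (m − m_prev)·dt; undefined for the first peak | s |
| delta_l2Dymax | (argmax-of-dy frame − l)·dt | s |
| delta_m2Dymin | (argmin-of-dy frame − m)·dt | s |
| Peak_distance_median | median of the signal's defined deltas | s |

R integrates the raw intensity with no baseline subtraction, so an
intensity offset c changes R by exactly c·(r−l)·dt and leaves every other
variable unchanged; scaling intensities by k scales the amplitude-,
derivative- and area-type variables by k and leaves durations unchanged.
The test suite asserts both properties to 1e−9.

The interval for D2y_max is the rising side by default and switchable
(`d2y_max_side`): the defining descriptions of this variable disagree
between sources, and the choice is immaterial to the pipeline's structure.

The first peak's missing delta is imputed with the signal's
Peak_distance_median when a complete feature matrix is required (SVM
input); the rule engine reads the raw vectors and simply skips the phase
test for the first peak, so no imputed value reaches a rule.

## Analytical rule cascade

With max/min amplitude = max/min of (A_l, A_r), peaks are assessed left to
right:

1. first peak: abnormal if max amplitude < `amp_frac` (0.50) × the
   signal-mean max amplitude;
2. later peaks: abnormal if (the preceding peak is abnormal and max
   amplitude < `amp_frac` × signal mean) or max amplitude < `amp_frac` ×
   the **most recent normal** peak's max amplitude — the latter reading
   catches a whole run of consecutive shrunken peaks instead of only the
   first;
3. asymmetry (amplitude-normal peaks): abnormal if min amplitude <
   `asym_frac` (0.85) × max amplitude;
4. irregular phase (symmetric, amplitude-normal, non-first peaks):
   abnormal if |delta − median| > `phase_frac` (0.90) × median.

All comparisons are strict, so a value exactly at a threshold does not
fire. The phase rule is implemented as a relative deviation; the literal
alternative "delta > 0.9 × median" (available via
`RuleConfig(phase_mode="literal")`) flags roughly half the peaks of any
perfectly rhythmic signal and is kept only for comparison. A cell is
abnormal iff at least one of its peaks is. "Average" in rule 1/2 is the
arithmetic mean. Rule outcomes are invariant to intensity scaling (all
comparisons are ratios), and rule 3's verdict is final — nothing later
reverses it.

## SVM cascade and cross-validation

Both classifiers are support-vector machines with an RBF kernel, C = 1,
kernel width from the median heuristic (gamma = 1/(2·med²), med = median
pairwise Euclidean distance over at most the first 512 standardized
training rows), and inverse-class-frequency weighting; all are
configurable. These are ordinary defaults for low-dimensional continuous
features with class imbalance — the evaluation here is property-based, not
weight-matching, so nothing hinges on the exact kernel.

Standardization uses the training mean and the sample (n−1) standard
deviation per column; a zero-variance column is a hard error naming the
column. Test rows are always transformed with training statistics.

Peak-level validation is leave-one-signal-out: all peaks of one signal form
the held-out fold and the classifier (including its standardizer) is refit
on all other signals' peaks, so no information from the held-out signal —
features or labels — can reach the model that scores it. The test suite
probes this with a planted signal-unique marker feature and with label
flips. Cell-level features are built from the LOOCV predictions (not from a
model that saw the signal), keeping the cell classifier's inputs honest:

* `analytical_cell_label`, `svm_cell_label` — any-abnormal over the
  corresponding peak assessments, encoded 0/1 and standardized with the
  continuous variables;
* `prop_abnormal` — fraction of SVM-predicted abnormal peaks (switchable to
  the analytical labels via `prop_source`);
* `var_A`, `var_delta`, `var_R` — sample variances of max(A_l, A_r), of the
  defined deltas, and of R. A signal with a single defined delta gets
  var_delta = 0: one interval carries no spread information, and 0 keeps
  the signal scorable.

Decision scores are signed distances from the separating hyperplane with
abnormal positive; they feed the ROC. AUC is the trapezoid over the ROC
with tie-aware thresholds, which equals the probability that a random
abnormal instance outranks a random normal one (asserted against a
brute-force pairwise oracle to 1e−12).

## Synthetic cohorts

The generator emulates the study conditions end to end: 5 Hz sampling,
durations uniform on 12–32 s, a ~100 AU diastolic baseline with a slow
±1 AU drift, and one transient per beat with a logistic upstroke
(width 0.12 s, half-rise 0.9 s after onset — time-to-peak ≈ 1.0 s) times an
exponential decay (tau 0.45 s), normalised to an amplitude drawn from
N(200, 18) AU. The decay is smoothly shut off 1.8 decay constants after the
peak: real transients return fully to the diastolic level between beats,
and without the shutoff the residual exponential tail keeps the diastolic
derivative several AU/s below zero, which interacts with the `rt_up`
boundary rule. Cells beat at their own spontaneous rate (period
N(2.8, 0.15) s, clipped to [2.6, 3.2] s) with 0.08 s beat-to-beat jitter;
the last onset keeps 3 s of decay headroom before the recording ends.
Gaussian noise (sd 1.5 AU) is added last. At these settings a cohort
averages ≈ 7 transients per signal, so 200 signals carry ≈ 1400 peaks.

The 200 AU amplitude scale was chosen against the method's absolute
thresholds: the detected peak-left sits where the two-frame intensity
increment first exceeds t_up·2·dt = 12 AU, so A_l is truncated by roughly
5–15 AU regardless of amplitude; at 200 AU that truncation stays well
inside the 15% asymmetry allowance, as it must for normal peaks in any
data the method is applicable to.

A cell is abnormal with probability 0.6 (small_amplitude 0.15,
asymmetric_decay 0.15, irregular_phase 0.15, baseline_oscillation 0.075,
spontaneous_release_bump 0.075), chosen so cohort composition resembles a
drug-challenge experiment with a majority of affected cells. Each defect
maps onto the morphology it emulates:

* **small_amplitude** — 1–2 transients scaled to 30% amplitude
  (amplitude rules);
* **asymmetric_decay** — 1–2 transients with decay tau 2.0 s, leaving the
  signal elevated at the peak end (asymmetry rule);
* **irregular_phase** — a pause: two consecutive beats are skipped, so the
  next peak arrives ≈ 3 periods late (phase rule). A single skipped beat
  (2× the period) sits exactly at the 1.9×-median firing boundary under
  frame quantisation and jitter, so the unambiguous two-beat pause is used.
  Signals with fewer than six beats cannot express the defect and receive a
  small-amplitude defect instead (their ground-truth record says so);
* **baseline_oscillation** — a 20 AU, 0.6 Hz diastolic oscillation over the
  whole signal; every peak is labelled abnormal, matching how an expert
  treats diastolic Ca²⁺ oscillations. No single rule is guaranteed to fire,
  which is precisely the blind spot that motivates the learned classifiers;
* **spontaneous_release_bump** — 1–2 small (60 AU), fast extra release
  events between beats, labelled abnormal.

Ground truth is generative: peak positions are the argmax of the noiseless
composite within each inter-onset window, and labels record what was
injected — never what the rule engine says — so the rules and classifiers
can be scored against them. Emulated expert labels for *detected* peaks
inherit the label of the planted event whose true maximum falls inside the
detected boundary; a detection matching no planted event is labelled
abnormal, as an expert would treat a noise-born peak.

What the generator does not emulate: photobleaching trends, motion
artefacts, multi-cell cross-talk, drug-specific kinetic signatures,
ratiometric readouts, and graded/ambiguous morphologies on which human
experts disagree. Passing tests therefore demonstrate the pipeline's
internal correctness and its behaviour under the stated morphologies — not
clinical-grade accuracy on real recordings, where class separations are
narrower and label noise exists.

## Numerical and interface choices

* Detection and the rule cascade are fully deterministic; the SVMs are
  deterministic given fixed hyperparameters (no probability calibration),
  so identical configuration and seed reproduce byte-identical CSV outputs.
* Ties in argmax/argmin take the first occurrence.
* evaluate() reports sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP)
  with abnormal as the positive class, as percentages (one decimal in text
  output, full precision in JSON); with single-class truth the ROC/AUC are
  reported as missing rather than guessed.
* Trace CSVs are parsed with round-trip float precision, so
  write → read reproduces intensities bit-exactly.
* Problem sizes: the shipped benchmark and acceptance script use 200
  training and 54 test signals (≈ 1400 training peaks); the unit suite uses
  cohorts of 12–60 signals.

## Known limitations

* The boundary-referenced amplitudes (A_l in particular) are truncated by
  whatever intensity the upstroke has gained when the derivative crosses
  t_up; on low-amplitude recordings (≲ 80 AU at 5 Hz) this systematically
  inflates asymmetry and the thresholds would need recalibration.
* A transient whose decay is interrupted by the next upstroke before
  returning near baseline (fast beating with slow reuptake) is flagged
  asymmetric by construction; that is arguably correct physiology but means
  rule 3 conflates two morphologies.
* The analytical cell label is a strict any-abnormal OR: one noisy peak
  flips the cell. The cell-level SVM compensates only as far as its
  training labels allow.
* LOOCV refits one classifier per signal; for cohorts far beyond ~10³
  signals a grouped k-fold would be the pragmatic substitute.
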