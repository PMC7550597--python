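"""End-to-end orchestration: detection -> features -> rules -> SVM cascade.

These functions tie the modules together for the CLI and for benchmark
scripts; they hold no science of their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .analytical_rules import (
    RuleConfig,
    assess_cell_analytical,
    assess_peaks_analytical,
)
from .evaluation import EvaluationReport, evaluate
from .peak_detection import (
    DetectionConfig,
    apply_min_peak_filter,
    detect_and_filter,
)
from .peak_features import features_frame, quantify_signal
from .svm_pipeline import (
    SVMConfig,
    TrainedClassifier,
    build_cell_features,
    loocv_cell_predictions,
    loocv_peak_predictions,
    predict_cells,
    train_cell_svm,
    train_peak_svm,
)
from .synthetic_data import Cohort, GeneratorConfig, generate_cohort, label_detected_peaks
from .trace_model import CalciumTrace, PeakAssessment, PeakBoundary, PeakFeatureVector

logger = logging.getLogger(__name__)


@dataclass
class ProcessedSignal:
    """One retained signal after detection, filtering and quantification."""

    trace: CalciumTrace
    peaks: list[PeakBoundary]
    vectors: list[PeakFeatureVector]
    frame: pd.DataFrame  # cell_id, peak_index + the 14 variables (delta imputed)


def process_traces(
    traces: Sequence[CalciumTrace], det_cfg: DetectionConfig | None = None
) -> tuple[list[ProcessedSignal], list[tuple[str, str]]]:
    """Detect, filter and quantify every trace; report per-signal exclusions."""
    det_cfg = det_cfg or DetectionConfig()
    detected = [(t, detect_and_filter(t, det_cfg)) for t in traces]
    retained, excluded = apply_min_peak_filter(detected, det_cfg)
    processed = []
    for trace, peaks in retained:
        vectors = quantify_signal(trace, peaks)
        processed.append(
            ProcessedSignal(trace, peaks, vectors,
                            features_frame(trace.cell_id, vectors))
        )
    return processed, excluded


def assess_processed(
    processed: Sequence[ProcessedSignal], rule_cfg: RuleConfig | None = None
) -> tuple[dict[str, list[PeakAssessment]], dict[str, str]]:
    """Analytical peak assessments and the derived cell labels per signal."""
    rule_cfg = rule_cfg or RuleConfig()
    peak_assessments: dict[str, list[PeakAssessment]] = {}
    cell_labels: dict[str, str] = {}
    for sig in processed:
        assessments = assess_peaks_analytical(sig.vectors, rule_cfg)
        peak_assessments[sig.trace.cell_id] = assessments
        cell_labels[sig.trace.cell_id] = assess_cell_analytical(assessments).label
    return peak_assessments, cell_labels


@dataclass
class TrainingResult:
    peak_model: TrainedClassifier
    cell_model: TrainedClassifier
    peak_features: pd.DataFrame          # pooled, with cell_id/peak_index
    expert_peak_labels: pd.Series        # aligned with peak_features rows
    analytical_peak_labels: pd.Series
    loocv_peak: pd.DataFrame             # cell_id, peak_index, label, score
    cell_features: pd.DataFrame
    expert_cell_labels: pd.Series        # indexed by cell_id
    analytical_cell_labels: pd.Series
    loocv_cell: pd.DataFrame             # cell_id, label, score
    reports: dict[str, EvaluationReport]
    exclusions: list[tuple[str, str]]


def run_training(
    traces: Sequence[CalciumTrace],
    expert_peak_labels: Mapping[str, Sequence[str]],
    expert_cell_labels: Mapping[str, str],
    det_cfg: DetectionConfig | None = None,
    rule_cfg: RuleConfig | None = None,
    svm_cfg: SVMConfig | None = None,
) -> TrainingResult:
    """Train the full cascade on expert-labelled traces.

    ``expert_peak_labels`` maps cell_id to one label per detected peak (in
    peak order); ``expert_cell_labels`` maps cell_id to the cell label.
    Peak-level predictions for the training signals come from
    leave-one-signal-out CV, so the cell-level features are honest; the
    returned models are refit on all training data.
    """
    det_cfg = det_cfg or DetectionConfig()
    rule_cfg = rule_cfg or RuleConfig()
    svm_cfg = svm_cfg or SVMConfig()

    processed, excluded = process_traces(traces, det_cfg)
    if not processed:
        raise ValueError("no signal survived peak detection and filtering")

    analytical, analytical_cell = assess_processed(processed, rule_cfg)

    pooled = pd.concat([s.frame for s in processed], ignore_index=True)
    peak_labels = []
    for sig in processed:
        cid = sig.trace.cell_id
        labels = list(expert_peak_labels[cid])
        if len(labels) != len(sig.frame):
            raise ValueError(
                f"signal {cid!r}: {len(labels)} expert peak labels for "
                f"{len(sig.frame)} detected peaks"
            )
        peak_labels.extend(labels)
    peak_labels = pd.Series(peak_labels, name="expert")

    loocv_peak = loocv_peak_predictions(pooled, peak_labels, svm_cfg)
    peak_model = train_peak_svm(pooled, peak_labels, svm_cfg)

    svm_preds = {
        cid: group["label"].tolist()
        for cid, group in loocv_peak.groupby("cell_id", sort=False)
    }
    cell_frame = build_cell_features(
        {s.trace.cell_id: s.frame for s in processed},
        analytical,
        svm_preds,
        prop_source=svm_cfg.prop_source,
    )
    cell_ids = cell_frame["cell_id"].tolist()
    cell_labels = pd.Series([expert_cell_labels[c] for c in cell_ids],
                            index=cell_ids, name="expert")

    loocv_cell = loocv_cell_predictions(cell_frame, cell_labels.to_numpy(), svm_cfg)
    cell_model = train_cell_svm(cell_frame, cell_labels.to_numpy(), svm_cfg)

    analytical_peak = pd.Series(
        [a.label for s in processed for a in analytical[s.trace.cell_id]],
        name="analytical",
    )
    analytical_cell_series = pd.Series(
        [analytical_cell[c] for c in cell_ids], index=cell_ids, name="analytical"
    )
    loocv_cell_series = pd.Series(
        loocv_cell["label"].to_numpy(), index=loocv_cell["cell_id"], name="svm"
    )
    loocv_cell_scores = pd.Series(
        loocv_cell["score"].to_numpy(), index=loocv_cell["cell_id"], name="score"
    )

    reports = {
        "peak_analytical": evaluate(analytical_peak, peak_labels),
        "peak_svm_loocv": evaluate(loocv_peak["label"], peak_labels),
        "cell_analytical": evaluate(analytical_cell_series, cell_labels),
        "cell_svm_loocv": evaluate(loocv_cell_series, cell_labels,
                                   scores=loocv_cell_scores),
    }

    return TrainingResult(
        peak_model=peak_model,
        cell_model=cell_model,
        peak_features=pooled,
        expert_peak_labels=peak_labels,
        analytical_peak_labels=analytical_peak,
        loocv_peak=loocv_peak,
        cell_features=cell_frame,
        expert_cell_labels=cell_labels,
        analytical_cell_labels=analytical_cell_series,
        loocv_cell=loocv_cell,
        reports=reports,
        exclusions=excluded,
    )


def expert_labels_from_cohort(
    cohort: Cohort, processed: Sequence[ProcessedSignal]
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Emulated expert labels for a synthetic cohort's detected peaks."""
    peak_labels = {
        s.trace.cell_id: label_detected_peaks(
            cohort.peak_truth_for(s.trace.cell_id), s.peaks
        )
        for s in processed
    }
    cell_truth = cohort.cell_truth.set_index("cell_id")["label"]
    cell_labels = {s.trace.cell_id: str(cell_truth[s.trace.cell_id])
                   for s in processed}
    return peak_labels, cell_labels


@dataclass
class BenchmarkResult:
    training: TrainingResult
    test_predictions: pd.DataFrame
    test_exclusions: list[tuple[str, str]]
    reports: dict[str, EvaluationReport]
    counts: dict[str, int]


def run_benchmark(
    train_cfg: GeneratorConfig,
    test_cfg: GeneratorConfig,
    det_cfg: DetectionConfig | None = None,
    rule_cfg: RuleConfig | None = None,
    svm_cfg: SVMConfig | None = None,
) -> BenchmarkResult:
    """Full synthetic benchmark: train on one seeded cohort, score another.

    Expert labels are the generator's ground truth.  Reports cover both the
    analytical and the SVM route at peak and cell level, on the training
    cohort (via LOOCV) and the held-out test cohort.
    """
    det_cfg = det_cfg or DetectionConfig()
    rule_cfg = rule_cfg or RuleConfig()
    svm_cfg = svm_cfg or SVMConfig()

    train_cohort = generate_cohort(train_cfg)
    processed, _ = process_traces(train_cohort.traces, det_cfg)
    peak_labels, cell_labels = expert_labels_from_cohort(train_cohort, processed)
    training = run_training(
        train_cohort.traces, peak_labels, cell_labels, det_cfg, rule_cfg, svm_cfg
    )

    test_cohort = generate_cohort(test_cfg)
    predictions, test_excluded, _ = predict_cells(
        training.peak_model, training.cell_model, test_cohort.traces,
        det_cfg, rule_cfg, prop_source=svm_cfg.prop_source,
    )

    test_truth_all = test_cohort.cell_truth.set_index("cell_id")["label"]
    scored_ids = predictions["cell_id"].tolist()
    test_truth = test_truth_all.loc[scored_ids]
    test_pred = pd.Series(predictions["label"].to_numpy(), index=scored_ids)
    test_scores = pd.Series(predictions["score"].to_numpy(), index=scored_ids)

    # the analytical route on the test cohort, for the head-to-head comparison
    test_processed, _ = process_traces(test_cohort.traces, det_cfg)
    test_processed = [s for s in test_processed if s.trace.cell_id in set(scored_ids)]
    _, test_analytical_cell = assess_processed(test_processed, rule_cfg)
    test_analytical = pd.Series(
        {cid: test_analytical_cell[cid] for cid in scored_ids}
    ).loc[scored_ids]

    reports = dict(training.reports)
    reports["cell_test_svm"] = evaluate(test_pred, test_truth, scores=test_scores)
    reports["cell_test_analytical"] = evaluate(test_analytical, test_truth)

    counts = {
        "train_signals": len(training.cell_features),
        "train_peaks": len(training.peak_features),
        "test_signals": len(scored_ids),
        "test_excluded": len(test_excluded),
    }
    return BenchmarkResult(
        training=training,
        test_predictions=predictions,
        test_exclusions=test_excluded,
        reports=reports,
        counts=counts,
    )
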