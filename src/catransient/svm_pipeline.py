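"""The two-stage SVM cascade.

A peak-level SVM is trained on the 14 standardized peak variables against
expert peak labels.  Its leave-one-signal-out predictions (every peak scored
by a model that never saw any peak of its own signal, standardization refit
inside each fold) feed, together with the analytical assessments, into six
per-signal variables, on which a cell-level SVM predicts cell abnormality.

Kernel and hyperparameters default to an RBF kernel with C = 1, a
median-heuristic kernel width, and inverse-class-frequency weighting; all
are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.svm import SVC

from .analytical_rules import RuleConfig, assess_cell_analytical, assess_peaks_analytical
from .peak_detection import (
    DetectionConfig,
    apply_min_peak_filter,
    detect_and_filter,
)
from .peak_features import (
    StandardizationStats,
    apply_standardizer,
    features_frame,
    fit_standardizer,
    quantify_signal,
)
from .trace_model import (
    ABNORMAL,
    CELL_FEATURE_NAMES,
    NORMAL,
    PEAK_FEATURE_NAMES,
    CalciumTrace,
    PeakAssessment,
)

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: rows used for the median-heuristic pairwise-distance estimate
_MEDIAN_HEURISTIC_MAX_ROWS = 512


@dataclass
class SVMConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: Union[str, float] = "median"  # "median", "scale", or a float
    class_weight: Optional[str] = "balanced"
    prop_source: str = "svm"  # which peak labels feed prop_abnormal

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.prop_source not in ("svm", "analytical"):
            raise ValueError("prop_source must be 'svm' or 'analytical'")


def _median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF width from the median pairwise Euclidean distance: the kernel
    then resolves typical inter-point separations.  Deterministic: uses the
    first rows of the (already ordered) training matrix."""
    sample = X[:_MEDIAN_HEURISTIC_MAX_ROWS]
    if sample.shape[0] < 2:
        return 1.0 / X.shape[1]
    med = float(np.median(pdist(sample)))
    if med <= 0:
        return 1.0 / X.shape[1]
    return 1.0 / (2.0 * med * med)


@dataclass
class TrainedClassifier:
    """A fitted binary classifier plus the statistics needed to apply it.

    Scoring refuses feature frames whose feature column names or order
    differ from those seen at training time.  ``decision`` scores are signed
    distances from the separating boundary with abnormal positive.
    """

    level: str  # "peak" or "cell"
    feature_names: list[str]
    stats: StandardizationStats
    model: SVC
    metadata: dict = field(default_factory=dict)

    def _check_columns(self, frame: pd.DataFrame) -> None:
        present = [c for c in frame.columns if c in set(self.feature_names)]
        if present != self.feature_names:
            raise ValueError(
                f"{self.level}-level classifier expects feature columns "
                f"{self.feature_names} in order; got {present}"
            )

    def _matrix(self, frame: pd.DataFrame) -> np.ndarray:
        self._check_columns(frame)
        return apply_standardizer(self.stats, frame)[self.feature_names].to_numpy(
            dtype=float
        )

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        """Binary labels ('normal'/'abnormal') for each row."""
        X = self._matrix(frame)
        return np.where(self.model.predict(X) == 1, ABNORMAL, NORMAL)

    def decision_scores(self, frame: pd.DataFrame) -> np.ndarray:
        return self.model.decision_function(self._matrix(frame))


def _labels_to01(labels) -> np.ndarray:
    arr = np.asarray(
        [1 if str(v).strip().lower() == ABNORMAL else 0 for v in labels], dtype=int
    )
    return arr


def _train(
    level: str,
    frame: pd.DataFrame,
    feature_names: Sequence[str],
    labels,
    cfg: SVMConfig,
) -> TrainedClassifier:
    y = _labels_to01(labels)
    if len(y) != len(frame):
        raise ValueError("labels do not align with feature rows")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError(
            f"{level}-level training set contains a single class; "
            "both normal and abnormal examples are required"
        )
    stats = fit_standardizer(frame, feature_names)
    X = apply_standardizer(stats, frame)[list(feature_names)].to_numpy(dtype=float)
    gamma = cfg.gamma
    if gamma == "median":
        gamma = _median_heuristic_gamma(X)
    model = SVC(kernel=cfg.kernel, C=cfg.C, gamma=gamma,
                class_weight=cfg.class_weight)
    model.fit(X, y)
    meta = {
        "n_rows": int(len(y)),
        "n_normal": int(np.sum(y == 0)),
        "n_abnormal": int(np.sum(y == 1)),
        "gamma": float(gamma) if not isinstance(gamma, str) else gamma,
        "C": cfg.C,
        "kernel": cfg.kernel,
        "class_weight": cfg.class_weight,
    }
    return TrainedClassifier(level, list(feature_names), stats, model, meta)


def train_peak_svm(
    features: pd.DataFrame, labels, cfg: SVMConfig | None = None
) -> TrainedClassifier:
    """Fit the peak-level SVM on an (unstandardized) 14-variable matrix."""
    cfg = cfg or SVMConfig()
    return _train("peak", features, PEAK_FEATURE_NAMES, labels, cfg)


def train_cell_svm(
    cell_features: pd.DataFrame, labels, cfg: SVMConfig | None = None
) -> TrainedClassifier:
    """Fit the cell-level SVM on the 6 per-signal variables (the two binary
    label variables are standardized together with the continuous ones)."""
    cfg = cfg or SVMConfig()
    return _train("cell", cell_features, CELL_FEATURE_NAMES, labels, cfg)


def _loocv(
    frame: pd.DataFrame,
    labels,
    feature_names: Sequence[str],
    group_col: str,
    level: str,
    cfg: SVMConfig,
) -> pd.DataFrame:
    y = np.asarray([str(v).strip().lower() for v in labels])
    if len(y) != len(frame):
        raise ValueError("labels do not align with feature rows")
    groups = frame[group_col].to_numpy()
    unique = list(dict.fromkeys(groups))
    if len(unique) < 3:
        raise ValueError("leave-one-signal-out CV needs at least 3 signals")

    frame = frame.reset_index(drop=True)
    parts = []
    for sid in unique:
        held = groups == sid
        train_frame = frame.loc[~held]
        train_labels = y[~held]
        if len(set(train_labels)) < 2:
            raise ValueError(
                f"LOOCV fold holding out signal {sid!r} has single-class "
                "training labels"
            )
        clf = _train(level, train_frame, feature_names, train_labels, cfg)
        test_frame = frame.loc[held]
        part = test_frame[[c for c in (group_col, "peak_index") if c in frame.columns]].copy()
        part["label"] = clf.predict(test_frame)
        part["score"] = clf.decision_scores(test_frame)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def loocv_peak_predictions(
    features: pd.DataFrame, labels, cfg: SVMConfig | None = None
) -> pd.DataFrame:
    """Leave-one-signal-out peak predictions.

    ``features`` must carry a ``cell_id`` column grouping peaks into
    signals; each signal's peaks are predicted by a model fitted (with its
    own standardization) on all other signals' peaks only.
    """
    cfg = cfg or SVMConfig()
    if "cell_id" not in features.columns:
        raise ValueError("peak feature matrix must carry a cell_id column")
    return _loocv(features, labels, PEAK_FEATURE_NAMES, "cell_id", "peak", cfg)


def loocv_cell_predictions(
    cell_features: pd.DataFrame, labels, cfg: SVMConfig | None = None
) -> pd.DataFrame:
    """Leave-one-signal-out predictions for the cell-level classifier."""
    cfg = cfg or SVMConfig()
    if "cell_id" not in cell_features.columns:
        raise ValueError("cell feature matrix must carry a cell_id column")
    return _loocv(cell_features, labels, CELL_FEATURE_NAMES, "cell_id", "cell", cfg)


def _any_abnormal(labels: Sequence[str]) -> int:
    return int(any(str(v).strip().lower() == ABNORMAL for v in labels))


def build_cell_features(
    feature_frames: Mapping[str, pd.DataFrame],
    analytical: Mapping[str, Sequence[PeakAssessment]],
    svm_predictions: Mapping[str, Sequence[str]],
    prop_source: str = "svm",
) -> pd.DataFrame:
    """Assemble the 6 per-signal variables for each cell.

    * ``analytical_cell_label`` / ``svm_cell_label``: any-abnormal over the
      corresponding peak assessments (0 = normal, 1 = abnormal)
    * ``prop_abnormal``: fraction of abnormal peak predictions
    * ``var_A`` / ``var_delta`` / ``var_R``: sample variances of the per-peak
      max amplitude, the defined peak distances, and the peak areas
    """
    if prop_source not in ("svm", "analytical"):
        raise ValueError("prop_source must be 'svm' or 'analytical'")
    if set(feature_frames) != set(analytical) or set(feature_frames) != set(svm_predictions):
        raise ValueError("cell ids of the three peak-level sources do not match")

    rows = []
    for cell_id, frame in feature_frames.items():
        ana = [a.label for a in analytical[cell_id]]
        svm = [str(v).strip().lower() for v in svm_predictions[cell_id]]
        if not (len(frame) == len(ana) == len(svm)):
            raise ValueError(
                f"signal {cell_id!r}: peak counts differ between sources "
                f"(features {len(frame)}, analytical {len(ana)}, svm {len(svm)})"
            )
        prop_labels = svm if prop_source == "svm" else ana
        n = len(prop_labels)
        prop = sum(1 for v in prop_labels if v == ABNORMAL) / n

        amp = np.maximum(frame["A_l"].to_numpy(), frame["A_r"].to_numpy())
        deltas = frame.loc[frame["peak_index"] > 0, "delta"].to_numpy()
        areas = frame["R"].to_numpy()

        def _var(values: np.ndarray) -> float:
            # a single defined value carries no spread information
            return float(np.var(values, ddof=1)) if values.size >= 2 else 0.0

        rows.append(
            {
                "cell_id": cell_id,
                "analytical_cell_label": float(_any_abnormal(ana)),
                "svm_cell_label": float(_any_abnormal(svm)),
                "prop_abnormal": prop,
                "var_A": _var(amp),
                "var_delta": _var(deltas),
                "var_R": _var(areas),
            }
        )
    return pd.DataFrame(rows, columns=["cell_id"] + CELL_FEATURE_NAMES)


def predict_cells(
    peak_model: TrainedClassifier,
    cell_model: TrainedClassifier,
    traces: Sequence[CalciumTrace],
    det_cfg: DetectionConfig | None = None,
    rule_cfg: RuleConfig | None = None,
    prop_source: str = "svm",
) -> tuple[pd.DataFrame, list[tuple[str, str]], dict]:
    """Score new signals end to end with trained models.

    Each trace runs through detection, filtering, quantification, analytical
    rules and peak-SVM scoring (with the stored training standardization);
    the resulting cell variables are scored by the cell-level model.
    Signals retaining fewer than two peaks are reported as excluded, never
    silently dropped.  Returns (predictions, exclusions, provenance): the
    predictions table has columns cell_id, label, score, n_peaks,
    prop_abnormal, and provenance maps cell_id to the per-peak boundaries,
    analytical labels and SVM predictions that fed its cell vector.
    """
    det_cfg = det_cfg or DetectionConfig()
    rule_cfg = rule_cfg or RuleConfig()

    detected = [(t, detect_and_filter(t, det_cfg)) for t in traces]
    retained, excluded = apply_min_peak_filter(detected, det_cfg)

    feature_frames: dict[str, pd.DataFrame] = {}
    analytical: dict[str, list[PeakAssessment]] = {}
    svm_preds: dict[str, list[str]] = {}
    provenance: dict[str, dict] = {}
    for trace, peaks in retained:
        vectors = quantify_signal(trace, peaks)
        frame = features_frame(trace.cell_id, vectors)
        preds = list(peak_model.predict(frame))
        feature_frames[trace.cell_id] = frame
        analytical[trace.cell_id] = assess_peaks_analytical(vectors, rule_cfg)
        svm_preds[trace.cell_id] = preds
        provenance[trace.cell_id] = {
            "boundaries": [(p.left_idx, p.max_idx, p.right_idx) for p in peaks],
            "analytical_labels": [a.label for a in analytical[trace.cell_id]],
            "svm_peak_predictions": preds,
        }

    if not feature_frames:
        empty = pd.DataFrame(
            columns=["cell_id", "label", "score", "n_peaks", "prop_abnormal"]
        )
        return empty, excluded, provenance

    cell_frame = build_cell_features(feature_frames, analytical, svm_preds,
                                     prop_source=prop_source)
    out = cell_frame[["cell_id"]].copy()
    out["label"] = cell_model.predict(cell_frame)
    out["score"] = cell_model.decision_scores(cell_frame)
    out["n_peaks"] = [len(feature_frames[c]) for c in cell_frame["cell_id"]]
    out["prop_abnormal"] = cell_frame["prop_abnormal"]
    return out, excluded, provenance


def save_models(path, peak_model: TrainedClassifier,
                cell_model: TrainedClassifier, config: dict | None = None) -> None:
    """Serialize both classifiers (and the effective config) to one file."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "peak_model": peak_model,
            "cell_model": cell_model,
            "config": config or {},
        },
        path,
    )


def load_models(path) -> tuple[TrainedClassifier, TrainedClassifier, dict]:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model file version {version!r} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return payload["peak_model"], payload["cell_model"], payload["config"]
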