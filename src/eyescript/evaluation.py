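"""Leave-one-subject-out validation and recognition metrics.

A leave-one-subject-out (LOSO) fold holds out every epoch of one participant
and trains the normalization factors and (optional) SVM on the remaining
participants; the digit templates themselves are fixed canonical designs and
are never refitted.  Because the dissimilarity of a trace to a template does
not depend on the fold, the (n_traces x 10) dissimilarity matrix is computed
once and shared across folds.

Overall accuracy is (correctly classified patterns) / (total patterns);
per-participant accuracy restricts both counts to one participant; per-digit
precision, recall and F1 come from the pooled confusion matrix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._exceptions import ArgumentError
from .classification import (
    TemplateClassifier,
    WarpConstraints,
    train_combined,
)
from .trace_reconstruction import EyeTrace

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "visual_angle",
    "accuracy_overall",
    "digit_metrics",
    "loso_evaluate",
    "threshold_sweep",
]


def visual_angle(width_cm: float, distance_cm: float) -> float:
    """Full horizontal visual angle (degrees) of a flat screen.

    A screen of the given width viewed from its centre at the given
    perpendicular distance subtends ``2 * arctan(width / 2 / distance)``.
    """
    if not (width_cm > 0 and distance_cm > 0):
        raise ArgumentError("width and distance must be > 0")
    return math.degrees(2.0 * math.atan2(width_cm / 2.0, distance_cm))


@dataclass
class ConfusionMatrix:
    """10x10 count matrix; rows = true digit, columns = predicted digit."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (10, 10):
            raise ArgumentError("confusion matrix must be 10x10")
        if (self.counts < 0).any():
            raise ArgumentError("confusion counts must be >= 0")

    @classmethod
    def from_predictions(cls, true, pred) -> "ConfusionMatrix":
        counts = np.zeros((10, 10), dtype=int)
        for t, p in zip(true, pred):
            counts[int(t), int(p)] += 1
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def accuracy_overall(conf: ConfusionMatrix) -> float:
    """Trace of the confusion matrix over its total count."""
    if conf.total == 0:
        raise ArgumentError("empty confusion matrix")
    return float(np.trace(conf.counts) / conf.total)


def digit_metrics(conf: ConfusionMatrix, digit: int) -> dict:
    """Precision, recall and F1 for one digit.

    A zero denominator (the digit was never predicted, or never attempted)
    yields 0.0 with an ``undefined`` flag so report tables stay rectangular.
    """
    if digit not in range(10):
        raise ArgumentError("digit must be 0..9")
    tp = int(conf.counts[digit, digit])
    fp = int(conf.counts[:, digit].sum() - tp)
    fn = int(conf.counts[digit, :].sum() - tp)
    undefined = []
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    if tp + fp == 0:
        undefined.append("precision")
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    if tp + fn == 0:
        undefined.append("recall")
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    if precision + recall == 0:
        undefined.append("f1")
    return {"precision": precision, "recall": recall, "f1": f1,
            "undefined": undefined}


@dataclass
class EvalReport:
    """Aggregate LOSO results: overall, per-participant and per-digit."""

    overall_acc: float
    per_participant: dict
    per_digit: dict
    confusion: ConfusionMatrix
    config: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "overall_acc": self.overall_acc,
            "per_participant": self.per_participant,
            "per_digit": {str(k): v for k, v in self.per_digit.items()},
            "confusion": self.confusion.counts.tolist(),
            "config": self.config,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "EvalReport":
        text = Path(source).read_text() if isinstance(source, (str, Path)) \
            and str(source).endswith(".json") else str(source)
        payload = json.loads(text)
        return cls(
            payload["overall_acc"],
            payload["per_participant"],
            {int(k): v for k, v in payload["per_digit"].items()},
            ConfusionMatrix(np.array(payload["confusion"])),
            payload.get("config", {}),
        )

    def participant_mean_acc(self) -> float:
        """Unweighted mean of per-participant accuracies."""
        return float(np.mean(list(self.per_participant.values())))


def _dissimilarity_matrix(traces, clf: TemplateClassifier) -> np.ndarray:
    return np.array([clf.dissimilarities(t) for t in traces])


def loso_evaluate(
    traces: list[EyeTrace],
    labels: list[int],
    participants: list,
    templates: dict[int, EyeTrace],
    measure: str = "dpw",
    use_svm: bool = True,
    constraints: WarpConstraints | None = None,
    metric: str = "l1",
    holdout_group: set | None = None,
    dissim: np.ndarray | None = None,
) -> EvalReport:
    """Leave-one-subject-out evaluation of one classifier configuration.

    ``holdout_group`` lists participants that are only ever tested, never
    trained on (e.g. a patient group evaluated against models trained on
    the healthy cohort); their folds reuse the full non-holdout training
    set.  Deterministic: no randomness beyond the input data.
    """
    labels = np.asarray(labels, dtype=int)
    participants = np.asarray(participants, dtype=object)
    holdout_group = holdout_group or set()
    unique = list(dict.fromkeys(participants.tolist()))
    if len([p for p in unique if p not in holdout_group]) < 2:
        raise ArgumentError("LOSO needs at least 2 training participants")
    base = TemplateClassifier(templates, measure,
                              constraints or WarpConstraints(), metric)
    if dissim is None:
        dissim = _dissimilarity_matrix(traces, base)
    trainable = ~np.isin(participants, list(holdout_group))
    all_true, all_pred, all_pid = [], [], []
    for pid in unique:
        test_idx = np.flatnonzero(participants == pid)
        train_idx = np.flatnonzero(trainable & (participants != pid))
        clf = train_combined(
            [traces[i] for i in train_idx], labels[train_idx], templates,
            measure, constraints, metric, use_svm,
            dissim=dissim[train_idx],
        )
        from .classification import predict as _predict
        for i in test_idx:
            all_true.append(int(labels[i]))
            all_pred.append(_predict(clf, traces[i], dissim[i]))
            all_pid.append(pid)
    conf = ConfusionMatrix.from_predictions(all_true, all_pred)
    per_participant = {}
    for pid in unique:
        sel = [k for k, p in enumerate(all_pid) if p == pid]
        correct = sum(all_true[k] == all_pred[k] for k in sel)
        per_participant[str(pid)] = correct / len(sel)
    per_digit = {d: digit_metrics(conf, d) for d in range(10)}
    return EvalReport(
        accuracy_overall(conf), per_participant, per_digit, conf,
        {"measure": measure, "svm": use_svm,
         "M": (constraints or WarpConstraints()).M, "metric": metric},
    )


def threshold_sweep(
    recordings: list,
    labels: list[int],
    participants: list,
    thresholds,
    methods,
    templates: dict[int, EyeTrace],
    pipeline_cfg=None,
) -> list[dict]:
    """Overall LOSO accuracy per (threshold, method) combination.

    ``methods`` is an iterable of ``(measure, use_svm)`` pairs.  Epochs whose
    reconstruction fails at a given threshold (e.g. no segment survives a
    very high θ) count as misclassified.  Returns plot-ready rows
    ``{"threshold", "measure", "svm", "accuracy", "failed"}``.
    """
    from dataclasses import replace as _replace

    from ._exceptions import EyescriptError
    from .trace_reconstruction import PipelineConfig, reconstruct

    base_cfg = pipeline_cfg or PipelineConfig()
    rows = []
    for theta in thresholds:
        if not theta > 0:
            raise ArgumentError("thresholds must be > 0 (0 masks everything in)")
        cfg = _replace(base_cfg, threshold=float(theta))
        ok_idx, traces = [], []
        for i, rec in enumerate(recordings):
            try:
                traces.append(reconstruct(rec, cfg))
                ok_idx.append(i)
            except EyescriptError:
                pass
        for measure, use_svm in methods:
            if len(ok_idx) < len(recordings) * 0.5 or not ok_idx:
                rows.append({"threshold": float(theta), "measure": measure,
                             "svm": use_svm, "accuracy": 0.0,
                             "failed": len(recordings) - len(ok_idx)})
                continue
            try:
                report = loso_evaluate(
                    traces, [labels[i] for i in ok_idx],
                    [participants[i] for i in ok_idx], templates,
                    measure, use_svm)
                correct = round(report.overall_acc * len(ok_idx))
                acc = correct / len(recordings)
            except EyescriptError:
                acc = 0.0
            rows.append({"threshold": float(theta), "measure": measure,
                         "svm": use_svm, "accuracy": acc,
                         "failed": len(recordings) - len(ok_idx)})
    return rows
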