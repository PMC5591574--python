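"""Trace classification: DTW, DPW, nearest-template, and the SVM combination.

Both dissimilarity measures run on the *increments* of the traces (derivative
form), which makes them insensitive to absolute position.  Dynamic time
warping (DTW) aligns the two sequences in time under a step set
``{(1,m),(m,1) | 1 <= m <= M}``; each cell cost compares the one-step
increments of the two traces.  Dynamic positional warping (DPW) extends this
to 2-D shapes: the increment entering a cell's cost is taken relative to the
predecessor selected by the warp itself, so warping acts on the value axis
as well as time — a skewed or locally rescaled stroke pays less than under
DTW.

A nearest-template rule over the ten digit templates is the base classifier.
The SVM combination turns the ten dissimilarities into a feature vector:
each is divided by its class normalization factor (the mean within-class
dissimilarity on training data), and a linear multi-class SVM is trained on
those 10-dimensional vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from ._exceptions import ArgumentError, StateError, TrainingError
from .trace_reconstruction import EyeTrace

__all__ = [
    "WarpConstraints",
    "DissimilarityResult",
    "TemplateClassifier",
    "dtw_dissimilarity",
    "dpw_dissimilarity",
    "dissimilarity",
    "nearest_template",
    "fit_normalization",
    "feature_vector",
    "train_combined",
    "predict",
    "save_model",
    "load_model",
]

DEFAULT_M = 8


@dataclass(frozen=True)
class WarpConstraints:
    """Warping step set {(1,m),(m,1) | 1 <= m <= M}.

    ``M`` is the maximum warping distance per step.  Steps are enumerated in
    the canonical order (1,1),(1,2),...,(1,M),(2,1),...,(M,1); argmin ties
    resolve to the first step in this order.
    """

    M: int = DEFAULT_M

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ArgumentError("M must be >= 1")

    @property
    def steps(self) -> list[tuple[int, int]]:
        return [(1, m) for m in range(1, self.M + 1)] + [
            (m, 1) for m in range(2, self.M + 1)
        ]


@dataclass
class DissimilarityResult:
    """Dissimilarity value plus (optionally) the DP cost table."""

    d: float
    lengths: tuple[int, int]
    table: np.ndarray | None = None


def _increment_cost(da: np.ndarray, db: np.ndarray, metric: str) -> np.ndarray:
    diff = da - db
    if metric == "l1":
        return np.abs(diff).sum(axis=-1)
    if metric == "l2":
        return np.sqrt((diff ** 2).sum(axis=-1))
    raise ArgumentError(f"unknown metric '{metric}'")


def _check_pair(A: EyeTrace, B: EyeTrace) -> tuple[np.ndarray, np.ndarray]:
    if len(A) < 2 or len(B) < 2:
        raise ArgumentError("both traces need at least 2 points")
    return A.points, B.points


def dtw_dissimilarity(
    A: EyeTrace,
    B: EyeTrace,
    constraints: WarpConstraints | None = None,
    metric: str = "l1",
    keep_table: bool = False,
) -> DissimilarityResult:
    """Derivative-form DTW dissimilarity between two traces.

    Cell cost is the metric distance between the one-step increments
    ``A(i)-A(i-1)`` and ``B(j)-B(j-1)``; the accumulated cost adds the
    minimum predecessor over the step set.  Indices below the first sample
    clamp to it, and the (1,1) cell is zero.
    """
    c = constraints or WarpConstraints()
    a, b = _check_pair(A, B)
    n, m = len(a), len(b)
    M = c.M
    # one-step increments with the leading sample clamped (zero increment)
    dA = np.vstack([[0.0, 0.0], np.diff(a, axis=0)])
    dB = np.vstack([[0.0, 0.0], np.diff(b, axis=0)])
    cost = _increment_cost(dA[:, None, :], dB[None, :, :], metric)  # (n, m)
    tau = np.empty((n, m))
    # first row: all predecessors clamp onto row 0 itself -> left-to-right scan
    tau[0, 0] = 0.0
    for j in range(1, m):
        w = tau[0, max(j - M, 0):j]
        tau[0, j] = cost[0, j] + w.min()
    js = np.arange(m)
    col_shift = [np.maximum(js - off, 0) for off in range(M + 1)]
    for i in range(1, n):
        cands = [tau[max(i - 1, 0), col_shift[off]] for off in range(1, M + 1)]
        cands += [tau[max(i - off, 0), col_shift[1]] for off in range(2, M + 1)]
        omega = np.min(cands, axis=0)
        tau[i] = cost[i] + omega
    return DissimilarityResult(float(tau[-1, -1]), (n, m),
                               tau if keep_table else None)


def dpw_dissimilarity(
    A: EyeTrace,
    B: EyeTrace,
    constraints: WarpConstraints | None = None,
    metric: str = "l1",
    keep_table: bool = False,
) -> DissimilarityResult:
    """Derivative-form DPW dissimilarity between two traces.

    Each cell minimises, jointly over the warp steps, the cost of comparing
    increments taken *relative to the step's predecessor*
    (``A(i)-A(i_prev)`` vs ``B(j)-B(j_prev)``, with ``i_prev = i - C_A(c)``
    and ``j_prev = j - C_B(c)``) plus that predecessor's accumulated cost.
    Warping therefore acts on the value axis as well as time: a stroke
    traversed with a different local pacing is consolidated into one
    multi-sample increment instead of paying a per-sample mismatch.  For
    DTW's step-independent cell cost this recurrence reduces exactly to the
    classic ``cost + min_c tau`` form, of which this is the natural
    generalisation; the minimising step identifies the predecessor pair.
    """
    c = constraints or WarpConstraints()
    a, b = _check_pair(A, B)
    n, m = len(a), len(b)
    steps = c.steps
    M = c.M
    js = np.arange(m)
    jprev = np.stack([np.maximum(js - cb, 0) for _, cb in steps])  # (S, m)
    # B(j) - B(j - C_B(c)) for every step, clamped
    dB = np.stack([b - b[np.maximum(js - cb, 0)] for _, cb in steps])
    ca_arr = np.array([ca for ca, _ in steps])
    tau = np.empty((n, m))
    tau[0, 0] = 0.0
    for j in range(1, m):
        # i_prev clamps to the first sample: the A increment is zero
        tau[0, j] = min(
            tau[0, max(j - cb, 0)]
            + float(_increment_cost(np.zeros(2), b[j] - b[max(j - cb, 0)],
                                    metric))
            for _, cb in steps
        )
    for i in range(1, n):
        ip = np.maximum(i - ca_arr, 0)                       # (S,)
        da = a[i] - a[ip]                                    # (S, 2)
        cost = _increment_cost(da[:, None, :], dB, metric)   # (S, m)
        tau[i] = (cost + tau[ip[:, None], jprev]).min(axis=0)
    return DissimilarityResult(float(tau[-1, -1]), (n, m),
                               tau if keep_table else None)


def dissimilarity(
    A: EyeTrace,
    B: EyeTrace,
    measure: str = "dpw",
    constraints: WarpConstraints | None = None,
    metric: str = "l1",
) -> float:
    if measure == "dtw":
        return dtw_dissimilarity(A, B, constraints, metric).d
    if measure == "dpw":
        return dpw_dissimilarity(A, B, constraints, metric).d
    raise ArgumentError(f"unknown measure '{measure}'")


@dataclass
class TemplateClassifier:
    """Nearest-template classifier, optionally SVM-combined.

    ``normalization`` maps each digit to its mean within-class dissimilarity
    on training data; when an SVM is present it operates on the vector of
    normalized dissimilarities to the ten templates.
    """

    templates: dict[int, EyeTrace]
    measure: str = "dpw"
    constraints: WarpConstraints = field(default_factory=WarpConstraints)
    metric: str = "l1"
    normalization: dict[int, float] | None = None
    svm: SVC | None = None
    train_features: np.ndarray | None = None
    train_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if sorted(self.templates) != list(range(10)):
            raise ArgumentError("classifier needs templates for all labels 0..9")
        if self.svm is not None and self.normalization is None:
            raise ArgumentError("an SVM requires fitted normalization factors")

    def dissimilarities(self, trace: EyeTrace) -> np.ndarray:
        """Dissimilarity of a trace to each template, ordered by label."""
        return np.array([
            dissimilarity(trace, self.templates[k], self.measure,
                          self.constraints, self.metric)
            for k in range(10)
        ])


def nearest_template(trace: EyeTrace, clf: TemplateClassifier) -> int:
    """Label of the minimum-dissimilarity template (ties -> lowest label)."""
    return int(np.argmin(clf.dissimilarities(trace)))


def fit_normalization(
    traces: list[EyeTrace],
    labels: list[int],
    clf: TemplateClassifier,
    dissim: np.ndarray | None = None,
) -> dict[int, float]:
    """Per-class mean dissimilarity to the class's own template.

    ``dissim`` can supply a precomputed (n_traces, 10) dissimilarity matrix
    to avoid recomputation.
    """
    labels = np.asarray(labels)
    missing = sorted(set(range(10)) - set(labels.tolist()))
    if missing:
        raise TrainingError(f"training data lacks class(es) {missing}")
    if dissim is None:
        dissim = np.array([clf.dissimilarities(t) for t in traces])
    factors = {}
    for k in range(10):
        factors[k] = float(dissim[labels == k, k].mean())
        if factors[k] <= 0:
            raise TrainingError(
                f"class {k} has zero mean dissimilarity to its template; "
                "normalization is degenerate"
            )
    return factors


def feature_vector(
    trace: EyeTrace, clf: TemplateClassifier, dissim: np.ndarray | None = None
) -> np.ndarray:
    """Normalized-dissimilarity feature vector (component k = d_k / factor_k)."""
    if clf.normalization is None:
        raise StateError("normalization factors are not fitted")
    d = clf.dissimilarities(trace) if dissim is None else np.asarray(dissim)
    return d / np.array([clf.normalization[k] for k in range(10)])


def train_combined(
    traces: list[EyeTrace],
    labels: list[int],
    templates: dict[int, EyeTrace],
    measure: str = "dpw",
    constraints: WarpConstraints | None = None,
    metric: str = "l1",
    use_svm: bool = True,
    svm_c: float = 1.0,
    dissim: np.ndarray | None = None,
) -> TemplateClassifier:
    """Fit normalization factors and (optionally) the linear SVM.

    The SVM is a linear-kernel, one-vs-one multi-class maximum-margin
    classifier on the 10-dimensional normalized-dissimilarity features.
    """
    clf = TemplateClassifier(templates, measure,
                             constraints or WarpConstraints(), metric)
    labels = np.asarray(labels, dtype=int)
    if dissim is None:
        dissim = np.array([clf.dissimilarities(t) for t in traces])
    clf.normalization = fit_normalization(traces, labels, clf, dissim)
    if use_svm:
        factors = np.array([clf.normalization[k] for k in range(10)])
        feats = dissim / factors
        if np.allclose(feats.var(axis=0), 0):
            raise TrainingError("all features have zero variance")
        svm = SVC(kernel="linear", C=svm_c, decision_function_shape="ovo")
        svm.fit(feats, labels)
        clf.svm = svm
        clf.train_features = feats
        clf.train_labels = labels
    return clf


def predict(clf: TemplateClassifier, trace: EyeTrace,
            dissim: np.ndarray | None = None) -> int:
    """SVM decision when present, otherwise the nearest template."""
    d = clf.dissimilarities(trace) if dissim is None else np.asarray(dissim)
    if clf.svm is not None:
        feats = feature_vector(trace, clf, d)
        return int(clf.svm.predict(feats[None, :])[0])
    return int(np.argmin(d))


def save_model(clf: TemplateClassifier, path) -> None:
    """Serialize a classifier to JSON (templates, factors, SVM training set).

    The SVM itself is re-fitted deterministically on load from the stored
    feature matrix, which round-trips the decision function exactly.
    """
    payload = {
        "measure": clf.measure,
        "metric": clf.metric,
        "M": clf.constraints.M,
        "templates": {str(k): t.points.tolist() for k, t in clf.templates.items()},
        "normalization": (None if clf.normalization is None
                          else {str(k): v for k, v in clf.normalization.items()}),
        "svm": None,
    }
    if clf.svm is not None:
        payload["svm"] = {
            "C": float(clf.svm.C),
            "features": clf.train_features.tolist(),
            "labels": clf.train_labels.tolist(),
        }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> TemplateClassifier:
    payload = json.loads(Path(path).read_text())
    templates = {int(k): EyeTrace(np.array(v), normalized=True)
                 for k, v in payload["templates"].items()}
    clf = TemplateClassifier(templates, payload["measure"],
                             WarpConstraints(payload["M"]), payload["metric"])
    if payload["normalization"] is not None:
        clf.normalization = {int(k): float(v)
                             for k, v in payload["normalization"].items()}
    if payload["svm"] is not None:
        feats = np.array(payload["svm"]["features"])
        labels = np.array(payload["svm"]["labels"], dtype=int)
        svm = SVC(kernel="linear", C=payload["svm"]["C"],
                  decision_function_shape="ovo")
        svm.fit(feats, labels)
        clf.svm = svm
        clf.train_features = feats
        clf.train_labels = labels
    return clf
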