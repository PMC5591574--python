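"""From bipolar EOG to a normalized 2-D eye-writing trace.

The writing trace is the (horizontal, vertical) EOG sample pairs restricted
to saccadic segments (fixations carry no shape information and are dropped),
resampled so adjacent points are equidistant, and scaled to the unit box.

The vertical EOG component commonly contains a fraction of the horizontal
one (electrode placement is never perfectly symmetric about the horizontal
axis), which skews the reconstructed shape.  Writing the observed vertical
component as ``v_obs = v_true + alpha * h`` and noting that the true
increments of a written character are uncorrelated with the horizontal
increments on average, ``alpha`` is identifiable from the epoch itself: it
is the ordinary-least-squares slope of the vertical increments regressed on
the horizontal increments, and subtracting ``alpha * x`` from ``y`` is the
unique correction that zeroes that slope.  No calibration recording is
needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._exceptions import (
    ArgumentError,
    DegenerateTraceError,
    EstimationError,
    PipelineStageError,
)
from . import preprocessing as prep
from . import saccade_detection as sacc
from .io_formats import EogRecording
from .preprocessing import BipolarSignal
from .saccade_detection import SaccadeMask

__all__ = [
    "EyeTrace",
    "CrosstalkModel",
    "PipelineConfig",
    "extract_trace",
    "resample_equidistant",
    "normalize_box",
    "finite_difference",
    "estimate_alpha",
    "remove_crosstalk",
    "reconstruct",
]


@dataclass
class EyeTrace:
    """Ordered 2-D point sequence of reconstructed gaze writing."""

    points: np.ndarray  # (n, 2)
    normalized: bool = False
    source_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ArgumentError("trace points must have shape (n, 2)")
        if len(self.points) < 2:
            raise DegenerateTraceError("a trace needs at least 2 points")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass
class CrosstalkModel:
    """Estimated horizontal-to-vertical interdependency coefficient."""

    alpha: float
    fit_slope_before: float
    fit_slope_after: float


def extract_trace(sig: BipolarSignal, mask: SaccadeMask) -> EyeTrace:
    """Keep the (h, v) samples inside saccadic segments, in time order."""
    if len(mask.mask) != len(sig):
        raise ArgumentError("mask and signal lengths differ")
    if not mask.segments:
        raise DegenerateTraceError("no saccadic segments: nothing was written")
    idx = np.concatenate([np.arange(s, e + 1) for s, e in mask.segments])
    pts = np.column_stack([sig.h[idx], sig.v[idx]])
    return EyeTrace(pts, normalized=False,
                    source_meta={"segments": list(mask.segments)})


def _polyline_arcs(points: np.ndarray):
    """Drop zero-length segments; return cleaned points and segment lengths."""
    d = np.diff(points, axis=0)
    seg = np.hypot(d[:, 0], d[:, 1])
    keep = np.concatenate([[True], seg > 0])
    pts = points[keep]
    d = np.diff(pts, axis=0)
    seg = np.hypot(d[:, 0], d[:, 1])
    return pts, seg


def resample_equidistant(trace: EyeTrace, n_points: int) -> EyeTrace:
    """Resample so adjacent points are separated by equal Euclidean gaps.

    Points are placed at uniform arc-length positions along the input
    polyline, which makes every gap between neighbours on a common straight
    span an identical chord; only a gap whose span straddles a corner is
    (slightly) shorter, the chord cutting the corner.  An exact equal-chord
    placement with a fixed point count does not exist in general — the
    walk's residual jumps discontinuously whenever a chord starts to short-
    cut a corner — so uniform arc length is the well-posed reading.
    Endpoints are preserved.
    """
    if n_points < 2:
        raise ArgumentError("n_points must be >= 2")
    pts, seg = _polyline_arcs(trace.points)
    if len(pts) < 2:
        raise DegenerateTraceError("zero total path length; cannot resample")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, cum[-1], n_points)
    out = np.column_stack([np.interp(target, cum, pts[:, 0]),
                           np.interp(target, cum, pts[:, 1])])
    out[-1] = pts[-1]
    return EyeTrace(out, trace.normalized, dict(trace.source_meta))


def normalize_box(trace: EyeTrace) -> EyeTrace:
    """Scale each axis independently so the bounding box is [0,1] x [0,1].

    Aspect ratio is intentionally not preserved: width and height are both
    mapped to one.  An axis with (numerically) zero extent is centred at 0.5.
    """
    pts = trace.points.copy()
    for ax in (0, 1):
        lo, hi = pts[:, ax].min(), pts[:, ax].max()
        extent = hi - lo
        other = pts[:, 1 - ax].max() - pts[:, 1 - ax].min()
        if extent <= 1e-9 * max(other, 1.0):
            pts[:, ax] = 0.5
        else:
            pts[:, ax] = (pts[:, ax] - lo) / extent
    return EyeTrace(pts, normalized=True, source_meta=dict(trace.source_meta))


def finite_difference(series: np.ndarray) -> np.ndarray:
    """Central finite difference s'(t) = s(t+1) - s(t-1); length n-2."""
    s = np.asarray(series, dtype=float)
    if len(s) < 3:
        raise ArgumentError("finite difference needs at least 3 samples")
    return s[2:] - s[:-2]


def estimate_alpha(trace: EyeTrace) -> CrosstalkModel:
    """Estimate the crosstalk coefficient from the trace's own increments.

    alpha is the least-squares slope of dy on dx in finite-difference
    space — the unique value for which the compensated increments
    dy - alpha*dx have zero regression slope on dx.  The regression runs
    through the origin: the difference cloud of a written character is
    centred there by construction, and an intercept would let the shape's
    net displacement (start-to-end drift of the writing) masquerade as
    crosstalk.  Identifiability rests on the writing's own vertical
    increments being uncorrelated with its horizontal ones, which holds for
    patterns built from axis-aligned strokes; a shape dominated by one
    oblique stroke biases the estimate.
    """
    if len(trace) < 3:
        raise ArgumentError("alpha estimation needs at least 3 points")
    dx = finite_difference(trace.x)
    dy = finite_difference(trace.y)
    sxx = float(dx @ dx)
    if sxx <= 0:
        raise EstimationError("sum(dx^2) = 0: alpha is not identifiable")
    slope_before = float(dx @ dy) / sxx
    resid = dy - slope_before * dx
    slope_after = float(dx @ resid) / sxx
    return CrosstalkModel(slope_before, slope_before, slope_after)


def remove_crosstalk(
    trace: EyeTrace, model: CrosstalkModel, renormalize: bool = True
) -> EyeTrace:
    """Subtract alpha * x from y; x is untouched.

    The compensated trace is renormalized to the unit box by default (the
    correction changes the vertical extent).
    """
    pts = trace.points.copy()
    pts[:, 1] = pts[:, 1] - model.alpha * pts[:, 0]
    out = EyeTrace(pts, trace.normalized, dict(trace.source_meta))
    return normalize_box(out) if renormalize else out


@dataclass
class PipelineConfig:
    """Parameters of the full reconstruction pipeline."""

    target_rate: float = 64.0
    median_window_ms: float = 31.0
    blink_scales_ms: tuple = (100.0, 150.0, 200.0)
    blink_k_mad: float = 6.0
    blink_pair_window_ms: float = 250.0
    blink_min_amplitude_uv: float = 30.0
    baseline_ms: float = 100.0
    cwt_scale: int = sacc.DEFAULT_SCALE
    threshold: float = sacc.DEFAULT_THRESHOLD
    n_points: int = 128
    compensate_crosstalk: bool = True


def reconstruct(
    rec: EogRecording,
    cfg: PipelineConfig | None = None,
    return_stages: bool = False,
):
    """Run the full ordered pipeline from raw recording to normalized trace.

    downsample -> median filter -> blink detect -> baseline removal ->
    bipolar -> blink interpolation -> drift removal -> saccade detection ->
    extract -> equidistant resampling -> unit-box normalization ->
    crosstalk estimation/removal -> renormalization.

    With ``return_stages`` the intermediate artifacts are returned alongside
    the trace for inspection.
    """
    cfg = cfg or PipelineConfig()
    stages: dict = {}

    def run(name, fn):
        try:
            result = fn()
        except Exception as exc:
            if isinstance(exc, PipelineStageError):
                raise
            raise PipelineStageError(name, exc) from exc
        stages[name] = result
        return result

    low = run("downsample", lambda: prep.downsample(rec, cfg.target_rate))
    win = round(cfg.median_window_ms * 1e-3 * cfg.target_rate)
    win = max(1, win if win % 2 == 1 else win + 1)
    filt = run("median_filter", lambda: EogRecording(
        np.column_stack([prep.median_filter(low.samples[:, c], win)
                         for c in range(low.samples.shape[1])]),
        low.rate, dict(low.channels), dict(low.meta)))
    v_raw = filt.channel("above") - filt.channel("below")
    emphasized = run("blink_filter", lambda: prep.blink_emphasis_filter(
        v_raw, filt.rate, cfg.blink_scales_ms))
    blinks = run("detect_blinks", lambda: prep.detect_blinks(
        emphasized, cfg.blink_k_mad, cfg.blink_pair_window_ms,
        cfg.blink_min_amplitude_uv))
    debased = run("remove_baseline", lambda: EogRecording(
        np.column_stack([prep.remove_baseline(filt.samples[:, c], filt.rate,
                                              cfg.baseline_ms)
                         for c in range(filt.samples.shape[1])]),
        filt.rate, dict(filt.channels), dict(filt.meta)))
    bipolar = run("derive_bipolar", lambda: prep.derive_bipolar(debased))
    patched = run("interpolate_blinks",
                  lambda: prep.interpolate_blinks(bipolar, blinks))
    detrended = run("remove_drift", lambda: BipolarSignal(
        prep.remove_drift(patched.h), prep.remove_drift(patched.v),
        patched.rate))
    mask = run("detect_saccades", lambda: sacc.detect_saccades(
        detrended, cfg.threshold, cfg.cwt_scale))
    trace = run("extract_trace", lambda: extract_trace(detrended, mask))
    trace = run("resample", lambda: resample_equidistant(trace, cfg.n_points))
    trace = run("normalize", lambda: normalize_box(trace))
    if cfg.compensate_crosstalk:
        model = run("estimate_alpha", lambda: estimate_alpha(trace))
        trace = run("remove_crosstalk", lambda: remove_crosstalk(trace, model))
    trace = replace(trace, source_meta={**trace.source_meta,
                                        **{k: rec.meta[k] for k in rec.meta}})
    return (trace, stages) if return_stages else trace
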