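"""Signal conditioning ahead of saccade detection.

The stages mirror the acquisition pipeline of an EOG eye-writing session:

1. anti-aliased downsampling (2048 Hz acquisition -> 64 Hz analysis rate),
2. median filtering against impulsive high-frequency noise,
3. blink-artifact detection on the vertical channel and excision,
4. per-channel baseline removal (median of a short preceding window),
5. bipolar derivation (right-left horizontal, above-below vertical),
6. linear interpolation across excised blink gaps,
7. removal of slow linear drift by ordinary least squares.

Blinks dominate the vertical channels as large (~hundreds of microvolts)
transients a few hundred milliseconds long; saccades are step-like changes an
order of magnitude briefer in their edges.  The emphasis filter below is a
bank of paired moving-average differences (a smoothed first derivative at a
few scales around the blink half-duration): a blink maps onto a local maximum
followed, within roughly its half-duration, by a local minimum, while an
isolated saccadic step produces a single one-signed lobe and is never paired.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage, signal as sps

from ._exceptions import ArgumentError, ConfigurationError
from .io_formats import EogRecording

__all__ = [
    "BlinkInterval",
    "BlinkFilterOutput",
    "BipolarSignal",
    "downsample",
    "median_filter",
    "blink_emphasis_filter",
    "detect_blinks",
    "remove_baseline",
    "derive_bipolar",
    "interpolate_blinks",
    "remove_drift",
]


@dataclass
class BlinkInterval:
    """Closed sample-index interval [start, end] covering one blink."""

    start: int
    end: int
    peak: int

    def __post_init__(self) -> None:
        if not self.start <= self.peak <= self.end:
            raise ArgumentError("blink interval requires start <= peak <= end")


@dataclass
class BlinkFilterOutput:
    """Output of the blink emphasis filter plus the winning scale W."""

    values: np.ndarray
    width: int  # W, samples
    rate: float


@dataclass
class BipolarSignal:
    """Derived horizontal (right-left) and vertical (above-below) EOG."""

    h: np.ndarray
    v: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.h.shape != self.v.shape or self.h.ndim != 1:
            raise ArgumentError("h and v must be 1-D series of equal length")
        if not self.rate > 0:
            raise ArgumentError("rate must be > 0")

    def __len__(self) -> int:
        return len(self.h)


def downsample(rec: EogRecording, target_rate: float) -> EogRecording:
    """Resample a recording to ``target_rate`` with polyphase anti-aliasing."""
    if target_rate >= rec.rate:
        raise ArgumentError(
            f"target rate {target_rate} must be below the recording rate {rec.rate}"
        )
    ratio = Fraction(target_rate / rec.rate).limit_denominator(10_000)
    # line-extension padding: EOG rides on large baseline offsets, and the
    # default zero-padding would fabricate step transients at the epoch edges
    out = sps.resample_poly(rec.samples, ratio.numerator, ratio.denominator,
                            axis=0, padtype="line")
    return EogRecording(out, target_rate, dict(rec.channels), dict(rec.meta))


def median_filter(series: np.ndarray, window: int) -> np.ndarray:
    """Sliding-median filter with reflected edges; window must be odd."""
    window = int(window)
    if window < 1 or window % 2 == 0:
        raise ArgumentError("median filter window must be odd and >= 1")
    if window == 1:
        return np.asarray(series, dtype=float).copy()
    return ndimage.median_filter(
        np.asarray(series, dtype=float), size=window, mode="reflect"
    )


def _odd_window(ms: float, rate: float) -> int:
    n = max(1, round(ms * 1e-3 * rate))
    return n if n % 2 == 1 else n + 1


def blink_emphasis_filter(
    series: np.ndarray,
    rate: float,
    scales_ms: tuple = (100.0, 150.0, 200.0),
) -> BlinkFilterOutput:
    """Emphasise blink transients in a vertical EOG series.

    For each scale ``w`` the response is the mean of the next ``w`` of signal
    minus the mean of the previous ``w`` (a paired difference of moving
    averages).  The scale with the largest absolute response wins and defines
    the filter width ``W``.
    """
    s = np.asarray(series, dtype=float)
    best: BlinkFilterOutput | None = None
    for ms in scales_ms:
        w = max(2, round(ms * 1e-3 * rate))
        lead = np.empty_like(s)
        lag = np.empty_like(s)
        # trailing mean of s[t-w .. t-1] and leading mean of s[t+1 .. t+w]
        padded = np.pad(s, w, mode="edge")
        c = np.concatenate([[0.0], np.cumsum(padded)])
        idx = np.arange(len(s)) + w  # position of t in padded
        lag = (c[idx] - c[idx - w]) / w
        lead = (c[idx + 1 + w] - c[idx + 1]) / w
        f = lead - lag
        if best is None or np.max(np.abs(f)) > np.max(np.abs(best.values)):
            best = BlinkFilterOutput(f, w, rate)
    assert best is not None
    return best


def _local_extrema(f: np.ndarray, thr: float):
    """Indices of local maxima above +thr and minima below -thr."""
    maxima, _ = sps.find_peaks(f, height=thr)
    minima, _ = sps.find_peaks(-f, height=thr)
    return maxima, minima


def detect_blinks(
    filtered: BlinkFilterOutput,
    k_mad: float = 6.0,
    pair_window_ms: float = 250.0,
    min_amplitude_uv: float = 30.0,
    rel_max: float = 0.5,
) -> list[BlinkInterval]:
    """Detect blink intervals from the emphasis-filter output.

    A blink is a local maximum of the filter output followed within
    ``pair_window_ms`` by a local minimum, both exceeding an adaptive
    threshold of ``k_mad`` times the median absolute deviation of the
    filtered series.  Two guards keep the adaptive rule usable at the
    extremes: the threshold is floored at ``min_amplitude_uv`` (a nearly
    clean record cannot collapse it onto numerical ripple) and capped at
    ``rel_max`` times the largest absolute response (a short epoch dense
    with blinks cannot inflate the MAD past the blinks themselves).  The
    interval spans from one filter width W before the maximum to one width
    after the minimum, covering rise and fall of the artifact.  Saccadic
    steps excite only a single one-signed lobe and are never paired;
    opposite-direction strokes are separated by a fixation longer than the
    pairing window.
    """
    f = filtered.values
    n = len(f)
    mad = np.median(np.abs(f - np.median(f)))
    peak = float(np.max(np.abs(f), initial=0.0))
    thr = max(min(k_mad * mad, rel_max * peak), min_amplitude_uv)
    if thr <= 0:
        return []
    maxima, minima = _local_extrema(f, thr)
    if len(maxima) == 0 or len(minima) == 0:
        return []
    pair_window = pair_window_ms * 1e-3 * filtered.rate
    W = filtered.width
    intervals: list[BlinkInterval] = []
    used_max: set[int] = set()
    for mn in minima:
        earlier = maxima[(maxima < mn) & (maxima >= mn - pair_window)]
        earlier = [m for m in earlier if m not in used_max]
        if not earlier:
            continue
        mx = earlier[-1]  # nearest preceding maximum
        used_max.add(mx)
        start = max(0, int(mx - W))
        end = min(n - 1, int(mn + W))
        # the filter maximum marks the artifact's rising edge = its peak region
        intervals.append(BlinkInterval(start, end, int(mx)))
    # merge overlapping detections (double blinks very close together)
    intervals.sort(key=lambda b: b.start)
    merged: list[BlinkInterval] = []
    for b in intervals:
        if merged and b.start <= merged[-1].end:
            last = merged.pop()
            merged.append(
                BlinkInterval(last.start, max(last.end, b.end), last.peak)
            )
        else:
            merged.append(b)
    return merged


def remove_baseline(
    series: np.ndarray,
    rate: float,
    pre_window_ms: float = 100.0,
    epoch_start: int = 0,
) -> np.ndarray:
    """Subtract the median of the window preceding the writing epoch.

    When no epoch start marker is given the first ``pre_window_ms`` of the
    record serves as the pre-writing window.
    """
    s = np.asarray(series, dtype=float)
    n_pre = max(1, round(pre_window_ms * 1e-3 * rate))
    lo = max(0, epoch_start - n_pre) if epoch_start > 0 else 0
    hi = epoch_start if epoch_start > 0 else n_pre
    if len(s) < hi or hi <= lo:
        raise ArgumentError(
            f"signal too short for a {pre_window_ms:g} ms baseline window"
        )
    return s - np.median(s[lo:hi])


def derive_bipolar(rec: EogRecording) -> BipolarSignal:
    """Horizontal = right - left; vertical = above - below."""
    for role in ("left", "right", "above", "below"):
        if role not in rec.channels:
            raise ConfigurationError(f"recording lacks channel role '{role}'")
    return BipolarSignal(
        rec.channel("right") - rec.channel("left"),
        rec.channel("above") - rec.channel("below"),
        rec.rate,
    )


def _interpolate_series(s: np.ndarray, blinks) -> np.ndarray:
    out = s.copy()
    n = len(s)
    for b in blinks:
        lo = max(0, b.start)
        hi = min(n - 1, b.end)
        left = lo - 1
        right = hi + 1
        if left < 0 and right > n - 1:
            continue  # interval covers everything; nothing to anchor on
        if left < 0:  # hold the first valid post-interval value
            out[lo:hi + 1] = s[right]
        elif right > n - 1:  # hold the last valid pre-interval value
            out[lo:hi + 1] = s[left]
        else:
            out[lo:hi + 1] = np.interp(
                np.arange(lo, hi + 1), [left, right], [s[left], s[right]]
            )
    return out


def interpolate_blinks(sig: BipolarSignal, blinks) -> BipolarSignal:
    """Replace samples inside blink intervals by linear interpolation.

    The replacement is the straight line joining the last sample before and
    the first sample after each interval; intervals touching a signal
    boundary hold the nearest valid value instead.
    """
    for b in blinks:
        if b.start > len(sig) - 1 or b.end < 0:
            raise ArgumentError(f"blink interval {b} outside signal range")
    return BipolarSignal(
        _interpolate_series(sig.h, blinks),
        _interpolate_series(sig.v, blinks),
        sig.rate,
    )


def remove_drift(series: np.ndarray) -> np.ndarray:
    """Subtract the ordinary-least-squares line fitted over the full epoch."""
    s = np.asarray(series, dtype=float)
    if len(s) < 2:
        raise ArgumentError("drift removal needs at least 2 samples")
    t = np.arange(len(s), dtype=float)
    slope, intercept = np.polyfit(t, s, 1)
    return s - (slope * t + intercept)
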