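"""Saccade detection by a continuous wavelet transform with a Haar wavelet.

A saccade appears in bipolar EOG as a step; convolving with a Haar wavelet at
a scale wide enough to straddle the step (20 samples at the 64 Hz analysis
rate) converts each step into a coefficient peak proportional to the step
amplitude.  Samples whose absolute coefficient on either the horizontal or
vertical channel exceeds a threshold θ form the saccadic mask; everything
else is treated as fixation and later dropped from the reconstructed trace.

θ is either supplied (120 µV-scale by default, the best-performing value in a
sensitivity sweep) or derived from annotated calibration epochs: each labeled
saccadic region contributes its peak absolute coefficient, and θ is the
minimum of those peaks — the largest threshold that still detects every
annotated saccade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ArgumentError
from .preprocessing import BipolarSignal

#: Default wavelet scale in samples at the analysis rate.
DEFAULT_SCALE = 20

#: Default detection threshold (microvolt scale).
DEFAULT_THRESHOLD = 120.0


@dataclass
class CwtResult:
    """Wavelet coefficients aligned to signal positions, at one scale."""

    coefficients: np.ndarray
    scale: int


@dataclass
class SaccadeMask:
    """Boolean saccade mask plus its maximal true-runs and the θ used."""

    mask: np.ndarray
    segments: list = field(default_factory=list)
    threshold: float = DEFAULT_THRESHOLD


def haar_cwt(series: np.ndarray, scale: int = DEFAULT_SCALE) -> CwtResult:
    """Continuous wavelet transform of a 1-D series with a Haar wavelet.

    The coefficient at position ``b`` is the Haar inner product over a
    centred window of ``scale`` samples::

        C_b = (sum of the half-window starting at b
               - sum of the half-window ending at b-1) / sqrt(scale)

    so an upward step between ``b-1`` and ``b`` yields the peak coefficient
    at ``b``.  Edges are handled by reflection padding.
    """
    s = np.asarray(series, dtype=float)
    scale = int(scale)
    if scale < 2 or scale % 2 != 0:
        raise ArgumentError("wavelet scale must be even and >= 2")
    if scale > len(s):
        raise ArgumentError(f"scale {scale} exceeds signal length {len(s)}")
    h = scale // 2
    padded = np.pad(s, h, mode="reflect")
    c = np.concatenate([[0.0], np.cumsum(padded)])
    b = np.arange(len(s)) + h  # position of original sample b in padded
    second = c[b + h] - c[b]          # sum of padded[b .. b+h-1] = s[b .. b+h-1]
    first = c[b] - c[b - h]           # sum of s[b-h .. b-1]
    coeffs = (second - first) / np.sqrt(scale)
    return CwtResult(coeffs, scale)


def mask_to_segments(mask: np.ndarray, merge_gap: int = 2, min_len: int = 2) -> list:
    """Maximal true-runs of a boolean mask, with segment hygiene.

    Runs separated by fewer than ``merge_gap`` false samples are merged and
    runs shorter than ``min_len`` are discarded, preventing fragmentation
    from coefficient values hovering around θ.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], m.view(np.int8), [0]])))
    runs = [(int(edges[i]), int(edges[i + 1]) - 1) for i in range(0, len(edges), 2)]
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe - 1 < merge_gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s + 1 >= min_len]


def detect_saccades(
    sig: BipolarSignal,
    threshold: float = DEFAULT_THRESHOLD,
    scale: int = DEFAULT_SCALE,
) -> SaccadeMask:
    """Mark samples whose |C| exceeds θ on the horizontal OR vertical channel."""
    if not threshold > 0:
        raise ArgumentError("threshold must be > 0")
    ch = haar_cwt(sig.h, scale).coefficients
    cv = haar_cwt(sig.v, scale).coefficients
    mask = (np.abs(ch) > threshold) | (np.abs(cv) > threshold)
    segments = mask_to_segments(mask)
    clean = np.zeros_like(mask)
    for s, e in segments:
        clean[s:e + 1] = True
    return SaccadeMask(clean, segments, threshold)


def derive_threshold(
    epochs: list[BipolarSignal],
    annotations: list[list[tuple]],
    scale: int = DEFAULT_SCALE,
) -> float:
    """Derive θ from calibration epochs with annotated saccadic regions.

    Each annotated region ``(start, end)`` (inclusive sample indices)
    contributes the peak absolute wavelet coefficient reached inside it, on
    either channel; θ is the minimum of those peaks, i.e. every annotated
    saccade on the calibration data would still be detected at θ (up to the
    strict-inequality boundary).
    """
    if len(epochs) != len(annotations):
        raise ArgumentError("need one annotation list per epoch")
    peaks = []
    for sig, regions in zip(epochs, annotations):
        if not regions:
            raise ArgumentError("every calibration epoch needs >= 1 annotated region")
        ch = np.abs(haar_cwt(sig.h, scale).coefficients)
        cv = np.abs(haar_cwt(sig.v, scale).coefficients)
        c = np.maximum(ch, cv)
        for s, e in regions:
            if not 0 <= s <= e < len(c):
                raise ArgumentError(f"annotated region ({s}, {e}) out of range")
            peaks.append(float(np.max(c[s:e + 1])))
    if not peaks:
        raise ArgumentError("no annotated regions given")
    return min(peaks)
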