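"""Canonical digit patterns and their conversion to comparable traces.

The ten digit shapes are stored as waypoint polylines on a small integer
lattice in a versioned JSON data file, so they can be re-traced or edited
without code changes.  ``template_trace`` turns a pattern into an
:class:`~eyescript.trace_reconstruction.EyeTrace` that went through the same
equidistant resampling and unit-box normalization as a reconstructed trace —
templates contain only the written strokes, no fixation parts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from ._exceptions import ArgumentError
from .trace_reconstruction import EyeTrace, normalize_box, resample_equidistant

DEFAULT_N_POINTS = 128


@dataclass
class DigitTemplate:
    """Labeled polyline for one digit on the writing grid (+row = up)."""

    label: int
    waypoints: np.ndarray  # (k, 2) of (column, row)

    def __post_init__(self) -> None:
        self.waypoints = np.asarray(self.waypoints, dtype=float)
        if self.label not in range(10):
            raise ArgumentError(f"digit label must be 0..9, got {self.label}")
        if len(self.waypoints) < 2:
            raise ArgumentError("a template needs at least 2 waypoints")
        if np.any(np.all(np.diff(self.waypoints, axis=0) == 0, axis=1)):
            raise ArgumentError("consecutive waypoints must be distinct")

    @property
    def n_strokes(self) -> int:
        return len(self.waypoints) - 1


def builtin_templates() -> list[DigitTemplate]:
    """The ten shipped digit patterns, labels 0-9, ordered by label."""
    payload = json.loads(
        resources.files("eyescript").joinpath("data/digit_templates.json").read_text()
    )
    out = [DigitTemplate(t["label"], t["waypoints"]) for t in payload["templates"]]
    labels = [t.label for t in out]
    if sorted(labels) != list(range(10)):
        raise ArgumentError(f"template set must cover labels 0..9, got {labels}")
    return sorted(out, key=lambda t: t.label)


def template_trace(tpl: DigitTemplate, n_points: int = DEFAULT_N_POINTS) -> EyeTrace:
    """Template polyline as an equidistantly resampled, normalized trace."""
    raw = EyeTrace(tpl.waypoints, normalized=False,
                   source_meta={"template": tpl.label})
    return normalize_box(resample_equidistant(raw, n_points))


def template_traces(n_points: int = DEFAULT_N_POINTS) -> dict[int, EyeTrace]:
    """All builtin templates rendered to traces, keyed by label."""
    return {t.label: template_trace(t, n_points) for t in builtin_templates()}
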