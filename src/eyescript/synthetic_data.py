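"""Ground-truth-annotated synthetic EOG of eye-written digits.

The generator emulates a 4-channel periocular montage sampled at 2048 Hz
while a subject eye-writes one digit pattern: gaze steps through the
template waypoints as logistic-sigmoid saccades separated by fixations, the
horizontal/vertical gaze components map linearly onto the bipolar EOG pairs
(split symmetrically onto the single-ended channels), and the record is
corrupted with per-channel baseline offsets, slow linear drift, Gaussian
noise, and blink transients.  A controllable coefficient ``alpha`` leaks the
horizontal component into the emitted vertical one (``v_emit = v + alpha*h``),
the very skew the reconstruction pipeline must remove.

Blink transients are raised-cosine bumps added to the above-eye channel with
a 20 % opposite-signed counterpart below the eye, and are placed inside
fixation periods only (blinks are suppressed during saccades, and a writing
task concentrates them in the pauses).

Every random quantity flows from one seed; subject-level and epoch-level
streams are split deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._exceptions import ArgumentError
from .io_formats import DatasetIndex, EogRecording
from .templates import DigitTemplate, builtin_templates

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SimulatedEpoch",
    "simulate_epoch",
    "simulate_cohort",
    "clean_config",
    "DEFAULT_SUBJECT_JITTER",
]


@dataclass
class SynthConfig:
    """Generation parameters; defaults emulate the acquisition conditions."""

    rate: float = 2048.0            # Hz
    amplitude_per_unit: float = 80.0  # microvolts of bipolar EOG per grid unit
    saccade_duration_ms: float = 60.0
    fixation_ms: float = 250.0       # dwell between strokes
    lead_ms: float = 700.0           # fixation before the first stroke
    tail_ms: float = 700.0           # fixation after the last stroke
    noise_sd_uv: float = 5.0
    drift_uv_per_s: float = 3.0      # max |slope| of per-channel linear drift
    blink_rate_per_epoch: float = 0.5
    blink_amp_uv: float = 300.0
    blink_dur_ms: float = 300.0
    alpha: float = 0.0               # injected horizontal->vertical crosstalk
    offset_range_uv: float = 100.0   # per-channel baseline offset, uniform +-
    waypoint_jitter: float = 0.06    # grid units, per-epoch Gaussian

    def __post_init__(self) -> None:
        for name in ("rate", "amplitude_per_unit", "saccade_duration_ms",
                     "fixation_ms", "lead_ms", "tail_ms", "blink_amp_uv",
                     "blink_dur_ms"):
            if not getattr(self, name) > 0:
                raise ArgumentError(f"{name} must be > 0")
        for name in ("noise_sd_uv", "drift_uv_per_s", "blink_rate_per_epoch",
                     "offset_range_uv", "waypoint_jitter"):
            if getattr(self, name) < 0:
                raise ArgumentError(f"{name} must be >= 0")


def clean_config(**overrides) -> SynthConfig:
    """A noiseless configuration: no noise, drift, blinks, offsets or jitter."""
    base = dict(noise_sd_uv=0.0, drift_uv_per_s=0.0, blink_rate_per_epoch=0.0,
                offset_range_uv=0.0, waypoint_jitter=0.0, alpha=0.0)
    base.update(overrides)
    return SynthConfig(**base)


@dataclass
class GroundTruth:
    """Everything the generator knows about one simulated epoch."""

    digit: int
    gaze_x: np.ndarray          # grid units vs time, at the recording rate
    gaze_y: np.ndarray
    saccades: list              # of (onset_sample, offset_sample), inclusive
    blinks: list                # of (start_sample, end_sample), inclusive
    alpha: float
    amplitude_per_unit: float
    rate: float

    def saccades_at(self, rate: float) -> list:
        """Saccade intervals converted to another sampling rate."""
        f = rate / self.rate
        return [(int(np.floor(s * f)), int(np.ceil(e * f))) for s, e in self.saccades]

    def blinks_at(self, rate: float) -> list:
        f = rate / self.rate
        return [(int(np.floor(s * f)), int(np.ceil(e * f))) for s, e in self.blinks]


@dataclass
class SimulatedEpoch:
    participant: str
    trial: int
    digit: int
    recording: EogRecording
    truth: GroundTruth


def _sigmoid_profile(n: int) -> np.ndarray:
    """Logistic position profile over n samples, exactly 0 -> 1."""
    u = np.linspace(-6.0, 6.0, n)
    s = 1.0 / (1.0 + np.exp(-u))
    return (s - s[0]) / (s[-1] - s[0])


def _gaze_path(waypoints: np.ndarray, cfg: SynthConfig):
    """Piecewise sigmoid gaze path through the waypoints.

    Returns (gx, gy, saccade intervals in samples)."""
    rate = cfg.rate
    n_sacc = max(2, round(cfg.saccade_duration_ms * 1e-3 * rate))
    n_fix = round(cfg.fixation_ms * 1e-3 * rate)
    n_lead = round(cfg.lead_ms * 1e-3 * rate)
    n_tail = round(cfg.tail_ms * 1e-3 * rate)
    profile = _sigmoid_profile(n_sacc)
    xs, ys, saccades = [], [], []
    xs.append(np.full(n_lead, waypoints[0, 0]))
    ys.append(np.full(n_lead, waypoints[0, 1]))
    pos = n_lead
    for k in range(len(waypoints) - 1):
        a, b = waypoints[k], waypoints[k + 1]
        xs.append(a[0] + (b[0] - a[0]) * profile)
        ys.append(a[1] + (b[1] - a[1]) * profile)
        saccades.append((pos, pos + n_sacc - 1))
        pos += n_sacc
        if k < len(waypoints) - 2:
            xs.append(np.full(n_fix, b[0]))
            ys.append(np.full(n_fix, b[1]))
            pos += n_fix
    xs.append(np.full(n_tail, waypoints[-1, 0]))
    ys.append(np.full(n_tail, waypoints[-1, 1]))
    return np.concatenate(xs), np.concatenate(ys), saccades


def _blink_bump(n: int) -> np.ndarray:
    """Raised-cosine bump of unit amplitude over n samples."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / (n - 1)))


def _place_blinks(n_total: int, saccades, cfg: SynthConfig, rng) -> list:
    """Poisson-count blinks placed inside fixation slots, non-overlapping."""
    n_blink = round(cfg.blink_dur_ms * 1e-3 * cfg.rate)
    margin = round(0.05 * cfg.rate)
    count = rng.poisson(cfg.blink_rate_per_epoch)
    if count == 0:
        return []
    # fixation slots between/around saccades, trimmed by a safety margin;
    # the first 150 ms stays clean for the baseline window
    bounds = [round(0.15 * cfg.rate)]
    for s, e in saccades:
        bounds += [s - margin, e + margin]
    bounds.append(n_total - margin)
    slots = []
    for i in range(0, len(bounds), 2):
        lo, hi = bounds[i], bounds[i + 1] - n_blink
        if hi > lo:
            slots.append((lo, hi))
    if not slots:
        return []
    widths = np.array([hi - lo for lo, hi in slots], dtype=float)
    blinks: list = []
    for _ in range(count):
        for _attempt in range(20):
            slot = rng.choice(len(slots), p=widths / widths.sum())
            lo, hi = slots[slot]
            start = int(rng.integers(lo, hi))
            if all(abs(start - b[0]) > n_blink + round(0.2 * cfg.rate)
                   for b in blinks):
                blinks.append((start, start + n_blink - 1))
                break
    return sorted(blinks)


def simulate_epoch(
    tpl: DigitTemplate,
    cfg: SynthConfig | None = None,
    seed=None,
) -> SimulatedEpoch:
    """Simulate one eye-written epoch of the given digit template.

    ``seed`` may be an int, a ``numpy.random.Generator`` or ``SeedSequence``.
    The same seed reproduces the recording bit-identically.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    waypoints = tpl.waypoints + (
        rng.normal(0.0, cfg.waypoint_jitter, tpl.waypoints.shape)
        if cfg.waypoint_jitter > 0 else 0.0
    )
    gx, gy, saccades = _gaze_path(waypoints, cfg)
    n = len(gx)
    amp = cfg.amplitude_per_unit
    h_ideal = amp * gx
    v_ideal = amp * gy
    v_emit = v_ideal + cfg.alpha * h_ideal
    offsets = rng.uniform(-cfg.offset_range_uv, cfg.offset_range_uv, 4)
    channels = {
        "left": -h_ideal / 2 + offsets[0],
        "right": h_ideal / 2 + offsets[1],
        "above": v_emit / 2 + offsets[2],
        "below": -v_emit / 2 + offsets[3],
    }
    t = np.arange(n) / cfg.rate
    if cfg.drift_uv_per_s > 0:
        slopes = rng.uniform(-cfg.drift_uv_per_s, cfg.drift_uv_per_s, 4)
        for i, name in enumerate(channels):
            channels[name] = channels[name] + slopes[i] * t
    blinks = _place_blinks(n, saccades, cfg, rng) \
        if cfg.blink_rate_per_epoch > 0 else []
    for s, e in blinks:
        bump = _blink_bump(e - s + 1) * cfg.blink_amp_uv
        channels["above"] = channels["above"].copy()
        channels["above"][s:e + 1] += bump
        channels["below"] = channels["below"].copy()
        channels["below"][s:e + 1] -= 0.2 * bump
    if cfg.noise_sd_uv > 0:
        for name in channels:
            channels[name] = channels[name] + rng.normal(0, cfg.noise_sd_uv, n)
    samples = np.column_stack([channels[r] for r in
                               ("left", "right", "above", "below")])
    rec = EogRecording(
        samples, cfg.rate,
        {"left": 0, "right": 1, "above": 2, "below": 3},
        {"digit": tpl.label},
    )
    truth = GroundTruth(tpl.label, gx, gy, saccades, blinks,
                        cfg.alpha, amp, cfg.rate)
    return SimulatedEpoch("sim", 0, tpl.label, rec, truth)


#: Per-subject uniform jitter ranges applied by :func:`simulate_cohort`.
DEFAULT_SUBJECT_JITTER = {
    "amplitude_factor": (0.85, 1.15),
    "alpha": (-0.3, 0.3),
    "noise_sd_uv": (4.0, 6.0),
    "saccade_duration_ms": (50.0, 80.0),
    "fixation_ms": (240.0, 320.0),
}


def simulate_cohort(
    n_participants: int,
    trials_per_digit: int = 3,
    cfg_base: SynthConfig | None = None,
    per_subject_jitter: dict | None = None,
    seed=0,
    digits: Sequence[int] = tuple(range(10)),
) -> list[SimulatedEpoch]:
    """Simulate a cohort: every subject writes every digit in every trial.

    Subject-level parameters (EOG gain, crosstalk, noise level, stroke
    timing) are drawn once per subject from the jitter ranges; epoch-level
    randomness (noise, drift, blinks, waypoint jitter) varies per epoch.
    """
    if n_participants < 1:
        raise ArgumentError("need at least one participant")
    cfg_base = cfg_base or SynthConfig()
    jit = dict(DEFAULT_SUBJECT_JITTER)
    if per_subject_jitter:
        jit.update(per_subject_jitter)
    templates = {t.label: t for t in builtin_templates()}
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(n_participants)
    epochs: list[SimulatedEpoch] = []
    for p in range(n_participants):
        sub_ss = subject_seeds[p]
        sub_rng = np.random.default_rng(sub_ss)
        cfg = replace(
            cfg_base,
            amplitude_per_unit=cfg_base.amplitude_per_unit
            * sub_rng.uniform(*jit["amplitude_factor"]),
            alpha=sub_rng.uniform(*jit["alpha"]),
            noise_sd_uv=(sub_rng.uniform(*jit["noise_sd_uv"])
                         if cfg_base.noise_sd_uv > 0 else 0.0),
            saccade_duration_ms=sub_rng.uniform(*jit["saccade_duration_ms"]),
            fixation_ms=sub_rng.uniform(*jit["fixation_ms"]),
        )
        epoch_seeds = sub_ss.spawn(trials_per_digit * len(digits))
        k = 0
        for trial in range(trials_per_digit):
            for digit in digits:
                ep = simulate_epoch(templates[digit], cfg, epoch_seeds[k])
                k += 1
                pid = f"S{p + 1:02d}"
                ep = SimulatedEpoch(pid, trial, digit, ep.recording, ep.truth)
                ep.recording.meta.update(participant=pid, trial=trial)
                epochs.append(ep)
    return epochs


def cohort_index(epochs: list[SimulatedEpoch]) -> DatasetIndex:
    """Manifest-style index of a simulated cohort (paths are synthetic ids)."""
    return DatasetIndex([
        (e.participant, e.trial, e.digit,
         f"{e.participant}_t{e.trial}_d{e.digit}.csv")
        for e in epochs
    ])
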