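"""Reading and writing EOG recordings, dataset manifests and channel layouts.

The native on-disk format is a self-describing CSV: a first header line
``rate=<Hz>`` followed by a standard comma-separated table with one column per
channel.  Values are microvolts.  EDF/BDF-family files are supported through a
lazy reader interface backed by ``mne`` when that package is available; the
core never imports it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, DatasetError, FormatError

#: The four periocular electrode roles: left/right of the eyes, above/below
#: the right eye.
CHANNEL_ROLES = ("left", "right", "above", "below")

#: Default layout: role -> column name equals the role name.
IDENTITY_LAYOUT = {role: role for role in CHANNEL_ROLES}


@dataclass
class EogRecording:
    """Raw multi-channel EOG samples in microvolts.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        One column per electrode, microvolts.
    rate : float
        Sampling rate in Hz, > 0.
    channels : mapping
        Role map ``{left, right, above, below} -> column index``.
    meta : dict
        Free-form metadata (participant id, trial, intended digit ...).
    """

    samples: np.ndarray
    rate: float
    channels: Mapping[str, int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ConfigurationError("samples must be a 2-D array")
        if self.samples.shape[0] < 2:
            raise ConfigurationError("a recording needs at least 2 samples")
        if not self.rate > 0:
            raise ConfigurationError("sampling rate must be > 0")
        n_cols = self.samples.shape[1]
        missing = [r for r in CHANNEL_ROLES if r not in self.channels]
        if missing:
            raise ConfigurationError(f"missing channel role(s): {missing}")
        cols = [self.channels[r] for r in CHANNEL_ROLES]
        if len(set(cols)) != len(cols):
            raise ConfigurationError("channel roles must map to distinct columns")
        for c in cols:
            if not 0 <= c < n_cols:
                raise ConfigurationError(f"channel column {c} out of range (0..{n_cols - 1})")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def channel(self, role: str) -> np.ndarray:
        """Return the 1-D series recorded at the electrode with this role."""
        if role not in self.channels:
            raise ConfigurationError(f"unknown channel role '{role}'")
        return self.samples[:, self.channels[role]]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass
class DatasetIndex:
    """Index of a recorded dataset: one entry per eye-written epoch."""

    entries: list  # of (participant_id, trial, digit, path)

    def __post_init__(self) -> None:
        for pid, trial, digit, path in self.entries:
            if not str(pid):
                raise DatasetError("participant ids must be non-empty")
            if digit not in range(10):
                raise DatasetError(f"digit label {digit!r} outside 0..9 ({path})")

    def by_participant(self) -> dict:
        """Group entries by participant id, preserving order."""
        groups: dict = {}
        for e in self.entries:
            groups.setdefault(e[0], []).append(e)
        return groups

    def __len__(self) -> int:
        return len(self.entries)


def _resolve_layout(columns: Sequence[str], layout: Mapping[str, object] | None) -> dict:
    """Turn a role->(name|index) layout into a role->index map."""
    layout = dict(layout) if layout is not None else dict(IDENTITY_LAYOUT)
    resolved = {}
    for role in CHANNEL_ROLES:
        if role not in layout:
            raise ConfigurationError(f"layout does not map channel role '{role}'")
        ref = layout[role]
        if isinstance(ref, (int, np.integer)):
            resolved[role] = int(ref)
        else:
            if ref not in columns:
                raise ConfigurationError(
                    f"layout maps role '{role}' to column '{ref}' "
                    f"which is not in the file (columns: {list(columns)})"
                )
            resolved[role] = list(columns).index(ref)
    return resolved


def read_recording(path, layout: Mapping[str, object] | None = None) -> EogRecording:
    """Read a recording from CSV (native format) or an EDF/BDF-family file.

    ``layout`` maps each channel role to a column name or index; by default
    columns named ``left,right,above,below`` are expected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".csv", ".txt", ".tsv"}:
        return _read_csv_recording(path, layout)
    if suffix in {".edf", ".bdf", ".gdf"}:
        return _read_edf_recording(path, layout)
    raise FormatError(f"unsupported recording format '{suffix}' ({path})")


def _read_csv_recording(path: Path, layout) -> EogRecording:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("rate="):
            raise FormatError(f"{path}: first line must be 'rate=<Hz>', got {first!r}")
        try:
            rate = float(first.split("=", 1)[1])
        except ValueError as exc:
            raise FormatError(f"{path}: cannot parse sampling rate from {first!r}") from exc
        try:
            df = pd.read_csv(fh)
        except Exception as exc:  # malformed table
            raise FormatError(f"{path}: cannot parse CSV payload: {exc}") from exc
    if df.shape[0] < 2:
        raise FormatError(f"{path}: fewer than 2 samples")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise FormatError(f"{path}: non-numeric payload columns")
    channels = _resolve_layout(df.columns, layout)
    meta = {"path": str(path)}
    return EogRecording(df.to_numpy(dtype=float), rate, channels, meta)


def _read_edf_recording(path: Path, layout) -> EogRecording:
    try:
        import mne  # noqa: F401 -- optional dependency
    except ImportError as exc:
        raise FormatError(
            "EDF/BDF reading requires the optional 'mne' dependency"
        ) from exc
    reader = {".edf": mne.io.read_raw_edf, ".bdf": mne.io.read_raw_bdf,
              ".gdf": mne.io.read_raw_gdf}[path.suffix.lower()]
    raw = reader(path, preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # volts -> microvolts
    channels = _resolve_layout(raw.ch_names, layout)
    return EogRecording(data, float(raw.info["sfreq"]), channels, {"path": str(path)})


def write_recording(rec: EogRecording, path) -> None:
    """Write a recording in the native CSV format (round-trips with read)."""
    path = Path(path)
    inverse = {idx: role for role, idx in rec.channels.items()}
    names = [inverse.get(i, f"ch{i}") for i in range(rec.samples.shape[1])]
    try:
        with open(path, "w") as fh:
            fh.write(f"rate={rec.rate:g}\n")
            pd.DataFrame(rec.samples, columns=names).to_csv(
                fh, index=False, float_format="%.6f"
            )
    except OSError as exc:
        raise OSError(f"cannot write recording to {path}: {exc}") from exc


def read_manifest(manifest) -> DatasetIndex:
    """Read a dataset manifest CSV with columns participant,trial,digit,path."""
    df = pd.read_csv(manifest)
    required = {"participant", "trial", "digit", "path"}
    if not required.issubset(df.columns):
        raise DatasetError(
            f"manifest {manifest} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    entries = [
        (str(r.participant), int(r.trial), int(r.digit), str(r.path))
        for r in df.itertuples()
    ]
    return DatasetIndex(entries)


def load_dataset(root, manifest, layout: Mapping[str, object] | None = None):
    """Load every recording referenced by a manifest.

    Paths in the manifest are taken relative to ``root``.  Returns
    ``(DatasetIndex, {(participant, trial, digit): EogRecording})``.
    """
    root = Path(root)
    index = read_manifest(manifest)
    missing = [e[3] for e in index.entries if not (root / e[3]).exists()]
    if missing:
        raise DatasetError(f"manifest references missing file(s): {missing}")
    recordings = {}
    for pid, trial, digit, rel in index.entries:
        rec = read_recording(root / rel, layout)
        rec.meta.update(participant=pid, trial=trial, digit=digit)
        recordings[(pid, trial, digit)] = rec
    return index, recordings


def write_manifest(index: DatasetIndex, path) -> None:
    pd.DataFrame(
        index.entries, columns=["participant", "trial", "digit", "path"]
    ).to_csv(path, index=False)
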