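"""Epoched multichannel recordings and their on-disk container.

The in-memory container is :class:`EpochedRecording`: a dense
``(n_trials, n_channels, n_samples)`` float block plus sampling rate,
ordered channel labels and one class label per trial.  On disk a recording
is a pair of files sharing a stem: ``<stem>.npy`` holding the 3-D array and
``<stem>.yaml`` holding the metadata sidecar (fs, channels, labels, units,
optional band tag).  A directory of per-trial delimited text matrices
(channels x samples) with a ``labels.tsv`` table and a ``meta.yaml`` is
accepted as an alternative input layout for data exported from other tools.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from ._exceptions import ValidationError

__all__ = ["EpochedRecording", "read_recording", "write_recording", "read_trial_directory"]


@dataclass
class EpochedRecording:
    """Trials x channels x samples block with acquisition metadata.

    Parameters
    ----------
    data:
        Array of shape ``(n_trials, n_channels, n_samples)``; values are
        interpreted as microvolts but no unit conversion is ever applied.
    fs:
        Sampling rate in Hz.
    channels:
        Ordered channel labels, one per channel.
    labels:
        Per-trial class identifiers (any hashable scalar; two classes for
        the classification stages).
    band_tag:
        Name of the frequency band the data were filtered to, if any.
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    labels: np.ndarray
    band_tag: str | None = None
    units: str = "uV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.channels = [str(c) for c in self.channels]
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be 3-D (trials, channels, samples), got shape {self.data.shape}"
            )
        n_trials, n_channels, n_samples = self.data.shape
        if n_trials < 1 or n_channels < 2 or n_samples < 2:
            raise ValidationError(
                "need at least 1 trial, 2 channels and 2 samples, "
                f"got {self.data.shape}"
            )
        if len(self.channels) != n_channels:
            raise ValidationError(
                f"{len(self.channels)} channel labels for {n_channels} channels"
            )
        if len(set(self.channels)) != n_channels:
            raise ValidationError("channel labels must be unique")
        if self.labels.shape != (n_trials,):
            raise ValidationError(
                f"labels shape {self.labels.shape} does not match {n_trials} trials"
            )
        if not np.isfinite(self.data).all():
            raise ValidationError("data contains non-finite samples")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def classes(self) -> list:
        """Distinct trial labels in first-appearance order."""
        seen: dict = {}
        for lab in self.labels.tolist():
            seen.setdefault(lab, None)
        return list(seen)

    def with_data(self, data: np.ndarray, **kwargs) -> "EpochedRecording":
        """Copy of this recording with ``data`` (and any metadata) replaced."""
        return replace(self, data=data, **kwargs)


def write_recording(rec: EpochedRecording, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.npy`` + ``<stem>.yaml``; returns the two paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    data_path = stem.with_suffix(".npy")
    meta_path = stem.with_suffix(".yaml")
    np.save(data_path, rec.data)
    meta = {
        "fs": float(rec.fs),
        "channels": list(rec.channels),
        "labels": [_scalar(v) for v in rec.labels.tolist()],
        "band_tag": rec.band_tag,
        "units": rec.units,
        "shape": list(rec.data.shape),
    }
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))
    return data_path, meta_path


def read_recording(stem: str | Path) -> EpochedRecording:
    """Read a recording written by :func:`write_recording`."""
    stem = Path(stem)
    data_path = stem.with_suffix(".npy")
    meta_path = stem.with_suffix(".yaml")
    for p in (data_path, meta_path):
        if not p.exists():
            raise ValidationError(f"missing recording file: {p}")
    meta = yaml.safe_load(meta_path.read_text())
    data = np.load(data_path)
    return EpochedRecording(
        data=data,
        fs=meta["fs"],
        channels=meta["channels"],
        labels=np.asarray(meta["labels"]),
        band_tag=meta.get("band_tag"),
        units=meta.get("units", "uV"),
    )


def read_trial_directory(path: str | Path) -> EpochedRecording:
    """Read a directory of per-trial text matrices.

    Layout: ``meta.yaml`` with keys ``fs`` and ``channels``; ``labels.tsv``
    with tab-separated columns ``file`` and ``label`` (one row per trial, in
    trial order); each referenced file a whitespace/tab-delimited
    channels x samples matrix.
    """
    path = Path(path)
    meta_path = path / "meta.yaml"
    labels_path = path / "labels.tsv"
    for p in (meta_path, labels_path):
        if not p.exists():
            raise ValidationError(f"missing file in trial directory: {p}")
    meta = yaml.safe_load(meta_path.read_text())
    rows = [ln.split("\t") for ln in labels_path.read_text().splitlines() if ln.strip()]
    header = [c.strip() for c in rows[0]]
    if header != ["file", "label"]:
        raise ValidationError(f"labels.tsv header must be 'file<TAB>label', got {header}")
    trials, labels = [], []
    for fname, label in (r[:2] for r in rows[1:]):
        mat = np.loadtxt(path / fname.strip(), ndmin=2)
        trials.append(mat)
        labels.append(label.strip())
    if not trials:
        raise ValidationError("labels.tsv lists no trials")
    shapes = {t.shape for t in trials}
    if len(shapes) != 1:
        raise ValidationError(f"trials have inconsistent shapes: {sorted(shapes)}")
    return EpochedRecording(
        data=np.stack(trials),
        fs=meta["fs"],
        channels=meta["channels"],
        labels=np.asarray(labels),
    )


def _scalar(v):
    # YAML cannot represent numpy scalars; coerce to builtin types.
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v
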