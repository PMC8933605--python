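"""Preprocessing of epoched multichannel EEG: CAR, interval, band-pass, channels.

The pipeline order is fixed as common-average reference -> sample-interval
extraction -> band-pass filtering -> channel selection, i.e. the CAR is taken
over every channel present in the raw montage before any subsetting.

Band-pass filtering uses a zero-phase (forward-backward) Butterworth filter
of order 4 with passband edges at the band bounds.  Note the conventional
rhythm-band bounds share edges: 13 Hz belongs to both the alpha and beta
bands and 21 Hz to both beta sub-bands, and the shared edge frequency is
included in both bands' spectral grids downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from ._exceptions import ValidationError
from .recording import EpochedRecording

__all__ = [
    "Band",
    "BANDS",
    "car_filter",
    "select_interval",
    "interval_from_seconds",
    "bandpass_filter",
    "select_channels",
]


@dataclass(frozen=True)
class Band:
    """A named EEG rhythm band with integer-Hz bounds (both inclusive)."""

    name: str
    f_low: int
    f_high: int

    def __post_init__(self) -> None:
        if not self.f_low < self.f_high:
            raise ValidationError(f"band {self.name}: f_low must be < f_high")

    @property
    def n_freqs(self) -> int:
        """Number of integer-Hz grid points, endpoints inclusive."""
        return self.f_high - self.f_low + 1

    def freqs(self) -> np.ndarray:
        return np.arange(self.f_low, self.f_high + 1)


#: The four built-in motor-imagery rhythm bands (Hz).
BANDS: dict[str, Band] = {
    "alpha": Band("alpha", 8, 13),
    "beta": Band("beta", 13, 30),
    "beta1": Band("beta1", 13, 21),
    "beta2": Band("beta2", 21, 30),
}


def car_filter(rec: EpochedRecording) -> EpochedRecording:
    """Common average reference: subtract the instantaneous cross-channel mean.

    For every trial and time sample, the mean over all channels is removed,
    so the output channel mean is zero at every sample.  Idempotent.
    """
    if rec.n_channels < 2:
        raise ValidationError("CAR needs at least 2 channels")
    out = rec.data - rec.data.mean(axis=1, keepdims=True)
    return rec.with_data(out)


def select_interval(rec: EpochedRecording, a: int, b: int) -> EpochedRecording:
    """Extract the sample interval ``[a, b]`` (0-based, both ends included).

    The output has ``K = b - a + 1`` samples per trial.
    """
    a, b = int(a), int(b)
    if a < 0 or b >= rec.n_samples or a > b:
        raise IndexError(
            f"interval [{a}, {b}] invalid for {rec.n_samples} samples"
        )
    return rec.with_data(rec.data[:, :, a : b + 1])


def interval_from_seconds(fs: float, a_s: float, b_s: float) -> tuple[int, int]:
    """Convert an interval in seconds to 0-based inclusive sample indices.

    Both endpoints are rounded to the nearest sample; e.g. 3.5-7 s at
    250 Hz maps to samples (875, 1750), i.e. K = 876 samples.
    """
    a = int(round(a_s * fs))
    b = int(round(b_s * fs))
    return a, b


def bandpass_filter(rec: EpochedRecording, band: Band, order: int = 4) -> EpochedRecording:
    """Zero-phase Butterworth band-pass to ``band``, per channel per trial.

    Passband gain is ~1 and the stopband strongly attenuated; filtering is
    forward-backward (``sosfiltfilt``) so no phase distortion is introduced,
    which matters because the connectivity stage is phase-sensitive.
    """
    if not rec.fs > 2 * band.f_high:
        raise ValidationError(
            f"sampling rate {rec.fs} Hz too low for band "
            f"{band.name} ({band.f_low}-{band.f_high} Hz)"
        )
    sos = _sig.butter(
        order, [band.f_low, band.f_high], btype="bandpass", fs=rec.fs, output="sos"
    )
    out = _sig.sosfiltfilt(sos, rec.data, axis=-1)
    return rec.with_data(np.ascontiguousarray(out), band_tag=band.name)


def select_channels(rec: EpochedRecording, keep: list[str]) -> EpochedRecording:
    """Subset/reorder channels to ``keep`` (labels, no duplicates)."""
    keep = [str(c) for c in keep]
    if len(set(keep)) != len(keep):
        raise KeyError(f"duplicate channel labels in keep list: {keep}")
    index = {c: i for i, c in enumerate(rec.channels)}
    missing = [c for c in keep if c not in index]
    if missing:
        raise KeyError(f"unknown channel labels: {missing}")
    idx = [index[c] for c in keep]
    return rec.with_data(rec.data[:, idx, :].copy(), channels=list(keep))
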