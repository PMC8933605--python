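"""Directed transfer function with truncated spectral order (DDTF).

Given a fitted MVAR(p) model, the spectral coefficient matrix truncated at
order ``m`` (1 <= m <= p) is

    B^m(f) = -I + sum_{r=1..m} A(r) exp(-j 2 pi f r / fs),

its inverse H^m(f) = [B^m(f)]^-1 is the transfer matrix, the squared
magnitude theta^2_{ls}(f) = |H_{ls}(f)|^2 quantifies directed influence from
channel s to channel l, and row normalization

    gamma^2_{ls}(f) = theta^2_{ls}(f) / sum_q theta^2_{lq}(f)

scales each inflow profile to the unit simplex.  Averaging gamma^2 over an
integer-Hz band grid yields the band adjacency matrix whose entry (l, s) is
the connection intensity from channel s to channel l.

Sign convention: at m = p this B differs from the classical spectral matrix
A_bar(f) = I - sum_r A(r) e^{-j 2 pi f r / fs} only by a global sign, so all
|H|^2-derived quantities coincide exactly with the classical DTF; the DTF is
therefore available as the ``m = p`` special case.  Truncation at m < p is
what makes the measure "dynamic": it weights the m most recent lags only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._exceptions import DegenerateInputError, NearSingularError, ValidationError
from .mvar import MVARModel, fit_mvar, select_order_sbc
from .preprocessing import Band
from .recording import EpochedRecording

__all__ = [
    "SpectralTransfer",
    "AdjacencyMatrix",
    "truncated_spectral_matrix",
    "transfer_matrix",
    "spectral_transfer",
    "normalize_rows",
    "band_average",
    "compute_adjacency",
]

#: Reciprocal condition number below which B(f) is treated as singular.
RCOND_THRESHOLD = 1e-12


@dataclass
class SpectralTransfer:
    """Spectral matrices of a truncated-order model on an integer-Hz grid.

    ``B``, ``H`` are complex arrays of shape ``(F, N, N)``; ``theta2`` is
    ``|H|^2`` and ``gamma2`` its row-normalized version, both real.
    """

    freqs: np.ndarray
    m: int
    B: np.ndarray
    H: np.ndarray
    theta2: np.ndarray
    gamma2: np.ndarray


@dataclass
class AdjacencyMatrix:
    """Band-averaged directed network: entry (l, s) is the flow s -> l."""

    values: np.ndarray
    band: Band
    m: int
    channels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.channels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"adjacency shape {self.values.shape} does not match "
                f"{n} channel labels"
            )

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> Path:
        """Write a labeled TSV (header row/column = channel labels)."""
        path = Path(path)
        lines = ["\t".join(["channel"] + self.channels)]
        for l, row in enumerate(self.values):
            lines.append(
                "\t".join([self.channels[l]] + [f"{v:.6g}" for v in row])
            )
        path.write_text("\n".join(lines) + "\n")
        return path


def truncated_spectral_matrix(model: MVARModel, m: int, f: float) -> np.ndarray:
    """B^m(f) = -I + sum_{r=1..m} A(r) e^{-j 2 pi f r / fs}; B^0(f) = -I."""
    m = int(m)
    if not 0 <= m <= model.order:
        raise ValidationError(f"m={m} outside 0..p={model.order}")
    n = model.n_channels
    b = -np.eye(n, dtype=complex)
    dt = 1.0 / model.fs
    for r in range(1, m + 1):
        b = b + model.coeffs[r - 1] * np.exp(-2j * np.pi * f * r * dt)
    return b


def transfer_matrix(b: np.ndarray, f: float | None = None) -> np.ndarray:
    """H = B^-1, refusing matrices with reciprocal condition < 1e-12."""
    b = np.asarray(b, dtype=complex)
    sv = np.linalg.svd(b, compute_uv=False)
    rcond = sv[-1] / sv[0] if sv[0] > 0 else 0.0
    if rcond < RCOND_THRESHOLD:
        where = "" if f is None else f" at f={f} Hz"
        raise NearSingularError(
            f"spectral coefficient matrix near-singular{where} "
            f"(reciprocal condition {rcond:.2e})"
        )
    return np.linalg.inv(b)


def normalize_rows(theta2: np.ndarray) -> np.ndarray:
    """Row-normalize a nonnegative matrix so each row sums to 1."""
    theta2 = np.asarray(theta2, dtype=float)
    if (theta2 < 0).any():
        raise ValidationError("theta2 must be nonnegative")
    row_sums = theta2.sum(axis=-1, keepdims=True)
    if (row_sums <= 0).any():
        raise DegenerateInputError("cannot normalize a row with zero sum")
    return theta2 / row_sums


def spectral_transfer(
    model: MVARModel, m: int, freqs: np.ndarray
) -> SpectralTransfer:
    """Evaluate B, H, theta^2 and gamma^2 on a frequency grid (Hz)."""
    freqs = np.asarray(freqs, dtype=float)
    n = model.n_channels
    nf = len(freqs)
    b_all = np.empty((nf, n, n), dtype=complex)
    h_all = np.empty((nf, n, n), dtype=complex)
    for i, f in enumerate(freqs):
        b_all[i] = truncated_spectral_matrix(model, m, f)
        h_all[i] = transfer_matrix(b_all[i], f=f)
    theta2 = np.abs(h_all) ** 2
    gamma2 = normalize_rows(theta2)
    return SpectralTransfer(
        freqs=freqs, m=int(m), B=b_all, H=h_all, theta2=theta2, gamma2=gamma2
    )


def band_average(
    gamma2_by_freq: np.ndarray, freqs: np.ndarray, band: Band
) -> np.ndarray:
    """Average gamma^2(f) over the band's integer-Hz grid (endpoints included).

    The divisor is ``f_high - f_low + 1``, i.e. the number of integer grid
    points, so a constant profile averages to itself.
    """
    freqs = np.asarray(freqs)
    wanted = band.freqs()
    idx = []
    for f in wanted:
        hits = np.nonzero(np.isclose(freqs, f))[0]
        if len(hits) == 0:
            raise ValidationError(
                f"frequency grid missing {f} Hz required by band {band.name}"
            )
        idx.append(hits[0])
    return np.asarray(gamma2_by_freq)[idx].sum(axis=0) / band.n_freqs


def compute_adjacency(
    trial: np.ndarray | EpochedRecording,
    band: Band,
    m: int,
    *,
    model: MVARModel | None = None,
    order: int | None = None,
    p_max: int = 20,
    fs: float | None = None,
    channels: list[str] | None = None,
    exclude_self: bool = False,
) -> AdjacencyMatrix:
    """Band-averaged DDTF adjacency matrix of one trial.

    Parameters
    ----------
    trial:
        Either a channels x samples array or an ``EpochedRecording`` with a
        single trial (band-pass filtered to ``band`` upstream).
    band, m:
        Analysis band and spectral truncation order (1 <= m <= p).
    model:
        Optional pre-fitted MVAR model; when absent one is fitted here with
        ``order`` lags (or an SBC-selected order up to ``p_max``).
    exclude_self:
        Zero the diagonal of theta^2 before row normalization.  Off by
        default: self-terms are part of the definition of the flows.
    """
    if isinstance(trial, EpochedRecording):
        if trial.n_trials != 1:
            raise ValidationError(
                f"expected a single-trial recording, got {trial.n_trials} trials"
            )
        fs = trial.fs
        channels = trial.channels
        x = trial.data[0]
    else:
        x = np.asarray(trial, dtype=float)
    if model is None:
        if fs is None:
            raise ValidationError("fs required when no fitted model is supplied")
        p = int(order) if order is not None else select_order_sbc(x, p_max=p_max)
        model = fit_mvar(x, p)
        model.fs = fs
    if channels is None:
        channels = [f"ch{i + 1}" for i in range(model.n_channels)]
    if not 1 <= m <= model.order:
        raise ValidationError(f"m={m} outside 1..p={model.order}")
    st = spectral_transfer(model, m, band.freqs().astype(float))
    theta2 = st.theta2
    if exclude_self:
        theta2 = theta2.copy()
        di = np.arange(theta2.shape[1])
        theta2[:, di, di] = 0.0
    gamma2 = normalize_rows(theta2)
    values = band_average(gamma2, st.freqs, band)
    return AdjacencyMatrix(values=values, band=band, m=int(m), channels=list(channels))
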