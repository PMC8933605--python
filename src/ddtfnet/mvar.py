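"""Multivariate autoregressive (MVAR) model fitting and order selection.

The model is

    x(t) = sum_{r=1..p} A(r) x(t-r) + e(t)

with x(t) an N-vector of channel samples, A(r) the N x N lag-r coefficient
matrix and e(t) zero-mean white noise with covariance ``noise_cov``.  No
intercept is fitted: inputs are CAR-referenced and band-passed, hence
zero-mean by construction.

Coefficients are estimated by ordinary least squares on the stacked lag
regression, and the order is chosen by the Schwarz Bayesian Criterion (SBC)
evaluated on a common effective sample span so candidate orders are
comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._exceptions import NumericalError, ValidationError

__all__ = ["MVARModel", "fit_mvar", "select_order_sbc", "companion_spectral_radius"]


@dataclass
class MVARModel:
    """A fitted MVAR(p) model.

    Attributes
    ----------
    order:
        Model order p (number of lags).
    coeffs:
        Array of shape ``(p, N, N)``; ``coeffs[r-1]`` is A(r).
    noise_cov:
        N x N residual covariance of the one-step prediction errors.
    fs:
        Sampling rate of the fitted signal (Hz); sets the spectral grid.
    n_samples_fit:
        Effective number of regression equations (K - p).
    """

    order: int
    coeffs: np.ndarray
    noise_cov: np.ndarray
    fs: float
    n_samples_fit: int

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        p = int(self.order)
        if p < 1:
            raise ValidationError(f"order must be >= 1, got {p}")
        if self.coeffs.shape != (p, self.n_channels, self.n_channels):
            raise ValidationError(
                f"coeffs shape {self.coeffs.shape} inconsistent with order {p}"
            )
        if not (np.isfinite(self.coeffs).all() and np.isfinite(self.noise_cov).all()):
            raise ValidationError("non-finite model parameters")

    @property
    def n_channels(self) -> int:
        return self.noise_cov.shape[0]

    def spectral_radius(self) -> float:
        """Spectral radius of the companion matrix (< 1 means stable)."""
        return companion_spectral_radius(self.coeffs)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "order": int(self.order),
                "n_channels": int(self.n_channels),
                "fs": float(self.fs),
                "n_samples_fit": int(self.n_samples_fit),
                "coeffs": self.coeffs.tolist(),
                "noise_cov": self.noise_cov.tolist(),
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "MVARModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            order=d["order"],
            coeffs=np.asarray(d["coeffs"]),
            noise_cov=np.asarray(d["noise_cov"]),
            fs=d["fs"],
            n_samples_fit=d["n_samples_fit"],
        )


def companion_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix of ``coeffs`` (p, N, N)."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, n, _ = coeffs.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    return float(np.abs(np.linalg.eigvals(comp)).max())


def _lag_regression(x: np.ndarray, p: int, start: int) -> tuple[np.ndarray, np.ndarray]:
    """Build response Y (N, T) and regressor Z (N*p, T) from sample ``start`` on."""
    n, k = x.shape
    t_idx = np.arange(start, k)
    y = x[:, t_idx]
    z = np.concatenate([x[:, t_idx - r] for r in range(1, p + 1)], axis=0)
    return y, z


def fit_mvar(signal: np.ndarray, order: int) -> "MVARModel":
    """Fit an MVAR(``order``) model to one trial block by least squares.

    Parameters
    ----------
    signal:
        Array of shape ``(N, K)`` (channels x samples).  May also carry an
        ``fs`` attribute; otherwise the model's ``fs`` defaults to 1.0 and
        should be set by the caller.
    order:
        Number of lags p >= 1.

    Raises
    ------
    ValidationError
        If K <= N*p + p (not enough samples for the least-squares problem).
    NumericalError
        If the regressor matrix is rank deficient.
    """
    fs = float(getattr(signal, "fs", 1.0))
    x = np.asarray(signal, dtype=float)
    if x.ndim != 2:
        raise ValidationError(f"signal must be 2-D (channels, samples), got {x.shape}")
    n, k = x.shape
    p = int(order)
    if p < 1:
        raise ValidationError(f"order must be >= 1, got {p}")
    if k <= n * p + p:
        raise ValidationError(
            f"K={k} samples insufficient for N={n}, p={p} (need K > N*p + p)"
        )
    y, z = _lag_regression(x, p, start=p)
    coeffs_flat, _, rank, _ = np.linalg.lstsq(z.T, y.T, rcond=None)
    if rank < n * p:
        raise NumericalError(
            f"rank-deficient lag regressor (rank {rank} < {n * p}); "
            "channels may be linearly dependent or constant"
        )
    a = coeffs_flat.T  # (N, N*p)
    resid = y - a @ z
    t_eff = y.shape[1]
    noise_cov = resid @ resid.T / t_eff
    coeffs = a.reshape(n, p, n).transpose(1, 0, 2)
    return MVARModel(
        order=p, coeffs=coeffs, noise_cov=noise_cov, fs=fs, n_samples_fit=t_eff
    )


def _sbc(x: np.ndarray, p: int, start: int) -> float:
    """SBC of an order-p fit evaluated on the common span starting at ``start``."""
    n = x.shape[0]
    y, z = _lag_regression(x, p, start=start)
    t_eff = y.shape[1]
    coeffs_flat, _, rank, _ = np.linalg.lstsq(z.T, y.T, rcond=None)
    if rank < n * p:
        raise NumericalError(f"rank-deficient regressor at candidate order {p}")
    resid = y - coeffs_flat.T @ z
    sigma = resid @ resid.T / t_eff
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise NumericalError(f"singular residual covariance at candidate order {p}")
    return float(logdet + np.log(t_eff) / t_eff * n**2 * p)


def select_order_sbc(signal: np.ndarray, p_max: int = 20, p_min: int = 1) -> int:
    """Choose the MVAR order in ``p_min..p_max`` minimizing the SBC.

    SBC(p) = ln det(Sigma_p) + (ln K_eff / K_eff) * N^2 * p, where every
    candidate is fitted on the same effective span (samples p_max..K-1) so
    the criteria are comparable.  Ties break toward the smaller order.
    """
    x = np.asarray(signal, dtype=float)
    n, k = x.shape
    p_max, p_min = int(p_max), int(p_min)
    if not 1 <= p_min <= p_max:
        raise ValidationError(f"need 1 <= p_min <= p_max, got ({p_min}, {p_max})")
    if k <= n * p_max + p_max:
        raise ValidationError(
            f"K={k} too small for p_max={p_max} with N={n} channels"
        )
    scores: dict[int, float] = {}
    errors: list[str] = []
    for p in range(p_min, p_max + 1):
        try:
            scores[p] = _sbc(x, p, start=p_max)
        except NumericalError as exc:  # pragma: no cover - rare degenerate data
            errors.append(str(exc))
    if not scores:
        raise NumericalError("all candidate orders failed: " + "; ".join(errors))
    return min(scores, key=lambda p: (scores[p], p))
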