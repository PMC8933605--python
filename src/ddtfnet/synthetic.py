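"""Ground-truth two-class MVAR simulations for the whole pipeline.

Trials are generated by iterating a stable MVAR recursion per trial from a
zeroed burn-in (10 p samples, discarded), so every downstream stage -- model
fitting, spectral transfer, band-averaged adjacency, network features,
classification -- can be checked against known coefficients.

Two ingredients make the presets band-specific:

* **Resonant drivers.**  A channel with AR(2) self-dynamics
  ``x(t) = 2 rho cos(2 pi f0 / fs) x(t-1) - rho^2 x(t-2) + e(t)``
  oscillates preferentially near ``f0`` Hz with sharpness ``rho``.

* **Band-limited coupling kernels.**  Directed influence enters as an FIR
  kernel across lags (a windowed band-pass design with exact unit-circle
  notches in the rhythm bands that must stay silent).  A flat lag-1
  coupling coefficient is *broadband* -- its directed-transfer footprint
  spans every band -- so band-specific class structure requires shaping
  the coupling transfer function itself.

The classification presets add class-independent nuisance coupling on the
same directed edges: per-trial random coupling strength in the uninformative
bands.  The class label only controls the band-limited component in the
preset's target band, which is exactly the situation the adaptive
frequency-band search is designed to resolve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from ._exceptions import StabilityError, ValidationError
from .mvar import companion_spectral_radius
from .recording import EpochedRecording

__all__ = [
    "SyntheticConfig",
    "oscillator_coeffs",
    "bandpass_coupling_kernel",
    "generate_mvar_epochs",
    "make_two_class_dataset",
    "PRESETS",
]

#: Trial geometry shared by all presets: 250 Hz sampling and 876 samples
#: (a 3.5 s analysis window, the typical motor-imagery interval length).
PRESET_FS = 250.0
PRESET_N_SAMPLES = 876
#: Peak directed coupling gain and innovation variance used by the presets.
PRESET_COUPLING = 0.5
PRESET_NOISE_VAR = 1.0

PRESETS = ("alpha_coupling", "beta2_coupling", "direction_flip")


@dataclass
class SyntheticConfig:
    """Two-class MVAR simulation settings.

    ``coeffs_by_class`` holds one ``(p, N, N)`` lag-coefficient stack per
    class; both classes share ``noise_cov`` (N x N, symmetric positive
    definite).  Each trial runs its own recursion seeded from ``seed``, with
    a discarded burn-in of ``burnin_factor * p`` samples.
    """

    n_channels: int
    fs: float
    n_samples: int
    n_trials_per_class: int
    coeffs_by_class: list[np.ndarray]
    noise_cov: np.ndarray
    seed: int = 0
    burnin_factor: int = 10
    class_labels: tuple = (0, 1)
    channels: list[str] | None = None

    def __post_init__(self) -> None:
        self.coeffs_by_class = [np.asarray(c, dtype=float) for c in self.coeffs_by_class]
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        n = self.n_channels
        if self.n_trials_per_class < 1:
            raise ValidationError("need at least one trial per class")
        if len(self.coeffs_by_class) != len(self.class_labels):
            raise ValidationError("one coefficient stack per class required")
        for c, stack in zip(self.class_labels, self.coeffs_by_class):
            if stack.ndim != 3 or stack.shape[1:] != (n, n):
                raise ValidationError(
                    f"class {c}: coefficient stack must be (p, {n}, {n}), "
                    f"got {stack.shape}"
                )
            rho = companion_spectral_radius(stack)
            if rho >= 1.0:
                raise StabilityError(
                    f"class {c}: companion spectral radius {rho:.4f} >= 1"
                )
        if self.noise_cov.shape != (n, n):
            raise ValidationError("noise_cov must be N x N")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValidationError("noise_cov must be symmetric")
        eigs = np.linalg.eigvalsh(self.noise_cov)
        if eigs.min() <= 0:
            raise ValidationError("noise_cov must be positive definite")
        if self.channels is None:
            self.channels = [f"ch{i + 1}" for i in range(n)]


def oscillator_coeffs(f0: float, fs: float, rho: float) -> tuple[float, float]:
    """AR(2) coefficients of a damped oscillator resonating at ``f0`` Hz.

    Returns ``(a1, a2) = (2 rho cos(2 pi f0 / fs), -rho^2)``; 0 < rho < 1
    sets the resonance sharpness (poles at radius rho).
    """
    if not 0 < rho < 1:
        raise ValidationError(f"rho must be in (0, 1), got {rho}")
    w = 2.0 * np.pi * f0 / fs
    return 2.0 * rho * np.cos(w), -(rho**2)


def bandpass_coupling_kernel(
    f_low: float,
    f_high: float,
    fs: float,
    *,
    f_peak: float | None = None,
    peak_gain: float = PRESET_COUPLING,
    notch_freqs: tuple[float, ...] = (),
    numtaps: int = 21,
) -> np.ndarray:
    """FIR lag kernel whose transfer function is band-passed to [f_low, f_high].

    A Hamming-windowed band-pass design (``scipy.signal.firwin``) is
    convolved with exact unit-circle zero pairs at ``notch_freqs`` so the
    kernel has literally no transfer at those frequencies, then scaled so
    the gain at ``f_peak`` (band centre by default) equals ``peak_gain``.
    The result is applied at lags 1..L of the receiving channel's row.
    """
    h = _sig.firwin(numtaps, [f_low, f_high], pass_zero=False, fs=fs)
    for fz in notch_freqs:
        w = 2.0 * np.pi * fz / fs
        h = np.convolve(h, [1.0, -2.0 * np.cos(w), 1.0])
    if f_peak is None:
        f_peak = 0.5 * (f_low + f_high)
    lags = np.arange(len(h)) + 1
    gain = np.abs(np.exp(-2j * np.pi * f_peak * lags / fs) @ h)
    return h * (peak_gain / gain)


def _simulate_trial(
    coeffs: np.ndarray,
    noise_chol: np.ndarray,
    n_samples: int,
    burnin: int,
    rng: np.random.Generator,
) -> np.ndarray:
    p, n, _ = coeffs.shape
    total = n_samples + burnin
    x = np.zeros((n, total + p))
    e = noise_chol @ rng.standard_normal((n, total))
    # (N, N*p) view so one matmul covers all lags per step
    a_flat = np.concatenate(list(coeffs), axis=1)
    for t in range(total):
        # lag-major stacked state [x(t-1); x(t-2); ...] to match a_flat
        window = x[:, p + t - 1 : t - 1 if t >= 1 else None : -1]
        x[:, p + t] = e[:, t] + a_flat @ window.T.reshape(-1)
    return x[:, p + burnin :]


def generate_mvar_epochs(cfg: SyntheticConfig) -> EpochedRecording:
    """Simulate all trials of both classes; fully reproducible from the seed.

    Trials are laid out class-interleaved (0, 1, 0, 1, ...) so any prefix of
    the dataset stays balanced.
    """
    rng = np.random.default_rng(cfg.seed)
    chol = np.linalg.cholesky(cfg.noise_cov)
    stacks = dict(zip(cfg.class_labels, cfg.coeffs_by_class))
    trials, labels = [], []
    for _ in range(cfg.n_trials_per_class):
        for lab in cfg.class_labels:
            stack = stacks[lab]
            burnin = cfg.burnin_factor * stack.shape[0]
            trials.append(
                _simulate_trial(stack, chol, cfg.n_samples, burnin, rng)
            )
            labels.append(lab)
    return EpochedRecording(
        data=np.stack(trials),
        fs=cfg.fs,
        channels=list(cfg.channels),
        labels=np.asarray(labels),
    )


def _banded_preset_trials(
    target: str,
    seed: int,
    n_trials_per_class: int,
    nuisance_max: float = PRESET_COUPLING,
) -> EpochedRecording:
    """Shared machinery of the alpha/beta2 classification presets.

    Four channels in two directed pairs (1 -> 2 and 3 -> 4).  The driving
    channels resonate at the target band's centre; the class-0 trials add a
    band-limited coupling kernel in the target band on both edges, while
    every trial (both classes) carries nuisance coupling in the two
    non-target rhythm bands whose peak gain is re-drawn uniformly from
    [0, nuisance_max] per trial and per band.
    """
    fs = PRESET_FS
    n = 4
    if target == "beta2":
        f0 = 26.5
        signal_kernel = bandpass_coupling_kernel(
            22.0, 31.0, fs, f_peak=f0, notch_freqs=(17.0, 21.0))
        nuis_kernels = [
            bandpass_coupling_kernel(8.0, 13.0, fs, f_peak=10.5,
                                     notch_freqs=(25.0, 28.0)),
            bandpass_coupling_kernel(13.0, 21.0, fs, f_peak=17.0,
                                     notch_freqs=(25.0, 28.0)),
        ]
    elif target == "alpha":
        f0 = 10.5
        signal_kernel = bandpass_coupling_kernel(
            8.0, 13.0, fs, f_peak=f0, notch_freqs=(17.0, 25.0))
        nuis_kernels = [
            bandpass_coupling_kernel(13.0, 21.0, fs, f_peak=17.0,
                                     notch_freqs=(9.0, 12.0)),
            bandpass_coupling_kernel(22.0, 31.0, fs, f_peak=26.5,
                                     notch_freqs=(9.0, 12.0)),
        ]
    else:  # pragma: no cover - internal
        raise ValidationError(f"unknown banded preset target {target!r}")

    L = max(len(signal_kernel), *(len(k) for k in nuis_kernels))

    def pad(h: np.ndarray) -> np.ndarray:
        out = np.zeros(L)
        out[: len(h)] = h
        return out

    signal_kernel = pad(signal_kernel)
    nuis_kernels = [pad(k) for k in nuis_kernels]
    a1o, a2o = oscillator_coeffs(f0, fs, rho=0.9)
    rng = np.random.default_rng(seed)
    chol = np.sqrt(PRESET_NOISE_VAR) * np.eye(n)
    trials, labels = [], []
    for _ in range(n_trials_per_class):
        for lab in (0, 1):
            a = np.zeros((L, n, n))
            for drv, rcv in ((0, 1), (2, 3)):
                a[0, drv, drv], a[1, drv, drv] = a1o, a2o
                a[0, rcv, rcv] = 0.3
                edge = np.zeros(L)
                for kern in nuis_kernels:
                    # effective nuisance peak gain ~ U(0, nuisance_max * peak)
                    edge += rng.uniform(0.0, nuisance_max) * kern
                if lab == 0:
                    edge += signal_kernel
                a[:, rcv, drv] = edge
            trials.append(_simulate_trial(a, chol, PRESET_N_SAMPLES, 10 * L, rng))
            labels.append(lab)
    return EpochedRecording(
        data=np.stack(trials),
        fs=fs,
        channels=[f"ch{i + 1}" for i in range(n)],
        labels=np.asarray(labels),
    )


def _direction_flip_trials(seed: int, n_trials_per_class: int) -> EpochedRecording:
    """Two 10.5 Hz oscillators; the lag-1 coupling direction flips by class."""
    fs = PRESET_FS
    n = 4
    a1o, a2o = oscillator_coeffs(10.5, fs, rho=0.8)

    def stack(to: int, frm: int) -> np.ndarray:
        a = np.zeros((2, n, n))
        for i in (0, 1):
            a[0, i, i], a[1, i, i] = a1o, a2o
        for i in (2, 3):
            a[0, i, i] = 0.3
        a[0, to, frm] = PRESET_COUPLING
        return a

    cfg = SyntheticConfig(
        n_channels=n,
        fs=fs,
        n_samples=PRESET_N_SAMPLES,
        n_trials_per_class=n_trials_per_class,
        coeffs_by_class=[stack(1, 0), stack(0, 1)],
        noise_cov=PRESET_NOISE_VAR * np.eye(n),
        seed=seed,
    )
    return generate_mvar_epochs(cfg)


def make_two_class_dataset(
    preset: str, seed: int = 0, n_trials_per_class: int = 50
) -> EpochedRecording:
    """Generate a labeled two-class dataset from a named preset.

    All presets use 4 channels, 250 Hz, 876 samples per trial, unit
    innovation variance and peak coupling gain 0.5.

    * ``alpha_coupling``  -- class 0 carries alpha-band (8-13 Hz) directed
      coupling on the edges ch1 -> ch2 and ch3 -> ch4; both classes carry
      per-trial random nuisance coupling in the beta sub-bands on the same
      edges.
    * ``beta2_coupling``  -- mirror image: the class difference lives in
      the upper beta band (21-30 Hz), the nuisance in alpha/lower beta.
    * ``direction_flip``  -- ch1 and ch2 are 10.5 Hz oscillators with a
      strong lag-1 coupling whose direction (1 -> 2 vs 2 -> 1) is the class
      label; used for direction-recovery checks.
    """
    if n_trials_per_class < 1:
        raise ValidationError("need at least one trial per class")
    if preset == "alpha_coupling":
        return _banded_preset_trials("alpha", seed, n_trials_per_class)
    if preset == "beta2_coupling":
        return _banded_preset_trials("beta2", seed, n_trials_per_class)
    if preset == "direction_flip":
        return _direction_flip_trials(seed, n_trials_per_class)
    raise ValidationError(f"unknown preset {preset!r}; choose from {PRESETS}")
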