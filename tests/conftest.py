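import numpy as np
import pytest

from ddtfnet import EpochedRecording, MVARModel
from ddtfnet.mvar import companion_spectral_radius


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_recording(rng):
    """Unstructured 6-trial, 4-channel, 500-sample recording at 250 Hz."""
    data = rng.standard_normal((6, 4, 500))
    return EpochedRecording(
        data=data,
        fs=250.0,
        channels=["C3", "Cz", "C4", "Pz"],
        labels=np.array([0, 1, 0, 1, 0, 1]),
    )


def random_stable_mvar(rng, n, p, fs=250.0, radius=0.9):
    """Random MVAR(p) model rescaled to a target companion spectral radius."""
    coeffs = 0.3 * rng.standard_normal((p, n, n))
    rho = companion_spectral_radius(coeffs)
    if rho > 0:
        # scale lag r by s^r to move every companion eigenvalue by factor s
        s = radius / rho
        coeffs = coeffs * (s ** np.arange(1, p + 1))[:, None, None]
    return MVARModel(
        order=p,
        coeffs=coeffs,
        noise_cov=np.eye(n),
        fs=fs,
        n_samples_fit=0,
    )


def simulate_var(model, n_samples, rng, burnin=None):
    """Direct simulation of an MVAR model (independent of the package's
    generator; used as ground truth in fitting tests)."""
    p, n = model.order, model.n_channels
    if burnin is None:
        burnin = 10 * p
    chol = np.linalg.cholesky(model.noise_cov)
    total = n_samples + burnin
    x = np.zeros((n, total + p))
    e = chol @ rng.standard_normal((n, total))
    for t in range(total):
        acc = e[:, t].copy()
        for r in range(1, p + 1):
            acc += model.coeffs[r - 1] @ x[:, p + t - r]
        x[:, p + t] = acc
    return x[:, p + burnin:]
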