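import numpy as np
import pytest

from ddtfnet import (
    BANDS,
    AdjacencyMatrix,
    DegenerateInputError,
    MVARModel,
    NearSingularError,
    ValidationError,
    band_average,
    compute_adjacency,
    normalize_rows,
    spectral_transfer,
    transfer_matrix,
    truncated_spectral_matrix,
)

from conftest import random_stable_mvar, simulate_var


def classical_dtf_band_matrix(coeffs, fs, band):
    """Independent full-order DTF oracle.

    Textbook formulation: A_bar(f) = I - sum_r A(r) e^{-j 2 pi f r / fs},
    H = A_bar^{-1}, theta2 = |H|^2, row-normalize, average over the
    integer-Hz band grid.  Shares no code with the implementation.
    """
    p = coeffs.shape[0]
    freqs = np.arange(band.f_low, band.f_high + 1)
    acc = 0.0
    for f in freqs:
        a_bar = np.eye(coeffs.shape[1], dtype=complex)
        for r in range(1, p + 1):
            a_bar -= coeffs[r - 1] * np.exp(-2j * np.pi * f * r / fs)
        h = np.linalg.inv(a_bar)
        t2 = np.abs(h) ** 2
        acc = acc + t2 / t2.sum(axis=1, keepdims=True)
    return acc / len(freqs)


def model_from(coeffs, fs=250.0):
    p, n, _ = np.asarray(coeffs).shape
    return MVARModel(order=p, coeffs=np.asarray(coeffs, float),
                     noise_cov=np.eye(n), fs=fs, n_samples_fit=0)


class TestTruncatedSpectralMatrix:
    def test_order_zero_is_minus_identity(self, rng):
        model = random_stable_mvar(rng, 3, 2)
        assert np.allclose(truncated_spectral_matrix(model, 0, 17.0),
                           -np.eye(3))

    def test_scalar_dc_value(self):
        model = model_from(np.array([[[0.5]]]))
        b = truncated_spectral_matrix(model, 1, 0.0)
        assert b[0, 0] == pytest.approx(-0.5)

    def test_diagonal_coeffs_give_diagonal_b(self, rng):
        coeffs = np.stack([np.diag(rng.uniform(-0.4, 0.4, 3)) for _ in range(2)])
        model = model_from(coeffs)
        for f in (5.0, 12.0, 25.0):
            b = truncated_spectral_matrix(model, 2, f)
            assert np.allclose(b - np.diag(np.diag(b)), 0.0)

    def test_m_above_order_rejected(self, rng):
        model = random_stable_mvar(rng, 2, 2)
        with pytest.raises(ValidationError):
            truncated_spectral_matrix(model, 3, 10.0)


class TestTransferMatrix:
    def test_minus_identity(self):
        assert np.allclose(transfer_matrix(-np.eye(3)), -np.eye(3))

    def test_scalar_inverse(self):
        h = transfer_matrix(np.array([[-0.5]], dtype=complex))
        assert h[0, 0] == pytest.approx(-2.0)
        assert np.abs(h[0, 0]) ** 2 == pytest.approx(4.0)

    def test_inverse_property(self, rng):
        b = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
        b += 4 * np.eye(4)  # keep well conditioned
        h = transfer_matrix(b)
        assert np.abs(b @ h - np.eye(4)).max() < 1e-8

    def test_near_singular_names_frequency(self):
        b = np.array([[1.0, 1.0], [1.0, 1.0 + 1e-15]], dtype=complex)
        with pytest.raises(NearSingularError, match="13"):
            transfer_matrix(b, f=13.0)


class TestNormalizeRows:
    @pytest.mark.parametrize(
        "row,expected",
        [([4.0, 0.0], [1.0, 0.0]), ([1.0, 1.0, 2.0], [0.25, 0.25, 0.5])],
    )
    def test_examples(self, row, expected):
        out = normalize_rows(np.array([row]))
        assert np.allclose(out[0], expected)

    def test_rows_sum_to_one(self, rng):
        theta2 = rng.uniform(0.1, 2.0, (5, 6, 6))
        out = normalize_rows(theta2)
        assert np.allclose(out.sum(axis=-1), 1.0, atol=1e-12)
        assert ((out >= 0) & (out <= 1)).all()

    def test_zero_row_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_rows(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestBandAverage:
    def test_constant_profile(self):
        band = BANDS["alpha"]
        freqs = band.freqs().astype(float)
        g = np.full((len(freqs), 2, 2), 0.25)
        assert np.allclose(band_average(g, freqs, band), 0.25)

    def test_alpha_divisor_is_six(self):
        band = BANDS["alpha"]
        assert band.n_freqs == 6
        freqs = band.freqs().astype(float)
        g = np.zeros((6, 1, 1))
        g[0] = 1.0  # single spike averages to 1/6
        assert band_average(g, freqs, band)[0, 0] == pytest.approx(1 / 6)

    def test_beta2_ramp(self):
        band = BANDS["beta2"]
        freqs = band.freqs().astype(float)
        g = np.arange(1.0, 11.0)[:, None, None]
        assert band_average(g, freqs, band)[0, 0] == pytest.approx(5.5)

    def test_missing_frequency_rejected(self):
        band = BANDS["beta2"]
        freqs = np.arange(22.0, 31.0)  # 21 Hz missing
        with pytest.raises(ValidationError):
            band_average(np.zeros((9, 1, 1)), freqs, band)


class TestComputeAdjacency:
    def test_uncoupled_channels_give_identity(self, rng):
        coeffs = np.stack([np.diag([0.4, 0.3, -0.2])])
        model = model_from(coeffs)
        am = compute_adjacency(np.zeros((3, 10)), BANDS["alpha"], 1, model=model)
        assert np.allclose(am.values, np.eye(3), atol=1e-12)

    def test_rows_stochastic(self, rng):
        model = random_stable_mvar(rng, 4, 3)
        x = simulate_var(model, 1200, rng)
        am = compute_adjacency(x, BANDS["beta"], 2, order=3, fs=250.0)
        assert np.allclose(am.values.sum(axis=1), 1.0, atol=1e-10)
        assert am.values.sum() == pytest.approx(4.0)

    @pytest.mark.parametrize("n,p", [(2, 1), (3, 4), (5, 8)])
    def test_full_truncation_matches_classical_dtf(self, rng, n, p):
        """At m = p the dynamic DTF reduces exactly to the classical DTF."""
        model = random_stable_mvar(rng, n, p)
        for band in ("alpha", "beta2"):
            mine = compute_adjacency(
                np.zeros((n, 10)), BANDS[band], p, model=model
            ).values
            oracle = classical_dtf_band_matrix(model.coeffs, model.fs, BANDS[band])
            assert np.abs(mine - oracle).max() < 1e-10

    def test_global_sign_invariance(self, rng):
        model = random_stable_mvar(rng, 3, 2)
        st = spectral_transfer(model, 2, BANDS["alpha"].freqs().astype(float))
        for i in range(len(st.freqs)):
            h_neg = transfer_matrix(-st.B[i])
            assert np.allclose(np.abs(h_neg) ** 2, st.theta2[i], atol=1e-12)

    def test_truncation_settles_to_dtf(self, rng):
        model = random_stable_mvar(rng, 3, 6)
        band = BANDS["beta1"]
        full = compute_adjacency(np.zeros((3, 10)), band, 6, model=model).values
        gaps = [
            np.abs(compute_adjacency(np.zeros((3, 10)), band, m, model=model).values
                   - full).max()
            for m in (1, 6)
        ]
        assert gaps[-1] == pytest.approx(0.0, abs=1e-14)

    def test_exclude_self_zeroes_diagonal_flow(self, rng):
        model = random_stable_mvar(rng, 3, 2)
        am = compute_adjacency(np.zeros((3, 10)), BANDS["alpha"], 2,
                               model=model, exclude_self=True)
        assert np.allclose(np.diag(am.values), 0.0)
        assert np.allclose(am.values.sum(axis=1), 1.0, atol=1e-10)

    def test_direction_convention(self, rng):
        """Unidirectional coupling ch1 -> ch2 shows up at entry (2, 1)."""
        a1 = np.array([[0.4, 0.0], [0.6, 0.4]])
        model = model_from(a1[None])
        am = compute_adjacency(np.zeros((2, 10)), BANDS["alpha"], 1, model=model)
        assert am.values[1, 0] > 0.1
        assert am.values[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_adjacency_tsv_export(tmp_path, rng):
    am = AdjacencyMatrix(values=np.array([[0.7, 0.3], [0.4, 0.6]]),
                         band=BANDS["alpha"], m=1, channels=["C3", "C4"])
    path = am.to_tsv(tmp_path / "am.tsv")
    lines = path.read_text().splitlines()
    assert lines[0].split("\t") == ["channel", "C3", "C4"]
    assert lines[1].split("\t") == ["C3", "0.7", "0.3"]
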