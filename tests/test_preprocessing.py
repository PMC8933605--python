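import numpy as np
import pytest

from ddtfnet import (
    BANDS,
    Band,
    EpochedRecording,
    ValidationError,
    bandpass_filter,
    car_filter,
    interval_from_seconds,
    select_channels,
    select_interval,
)


def make_rec(data, fs=250.0, labels=None):
    data = np.asarray(data, dtype=float)
    n_trials, n_channels, _ = data.shape
    return EpochedRecording(
        data=data,
        fs=fs,
        channels=[f"ch{i}" for i in range(n_channels)],
        labels=np.zeros(n_trials) if labels is None else labels,
    )


class TestCarFilter:
    def test_common_mode_removed(self):
        common = np.sin(np.linspace(0, 10, 100))
        rec = make_rec(np.tile(common, (1, 3, 1)))
        assert np.allclose(car_filter(rec).data, 0.0)

    def test_two_channel_column(self):
        rec = make_rec(np.array([[[3.0, 3.0], [1.0, 1.0]]]))
        out = car_filter(rec)
        assert np.allclose(out.data[0, :, 0], [1.0, -1.0])

    def test_channel_means_vanish(self, rng):
        rec = make_rec(rng.standard_normal((1, 4, 100)))
        out = car_filter(rec)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-12

    def test_idempotent(self, rng):
        rec = make_rec(rng.standard_normal((2, 5, 64)))
        once = car_filter(rec)
        twice = car_filter(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)


class TestSelectInterval:
    def test_identity(self, small_recording):
        out = select_interval(small_recording, 0, small_recording.n_samples - 1)
        assert np.array_equal(out.data, small_recording.data)

    def test_inclusive_length(self, rng):
        rec = make_rec(rng.standard_normal((1, 2, 10)))
        out = select_interval(rec, 3, 7)
        assert out.n_samples == 5
        assert np.array_equal(out.data, rec.data[:, :, 3:8])

    def test_seconds_convention(self):
        # 3.5-7 s at 250 Hz: inclusive window of 876 samples
        a, b = interval_from_seconds(250.0, 3.5, 7.0)
        assert (a, b) == (875, 1750)
        assert b - a + 1 == 876

    def test_composition(self, rng):
        rec = make_rec(rng.standard_normal((1, 2, 50)))
        ab = select_interval(select_interval(rec, 10, 40), 5, 20)
        direct = select_interval(rec, 15, 30)
        assert np.array_equal(ab.data, direct.data)

    @pytest.mark.parametrize("a,b", [(5, 3), (-1, 4), (0, 999)])
    def test_bad_indices(self, small_recording, a, b):
        with pytest.raises(IndexError):
            select_interval(small_recording, a, b)


class TestBandpassFilter:
    def _tone(self, freq, fs=250.0, n=1000):
        t = np.arange(n) / fs
        return make_rec(np.tile(np.sin(2 * np.pi * freq * t), (1, 2, 1)), fs=fs)

    def test_passband_gain_near_unity(self):
        rec = self._tone(10.0)
        out = bandpass_filter(rec, BANDS["alpha"])
        core = slice(200, 800)  # avoid edge transients
        ratio = np.abs(out.data[0, 0, core]).max() / np.abs(rec.data[0, 0, core]).max()
        assert 0.9 < ratio < 1.1

    def test_stopband_attenuated(self):
        rec = self._tone(40.0)
        out = bandpass_filter(rec, BANDS["alpha"])
        core = slice(200, 800)
        ratio = np.abs(out.data[0, 0, core]).max() / np.abs(rec.data[0, 0, core]).max()
        assert ratio < 0.1

    def test_zero_in_zero_out(self):
        rec = make_rec(np.zeros((1, 2, 100)))
        assert np.allclose(bandpass_filter(rec, BANDS["beta"]).data, 0.0)

    def test_shape_and_tag(self, small_recording):
        out = bandpass_filter(small_recording, BANDS["beta2"])
        assert out.data.shape == small_recording.data.shape
        assert out.band_tag == "beta2"

    def test_low_fs_rejected(self, rng):
        rec = make_rec(rng.standard_normal((1, 2, 100)), fs=50.0)
        with pytest.raises(ValidationError):
            bandpass_filter(rec, BANDS["beta"])  # needs fs > 60 Hz


class TestSelectChannels:
    def test_identity(self, small_recording):
        out = select_channels(small_recording, small_recording.channels)
        assert np.array_equal(out.data, small_recording.data)
        assert out.channels == small_recording.channels

    def test_subset_and_reorder(self, small_recording):
        out = select_channels(small_recording, ["C4", "C3"])
        assert out.channels == ["C4", "C3"]
        assert np.array_equal(out.data[:, 0], small_recording.data[:, 2])
        assert np.array_equal(out.data[:, 1], small_recording.data[:, 0])

    def test_duplicate_rejected(self, small_recording):
        with pytest.raises(KeyError):
            select_channels(small_recording, ["C3", "C3"])

    def test_unknown_rejected(self, small_recording):
        with pytest.raises(KeyError):
            select_channels(small_recording, ["C3", "F7"])


def test_band_definitions():
    assert (BANDS["alpha"].f_low, BANDS["alpha"].f_high) == (8, 13)
    assert (BANDS["beta"].f_low, BANDS["beta"].f_high) == (13, 30)
    assert (BANDS["beta1"].f_low, BANDS["beta1"].f_high) == (13, 21)
    assert (BANDS["beta2"].f_low, BANDS["beta2"].f_high) == (21, 30)
    with pytest.raises(ValidationError):
        Band("bad", 20, 10)
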