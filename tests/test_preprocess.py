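"""Filtering, reference construction, and subspace cleaning."""

import numpy as np
import pytest

from wakenet.bands import DEFAULT_BANDS
from wakenet.io import Recording
from wakenet.preprocess import (
    NoReferenceError,
    asr_clean,
    band_decompose,
    bandpass_filter,
    build_reference_signal,
)


def sinusoid_recording(freq, fs=500.0, duration=30.0, amplitude=1.0, n_channels=1):
    t = np.arange(0, duration, 1 / fs)
    data = np.tile(amplitude * np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return Recording([f"ch{i}" for i in range(n_channels)], fs, data)


class TestBandpass:
    def test_zero_in_zero_out(self):
        rec = Recording(["a"], 500.0, np.zeros((1, 5000)))
        assert np.allclose(bandpass_filter(rec, 1, 3).data, 0.0)

    def test_passband_amplitude_preserved(self):
        rec = sinusoid_recording(2.0)
        out = bandpass_filter(rec, 1.0, 3.0)
        edge = 1000  # discard 2 s at each end
        ratio = np.abs(out.data[0, edge:-edge]).max() / 1.0
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_attenuation(self):
        rec = sinusoid_recording(30.0)
        out = bandpass_filter(rec, 1.0, 3.0)
        rms_in = np.sqrt(np.mean(rec.data**2))
        rms_out = np.sqrt(np.mean(out.data[0, 1000:-1000] ** 2))
        assert rms_out < 0.01 * rms_in

    def test_length_preserved(self, rng):
        rec = Recording(["a"], 500.0, rng.normal(size=(1, 4321)))
        assert bandpass_filter(rec, 0.5, 50).n_samples == 4321

    def test_passband_idempotence(self, rng):
        """A second identical filtering changes mid-band content < 5%."""
        rec = sinusoid_recording(2.0)
        once = bandpass_filter(rec, 1.0, 3.0)
        twice = bandpass_filter(once, 1.0, 3.0)
        mid = slice(2000, -2000)
        a1 = np.abs(once.data[0, mid]).max()
        a2 = np.abs(twice.data[0, mid]).max()
        assert a2 / a1 == pytest.approx(1.0, abs=0.05)

    def test_band_above_nyquist_rejected(self):
        rec = sinusoid_recording(2.0, fs=100.0)
        with pytest.raises(ValueError):
            bandpass_filter(rec, 1.0, 60.0)


class TestReferenceSignal:
    def test_all_clean_keeps_everything(self, rng):
        data = rng.normal(0, 10, size=(3, 2000))
        rec = Recording(["a", "b", "c"], 500.0, data)
        ref = build_reference_signal(rec)
        assert ref.data.shape == data.shape
        assert ref.segments == [(0, 2000)]

    def test_spike_splits_segments(self, rng):
        fs = 500.0
        data = rng.normal(0, 10, size=(2, 5000))
        data[0, 2500] = 200.0  # one 200 uV spike at t = 5 s
        rec = Recording(["a", "b"], fs, data)
        ref = build_reference_signal(rec)
        assert len(ref.segments) == 2
        assert ref.data.shape[1] == 4999
        assert np.all(np.abs(ref.data) < 100.0)

    def test_short_runs_rejected(self, rng):
        fs = 500.0
        data = rng.normal(0, 10, size=(1, 4000))
        data[0, ::200] = 150.0  # contamination every 400 ms
        rec = Recording(["a"], fs, data)
        with pytest.raises(NoReferenceError):
            build_reference_signal(rec)

    def test_invariants_hold(self, rng):
        fs = 500.0
        data = rng.normal(0, 30, size=(2, 10000))
        data[1, 3000:3010] = 140.0
        rec = Recording(["a", "b"], fs, data)
        try:
            ref = build_reference_signal(rec)
        except NoReferenceError:
            pytest.skip("no qualifying segment in this draw")
        min_len = int(fs)  # 1000 ms
        assert all(e - s >= min_len for s, e in ref.segments)
        assert np.all(np.abs(ref.data) < 100.0)


class TestASRClean:
    def test_clean_data_pass_through(self, rng):
        data = rng.normal(0, 10, size=(3, 5000))
        rec = Recording(["a", "b", "c"], 500.0, data)
        ref = build_reference_signal(rec)
        out = asr_clean(rec, ref)
        assert np.array_equal(out.data, data)

    def test_burst_clamped_to_threshold(self, rng):
        fs = 500.0
        data = rng.normal(0, 20, size=(4, 10000))
        rec_ref = Recording(list("abcd"), fs, data.copy())
        ref = build_reference_signal(rec_ref)
        data[:, 5000:5100] += 500.0  # coherent 500 uV burst
        rec = Recording(list("abcd"), fs, data)
        out = asr_clean(rec, ref, window_ms=500.0, k_sd=5.0)
        # recompute projections in the burst window post hoc
        centered = ref.data - ref.data.mean(axis=1, keepdims=True)
        eigval, eigvec = np.linalg.eigh(centered @ centered.T / centered.shape[1])
        thr = 5.0 * np.sqrt(np.clip(eigval, 0, None))
        win = out.data[:, 5000:5250]
        rms = np.sqrt(np.mean((eigvec.T @ win) ** 2, axis=1))
        assert np.all(rms <= thr * (1 + 1e-9))

    def test_never_raises_axis_rms(self, rng):
        data = rng.normal(0, 20, size=(3, 6000))
        data[:, 2000:2100] += 300.0
        rec = Recording(list("abc"), 500.0, data)
        ref = build_reference_signal(Recording(list("abc"), 500.0, rng.normal(0, 20, (3, 6000))))
        out = asr_clean(rec, ref)
        centered = ref.data - ref.data.mean(axis=1, keepdims=True)
        _, eigvec = np.linalg.eigh(centered @ centered.T / centered.shape[1])
        for start in range(0, 6000, 250):
            before = np.sqrt(np.mean((eigvec.T @ rec.data[:, start:start + 250]) ** 2, axis=1))
            after = np.sqrt(np.mean((eigvec.T @ out.data[:, start:start + 250]) ** 2, axis=1))
            assert np.all(after <= before + 1e-9)

    def test_infinite_threshold_identity(self, rng):
        data = rng.normal(0, 20, size=(2, 4000))
        data[:, 1000:1050] += 400.0
        rec = Recording(["a", "b"], 500.0, data)
        ref = build_reference_signal(Recording(["a", "b"], 500.0, rng.normal(0, 20, (2, 4000))))
        out = asr_clean(rec, ref, k_sd=np.inf)
        assert np.array_equal(out.data, data)

    def test_window_longer_than_recording(self, rng):
        rec = Recording(["a"], 500.0, rng.normal(size=(1, 100)))
        ref = build_reference_signal(Recording(["a"], 500.0, rng.normal(0, 10, (1, 1000))))
        with pytest.raises(ValueError, match="window"):
            asr_clean(rec, ref, window_ms=10_000.0)


class TestBandDecompose:
    def test_four_default_bands(self, rng):
        rec = Recording(["a", "b"], 500.0, rng.normal(size=(2, 5000)))
        out = band_decompose(rec, DEFAULT_BANDS)
        assert set(out) == {"delta", "theta", "alpha", "beta"}
        assert all(r.data.shape == (2, 5000) for r in out.values())

    def test_alpha_sinusoid_lands_in_alpha(self):
        rec = sinusoid_recording(10.0)
        out = band_decompose(rec, DEFAULT_BANDS)
        mid = slice(2000, -2000)
        rms = {k: np.sqrt(np.mean(v.data[0, mid] ** 2)) for k, v in out.items()}
        assert rms["alpha"] / rms["delta"] > 20

    def test_zero_input(self):
        rec = Recording(["a"], 500.0, np.zeros((1, 5000)))
        out = band_decompose(rec, DEFAULT_BANDS)
        assert all(np.allclose(r.data, 0.0) for r in out.values())
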