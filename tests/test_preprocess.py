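"""Resampling, band-pass filtering, segmentation, padding, normalization."""

import numpy as np
import pytest
from scipy import signal as sps

from neurofuse.containers import MEGRecording, MRIVolume
from neurofuse.preprocess import (
    BANDS, bandpass, crop_volume, get_band, normalize, pad_volume, resample,
    segment,
)


def _rec(data, fs=500.0):
    return MEGRecording(data=np.asarray(data, dtype=np.float64), fs=fs)


class TestResample:
    def test_dc_invariance(self):
        rec = _rec(np.ones((3, 1000)), fs=1000.0)
        out = resample(rec, 250.0)
        assert out.fs == 250.0
        interior = out.data[:, 10:-10]
        assert np.abs(interior - 1.0).max() < 1e-6

    def test_same_rate_is_identity(self):
        rng = np.random.default_rng(0)
        rec = _rec(rng.standard_normal((2, 512)))
        out = resample(rec, rec.fs)
        assert np.array_equal(out.data, rec.data)

    def test_sine_peak_survives_downsampling(self):
        t = np.arange(4096) / 1000.0
        rec = _rec(np.sin(2 * np.pi * 10.0 * t)[None, :], fs=1000.0)
        out = resample(rec, 500.0)
        assert out.data.shape[1] == 2048
        freqs = np.fft.rfftfreq(out.data.shape[1], 1 / 500.0)
        spectrum = np.abs(np.fft.rfft(out.data[0]))
        assert freqs[np.argmax(spectrum)] == pytest.approx(10.0, abs=0.3)

    def test_invalid_rates_rejected(self):
        rec = _rec(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            resample(rec, 0.0)
        with pytest.raises(ValueError):
            resample(rec, 1000.0)


class TestBandpass:
    def test_zero_in_zero_out(self):
        out = bandpass(_rec(np.zeros((4, 2048))), "alpha")
        assert np.allclose(out.data, 0.0)

    def test_named_bands_resolve_to_canonical_edges(self):
        assert (BANDS["high_gamma"].lo, BANDS["high_gamma"].hi) == (52.0, 86.0)
        assert (BANDS["delta"].lo, BANDS["delta"].hi) == (2.0, 4.0)
        assert (BANDS["broadband"].lo, BANDS["broadband"].hi) == (0.5, 98.0)
        assert get_band("beta").hi == 30.0

    def test_alpha_band_power_concentrated(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.standard_normal((4, 8192)))
        out = bandpass(rec, "alpha")
        freqs, psd = sps.welch(out.data, fs=500.0, nperseg=1024, axis=1)
        inside = psd[:, (freqs >= 6) & (freqs <= 14)].sum()
        assert inside / psd.sum() >= 0.9

    def test_idempotent_within_passband_tolerance(self):
        # passband-interior content must survive refiltering almost unchanged
        t = np.arange(4096) / 500.0
        tones = sum(np.sin(2 * np.pi * f * t + f) for f in (16.0, 20.0, 24.0))
        rec = _rec(tones[None, :])
        once = bandpass(rec, "beta")
        twice = bandpass(once, "beta")
        p1 = (once.data ** 2).sum()
        p2 = (twice.data ** 2).sum()
        assert abs(p2 - p1) / p1 < 0.05

    def test_energy_not_created(self):
        rng = np.random.default_rng(3)
        rec = _rec(rng.standard_normal((3, 4096)))
        for band in ["delta", "alpha", "high_gamma", "broadband"]:
            out = bandpass(rec, band)
            assert (out.data ** 2).sum() <= (rec.data ** 2).sum() * (1 + 1e-6)

    def test_band_beyond_nyquist_rejected(self):
        rec = _rec(np.zeros((1, 1024)), fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, "high_gamma")


class TestSegment:
    def test_exact_length_unchanged(self):
        rec = _rec(np.arange(8192, dtype=float)[None, :].repeat(2, axis=0))
        out = segment(rec, 8192)
        assert np.array_equal(out.data, rec.data)

    def test_reference_window_shape(self):
        rec = _rec(np.zeros((102, 60000)))
        assert segment(rec, 8192).data.shape == (102, 8192)

    def test_offset_indexing_contract(self):
        ramp = np.arange(1000, dtype=float)[None, :]
        out = segment(_rec(ramp), 100, offset=100)
        assert out.data[0, 0] == 100.0

    def test_too_short_input_mentions_minimum_duration(self):
        with pytest.raises(ValueError, match="120"):
            segment(_rec(np.zeros((2, 100))), 8192)


class TestPadVolume:
    def test_default_padding_target(self):
        vol = MRIVolume(np.zeros((192, 192, 182), dtype=np.float32))
        out = pad_volume(vol)  # default target (192, 192, 192)
        assert out.data.shape == (192, 192, 192)

    def test_full_shape_pad(self):
        vol = MRIVolume(np.ones((8, 8, 6), dtype=np.float32))
        out = pad_volume(vol, (8, 8, 16))
        assert out.data.shape == (8, 8, 16)
        assert out.data[:, :, 5:11].sum() == pytest.approx(8 * 8 * 6)

    def test_identity_when_already_target(self):
        vol = MRIVolume(np.random.default_rng(0).standard_normal((8, 8, 8)))
        out = pad_volume(vol, (8, 8, 8))
        assert np.array_equal(out.data, vol.data)

    def test_pad_crop_round_trip_bit_exact(self):
        rng = np.random.default_rng(1)
        vol = MRIVolume(rng.standard_normal((7, 9, 5)).astype(np.float32))
        padded = pad_volume(vol, (10, 12, 8))
        back = crop_volume(padded, (7, 9, 5))
        assert np.array_equal(back.data, vol.data)
        assert np.allclose(back.affine, vol.affine)

    def test_odd_extra_voxel_goes_trailing(self):
        vol = MRIVolume(np.ones((3, 3, 3), dtype=np.float32))
        out = pad_volume(vol, (6, 3, 3))
        assert out.data[:1].sum() == 0  # one leading zero slab
        assert out.data[1:4].sum() == 27
        assert out.data[4:].sum() == 0  # two trailing zero slabs

    def test_smaller_target_rejected(self):
        vol = MRIVolume(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError):
            pad_volume(vol, (4, 8, 8))


class TestNormalize:
    def test_constant_zscore_returns_zeros(self):
        assert np.allclose(normalize(np.full((4, 4), 3.0), "zscore"), 0.0)

    def test_zscore_moments(self, rng):
        out = normalize(rng.standard_normal((50, 40)) * 3 + 2, "zscore")
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1.0) < 1e-9

    def test_unit_range_ramp(self):
        out = normalize(np.arange(10.0), "unit_range")
        assert np.allclose(out, np.arange(10.0) / 9.0)

    def test_container_round_trip(self):
        rec = MEGRecording(np.random.default_rng(0).standard_normal((3, 64)),
                           fs=500.0)
        out = normalize(rec, "zscore")
        assert isinstance(out, MEGRecording)
        assert out.fs == 500.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.zeros(4), "minmax")
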