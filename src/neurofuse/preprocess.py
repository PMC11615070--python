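"""Deterministic preprocessing: resampling, band-pass filtering, segmentation,
volume padding and intensity normalization.

Filtering is a 4th-order Butterworth applied forward-backward (zero phase),
one sensor at a time. Frequency bands follow the conventional M/EEG split:
delta 2-4 Hz, theta 4-8, alpha 8-12, beta 12-30, low gamma 30-48, high gamma
52-86, with the broadband analysis window at 0.5-98 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .containers import MEGRecording, MRIVolume


@dataclass(frozen=True)
class BandSpec:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not 0 < self.lo < self.hi:
            raise ValueError(f"band edges must satisfy 0 < lo < hi, got {self}")


BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 2.0, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 12.0, 30.0),
    "low_gamma": BandSpec("low_gamma", 30.0, 48.0),
    "high_gamma": BandSpec("high_gamma", 52.0, 86.0),
    "broadband": BandSpec("broadband", 0.5, 98.0),
}

MIN_DURATION_S = 120.0  # shortest usable resting-state recording


def get_band(band: "str | BandSpec") -> BandSpec:
    if isinstance(band, BandSpec):
        return band
    try:
        return BANDS[band]
    except KeyError:
        raise ValueError(
            f"unknown band {band!r}; choose from {sorted(BANDS)}"
        ) from None


def resample(recording: MEGRecording, fs_out: float) -> MEGRecording:
    """Anti-aliased polyphase resampling along the time axis."""
    if fs_out <= 0:
        raise ValueError(f"fs_out must be positive, got {fs_out}")
    if fs_out > recording.fs:
        raise ValueError(
            f"fs_out ({fs_out}) must not exceed the input rate ({recording.fs})"
        )
    if fs_out == recording.fs:
        return replace(recording, data=recording.data.copy())
    frac = Fraction(fs_out / recording.fs).limit_denominator(10_000)
    out = sps.resample_poly(recording.data, frac.numerator, frac.denominator, axis=1)
    return MEGRecording(data=out, fs=fs_out, subject_id=recording.subject_id)


def bandpass(recording: MEGRecording, band: "str | BandSpec", order: int = 4) -> MEGRecording:
    """Zero-phase Butterworth band-pass, each sensor filtered independently."""
    band = get_band(band)
    nyq = recording.fs / 2.0
    if band.hi >= nyq:
        raise ValueError(
            f"band {band.name} ({band.lo}-{band.hi} Hz) exceeds Nyquist {nyq} Hz"
        )
    sos = sps.butter(order, [band.lo, band.hi], btype="bandpass", fs=recording.fs,
                     output="sos")
    out = sps.sosfiltfilt(sos, recording.data, axis=1)
    return MEGRecording(data=out, fs=recording.fs, subject_id=recording.subject_id)


def segment(recording: MEGRecording, n_samples: int = 8192, offset: int = 0) -> MEGRecording:
    """Take one contiguous fixed-length window starting at ``offset``."""
    if n_samples <= 0 or offset < 0:
        raise ValueError("n_samples must be positive and offset nonnegative")
    if recording.n_samples < offset + n_samples:
        raise ValueError(
            f"recording too short: {recording.n_samples} samples available, "
            f"{offset + n_samples} required (a minimum of {MIN_DURATION_S:.0f} s "
            f"of data, i.e. {int(MIN_DURATION_S * 500)} samples at 500 Hz, "
            "is expected upstream)"
        )
    out = recording.data[:, offset:offset + n_samples].copy()
    return MEGRecording(data=out, fs=recording.fs, subject_id=recording.subject_id)


def _pad_amounts(src: tuple[int, ...], target: tuple[int, ...]) -> list[tuple[int, int]]:
    pads = []
    for s, t in zip(src, target):
        if t < s:
            raise ValueError(f"target shape {target} smaller than source {src}")
        extra = t - s
        front = extra // 2
        pads.append((front, extra - front))  # extra voxel goes trailing
    return pads


def pad_volume(volume: MRIVolume, target: tuple[int, int, int] = (192, 192, 192)) -> MRIVolume:
    """Zero-pad to ``target``, split evenly with the odd voxel trailing.

    The affine origin is shifted so padded voxels keep world coordinates
    consistent; a center crop back to the source shape is an exact inverse.
    """
    pads = _pad_amounts(volume.data.shape, tuple(target))
    out = np.pad(volume.data, pads)
    affine = volume.affine.copy()
    front = np.array([p[0] for p in pads], dtype=float)
    affine[:3, 3] = affine[:3, 3] - affine[:3, :3] @ front
    return MRIVolume(data=out, affine=affine, subject_id=volume.subject_id)


def crop_volume(volume: MRIVolume, original: tuple[int, int, int]) -> MRIVolume:
    """Center-crop back to ``original`` shape; inverse of :func:`pad_volume`."""
    pads = _pad_amounts(tuple(original), volume.data.shape)
    slc = tuple(slice(f, f + o) for (f, _), o in zip(pads, original))
    out = volume.data[slc].copy()
    affine = volume.affine.copy()
    front = np.array([p[0] for p in pads], dtype=float)
    affine[:3, 3] = affine[:3, 3] + affine[:3, :3] @ front
    return MRIVolume(data=out, affine=affine, subject_id=volume.subject_id)


def normalize(x, mode: str = "zscore"):
    """Normalize a MEGRecording, MRIVolume or array over all elements.

    ``zscore`` maps to mean 0 / SD 1; ``unit_range`` maps to [0, 1]. A
    constant input returns all zeros by convention.
    """
    if isinstance(x, MEGRecording):
        return replace(x, data=normalize(x.data, mode))
    if isinstance(x, MRIVolume):
        return replace(x, data=normalize(x.data, mode))
    arr = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("input must be finite")
    if mode == "zscore":
        sd = arr.std()
        if sd == 0:
            return np.zeros_like(arr)
        return (arr - arr.mean()) / sd
    if mode == "unit_range":
        lo, hi = arr.min(), arr.max()
        if hi == lo:
            return np.zeros_like(arr)
        return (arr - lo) / (hi - lo)
    raise ValueError(f"unknown mode {mode!r}; expected 'zscore' or 'unit_range'")


def band_power(recording: MEGRecording, band: "str | BandSpec",
               nperseg: int = 256) -> float:
    """Mean Welch power of all sensors inside a frequency band."""
    band = get_band(band)
    nperseg = min(nperseg, recording.n_samples)
    freqs, psd = sps.welch(recording.data, fs=recording.fs, nperseg=nperseg, axis=1)
    mask = (freqs >= band.lo) & (freqs <= band.hi)
    if not mask.any():
        raise ValueError(f"no Welch bins inside band {band}")
    return float(psd[:, mask].mean())
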