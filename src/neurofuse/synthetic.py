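"""Synthetic cohort generator shaped like a two-site MCI/control MEG+MRI study.

The generator emulates the *outputs* of a real acquisition and preprocessing
chain: magnetometer arrays of 102 sensors x 8,192 samples at 500 Hz already
band-limited to 0.5-98 Hz, T1-weighted volumes registered to a 192x192x182
grid, and a metadata table whose per-group marginals follow the reference
cohort summary (163 controls / 144 MCI after exclusions; site split 91/75 vs
68/90).

Class effects are injected on a controlled scale:

* MEG - the spectral content of the disease group inside a chosen frequency
  band is scaled so that band *power* changes by an exact multiplicative
  factor (applied in the Fourier domain, hence exact up to window leakage).
* MRI - the mean intensity inside an axis-aligned region is shifted by
  ``-d`` sampling standard deviations of that region's mean, so a two-sample
  Cohen's d computed on region means recovers ``d``.

All randomness flows from one integer seed through ``numpy``'s SeedSequence
splitting: subject ``i`` uses sub-streams ``(seed, i, domain)`` with domain
0 = metadata, 1 = MEG, 2 = MRI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import ndimage, optimize
from scipy import stats as sstats

from .containers import CohortTable, MEGRecording, MRIVolume, SubjectRecord
from .preprocess import BANDS, MIN_DURATION_S, BandSpec, get_band

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

DEFAULT_MEG_SHAPE = (102, 8192)
DEFAULT_MRI_SHAPE = (192, 192, 182)
DEFAULT_FS = 500.0


@dataclass(frozen=True)
class EffectSpec:
    """Class-dependent effect injected into the MCI group's data."""

    mri_region: Box
    mri_effect_d: float = 0.0
    meg_band: BandSpec = BANDS["high_gamma"]
    meg_power_ratio: float = 1.0

    def __post_init__(self):
        if self.meg_power_ratio <= 0:
            raise ValueError("meg_power_ratio must be positive")
        for lo, hi in self.mri_region:
            if hi <= lo or lo < 0:
                raise ValueError(f"malformed region {self.mri_region}")


def default_effect(mri_shape=DEFAULT_MRI_SHAPE, box_size: int = 24,
                   mri_effect_d: float = 0.0,
                   meg_band: "str | BandSpec" = "high_gamma",
                   meg_power_ratio: float = 1.0) -> EffectSpec:
    """A centered cubic MRI region plus a named MEG band."""
    region = tuple(
        ((s - min(box_size, s)) // 2, (s - min(box_size, s)) // 2 + min(box_size, s))
        for s in mri_shape
    )
    return EffectSpec(mri_region=region, mri_effect_d=mri_effect_d,
                      meg_band=get_band(meg_band), meg_power_ratio=meg_power_ratio)


# -- metadata ---------------------------------------------------------------

@dataclass(frozen=True)
class GroupMarginals:
    age: tuple[float, float]
    education: tuple[float, float]
    mmse: tuple[float, float]
    duration: tuple[float, float]
    p_site_cbu: float
    p_male: float


#: Reference cohort summary used as the default metadata marginals. Note the
#: categorical rows sum to 166/158 while the post-exclusion counts are
#: 163/144; both count sets are exposed and deliberately not reconciled.
COHORT_MARGINALS: dict[str, GroupMarginals] = {
    "HC": GroupMarginals(age=(71.3, 7.0), education=(14.5, 4.4),
                         mmse=(28.8, 1.2), duration=(481.5, 262.0),
                         p_site_cbu=91 / 166, p_male=82 / 166),
    "MCI": GroupMarginals(age=(72.9, 6.7), education=(10.8, 5.3),
                          mmse=(26.1, 2.8), duration=(180.0, 305.0),
                          p_site_cbu=68 / 158, p_male=80 / 158),
}

POST_EXCLUSION_COUNTS = {"HC": 163, "MCI": 144}
MARGINAL_COUNTS = {"HC": 166, "MCI": 158}


def _subject_rng(seed: int, index: int, domain: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(index), domain)))


@lru_cache(maxsize=None)
def _matched_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose truncated-normal mean equals ``mean``."""
    if not lo < mean < hi:
        raise ValueError(f"target mean {mean} outside bounds ({lo}, {hi})")

    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return sstats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    return float(optimize.brentq(trunc_mean, mean - 12 * sd, mean + 12 * sd,
                                 xtol=1e-8))


def _matched_truncnorm(rng, mean, sd, lo, hi=np.inf, size=None):
    """Truncated-normal draw whose *truncated* mean equals ``mean``.

    The location parameter is solved so the requested mean survives
    truncation (a plain truncnorm centered at ``mean`` is biased when a bound
    sits within a couple of SDs).
    """
    loc = _matched_loc(float(mean), float(sd), float(lo), float(hi))
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return sstats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def generate_cohort(n_hc: int, n_mci: int, seed: int = 0,
                    marginals: dict[str, GroupMarginals] = COHORT_MARGINALS
                    ) -> CohortTable:
    """Draw a metadata table with exact group counts and declared marginals."""
    if n_hc < 0 or n_mci < 0:
        raise ValueError("group counts must be nonnegative")
    records: list[SubjectRecord] = []
    for i in range(n_hc + n_mci):
        group = "HC" if i < n_hc else "MCI"
        m = marginals[group]
        rng = _subject_rng(seed, i, 0)
        site = "CBU" if rng.random() < m.p_site_cbu else "CTB"
        sex = "M" if rng.random() < m.p_male else "F"
        age = float(_matched_truncnorm(rng, *m.age, lo=18.0, hi=110.0))
        education = float(_matched_truncnorm(rng, *m.education, lo=0.0, hi=30.0))
        mmse = float(_matched_truncnorm(rng, *m.mmse, lo=0.0, hi=30.0))
        duration = float(_matched_truncnorm(rng, *m.duration, lo=MIN_DURATION_S))
        records.append(SubjectRecord(
            id=f"sub-{i:04d}", group=group, site=site, sex=sex, age=age,
            education=education, mmse=mmse, recording_duration=duration,
        ))
    return CohortTable(records=records, seed=seed)


# -- MEG --------------------------------------------------------------------

def generate_meg(record: SubjectRecord, shape=DEFAULT_MEG_SHAPE,
                 fs: float = DEFAULT_FS, effect: Optional[EffectSpec] = None,
                 seed: int = 0) -> MEGRecording:
    """Pink-noise magnetometer data band-limited to 0.5-98 Hz plus alpha and
    (if an effect band is set) in-band oscillatory components.

    For MCI subjects the Fourier coefficients inside ``effect.meg_band`` are
    scaled by ``sqrt(meg_power_ratio)``, multiplying band power exactly.
    """
    sensors, samples = (int(s) for s in shape)
    if sensors <= 0 or samples <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    broadband = BANDS["broadband"]
    top = broadband.hi if effect is None else max(broadband.hi, effect.meg_band.hi)
    if fs <= 2 * top:
        raise ValueError(
            f"fs={fs} too low: must exceed twice the highest synthesized "
            f"frequency ({top} Hz)"
        )
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(samples, d=1.0 / fs)
    in_band = (freqs >= broadband.lo) & (freqs <= broadband.hi)
    amp = np.zeros_like(freqs)
    amp[in_band] = 1.0 / np.sqrt(freqs[in_band])
    phases = rng.uniform(0, 2 * np.pi, size=(sensors, freqs.size))
    spectrum = amp * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=samples, axis=1)
    x /= x.std(axis=1, keepdims=True) + 1e-12

    t = np.arange(samples) / fs
    # a resting-state alpha rhythm, and a weak oscillation at the effect band
    # center so the band carries structured (not purely 1/f) signal
    alpha_phase = rng.uniform(0, 2 * np.pi, size=(sensors, 1))
    x += 0.4 * np.sin(2 * np.pi * 10.0 * t + alpha_phase)
    if effect is not None:
        f_mid = 0.5 * (effect.meg_band.lo + effect.meg_band.hi)
        osc_phase = rng.uniform(0, 2 * np.pi, size=(sensors, 1))
        x += 0.3 * np.sin(2 * np.pi * f_mid * t + osc_phase)

    if effect is not None and record.group == "MCI" and effect.meg_power_ratio != 1.0:
        spec = np.fft.rfft(x, axis=1)
        mask = (freqs >= effect.meg_band.lo) & (freqs <= effect.meg_band.hi)
        spec[:, mask] *= np.sqrt(effect.meg_power_ratio)
        x = np.fft.irfft(spec, n=samples, axis=1)

    return MEGRecording(data=x.astype(np.float32), fs=fs, subject_id=record.id)


# -- MRI --------------------------------------------------------------------

def _gauss_kernel(sigma: float) -> np.ndarray:
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _region_mean_sd(sigma: float, box_dims: tuple[int, ...]) -> float:
    """SD of the mean over an axis-aligned box of a unit-voxel-SD smoothed
    white-noise field (separable Gaussian covariance, exact interior formula).
    """
    k = _gauss_kernel(sigma)
    ac = np.correlate(k, k, mode="full")  # autocovariance at lags
    c0 = ac[ac.size // 2]
    factor = 1.0
    center = ac.size // 2
    for L in box_dims:
        lags = np.arange(-(ac.size // 2), ac.size // 2 + 1)
        weights = np.clip(L - np.abs(lags), 0, None)
        s = float((weights * ac).sum()) / L ** 2
        factor *= s / c0
    return float(np.sqrt(factor))


def generate_mri(record: SubjectRecord, shape=DEFAULT_MRI_SHAPE,
                 effect: Optional[EffectSpec] = None, seed: int = 0,
                 smooth_sigma: float = 3.0) -> MRIVolume:
    """Smooth Gaussian-random-field volume with an optional atrophy-like
    region-mean deficit for the MCI group."""
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValueError(f"shape must be positive, got {shape}")
    if effect is not None:
        for (lo, hi), s in zip(effect.mri_region, shape):
            if hi > s:
                raise ValueError(
                    f"effect region {effect.mri_region} outside volume {shape}"
                )
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_sigma)
    c0 = float(np.sum(_gauss_kernel(smooth_sigma) ** 2))
    field /= c0 ** (len(shape) / 2.0)  # unit interior voxel SD
    if effect is not None and record.group == "MCI" and effect.mri_effect_d != 0.0:
        box_dims = tuple(hi - lo for lo, hi in effect.mri_region)
        shift = effect.mri_effect_d * _region_mean_sd(smooth_sigma, box_dims)
        slc = tuple(slice(lo, hi) for lo, hi in effect.mri_region)
        field[slc] -= shift
    return MRIVolume(data=field.astype(np.float32), affine=np.eye(4),
                     subject_id=record.id)


def region_mean(volume: MRIVolume, region: Box) -> float:
    slc = tuple(slice(lo, hi) for lo, hi in region)
    return float(np.asarray(volume.data)[slc].mean())


# -- paired in-memory dataset ----------------------------------------------

@dataclass
class PairedDataset:
    """In-memory paired MEG/MRI arrays with labels (MCI = positive class)."""

    meg: np.ndarray   # (N, sensors, samples)
    mri: np.ndarray   # (N, X, Y, Z)
    labels: np.ndarray  # (N,) int, 0 = HC, 1 = MCI
    ids: list[str]
    fs: float = DEFAULT_FS
    cohort: Optional[CohortTable] = None
    effect: Optional[EffectSpec] = None

    def __len__(self):
        return self.labels.size


def save_paired_dataset(dataset: PairedDataset, out_dir) -> None:
    """Write cohort TSV plus one HDF5 (MEG) and one NIfTI (MRI) per subject."""
    from pathlib import Path

    from .containers import MEGRecording, save_meg, save_nifti, subject_paths

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if dataset.cohort is not None:
        dataset.cohort.to_tsv(out / "cohort.tsv")
    for i, sid in enumerate(dataset.ids):
        meg_path, mri_path = subject_paths(out, sid)
        save_meg(MEGRecording(dataset.meg[i], fs=dataset.fs, subject_id=sid), meg_path)
        save_nifti(MRIVolume(dataset.mri[i], subject_id=sid), mri_path)


def load_paired_dataset(data_dir) -> PairedDataset:
    """Load a directory written by :func:`save_paired_dataset`."""
    from pathlib import Path

    from .containers import load_meg, load_nifti, subject_paths

    data_dir = Path(data_dir)
    cohort = CohortTable.from_tsv(data_dir / "cohort.tsv")
    meg_list, mri_list, labels, ids = [], [], [], []
    fs = DEFAULT_FS
    for rec in cohort:
        meg_path, mri_path = subject_paths(data_dir, rec.id)
        m = load_meg(meg_path)
        fs = m.fs
        meg_list.append(m.data)
        mri_list.append(load_nifti(mri_path, subject_id=rec.id).data)
        labels.append(1 if rec.group == "MCI" else 0)
        ids.append(rec.id)
    return PairedDataset(meg=np.stack(meg_list), mri=np.stack(mri_list),
                         labels=np.asarray(labels, dtype=np.int64), ids=ids,
                         fs=fs, cohort=cohort)


def generate_paired_dataset(n_hc: int, n_mci: int, seed: int = 0,
                            meg_shape=DEFAULT_MEG_SHAPE,
                            mri_shape=DEFAULT_MRI_SHAPE,
                            fs: float = DEFAULT_FS,
                            effect: Optional[EffectSpec] = None,
                            normalize_inputs: bool = True) -> PairedDataset:
    """Generate a full paired synthetic dataset (metadata + both modalities).

    Each recording/volume is z-scored when ``normalize_inputs`` is set, the
    convention expected by the model branches.
    """
    if effect is None:
        effect = default_effect(mri_shape)
    cohort = generate_cohort(n_hc, n_mci, seed=seed)
    n = len(cohort)
    meg = np.empty((n,) + tuple(meg_shape), dtype=np.float32)
    mri = np.empty((n,) + tuple(mri_shape), dtype=np.float32)
    labels = np.empty(n, dtype=np.int64)
    ids = []
    for i, rec in enumerate(cohort):
        meg_seed = int(np.random.SeedSequence((seed, i, 1)).generate_state(1)[0] & 0x7FFFFFFF)
        mri_seed = int(np.random.SeedSequence((seed, i, 2)).generate_state(1)[0] & 0x7FFFFFFF)
        m = generate_meg(rec, shape=meg_shape, fs=fs, effect=effect, seed=meg_seed).data
        v = generate_mri(rec, shape=mri_shape, effect=effect, seed=mri_seed).data
        if normalize_inputs:
            m = (m - m.mean()) / (m.std() + 1e-8)
            v = (v - v.mean()) / (v.std() + 1e-8)
        meg[i] = m
        mri[i] = v
        labels[i] = 1 if rec.group == "MCI" else 0
        ids.append(rec.id)
    return PairedDataset(meg=meg, mri=mri, labels=labels, ids=ids, fs=fs,
                         cohort=cohort, effect=effect)
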