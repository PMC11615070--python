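"""Core data containers and their on-disk formats.

Volumes travel as NIfTI-1 (via nibabel), MEG sensor arrays as one HDF5 file
per subject (dataset ``data`` plus ``fs``/``subject_id`` attributes), and the
subject table as TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

GROUPS = ("HC", "MCI")
SITES = ("CBU", "CTB")
SEXES = ("M", "F")

COHORT_COLUMNS = [
    "id", "group", "site", "sex", "age", "education", "mmse",
    "recording_duration",
]


class FormatError(ValueError):
    """Raised when an on-disk file cannot be parsed as the expected format."""


@dataclass
class SubjectRecord:
    id: str
    group: str
    site: str
    sex: str
    age: float
    education: float
    mmse: float
    recording_duration: float

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not 0 <= self.mmse <= 30:
            raise ValueError(f"mmse must lie in [0, 30], got {self.mmse}")
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")


@dataclass
class CohortTable:
    records: list[SubjectRecord]
    seed: int = 0

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def group_counts(self) -> dict[str, int]:
        counts = {g: 0 for g in GROUPS}
        for r in self.records:
            counts[r.group] += 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[getattr(r, c) for c in COHORT_COLUMNS] for r in self.records],
            columns=COHORT_COLUMNS,
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, seed: int = 0) -> "CohortTable":
        df = pd.read_csv(path, sep="\t")
        missing = set(COHORT_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"cohort TSV missing columns: {sorted(missing)}")
        records = [
            SubjectRecord(**{c: row[c] for c in COHORT_COLUMNS})
            for _, row in df.iterrows()
        ]
        return cls(records=records, seed=seed)


@dataclass
class MEGRecording:
    """Sensor x time magnetometer array with its sampling rate."""

    data: np.ndarray
    fs: float
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"MEG data must be 2D (sensors x samples), got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("MEG data must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def sensor_count(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class MRIVolume:
    """3D intensity volume with voxel geometry (4x4 affine)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"MRI data must be 3D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("MRI data must be finite")

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return tuple(np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))


# -- NIfTI round trip -------------------------------------------------------

def save_nifti(volume: MRIVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine)
    nib.save(img, str(path))


def load_nifti(path, subject_id: str = "") -> MRIVolume:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(dtype=np.float32))
    except Exception as exc:  # nibabel raises several parse-error types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    return MRIVolume(data=data, affine=np.asarray(img.affine), subject_id=subject_id)


def write_read_nifti(volume: MRIVolume, path) -> MRIVolume:
    """Write then reload a volume; the round trip is lossless at float32."""
    save_nifti(volume, path)
    return load_nifti(path, subject_id=volume.subject_id)


# -- HDF5 MEG container -----------------------------------------------------

def save_meg(recording: MEGRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=np.asarray(recording.data, dtype=np.float32))
        f.attrs["fs"] = float(recording.fs)
        f.attrs["subject_id"] = recording.subject_id


def load_meg(path) -> MEGRecording:
    try:
        with h5py.File(path, "r") as f:
            data = f["data"][...]
            fs = float(f.attrs["fs"])
            subject_id = str(f.attrs.get("subject_id", ""))
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read MEG HDF5 file {path}: {exc}") from exc
    return MEGRecording(data=data, fs=fs, subject_id=subject_id)


def subject_paths(out_dir, subject_id: str) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    return out_dir / f"{subject_id}_meg.h5", out_dir / f"{subject_id}_T1w.nii.gz"
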