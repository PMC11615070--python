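"""Synthetic cohort generator: determinism, marginals, effect recovery, I/O."""

import numpy as np
import pytest
from scipy import stats as sstats

from neurofuse.containers import (
    CohortTable, FormatError, MEGRecording, MRIVolume, SubjectRecord,
    load_meg, load_nifti, save_meg, write_read_nifti,
)
from neurofuse.metrics import concordance_auc
from neurofuse.preprocess import band_power
from neurofuse.stats import permutation_pvalue
from neurofuse.synthetic import (
    EffectSpec, default_effect, generate_cohort, generate_meg, generate_mri,
    region_mean,
)

HC = SubjectRecord("hc-1", "HC", "CBU", "M", 70.0, 12.0, 29.0, 300.0)
MCI = SubjectRecord("mci-1", "MCI", "CTB", "F", 72.0, 11.0, 26.0, 200.0)


class TestCohort:
    def test_empty_cohort_is_valid(self):
        table = generate_cohort(0, 0, seed=1)
        assert len(table) == 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(-1, 5, seed=1)

    def test_exact_group_counts_at_marginal_sizes(self):
        table = generate_cohort(166, 158, seed=7)
        assert table.group_counts() == {"HC": 166, "MCI": 158}
        assert len({r.id for r in table.records}) == 324

    def test_determinism(self):
        a = generate_cohort(20, 20, seed=3).to_dataframe()
        b = generate_cohort(20, 20, seed=3).to_dataframe()
        assert a.equals(b)

    def test_metadata_invariants(self):
        df = generate_cohort(40, 40, seed=9).to_dataframe()
        assert df.mmse.between(0, 30).all()
        assert (df.age > 0).all()
        assert set(df.site) <= {"CBU", "CTB"}
        assert set(df.sex) <= {"M", "F"}
        assert (df.recording_duration >= 120).all()

    def test_mmse_group_means_recover_declared_values(self):
        # Monte-Carlo check: sampler is mean-matched to the declared 28.8/26.1
        df = generate_cohort(5000, 5000, seed=3).to_dataframe()
        for group, mean, sd in [("HC", 28.8, 1.2), ("MCI", 26.1, 2.8)]:
            sample = df[df.group == group].mmse
            se = sd / np.sqrt(len(sample))
            assert abs(sample.mean() - mean) < 3 * se


class TestMEG:
    def test_default_shape(self):
        rec = generate_meg(HC, seed=0)
        assert rec.data.shape == (102, 8192)
        assert rec.fs == 500.0
        assert np.all(np.isfinite(rec.data))

    def test_null_effect_groups_identical_in_law(self):
        eff = default_effect((32, 32, 32), box_size=8, meg_power_ratio=1.0)
        a = generate_meg(HC, shape=(8, 1024), effect=eff, seed=5)
        b = generate_meg(MCI, shape=(8, 1024), effect=eff, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_determinism(self):
        a = generate_meg(HC, shape=(8, 1024), seed=5)
        b = generate_meg(HC, shape=(8, 1024), seed=5)
        assert np.array_equal(a.data, b.data)

    def test_fs_too_low_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            generate_meg(HC, shape=(8, 1024), fs=150.0)

    def test_band_power_ratio_matches_welch_oracle(self):
        # power ratio 2 in 52-86 Hz recovers within 10% on an ensemble
        eff = default_effect((32, 32, 32), box_size=8, meg_band="high_gamma",
                             meg_power_ratio=2.0)
        hc, mci = [], []
        for i in range(100):
            hc.append(band_power(
                generate_meg(HC, shape=(8, 2048), effect=eff, seed=i),
                "high_gamma"))
            mci.append(band_power(
                generate_meg(MCI, shape=(8, 2048), effect=eff, seed=10_000 + i),
                "high_gamma"))
        ratio = np.mean(mci) / np.mean(hc)
        assert abs(ratio - 2.0) < 0.2


class TestMRI:
    def test_default_shape(self):
        vol = generate_mri(HC, seed=0)
        assert vol.data.shape == (192, 192, 182)
        assert np.all(np.isfinite(vol.data))

    def test_null_effect_identical_in_law(self):
        eff = default_effect((24, 24, 24), box_size=8, mri_effect_d=0.0)
        a = generate_mri(HC, shape=(24, 24, 24), effect=eff, seed=2)
        b = generate_mri(MCI, shape=(24, 24, 24), effect=eff, seed=2)
        assert np.array_equal(a.data, b.data)

    def test_region_out_of_bounds_rejected(self):
        eff = EffectSpec(mri_region=((0, 40), (0, 8), (0, 8)), mri_effect_d=1.0)
        with pytest.raises(ValueError, match="region"):
            generate_mri(HC, shape=(32, 32, 32), effect=eff, seed=0)

    def test_cohens_d_recovered_on_ensemble(self):
        # standardized region-mean difference within 0.15 of the requested 1.0
        eff = default_effect((32, 32, 32), box_size=10, mri_effect_d=1.0)
        a = np.array([
            region_mean(generate_mri(HC, (32, 32, 32), eff, seed=i,
                                     smooth_sigma=2.0), eff.mri_region)
            for i in range(500)])
        b = np.array([
            region_mean(generate_mri(MCI, (32, 32, 32), eff, seed=20_000 + i,
                                     smooth_sigma=2.0), eff.mri_region)
            for i in range(500)])
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        d = (a.mean() - b.mean()) / pooled
        assert abs(d - 1.0) < 0.15


def test_null_effect_permutation_pvalues_are_uniform():
    """With zero effects, a band-power permutation test must be null-calibrated."""
    eff = default_effect((16, 16, 16), box_size=4, meg_power_ratio=1.0)
    pvals = []
    for rep in range(20):
        powers, labels = [], []
        for i in range(24):
            rec = SubjectRecord(f"s{i}", "HC" if i < 12 else "MCI", "CBU", "M",
                                70.0, 12.0, 28.0, 200.0)
            meg = generate_meg(rec, shape=(4, 512), effect=eff,
                               seed=1000 * rep + i)
            powers.append(band_power(meg, "high_gamma"))
            labels.append(0 if i < 12 else 1)
        pvals.append(permutation_pvalue(powers, labels, n_perm=1000, seed=rep))
    ks = sstats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.005


class TestIO:
    def test_nifti_round_trip_lossless(self, tmp_path):
        vol = generate_mri(HC, shape=(16, 16, 12), seed=1)
        back = write_read_nifti(vol, tmp_path / "v.nii.gz")
        assert np.array_equal(back.data, vol.data)
        assert np.allclose(back.affine, vol.affine)

    def test_nifti_zero_volume_and_affine(self, tmp_path):
        vol = MRIVolume(np.zeros((4, 5, 6), dtype=np.float32), np.eye(4))
        back = write_read_nifti(vol, tmp_path / "z.nii.gz")
        assert np.array_equal(back.data, 0 * back.data)
        assert np.allclose(back.affine, np.eye(4))
        assert back.voxel_size == (1.0, 1.0, 1.0)

    def test_nifti_malformed_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.nii.gz"
        bad.write_bytes(b"this is not a nifti file")
        with pytest.raises(FormatError):
            load_nifti(bad)

    def test_meg_hdf5_round_trip(self, tmp_path):
        rec = generate_meg(HC, shape=(8, 256), seed=3)
        save_meg(rec, tmp_path / "m.h5")
        back = load_meg(tmp_path / "m.h5")
        assert np.array_equal(back.data, rec.data)
        assert back.fs == rec.fs
        assert back.subject_id == rec.subject_id

    def test_meg_malformed_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.h5"
        bad.write_bytes(b"not hdf5")
        with pytest.raises(FormatError):
            load_meg(bad)

    def test_cohort_tsv_round_trip(self, tmp_path):
        table = generate_cohort(5, 4, seed=2)
        table.to_tsv(tmp_path / "cohort.tsv")
        back = CohortTable.from_tsv(tmp_path / "cohort.tsv")
        assert back.to_dataframe().id.tolist() == table.to_dataframe().id.tolist()
        assert back.group_counts() == {"HC": 5, "MCI": 4}


def test_subject_record_validation():
    with pytest.raises(ValueError):
        SubjectRecord("x", "HC", "CBU", "M", 70.0, 12.0, 31.0, 100.0)  # mmse
    with pytest.raises(ValueError):
        SubjectRecord("x", "XX", "CBU", "M", 70.0, 12.0, 28.0, 100.0)  # group
    with pytest.raises(ValueError):
        MEGRecording(np.array([[np.nan, 1.0]]), fs=500.0)
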