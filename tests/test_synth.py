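import numpy as np
import pytest

from hiegrade.artifact import artifact_bandpass, detect_artifacts
from hiegrade.synth import GradeModelParams, generate_epoch, inject_artifacts, make_dataset


class TestGradeModelParams:
    def test_contradictory_params_rejected(self):
        with pytest.raises(ValueError, match="continuous"):
            GradeModelParams(grade=1, ibi_range_s=(2, 5))
        with pytest.raises(ValueError, match="10"):
            GradeModelParams(grade=2, ibi_range_s=(5, 12))
        with pytest.raises(ValueError):
            GradeModelParams(grade=3, ibi_range_s=(2, 5))
        with pytest.raises(ValueError, match="60"):
            GradeModelParams(grade=4, ibi_range_s=(30, 70))

    def test_defaults_respect_grade_bounds(self):
        p2 = GradeModelParams.for_grade(2)
        assert 0 < p2.ibi_range_s[0] <= p2.ibi_range_s[1] < 10
        p3 = GradeModelParams.for_grade(3)
        assert 10 <= p3.ibi_range_s[0] <= p3.ibi_range_s[1] <= 60


class TestGenerateEpoch:
    def test_grade4_amplitude_mode_below_10uv(self):
        rec, _ = generate_epoch(GradeModelParams.for_grade(4),
                                duration_s=120, seed=0)
        assert np.max(np.abs(rec.samples)) < 10.0

    def test_grade3_annotation_ibis_within_bounds(self):
        _, ann = generate_epoch(GradeModelParams.for_grade(3),
                                duration_s=900, seed=1)
        ibis = ann[ann.kind == "ibi"]
        durations = (ibis.end_s - ibis.start_s).to_numpy()
        # the trailing interval may be cut by the epoch end
        assert np.all(durations[:-1] >= 10.0)
        assert np.all(durations <= 60.0)

    def test_grade2_annotation_ibis_under_10s(self):
        _, ann = generate_epoch(GradeModelParams.for_grade(2),
                                duration_s=600, seed=2)
        ibis = ann[ann.kind == "ibi"]
        assert np.all((ibis.end_s - ibis.start_s) < 10.0)

    def test_grade1_single_background_interval(self):
        rec, ann = generate_epoch(GradeModelParams.for_grade(1),
                                  duration_s=60, seed=3)
        assert list(ann.kind) == ["background"]
        rms = np.sqrt((rec.samples**2).mean())
        assert rms == pytest.approx(25.0, rel=0.15)

    def test_seed_determinism(self):
        a, _ = generate_epoch(GradeModelParams.for_grade(2), duration_s=60, seed=9)
        b, _ = generate_epoch(GradeModelParams.for_grade(2), duration_s=60, seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_burst_timing_shared_across_channels(self):
        rec, ann = generate_epoch(GradeModelParams.for_grade(3),
                                  duration_s=600, seed=4)
        fs = rec.fs
        for _, burst in ann[ann.kind == "burst"].iloc[1:-1].iterrows():
            mid = int((burst.start_s + burst.end_s) / 2 * fs)
            sl = rec.samples[:, mid - 32 : mid + 32]
            assert np.all(sl.std(axis=1) > 10)  # every channel is bursting
        for _, ibi in ann[ann.kind == "ibi"].iloc[:-1].iterrows():
            if ibi.end_s - ibi.start_s < 4:
                continue
            mid = int((ibi.start_s + ibi.end_s) / 2 * fs)
            sl = rec.samples[:, mid - 32 : mid + 32]
            assert np.all(sl.std(axis=1) < 10)  # every channel suppressed

    def test_grade1_vs_grade4_spectral_energy_ratio(self):
        """Classes must be separable: grade-1 energy dominates grade-4 by
        over an order of magnitude at matched frequency bins."""
        from hiegrade.preprocess import EegSegment
        from hiegrade.tfd import tfd_pipeline

        tfds = {}
        for grade in (1, 4):
            rec, _ = generate_epoch(GradeModelParams.for_grade(grade),
                                    duration_s=300, n_channels=1, seed=5)
            seg = EegSegment(rec.samples[0], channel="x", fs=rec.fs)
            tfds[grade] = tfd_pipeline(seg).values
        # log-domain difference > log(10) on average
        assert (tfds[1] - tfds[4]).mean() > np.log(10)


class TestInjectArtifacts:
    def test_zero_rate_unchanged(self):
        rec, _ = generate_epoch(GradeModelParams.for_grade(1), duration_s=60,
                                seed=6)
        out, truth = inject_artifacts(rec, spike_rate_per_min=0, seed=0)
        assert np.array_equal(out.samples, rec.samples)
        assert len(truth) == 0

    def test_amp_range_validated(self):
        rec, _ = generate_epoch(GradeModelParams.for_grade(1), duration_s=10,
                                seed=6)
        with pytest.raises(ValueError, match="uV"):
            inject_artifacts(rec, amp_range_uv=(50, 200))

    def test_round_trip_stage1_fires_on_hemisphere(self):
        from hiegrade.preprocess import derive_montage

        rec, _ = generate_epoch(GradeModelParams.for_grade(4), duration_s=120,
                                seed=7)
        bip = derive_montage(rec)
        out, truth = inject_artifacts(bip, spike_rate_per_min=2.0,
                                      amp_range_uv=(450, 600), seed=8)
        assert len(truth) >= 1
        mask = detect_artifacts(artifact_bandpass(out))
        hemis = mask.hemisphere_map
        for _, ev in truth.iterrows():
            side = hemis[ev.channel]
            i0 = int(ev.start_s * out.fs)
            i1 = int(ev.end_s * out.fs)
            for ci, ch in enumerate(mask.channel_labels):
                if hemis[ch] == side:
                    assert mask.mask[ci, i0:i1].all()

    def test_truth_intervals_covered_by_detector(self):
        rec, _ = generate_epoch(GradeModelParams.for_grade(4), duration_s=180,
                                seed=9)
        from hiegrade.preprocess import derive_montage

        bip = derive_montage(rec)
        out, truth = inject_artifacts(bip, spike_rate_per_min=1.0, seed=10)
        mask = detect_artifacts(artifact_bandpass(out))
        for _, ev in truth.iterrows():
            ci = mask.channel_labels.index(ev.channel)
            i0 = int(ev.start_s * out.fs)
            i1 = int(ev.end_s * out.fs)
            # collar slack: the flagged run must cover the injected event
            assert mask.mask[ci, i0:i1].mean() > 0.95


class TestMakeDataset:
    def test_manifest_and_edf_round_trip(self, tmp_path):
        from hiegrade.io import read_edf

        manifest = make_dataset(4, (1, 1, 1, 1), duration_s=30, seed=1,
                                out_dir=tmp_path)
        assert len(manifest) == 4
        assert sorted(manifest.grade) == [1, 2, 3, 4]
        rec = read_edf(manifest.path.iloc[0])
        assert rec.n_channels == 9
        assert rec.fs == 64.0

    def test_round_trip_within_quantisation(self, tmp_path):
        from hiegrade.io import read_edf, write_edf
        from hiegrade.synth import generate_epoch

        rec, _ = generate_epoch(GradeModelParams.for_grade(2), duration_s=20,
                                seed=11)
        path = write_edf(rec, tmp_path / "x.edf")
        back = read_edf(path)
        lsb = 1600.0 / 65535.0  # physical range / 16-bit span
        err = np.max(np.abs(back.samples[:, : rec.n_times] - rec.samples))
        assert err <= lsb

    def test_empty_mix_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            make_dataset(0, (0, 0, 0, 0), out_dir=tmp_path)
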