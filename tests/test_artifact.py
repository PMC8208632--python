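import numpy as np
import pytest

from conftest import brute_force_artifact_mask
from hiegrade.artifact import (
    artifact_bandpass,
    detect_artifacts,
    envelope,
    percent_artifact,
)
from hiegrade.preprocess import EegRecording

FS = 64.0
LEFT_RIGHT = {"A-left": "left", "B-left": "left", "C-right": "right",
              "D-right": "right"}


def _recording(channels: dict[str, np.ndarray]) -> EegRecording:
    labels = list(channels)
    return EegRecording(np.vstack([channels[k] for k in labels]), FS, labels)


def _quiet(n):
    return np.zeros(n)


class TestBandpass:
    def test_passband_tone_preserved(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 5.0 * t)
        rec = EegRecording(x[None], FS, ["A-left"])
        out = artifact_bandpass(rec).samples[0]
        core = out[int(5 * FS) : int(-5 * FS)]
        assert np.sqrt(2) * core.std() == pytest.approx(1.0, rel=0.05)

    def test_slow_drift_strongly_attenuated(self):
        t = np.arange(int(120 * FS)) / FS
        x = np.sin(2 * np.pi * 0.1 * t)
        rec = EegRecording(x[None], FS, ["A-left"])
        out = artifact_bandpass(rec).samples[0]
        assert np.max(np.abs(out)) < 0.1  # > 90% amplitude reduction

    def test_zero_in_zero_out(self):
        rec = EegRecording(np.zeros((1, 640)), FS, ["A-left"])
        assert np.allclose(artifact_bandpass(rec).samples, 0)

    def test_low_rate_rejected(self):
        rec = EegRecording(np.zeros((1, 100)), 16.0, ["A-left"])
        with pytest.raises(ValueError, match="passband"):
            artifact_bandpass(rec)


class TestEnvelope:
    def test_tone_envelope_is_amplitude(self):
        t = np.arange(int(30 * FS)) / FS
        env = envelope(7.0 * np.cos(2 * np.pi * 6.0 * t))
        interior = env[int(FS) : int(-FS)]
        assert interior == pytest.approx(7.0, rel=0.02)

    def test_zero_signal(self):
        assert np.allclose(envelope(np.zeros(256)), 0)

    def test_sign_flip_invariant(self, rng):
        x = rng.normal(size=512)
        assert np.allclose(envelope(x), envelope(-x), atol=1e-9)


def _spike(n, at_s, amp, fs=FS, width_s=0.25):
    x = np.zeros(n)
    i0 = int(at_s * fs)
    w = int(width_s * fs)
    t = np.arange(w) / fs
    x[i0 : i0 + w] = amp * np.hanning(w) * np.sin(2 * np.pi * 6.0 * t)
    return x


class TestDetectArtifacts:
    def test_stage1_flags_whole_hemisphere_with_10s_collar(self):
        n = int(60 * FS)
        rec = _recording({
            "A-left": _spike(n, 30.0, 400.0),
            "B-left": _quiet(n),
            "C-right": _quiet(n),
            "D-right": _quiet(n),
        })
        mask = detect_artifacts(rec, LEFT_RIGHT)
        t = np.arange(n) / FS
        for ch in ("A-left", "B-left"):
            row = mask.mask[mask.channel_labels.index(ch)]
            flagged = t[row]
            assert flagged.min() == pytest.approx(20.0, abs=0.3)
            assert flagged.max() == pytest.approx(40.0, abs=0.3)
        assert not mask.mask[mask.channel_labels.index("C-right")].any()
        assert not mask.mask[mask.channel_labels.index("D-right")].any()

    def test_stage2_flags_single_channel_with_3s_collar(self):
        n = int(60 * FS)
        rec = _recording({
            "A-left": _spike(n, 30.0, 150.0),
            "B-left": _quiet(n),
            "C-right": _quiet(n),
            "D-right": _quiet(n),
        })
        mask = detect_artifacts(rec, LEFT_RIGHT)
        t = np.arange(n) / FS
        row = mask.mask[0]
        assert t[row].min() == pytest.approx(27.0, abs=0.3)
        assert t[row].max() == pytest.approx(33.0, abs=0.3)
        assert not mask.mask[1:].any()

    def test_quiet_recording_empty_mask(self):
        n = int(30 * FS)
        rec = _recording({k: _quiet(n) for k in LEFT_RIGHT})
        mask = detect_artifacts(rec, LEFT_RIGHT)
        assert not mask.mask.any()
        assert mask.percent == 0.0

    def test_unmapped_channel_rejected(self):
        rec = _recording({"A-left": _quiet(64), "X": _quiet(64),
                          "C-right": _quiet(64), "D-right": _quiet(64)})
        with pytest.raises(ValueError, match="X"):
            detect_artifacts(rec, LEFT_RIGHT)

    def test_threshold_monotonicity(self, rng):
        n = int(120 * FS)
        sig = rng.normal(scale=80, size=n)
        rec = _recording({"A-left": sig, "B-left": _quiet(n),
                          "C-right": _quiet(n), "D-right": _quiet(n)})
        base = detect_artifacts(rec, LEFT_RIGHT).mask.sum()
        higher1 = detect_artifacts(rec, LEFT_RIGHT,
                                   stage1_threshold_uv=400).mask.sum()
        higher2 = detect_artifacts(rec, LEFT_RIGHT,
                                   stage2_threshold_uv=150).mask.sum()
        assert higher1 <= base
        assert higher2 <= base

    def test_stage1_hemisphere_consistency_random(self, rng):
        n = int(90 * FS)
        channels = {
            k: rng.normal(scale=120, size=n) for k in LEFT_RIGHT
        }
        mask = detect_artifacts(_recording(channels), LEFT_RIGHT,
                                stage2_threshold_uv=1e9)  # stage 1 only
        left = [i for i, ch in enumerate(mask.channel_labels)
                if LEFT_RIGHT[ch] == "left"]
        right = [i for i, ch in enumerate(mask.channel_labels)
                 if LEFT_RIGHT[ch] == "right"]
        for grp in (left, right):
            for i in grp[1:]:
                assert np.array_equal(mask.mask[grp[0]], mask.mask[i])

    def test_matches_brute_force_oracle_on_random_spike_trains(self):
        """Single-channel-per-hemisphere layout removes hemisphere spread,
        so the mask must equal the sample-by-sample two-stage oracle."""
        rng = np.random.default_rng(7)
        fs = 32.0
        n = int(60 * fs)
        for _ in range(25):
            env_like = np.zeros(n)
            for _ in range(rng.integers(1, 6)):
                i = int(rng.integers(0, n))
                env_like[i] = rng.uniform(50, 500)
            rec = EegRecording(env_like[None], fs, ["A-left"])
            got = detect_artifacts(
                rec, {"A-left": "left"},
            )
            env = envelope(env_like)
            want = brute_force_artifact_mask(env, fs, 300.0, 10.0, 100.0, 3.0)
            assert np.array_equal(got.mask[0], want)


class TestPercentArtifact:
    def test_20s_of_60_is_a_third(self):
        n = int(60 * FS)
        rec = _recording({"A-left": _spike(n, 30.0, 400.0)})
        mask = detect_artifacts(rec, {"A-left": "left"})
        epoch_pct, per_channel = percent_artifact(mask)
        assert epoch_pct == pytest.approx(100 * 20 / 60, rel=0.03)
        assert per_channel["A-left"] == pytest.approx(epoch_pct)

    def test_empty_and_full(self):
        n = 640
        empty = detect_artifacts(
            _recording({"A-left": _quiet(n)}), {"A-left": "left"}
        )
        assert percent_artifact(empty)[0] == 0.0
        full = detect_artifacts(
            _recording({"A-left": np.full(n, 500.0)}), {"A-left": "left"}
        )
        assert percent_artifact(full)[0] == pytest.approx(100.0)
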