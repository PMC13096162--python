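import numpy as np
import pytest

from fibconn.io import Recording, read_recording, write_recording
from fibconn.preprocess import (
    DEFAULT_MONTAGE,
    RejectionCriteria,
    Segment,
    apply_montage,
    bandpass_resample,
    common_average_reference,
    reject_artifacts,
    segment,
)


def _recording(data, fs=128.0, labels=None):
    data = np.asarray(data, dtype=float)
    labels = labels or [f"ch{i}" for i in range(data.shape[1])]
    return Recording(data=data, fs=fs, channel_labels=labels)


def _segment(data, fs=128.0):
    data = np.asarray(data, dtype=float)
    return Segment(
        data=data,
        fs=fs,
        index=0,
        start_sample=0,
        channel_labels=[f"ch{i}" for i in range(data.shape[1])],
    )


def _clean_noise(n=1280, channels=1, sd=5.0, seed=0):
    """Sub-threshold white noise fixture: passes all four criteria."""
    rng = np.random.default_rng(seed)
    x = np.clip(sd * rng.standard_normal((n, channels)), -20, 20)
    # keep the per-sample gradient below 10 uV/ms at 128 Hz
    return x


class TestBandpassResample:
    def test_output_length_scales_with_rate(self):
        rng = np.random.default_rng(0)
        rec = _recording(rng.standard_normal((150_000, 2)), fs=500.0)
        out = bandpass_resample(rec, 0.1, 64.0, 128.0)
        assert out.fs == 128.0
        assert out.n_samples == 38_400  # 300 s at 128 Hz

    def test_stopband_attenuates_fast_oscillation(self):
        from scipy import signal as sig

        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        rec = _recording(np.sin(2 * np.pi * 80 * t)[:, None] * 50, fs=fs)
        out = bandpass_resample(rec, 0.1, 64.0, 128.0)
        # oracle: the zero-phase (squared-magnitude) response of the
        # 4th-order Butterworth at 80 Hz bounds the surviving amplitude
        sos = sig.butter(4, [0.1, 64.0], btype="bandpass", fs=fs, output="sos")
        _, h = sig.sosfreqz(sos, worN=[80.0], fs=fs)
        bound = float(np.abs(h[0]) ** 2)
        assert bound < 0.3
        # steady state only: the 0.1 Hz high-pass has multi-second edge
        # transients, so discard 20 s at each end before measuring
        interior = out.data[int(20 * 128) : -int(20 * 128)]
        assert interior.std() <= 1.2 * bound * rec.data.std()

    def test_dc_removed_by_highpass(self):
        rec = _recording(np.full((20_000, 1), 42.0), fs=500.0)
        out = bandpass_resample(rec, 0.1, 64.0, 128.0)
        assert np.abs(out.data[2000:-2000]).max() < 1.0

    def test_invalid_settings_rejected(self):
        rec = _recording(np.zeros((1000, 1)), fs=100.0)
        with pytest.raises(ValueError):
            bandpass_resample(rec, 0.1, 64.0, 128.0)  # upsampling
        with pytest.raises(ValueError):
            bandpass_resample(rec, 0.1, 60.0, 100.0)  # high >= Nyquist


class TestSegment:
    @pytest.mark.parametrize(
        "duration,expected", [(300, 30), (305, 30), (9, 0), (10, 1)]
    )
    def test_segment_counts(self, duration, expected):
        rec = _recording(np.zeros((int(duration * 128), 1)))
        assert len(segment(rec, 10)) == expected

    def test_segments_are_consecutive_non_overlapping(self):
        rec = _recording(np.arange(1280 * 3, dtype=float)[:, None])
        segs = segment(rec, 10)
        assert [s.start_sample for s in segs] == [0, 1280, 2560]
        np.testing.assert_array_equal(segs[1].data[:, 0], np.arange(1280, 2560))


class TestRejectionCriteria:
    def test_gradient_criterion(self):
        x = _clean_noise()
        x[100, 0] += 100.0  # 100 uV jump over 7.8 ms = 12.8 uV/ms
        kept, log = reject_artifacts([_segment(x)])
        assert not kept
        assert "gradient" in set(log.criterion)

    def test_minmax_criterion(self):
        x = _clean_noise()
        # slow swing of 120 uV within a 200 ms window, gradient-safe
        ramp = np.linspace(0, 120, 13)
        x[200 : 200 + 13, 0] += ramp
        x[213 : 213 + 13, 0] += ramp[::-1]
        kept, log = reject_artifacts([_segment(x)])
        assert not kept
        assert "minmax" in set(log.criterion)

    def test_amplitude_criterion(self):
        x = _clean_noise()
        drift = np.zeros_like(x)
        drift[:, 0] = np.linspace(0, 200, len(x))  # slow drift beyond +150
        kept, log = reject_artifacts([_segment(x + drift)])
        assert not kept
        assert "amplitude" in set(log.criterion)

    def test_low_activity_criterion(self):
        x = _clean_noise()
        x[500:600, 0] = 0.0  # flatline well beyond the 100 ms window
        kept, log = reject_artifacts([_segment(x)])
        assert not kept
        assert "low_activity" in set(log.criterion)
        assert (log.loc[log.criterion == "low_activity", "value"] == 0.0).all()

    def test_all_zero_segment_rejected_as_low_activity(self):
        kept, log = reject_artifacts([_segment(np.zeros((1280, 2)))])
        assert not kept
        assert set(log.criterion) == {"low_activity"}

    def test_clean_subthreshold_fixture_retained(self):
        kept, log = reject_artifacts([_segment(_clean_noise())])
        assert len(kept) == 1
        assert log.empty

    def test_rejection_idempotent(self):
        segs = [_segment(_clean_noise(seed=s)) for s in range(5)]
        segs[2].data[10, 0] = 400.0
        kept, _ = reject_artifacts(segs)
        kept2, log2 = reject_artifacts(kept)
        assert len(kept2) == len(kept) == 4
        assert log2.empty

    def test_custom_thresholds(self):
        x = _clean_noise(sd=5.0)
        kept, _ = reject_artifacts(
            [_segment(x)], RejectionCriteria(amp_min_uv=-1.0, amp_max_uv=1.0)
        )
        assert not kept


class TestMontage:
    def test_mean_and_normalization(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(1000)
        b = rng.standard_normal(1000)
        rec = Recording(
            data=np.column_stack([a, b]),
            fs=128.0,
            channel_labels=["e1", "e2"],
        )
        out = apply_montage(rec, {"region": ["e1", "e2"]})
        m = (a + b) / 2
        expected = (m - m.mean()) / m.std()
        np.testing.assert_allclose(out.data[:, 0], expected, atol=1e-10)
        assert abs(out.data.mean()) < 1e-10
        assert out.data.std() == pytest.approx(1.0, abs=1e-10)

    def test_identical_members_give_common_signal(self):
        x = np.sin(np.linspace(0, 20, 500))
        rec = _recording(np.column_stack([x, x]), labels=["e1", "e2"])
        out = apply_montage(rec, {"r": ["e1", "e2"]})
        np.testing.assert_allclose(out.data[:, 0], (x - x.mean()) / x.std(), atol=1e-10)

    def test_permutation_within_region_commutes(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((500, 3))
        rec = _recording(data, labels=["a", "b", "c"])
        out1 = apply_montage(rec, {"r": ["a", "b", "c"]})
        out2 = apply_montage(rec, {"r": ["c", "a", "b"]})
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-12)

    def test_missing_electrode_named_in_error(self):
        rec = _recording(np.zeros((100, 1)), labels=["e1"])
        with pytest.raises(ValueError, match="e9"):
            apply_montage(rec, {"r": ["e1", "e9"]})

    def test_default_montage_disjoint_eight_regions(self):
        assert len(DEFAULT_MONTAGE) == 8
        all_electrodes = [e for els in DEFAULT_MONTAGE.values() for e in els]
        assert len(all_electrodes) == len(set(all_electrodes))


def test_common_average_reference_zero_mean_rows():
    rng = np.random.default_rng(3)
    rec = _recording(rng.standard_normal((200, 4)) + 5.0)
    out = common_average_reference(rec)
    np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-12)


def test_recording_roundtrip(tmp_path):
    rng = np.random.default_rng(4)
    rec = Recording(
        data=rng.standard_normal((100, 3)),
        fs=128.0,
        channel_labels=["a", "b", "c"],
        meta={"participant_id": "P001", "condition": "pre"},
    )
    write_recording(rec, tmp_path / "rec")
    back = read_recording(tmp_path / "rec")
    np.testing.assert_allclose(back.data, rec.data, atol=1e-6)
    assert back.channel_labels == rec.channel_labels
    assert back.meta["condition"] == "pre"
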