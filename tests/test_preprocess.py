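import numpy as np
import pytest

from emdwave.io_signals import DomainError, EEGRecording
from emdwave.preprocess import (
    bandpass_fir,
    extract_segments,
    notch_filter,
    preprocess,
)


def tone_recording(freq_hz, fs=500.0, duration_s=10.0, amplitude=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return EEGRecording(x[None, :], fs, ("Fp1",))


def central_rms(x, frac=0.8):
    n = x.shape[-1]
    lo = int(n * (1 - frac) / 2)
    return np.sqrt(np.mean(x[..., lo : n - lo] ** 2))


class TestNotch:
    def test_line_frequency_killed(self):
        rec = tone_recording(50.0)
        out = notch_filter(rec, 50.0)
        assert central_rms(out.data) <= 0.03 * central_rms(rec.data)

    def test_passband_preserved(self):
        rec = tone_recording(10.0)
        out = notch_filter(rec, 50.0)
        assert central_rms(out.data) == pytest.approx(
            central_rms(rec.data), rel=0.05
        )

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(DomainError):
            notch_filter(tone_recording(10.0, fs=500.0), f0=300.0)

    def test_shape_and_rate_unchanged(self):
        rec = tone_recording(10.0)
        out = notch_filter(rec)
        assert out.data.shape == rec.data.shape and out.fs == rec.fs


class TestBandpass:
    def test_dc_removed_entirely(self):
        rec = EEGRecording(np.full((1, 5000), 100.0), 500.0, ("Fp1",))
        out = bandpass_fir(rec)
        assert np.max(np.abs(out.data)) < 1e-3 * 100.0
        assert abs(out.data.mean()) < 1e-6

    def test_passband_preserved(self):
        rec = tone_recording(10.0)
        out = bandpass_fir(rec)
        assert central_rms(out.data) == pytest.approx(
            central_rms(rec.data), rel=0.05
        )

    def test_stopband_attenuated(self):
        rec = tone_recording(100.0)
        out = bandpass_fir(rec)
        assert central_rms(out.data) <= 0.01 * central_rms(rec.data)

    def test_invalid_corners_rejected(self):
        rec = tone_recording(10.0, fs=100.0)
        with pytest.raises(DomainError):
            bandpass_fir(rec, f_lo=0.5, f_hi=60.0)  # above Nyquist

    def test_too_short_signal_rejected(self, rng):
        rec = EEGRecording(rng.normal(size=(1, 100)), 500.0, ("Fp1",))
        with pytest.raises(DomainError, match="shorter"):
            bandpass_fir(rec)


class TestFilterProperties:
    def test_linearity(self, rng):
        x = EEGRecording(rng.normal(size=(1, 5000)), 500.0, ("Fp1",))
        y = EEGRecording(rng.normal(size=(1, 5000)), 500.0, ("Fp1",))
        combined = EEGRecording(2.0 * x.data - 3.0 * y.data, 500.0, ("Fp1",))
        lhs = bandpass_fir(combined).data
        rhs = 2.0 * bandpass_fir(x).data - 3.0 * bandpass_fir(y).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_notch_and_bandpass_commute(self, rng):
        # LTI operators commute in the interior; boundary handling differs,
        # so the filter-length-wide edges are excluded
        rec = EEGRecording(rng.normal(size=(2, 10_000)), 500.0,
                          ("Fp1", "Fp2"))
        a = bandpass_fir(notch_filter(rec)).data[:, 2000:-2000]
        b = notch_filter(bandpass_fir(rec)).data[:, 2000:-2000]
        np.testing.assert_allclose(a, b, rtol=0, atol=1e-4 * np.abs(a).max())


class TestExtractSegments:
    def test_standard_length_at_500hz(self, rng):
        rec = EEGRecording(rng.normal(size=(2, 100_000)), 500.0,
                          ("Fp1", "Fp2"))
        segs, skipped = extract_segments(
            rec, [("lecture", 0.0, 200.0)], standard_length_s=154.0
        )
        assert not skipped
        assert segs[0].n_samples == 77_000  # 2 min 34 s at 500 Hz

    def test_interval_equal_to_standard_returned_whole(self, rng):
        rec = EEGRecording(rng.normal(size=(1, 1000)), 100.0, ("Fp1",))
        segs, _ = extract_segments(rec, [("lecture", 0.0, 10.0)],
                                   standard_length_s=10.0)
        np.testing.assert_array_equal(segs[0].data, rec.data)

    def test_short_interval_skipped_with_warning(self, rng, caplog):
        rec = EEGRecording(rng.normal(size=(1, 2000)), 100.0, ("Fp1",))
        segs, skipped = extract_segments(
            rec, [("short", 0.0, 5.0), ("ok", 5.0, 20.0)],
            standard_length_s=10.0,
        )
        assert skipped == ["short"] and len(segs) == 1

    def test_interval_outside_recording_rejected(self, rng):
        rec = EEGRecording(rng.normal(size=(1, 1000)), 100.0, ("Fp1",))
        with pytest.raises(DomainError, match="outside"):
            extract_segments(rec, [("x", 5.0, 30.0)], standard_length_s=5.0)

    def test_all_segments_same_length(self, rng):
        rec = EEGRecording(rng.normal(size=(1, 5000)), 100.0, ("Fp1",))
        intervals = [("a", 0.0, 13.0), ("b", 13.0, 29.5), ("c", 30.0, 50.0)]
        segs, _ = extract_segments(rec, intervals, standard_length_s=12.0)
        assert {s.n_samples for s in segs} == {1200}


def test_preprocess_chain_removes_line_and_drift(rng):
    t = np.arange(5000) / 500.0
    clean = np.sin(2 * np.pi * 10.0 * t)
    dirty = clean + 5.0 * np.sin(2 * np.pi * 50.0 * t) + 40.0  # line + offset
    rec = EEGRecording(dirty[None, :], 500.0, ("Fp1",))
    out = preprocess(rec)
    assert central_rms(out.data) == pytest.approx(
        central_rms(clean[None, :]), rel=0.05
    )
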