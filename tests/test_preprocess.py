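import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.signal import butter, sosfreqz

import cecgpose as cp
from cecgpose.errors import InsufficientDataError, ParameterError
from cecgpose.preprocess import RPeakList, mmd_transform

from conftest import spike_train_record


def flat_record(x, fs=500.0):
    n = len(x)
    sched = cp.PostureSchedule([(0, n / fs, cp.PostureLabel.SUPINE)])
    return cp.SignalRecord("t", fs, np.stack([x, x]), sched)


class TestBandpass:
    def test_dc_removed(self):
        rec = flat_record(np.full(5000, 3.0))
        out = cp.bandpass(rec)
        assert np.abs(out.channels).mean() < 0.03  # < 1% of the 3 mV offset

    def test_50hz_attenuation_matches_design(self):
        """Powerline RMS after filtering must match the designed magnitude
        response at 50 Hz (independently evaluated via sosfreqz) and stay
        below 20% of the input RMS."""
        fs = 500.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 50.0 * t)
        out = cp.bandpass(flat_record(x, fs)).channels[0]
        sos = butter(4, [0.5, 40.0], btype="bandpass", fs=fs, output="sos")
        _, h = sosfreqz(sos, worN=[50.0], fs=fs)
        expected = np.abs(h[0]) ** 2  # forward-backward doubles the attenuation
        core = slice(int(fs), int(9 * fs))  # ignore filter edge transients
        ratio = np.sqrt(np.mean(out[core] ** 2) / np.mean(x[core] ** 2))
        assert ratio < 0.20
        assert ratio == pytest.approx(expected, rel=0.05)

    def test_10hz_passband_flat(self):
        fs = 500.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        out = cp.bandpass(flat_record(x, fs)).channels[0]
        core = slice(int(fs), int(9 * fs))
        ratio = np.sqrt(np.mean(out[core] ** 2) / np.mean(x[core] ** 2))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_invalid_cutoffs(self):
        rec = flat_record(np.zeros(1000))
        with pytest.raises(ParameterError):
            cp.bandpass(rec, low_hz=40, high_hz=0.5)
        with pytest.raises(ParameterError):
            cp.bandpass(rec, low_hz=0.5, high_hz=300)


class TestExcision:
    def test_clean_record_untouched(self):
        rec = flat_record(np.random.default_rng(0).normal(0, 0.1, 5000))
        clean, mask = cp.excise_artifacts(rec)
        assert mask.valid.all()
        assert mask.excised_intervals == []
        assert mask.valid_fraction == 1.0

    def test_bursts_fully_excised_with_padding(self):
        rec = cp.overnight_protocol(duration_min=12.0, seed=6, fs=250)
        assert rec.artifact_intervals  # schedule has transitions
        _, mask = cp.excise_artifacts(rec, pad_s=0.5)
        for a, b in rec.artifact_intervals:
            i0 = int(a * rec.fs)
            i1 = int(b * rec.fs)
            over = np.any(np.abs(rec.channels[:, i0:i1]) > 5.0, axis=0)
            bad_idx = np.flatnonzero(over) + i0
            assert not mask.valid[bad_idx].any()

    def test_values_never_altered(self):
        rec = cp.overnight_protocol(duration_min=12.0, seed=6, fs=250)
        before = rec.channels.copy()
        clean, _ = cp.excise_artifacts(rec)
        np.testing.assert_array_equal(clean.channels, before)

    def test_retention_fraction(self):
        """337 of 366 minutes surviving excision is 92.1% retention."""
        fs = 100.0
        n = int(366 * 60 * fs)
        x = np.zeros(n)
        # 29 one-minute excisions: 59 s burst + 0.5 s padding on each side
        for k in range(29):
            start = int((5 + 12.5 * k) * 60 * fs) + int(0.5 * fs)
            x[start : start + int(59 * fs)] = 8.0
        sched = cp.PostureSchedule([(0, n / fs, cp.PostureLabel.SUPINE)])
        rec = cp.SignalRecord("night", fs, np.stack([x, np.zeros(n)]), sched)
        _, mask = cp.excise_artifacts(rec, threshold_mv=5.0, pad_s=0.5)
        assert round(100 * mask.valid_fraction, 1) == 92.1


class TestMmd:
    def test_constant_signal_zero(self):
        assert np.allclose(mmd_transform(np.full(100, 2.5), scales=(5,)), 0.0)

    def test_unit_impulse_response(self):
        """At the impulse, dilation=1, erosion=0, f=1: |1 + 0 - 2| = 1."""
        x = np.zeros(51)
        x[25] = 1.0
        out = mmd_transform(x, scales=(5,))
        assert out[25] == pytest.approx(1.0)

    @given(seed=st.integers(0, 10**6))
    def test_sign_flip_invariance(self, seed):
        x = np.random.default_rng(seed).normal(size=200)
        np.testing.assert_allclose(mmd_transform(x), mmd_transform(-x), atol=1e-12)

    def test_rejects_even_or_tiny_scales(self):
        with pytest.raises(ParameterError):
            mmd_transform(np.zeros(10), scales=(4,))
        with pytest.raises(ParameterError):
            mmd_transform(np.zeros(10), scales=())


class TestDetector:
    def test_high_f1_on_clean_records(self, small_cohort):
        tp = fp = fn = 0
        for rec in small_cohort:
            filt = cp.bandpass(rec)
            _, mask = cp.excise_artifacts(rec)
            det = cp.detect_r_peaks(filt, mask).times_s
            true = rec.beat_times
            used = np.zeros(len(det), bool)
            for t in true:
                d = np.abs(det - t)
                j = int(np.argmin(d))
                if d[j] <= 0.05 and not used[j]:
                    used[j] = True
                    tp += 1
                else:
                    fn += 1
            fp += int((~used).sum())
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert f1 >= 0.99

    def test_polarity_invariance(self, small_cohort):
        rec = small_cohort[0]
        filt = cp.bandpass(rec)
        flipped = cp.SignalRecord(
            rec.subject_id, rec.fs, -filt.channels, rec.labels, mask=filt.mask
        )
        a = cp.detect_r_peaks(filt)
        b = cp.detect_r_peaks(flipped)
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_refractory_merges_close_peaks(self):
        rec = spike_train_record([1.0, 1.18, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        peaks = cp.detect_r_peaks(rec)
        near = peaks.times_s[(peaks.times_s > 0.8) & (peaks.times_s < 1.4)]
        assert len(near) == 1  # 180 ms apart -> one detection

    def test_peaks_inside_excised_intervals_dropped(self):
        rec = cp.overnight_protocol(duration_min=12.0, seed=6, fs=250)
        filt = cp.bandpass(rec)
        _, mask = cp.excise_artifacts(rec)
        peaks = cp.detect_r_peaks(filt, mask)
        assert mask.valid[peaks.indices].all()

    def test_too_short_record(self):
        rec = spike_train_record([0.5], duration_s=1.0)
        with pytest.raises(InsufficientDataError):
            cp.detect_r_peaks(rec)


class TestRRSeries:
    def test_simple_differences(self):
        peaks = RPeakList(indices=np.array([0, 500, 1000]), channel_used=0, fs=500.0)
        np.testing.assert_allclose(cp.rr_series(peaks).intervals_s, [1.0, 1.0])

    def test_length(self):
        peaks = RPeakList(indices=np.arange(0, 5000, 400), channel_used=0, fs=500.0)
        assert len(cp.rr_series(peaks).intervals_s) == len(peaks) - 1

    def test_requires_two_peaks(self):
        with pytest.raises(InsufficientDataError):
            cp.rr_series(RPeakList(indices=np.array([100]), channel_used=0, fs=500.0))

    def test_monte_carlo_mean_matches_subject(self, small_cohort):
        """Detected RR mean within 3 SE of the generating subject's mean RR."""
        rec = small_cohort[1]
        subj_rr = None
        # regenerate the phenotype that produced this record
        from cecgpose.synth import _subject_seeds, make_subject

        seeds = _subject_seeds(7, 3)
        subj = make_subject(int(seeds[1]), subject_id=rec.subject_id)
        subj_rr = 60.0 / subj.mean_hr
        filt = cp.bandpass(rec)
        rr = cp.rr_series(cp.detect_r_peaks(filt)).intervals_s
        sd_rr = subj.hr_sd * 60.0 / subj.mean_hr**2
        assert abs(rr.mean() - subj_rr) < 3 * sd_rr / np.sqrt(len(rr)) + 0.01
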