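import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cecgpose as cp

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_subject() -> cp.SubjectPhenotype:
    """One noiseless phenotype (cardiac signal only)."""
    return cp.make_subject(3).without_noise()


@pytest.fixture(scope="session")
def small_cohort() -> list[cp.SignalRecord]:
    """Three subjects, 1 min per posture, 500 Hz — shared across tests."""
    return cp.short_term_protocol(n_subjects=3, minutes_per_posture=1.0, fs=500, seed=7)


@pytest.fixture(scope="session")
def prepared_record(small_cohort):
    """(raw record, band-passed record, clean mask, detected peaks)."""
    rec = small_cohort[0]
    filt = cp.bandpass(rec)
    _, mask = cp.excise_artifacts(rec)
    peaks = cp.detect_r_peaks(filt, mask)
    return rec, filt, mask, peaks


def spike_train_record(
    spike_times_s, fs: float = 500.0, duration_s: float = 10.0, amp_mv: float = 1.5,
    width_s: float = 0.02, label=cp.PostureLabel.SUPINE,
) -> cp.SignalRecord:
    """Synthetic record of Gaussian spikes at known times (detector probing)."""
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    x = np.zeros(n)
    for ts in spike_times_s:
        x += amp_mv * np.exp(-0.5 * ((t - ts) / width_s) ** 2)
    ch = np.stack([x, 0.5 * x])
    return cp.SignalRecord(
        subject_id="spikes",
        fs=fs,
        channels=ch,
        labels=cp.PostureSchedule([(0.0, duration_s, label)]),
    )
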