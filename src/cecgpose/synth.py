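"""Synthetic posture-labelled capacitive-ECG generator.

The generative model treats the heart as a rotating 2-D dipole in the frontal
plane.  Each beat is a sum of five Gaussian waves (P, Q, R, S, T) placed on
the cardiac phase circle; every wave carries its own projection axis, so the
instantaneous dipole traces a loop rather than a line.  A mattress electrode
pair is a fixed lead direction ``u(phi)``; lying supine / left / right
rotates the whole loop by a posture angle ``theta``, which changes how each
wave projects onto each channel.  That posture-dependent morphology is the
signal the downstream classifier exploits.

On top of the cardiac signal the generator adds the nuisances a capacitive
mattress measurement actually contains: baseline wander (below 0.4 Hz),
50 Hz powerline pickup, white sensor noise, and — at posture transitions —
large motion-artifact bursts whose amplitude always exceeds the 5 mV bound
used by the artifact cleaner.

Everything is driven by ``numpy.random.Generator`` streams derived from
explicit seeds, so identical inputs give bit-identical records.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, RateError
from .records import POSTURE_ORDER, PostureLabel, PostureSchedule, SignalRecord

__all__ = [
    "WaveParams",
    "SubjectPhenotype",
    "PostureGeometry",
    "DEFAULT_GEOMETRY",
    "make_subject",
    "synthesize",
    "short_term_protocol",
    "overnight_protocol",
]

WAVE_NAMES = ("P", "Q", "R", "S", "T")

# Population-level wave template: amplitudes in mV, centers/widths in radians
# of cardiac phase (R wave at phase 0, one beat = 2*pi), projection axis in
# degrees in the frontal plane.  Centered on textbook adult morphology.
_BASE_AMP = {"P": 0.12, "Q": -0.12, "R": 1.5, "S": -0.25, "T": 0.35}
_BASE_CENTER = {"P": -1.047, "Q": -0.262, "R": 0.0, "S": 0.262, "T": 1.571}
_BASE_WIDTH = {"P": 0.25, "Q": 0.10, "R": 0.10, "S": 0.10, "T": 0.40}
_BASE_AXIS = {"P": 55.0, "Q": 25.0, "R": 30.0, "S": 20.0, "T": 45.0}


@dataclass(frozen=True)
class WaveParams:
    """One Gaussian wave on the cardiac phase circle."""

    amp_mv: float
    center_rad: float
    width_rad: float
    axis_deg: float


@dataclass(frozen=True)
class SubjectPhenotype:
    """Per-subject generative parameters.

    ``coupling_gain`` models subject-dependent capacitive coupling strength
    per channel (clothing, contact area); unitless multipliers.
    """

    subject_id: str
    waves: dict[str, WaveParams]
    mean_hr: float  # beats/min
    hr_sd: float  # beats/min
    baseline_amp: float  # mV
    powerline_amp: float  # mV
    noise_sd: float  # mV
    coupling_gain: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if not (40.0 <= self.mean_hr <= 120.0):
            raise ParameterError(f"mean_hr {self.mean_hr} outside [40, 120] bpm")
        for name, w in self.waves.items():
            if w.width_rad <= 0:
                raise ParameterError(f"wave {name} width must be positive")
        r_amp = abs(self.waves["R"].amp_mv)
        for name, w in self.waves.items():
            if name != "R" and abs(w.amp_mv) >= r_amp:
                raise ParameterError("R wave must have the largest amplitude magnitude")

    def without_noise(self) -> "SubjectPhenotype":
        return replace(self, baseline_amp=0.0, powerline_amp=0.0, noise_sd=0.0)


@dataclass(frozen=True)
class PostureGeometry:
    """Posture rotation angles and electrode lead angles, in degrees.

    ``theta`` rotates the cardiac loop about the body's longitudinal axis
    (supine = 0 by convention); ``phi`` are the lead directions of the two
    mattress electrode pairs.  Values are a fixed, documented convention —
    they guarantee distinct projections per posture without claiming
    anatomical fidelity.
    """

    theta: dict[PostureLabel, float] = field(
        default_factory=lambda: {
            PostureLabel.SUPINE: 0.0,
            PostureLabel.LEFT: -60.0,
            PostureLabel.RIGHT: 60.0,
        }
    )
    phi: tuple[float, float] = (0.0, 75.0)

    def __post_init__(self) -> None:
        if self.theta.get(PostureLabel.SUPINE, 0.0) != 0.0:
            raise ParameterError("theta(SUPINE) must be 0 by convention")
        if self.theta[PostureLabel.LEFT] == self.theta[PostureLabel.RIGHT]:
            raise ParameterError("LEFT and RIGHT rotation angles must differ")
        if self.phi[0] == self.phi[1]:
            raise ParameterError("the two channel lead angles must differ")


DEFAULT_GEOMETRY = PostureGeometry()


def _record_rng(seed: int, subject_id: str) -> np.random.Generator:
    """One RNG stream per record, keyed by (seed, subject id)."""
    sid_hash = zlib.crc32(subject_id.encode("utf-8")) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), sid_hash]))


def make_subject(seed: int, subject_id: str | None = None) -> SubjectPhenotype:
    """Draw a subject phenotype from documented physiologic ranges.

    Deterministic for a fixed seed.  Inter-subject variation jitters wave
    amplitudes, timings, widths and projection axes, heart rate, and the
    amount of each nuisance signal, so a leave-one-subject-out protocol
    faces genuinely unseen morphology in every fold.
    """
    rng = np.random.default_rng(np.random.SeedSequence([1315423911, int(seed) % (2**31)]))
    waves: dict[str, WaveParams] = {}
    for name in WAVE_NAMES:
        if name == "R":
            amp = rng.uniform(1.2, 2.0)
        else:
            amp = _BASE_AMP[name] * rng.uniform(0.75, 1.25)
        center = _BASE_CENTER[name]
        if name != "R":
            center += rng.uniform(-0.04, 0.04) * abs(_BASE_CENTER[name])
        width = _BASE_WIDTH[name] * rng.uniform(0.85, 1.15)
        axis = _BASE_AXIS[name] + rng.uniform(-12.0, 12.0)
        waves[name] = WaveParams(amp, center, width, axis)
    # sleeping heart rate: slower than resting wake values
    mean_hr = float(np.clip(rng.normal(62.0, 7.0), 45.0, 90.0))
    return SubjectPhenotype(
        subject_id=subject_id if subject_id is not None else f"subj{seed:03d}",
        waves=waves,
        mean_hr=mean_hr,
        hr_sd=float(rng.uniform(2.0, 6.0)),
        baseline_amp=float(rng.uniform(0.10, 0.30)),
        powerline_amp=float(rng.uniform(0.02, 0.08)),
        noise_sd=float(rng.uniform(0.03, 0.08)),
        coupling_gain=(float(rng.uniform(0.8, 1.2)), float(rng.uniform(0.8, 1.2))),
    )


def _draw_beat_times(
    subject: SubjectPhenotype,
    duration_s: float,
    rng: np.random.Generator,
    rsa_depth: float = 0.03,
    rsa_hz: float = 0.25,
) -> np.ndarray:
    """R-wave times covering [-2, duration + 2] s.

    RR intervals are i.i.d. truncated-Normal around 60/mean_hr with a small
    0.25 Hz sinusoidal modulation emulating respiratory sinus arrhythmia.
    """
    mean_rr = 60.0 / subject.mean_hr
    sd_rr = subject.hr_sd * 60.0 / subject.mean_hr**2
    times = [-2.0 + rng.uniform(0.0, mean_rr)]
    while times[-1] < duration_s + 2.0:
        rr = rng.normal(mean_rr, sd_rr)
        rr = float(np.clip(rr, 0.35, 2.5))
        if rsa_depth > 0:
            rr *= 1.0 + rsa_depth * np.sin(2.0 * np.pi * rsa_hz * times[-1])
        times.append(times[-1] + rr)
    return np.asarray(times)


def _wave_channel_amp(
    subject: SubjectPhenotype, geometry: PostureGeometry, posture: PostureLabel
) -> np.ndarray:
    """(n_channels, n_waves) projected wave amplitudes in mV for one posture.

    Channel k sees ``gain_k * amp_w * cos(axis_w + theta_posture - phi_k)``,
    i.e. the dot product of the rotated wave axis with the lead direction.
    """
    theta = geometry.theta[posture]
    amps = np.empty((2, len(WAVE_NAMES)))
    for k in range(2):
        for j, name in enumerate(WAVE_NAMES):
            w = subject.waves[name]
            proj = np.cos(np.deg2rad(w.axis_deg + theta - geometry.phi[k]))
            amps[k, j] = subject.coupling_gain[k] * w.amp_mv * proj
    return amps


def render_beat_template(
    subject: SubjectPhenotype,
    geometry: PostureGeometry,
    posture: PostureLabel,
    rr_s: float,
    fs: float,
) -> np.ndarray:
    """Noiseless two-channel waveform of one beat spanning [R, next R).

    Used both by the synthesizer (indirectly, same projection math) and by
    tests probing posture separability.
    """
    n = int(round(rr_s * fs))
    t = np.arange(n) / fs
    amps = _wave_channel_amp(subject, geometry, posture)
    out = np.zeros((2, n))
    for j, name in enumerate(WAVE_NAMES):
        w = subject.waves[name]
        center = w.center_rad / (2 * np.pi) * rr_s
        # waves with negative phase (P, Q) belong to the *next* R; within the
        # [R, next R) span they appear near the end of the beat
        if center < 0:
            center += rr_s
        sigma = w.width_rad / (2 * np.pi) * rr_s
        out += amps[:, j : j + 1] * np.exp(-0.5 * ((t - center) / sigma) ** 2)[None, :]
    return out


def synthesize(
    subject: SubjectPhenotype,
    geometry: PostureGeometry,
    schedule: PostureSchedule,
    fs: float = 500.0,
    seed: int = 0,
    transition_artifacts: bool = False,
) -> SignalRecord:
    """Render a full two-channel record for one subject and schedule.

    The cardiac component is the sum over beats of the five projected
    Gaussian waves; each beat's posture is the schedule label at its R time.
    Baseline wander, powerline pickup and white noise are added per channel.
    When ``transition_artifacts`` is set, a low-frequency burst exceeding
    5 mV is injected at every posture change and logged in
    ``record.artifact_intervals``.
    """
    if fs < 100.0:
        raise RateError(f"fs must be >= 100 Hz for ECG morphology, got {fs}")
    schedule.validate()
    rng = _record_rng(seed, subject.subject_id)
    duration = schedule.duration_s
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    sig = np.zeros((2, n))

    beat_times = _draw_beat_times(subject, duration, rng)
    # posture of each beat = schedule label at its R time (clamped to record)
    beat_post_idx = schedule.labels_at(np.clip(beat_times, 0.0, duration - 1e-9))
    amp_by_posture = np.stack(
        [_wave_channel_amp(subject, geometry, p) for p in POSTURE_ORDER]
    )  # (3, 2, n_waves)

    wave_centers = np.array([subject.waves[nm].center_rad for nm in WAVE_NAMES])
    wave_widths = np.array([subject.waves[nm].width_rad for nm in WAVE_NAMES])

    for k in range(len(beat_times) - 1):
        t_r = beat_times[k]
        rr = beat_times[k + 1] - t_r
        amps = amp_by_posture[beat_post_idx[k]]  # (2, n_waves)
        for j in range(len(WAVE_NAMES)):
            center = wave_centers[j] / (2 * np.pi) * rr
            if center < 0:  # P/Q of beat k+1, rendered relative to next R
                t_w = beat_times[k + 1] + center
                a = amp_by_posture[beat_post_idx[k + 1]][:, j]
            else:
                t_w = t_r + center
                a = amps[:, j]
            sigma = wave_widths[j] / (2 * np.pi) * rr
            i0 = max(int(np.floor((t_w - 4 * sigma) * fs)), 0)
            i1 = min(int(np.ceil((t_w + 4 * sigma) * fs)) + 1, n)
            if i1 <= i0:
                continue
            g = np.exp(-0.5 * ((t[i0:i1] - t_w) / sigma) ** 2)
            sig[0, i0:i1] += a[0] * g
            sig[1, i0:i1] += a[1] * g

    # nuisances, drawn per channel
    for k in range(2):
        if subject.baseline_amp > 0:
            for _ in range(3):
                f = rng.uniform(0.05, 0.4)
                ph = rng.uniform(0, 2 * np.pi)
                sig[k] += (subject.baseline_amp / 3.0) * np.sin(2 * np.pi * f * t + ph)
        if subject.powerline_amp > 0:
            ph = rng.uniform(0, 2 * np.pi)
            sig[k] += subject.powerline_amp * np.sin(2 * np.pi * 50.0 * t + ph)
        if subject.noise_sd > 0:
            sig[k] += rng.normal(0.0, subject.noise_sd, size=n)

    artifact_intervals: list[tuple[float, float]] = []
    if transition_artifacts:
        for tb in schedule.transition_times:
            dur_b = rng.uniform(2.0, 5.0)
            a0 = max(tb - dur_b / 2.0, 0.0)
            a1 = min(tb + dur_b / 2.0, duration)
            i0, i1 = int(round(a0 * fs)), int(round(a1 * fs))
            m = i1 - i0
            if m <= 0:
                continue
            tt = np.arange(m) / fs
            f_b = rng.uniform(1.0, 4.0)
            win = np.hanning(m)
            for k in range(2):
                peak = rng.uniform(7.0, 11.0)
                ph = rng.uniform(0, 2 * np.pi)
                burst = peak * win * np.sin(2 * np.pi * f_b * tt + ph)
                # guarantee the 5 mV excision bound is violated on this channel
                mx = np.max(np.abs(burst))
                if mx < 6.0:
                    burst *= 6.0 / mx
                sig[k, i0:i1] += burst
            artifact_intervals.append((a0, a1))

    visible = (beat_times >= 0.0) & (beat_times < duration)
    return SignalRecord(
        subject_id=subject.subject_id,
        fs=fs,
        channels=sig,
        labels=schedule,
        beat_times=beat_times[visible],
        artifact_intervals=artifact_intervals,
    )


def _subject_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(int(seed) % (2**31)).generate_state(n) % (2**31)


def short_term_protocol(
    n_subjects: int = 15,
    minutes_per_posture: float = 5.0,
    fs: float = 500.0,
    seed: int = 0,
    geometry: PostureGeometry = DEFAULT_GEOMETRY,
) -> list[SignalRecord]:
    """Simulate the attended short-term protocol.

    Each subject holds the three postures in a randomized order for
    ``minutes_per_posture`` each (one record per subject, three contiguous
    blocks, no transition artifacts — transition segments are assumed to
    have been trimmed by the operator).
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    sub_seeds = _subject_seeds(seed, n_subjects)
    order_rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 7]))
    records = []
    block_s = minutes_per_posture * 60.0
    for i in range(n_subjects):
        subject = make_subject(int(sub_seeds[i]), subject_id=f"subj{i + 1:02d}")
        order = list(POSTURE_ORDER)
        order_rng.shuffle(order)
        schedule = PostureSchedule(
            [(j * block_s, (j + 1) * block_s, p) for j, p in enumerate(order)]
        )
        records.append(
            synthesize(subject, geometry, schedule, fs=fs, seed=seed, transition_artifacts=False)
        )
    return records


def overnight_protocol(
    duration_min: float = 366.0,
    seed: int = 0,
    fs: float = 500.0,
    geometry: PostureGeometry = DEFAULT_GEOMETRY,
    subject_seed: int | None = None,
) -> SignalRecord:
    """Simulate one unattended overnight recording.

    Postures follow a random piecewise-constant schedule with dwell times of
    5–60 min (never repeating the previous posture), and every posture change
    injects a motion-artifact burst exceeding 5 mV.
    """
    if duration_min <= 0:
        raise ParameterError("duration_min must be positive")
    duration_s = duration_min * 60.0
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 99]))
    if subject_seed is None:
        subject_seed = int(_subject_seeds(seed, 64)[63])
    subject = make_subject(subject_seed, subject_id="overnight01")
    intervals = []
    t0 = 0.0
    prev: PostureLabel | None = None
    while t0 < duration_s - 1e-9:
        dwell = rng.uniform(5.0, 60.0) * 60.0
        t1 = min(t0 + dwell, duration_s)
        choices = [p for p in POSTURE_ORDER if p is not prev]
        p = choices[rng.integers(len(choices))]
        intervals.append((t0, t1, p))
        prev = p
        t0 = t1
    schedule = PostureSchedule(intervals)
    return synthesize(subject, geometry, schedule, fs=fs, seed=seed, transition_artifacts=True)
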