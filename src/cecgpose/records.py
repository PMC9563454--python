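"""Core data containers: posture labels, schedules, and signal records.

Conventions (single source of truth for the whole package):

* time is 0-based seconds; sample index ``i`` corresponds to time ``i / fs``;
* label intervals are half-open ``[start_s, end_s)``;
* all signal amplitudes are in millivolts (mV).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np

from .errors import RateError, ScheduleError, ShapeError

__all__ = [
    "PostureLabel",
    "POSTURE_ORDER",
    "PostureInterval",
    "PostureSchedule",
    "SignalRecord",
    "CleanMask",
]


class PostureLabel(Enum):
    """The three sleep postures distinguished by the classifier.

    Serialized as single letters "S", "L", "R".  Prone is deliberately
    not modelled.
    """

    SUPINE = "S"
    LEFT = "L"
    RIGHT = "R"

    @classmethod
    def from_code(cls, code: str) -> "PostureLabel":
        code = code.strip().upper()
        for p in cls:
            if p.value == code:
                return p
        raise ValueError(f"unknown posture code {code!r} (expected S, L or R)")

    @property
    def index(self) -> int:
        return POSTURE_ORDER.index(self)


#: Fixed class order (supine, left lateral, right lateral) used for
#: confusion matrices, softmax outputs and tie-breaking.
POSTURE_ORDER: tuple[PostureLabel, ...] = (
    PostureLabel.SUPINE,
    PostureLabel.LEFT,
    PostureLabel.RIGHT,
)


@dataclass(frozen=True)
class PostureInterval:
    start_s: float
    end_s: float
    label: PostureLabel

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


class PostureSchedule:
    """Ordered, gap-free, non-overlapping posture intervals over [0, duration)."""

    def __init__(self, intervals: Iterable[tuple[float, float, PostureLabel] | PostureInterval]):
        ivs = []
        for iv in intervals:
            if not isinstance(iv, PostureInterval):
                iv = PostureInterval(float(iv[0]), float(iv[1]), iv[2])
            ivs.append(iv)
        ivs.sort(key=lambda iv: iv.start_s)
        self.intervals: list[PostureInterval] = ivs
        self.validate()

    def validate(self) -> None:
        if not self.intervals:
            raise ScheduleError("schedule has no intervals")
        prev_end = None
        for iv in self.intervals:
            if iv.start_s >= iv.end_s:
                raise ScheduleError(f"interval start {iv.start_s} >= end {iv.end_s}")
            if prev_end is not None and abs(iv.start_s - prev_end) > 1e-9:
                raise ScheduleError(
                    f"intervals not gap-free: previous ends at {prev_end}, next starts at {iv.start_s}"
                )
            prev_end = iv.end_s
        if abs(self.intervals[0].start_s) > 1e-9:
            raise ScheduleError("schedule must start at 0 s")

    @property
    def duration_s(self) -> float:
        return self.intervals[-1].end_s

    @property
    def transition_times(self) -> list[float]:
        """Interior boundaries where the posture changes."""
        times = []
        for a, b in zip(self.intervals[:-1], self.intervals[1:]):
            if a.label is not b.label:
                times.append(b.start_s)
        return times

    def label_at(self, t_s: float) -> PostureLabel:
        """Posture at time ``t_s`` (half-open interval convention)."""
        for iv in self.intervals:
            if iv.start_s <= t_s < iv.end_s:
                return iv.label
        if abs(t_s - self.duration_s) < 1e-9:  # closing endpoint
            return self.intervals[-1].label
        raise ScheduleError(f"time {t_s} s outside schedule [0, {self.duration_s})")

    def labels_at(self, t_s: np.ndarray) -> np.ndarray:
        """Vectorized class indices (into POSTURE_ORDER) for sample times."""
        edges = np.array([iv.start_s for iv in self.intervals] + [self.duration_s])
        idx = np.clip(np.searchsorted(edges, t_s, side="right") - 1, 0, len(self.intervals) - 1)
        codes = np.array([iv.label.index for iv in self.intervals])
        return codes[idx]

    def shifted(self, offset_s: float) -> "PostureSchedule":
        return PostureSchedule(
            [(iv.start_s + offset_s, iv.end_s + offset_s, iv.label) for iv in self.intervals]
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, PostureSchedule) and self.intervals == other.intervals


@dataclass
class SignalRecord:
    """Two-channel cECG record with posture labels and a validity mask.

    ``channels`` has shape (2, n_samples), units mV.  ``mask`` flags samples
    that survived artifact excision (all True for freshly simulated data).
    ``start_s`` is the offset of sample 0 in the parent timeline when the
    record is an excerpt of a longer one; the label schedule is always
    expressed in the record's own 0-based time.

    ``beat_times`` (true R-wave times, seconds) and ``artifact_intervals``
    (injected motion-artifact spans) are simulation ground truth carried for
    validation; they are not persisted by the file writers.
    """

    subject_id: str
    fs: float
    channels: np.ndarray
    labels: PostureSchedule
    mask: np.ndarray | None = None
    start_s: float = 0.0
    beat_times: np.ndarray | None = None
    artifact_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.mask is None:
            self.mask = np.ones(self.channels.shape[1], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.fs <= 0:
            raise RateError(f"fs must be positive, got {self.fs}")
        if self.channels.ndim != 2 or self.channels.shape[0] != 2:
            raise ShapeError(f"expected (2, n) channel array, got {self.channels.shape}")
        if self.mask.shape != (self.channels.shape[1],):
            raise ShapeError("mask length must match channel length")
        if abs(self.labels.duration_s - self.duration_s) > 1.0 / self.fs + 1e-9:
            raise ScheduleError(
                f"labels cover {self.labels.duration_s} s but record lasts {self.duration_s} s"
            )

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def excerpt(self, start_s: float, end_s: float, label: PostureLabel | None = None) -> "SignalRecord":
        """Contiguous sub-record on [start_s, end_s); labels re-based to 0."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round(end_s * self.fs))
        if not (0 <= i0 < i1 <= self.n_samples):
            raise ShapeError(f"excerpt [{start_s}, {end_s}) outside record")
        if label is None:
            label = self.labels.label_at(start_s)
        dur = (i1 - i0) / self.fs
        bt = None
        if self.beat_times is not None:
            sel = (self.beat_times >= start_s) & (self.beat_times < end_s)
            bt = self.beat_times[sel] - start_s
        return SignalRecord(
            subject_id=self.subject_id,
            fs=self.fs,
            channels=self.channels[:, i0:i1].copy(),
            labels=PostureSchedule([(0.0, dur, label)]),
            mask=self.mask[i0:i1].copy(),
            start_s=self.start_s + i0 / self.fs,
            beat_times=bt,
        )


@dataclass
class CleanMask:
    """Per-sample validity flags plus the excised intervals that produced them."""

    valid: np.ndarray
    excised_intervals: list[tuple[float, float]]
    fs: float

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.valid))

    def is_valid_span(self, start_s: float, end_s: float) -> bool:
        """True if every sample in [start_s, end_s) is valid."""
        i0 = int(np.floor(start_s * self.fs))
        i1 = int(np.ceil(end_s * self.fs))
        i0 = max(i0, 0)
        i1 = min(i1, len(self.valid))
        return bool(np.all(self.valid[i0:i1]))
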