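"""Classifier input construction: posture blocks, 30-s windows, beat segments.

A *beat segment* is the two-channel trace over one RR interval
``[R_i, R_{i+1})``, linearly resampled to a fixed 250 samples (removing the
heart-rate dependence of segment length) and z-scored per channel.  A
*window* groups the beats whose R wave falls inside one non-overlapping 30-s
epoch; window-level classification is a majority vote over its beats.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .preprocess import RPeakList
from .records import PostureLabel, SignalRecord

__all__ = [
    "BeatSegment",
    "Window",
    "cut_posture_blocks",
    "make_windows",
    "make_beat_segments",
    "normalize_segment",
    "assign_beats_to_windows",
    "segment_record",
]

log = logging.getLogger(__name__)

TARGET_LEN = 250
FLAT_SD_MV = 1e-9  # below this a channel is "flat" and the beat is dropped


@dataclass
class BeatSegment:
    """One normalized beat: (2, target_len) matrix plus provenance."""

    matrix: np.ndarray
    label: PostureLabel
    subject_id: str
    window_id: str
    beat_span: tuple[float, float]  # (start_s, end_s) in the parent timeline
    beat_idx: int = 0


@dataclass
class Window:
    """One fixed-length epoch and the beats whose R wave starts inside it."""

    window_id: str
    span: tuple[float, float]
    label: PostureLabel
    subject_id: str
    beats: list[BeatSegment] = field(default_factory=list)


def cut_posture_blocks(
    record: SignalRecord, block_min: float = 5.0
) -> list[tuple[PostureLabel, SignalRecord]]:
    """One contiguous ``block_min``-minute excerpt per posture interval.

    The excerpt starts at the beginning of the first fully valid stretch of
    the interval, so posture transitions and excised artifacts never leak
    into a block.  Intervals without ``block_min`` contiguous valid minutes
    are skipped with a warning.
    """
    if block_min <= 0:
        raise ParameterError("block_min must be positive")
    need = int(round(block_min * 60.0 * record.fs))
    blocks: list[tuple[PostureLabel, SignalRecord]] = []
    for iv in record.labels:
        i0 = int(round(iv.start_s * record.fs))
        i1 = min(int(round(iv.end_s * record.fs)), record.n_samples)
        valid = record.mask[i0:i1]
        start = _first_valid_run(valid, need)
        if start is None:
            log.warning(
                "posture interval [%.1f, %.1f) of %s has no %.1f contiguous valid minutes; skipped",
                iv.start_s,
                iv.end_s,
                record.subject_id,
                block_min,
            )
            continue
        a = (i0 + start) / record.fs
        blocks.append((iv.label, record.excerpt(a, a + need / record.fs, label=iv.label)))
    return blocks


def _first_valid_run(valid: np.ndarray, need: int) -> int | None:
    """Start offset of the first run of >= need True values, else None."""
    if need <= 0 or len(valid) < need:
        return None
    run = 0
    for i, v in enumerate(valid):
        run = run + 1 if v else 0
        if run >= need:
            return i - need + 1
    return None


def make_windows(block: SignalRecord, window_s: float = 30.0) -> list[Window]:
    """Tile a single-posture block with contiguous, non-overlapping windows.

    The trailing remainder shorter than ``window_s`` is dropped.
    """
    if window_s <= 0:
        raise ParameterError("window_s must be positive")
    label = block.labels.intervals[0].label
    n_win = int(np.floor(block.duration_s / window_s + 1e-9))
    wins = []
    for j in range(n_win):
        a = block.start_s + j * window_s
        wins.append(
            Window(
                window_id=f"{block.subject_id}:{a:.3f}",
                span=(a, a + window_s),
                label=label,
                subject_id=block.subject_id,
            )
        )
    return wins


def normalize_segment(matrix: np.ndarray) -> np.ndarray:
    """Per-channel z-score; idempotent within floating-point error."""
    mu = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, keepdims=True)
    return (matrix - mu) / sd


def _resample_linear(x: np.ndarray, target_len: int) -> np.ndarray:
    src = np.linspace(0.0, 1.0, x.shape[1])
    dst = np.linspace(0.0, 1.0, target_len)
    return np.stack([np.interp(dst, src, row) for row in x])


def make_beat_segments(
    record: SignalRecord,
    peaks: RPeakList,
    target_len: int = TARGET_LEN,
) -> list[BeatSegment]:
    """Cut, resample and normalize one segment per RR interval.

    Beat ``i`` spans ``[R_i, R_{i+1})``; its label is the posture at ``R_i``.
    Beats touching invalid (excised) samples, crossing a posture boundary, or
    with a flat channel are dropped.  Channels are linearly resampled to
    ``target_len`` and then z-scored, so every output channel has mean 0 and
    unit standard deviation regardless of heart rate.
    """
    if len(peaks) < 2:
        raise InsufficientDataError("need at least 2 R peaks to form beats")
    segments: list[BeatSegment] = []
    idx = peaks.indices
    fs = record.fs
    for i in range(len(idx) - 1):
        a, b = int(idx[i]), int(idx[i + 1])
        if b - a < 2:
            continue
        if not np.all(record.mask[a:b]):
            continue
        t_a, t_b = a / fs, b / fs
        label = record.labels.label_at(t_a)
        # guard against label changes inside the beat (no mixed segments)
        if record.labels.label_at(max(t_b - 1.0 / fs, t_a)) is not label:
            continue
        raw = record.channels[:, a:b]
        if np.any(raw.std(axis=1) < FLAT_SD_MV):
            continue
        mat = normalize_segment(_resample_linear(raw, target_len))
        segments.append(
            BeatSegment(
                matrix=mat.astype(np.float32),
                label=label,
                subject_id=record.subject_id,
                window_id="",
                beat_span=(record.start_s + t_a, record.start_s + t_b),
                beat_idx=i,
            )
        )
    return segments


def assign_beats_to_windows(windows: list[Window], beats: list[BeatSegment]) -> list[Window]:
    """Attach each beat to the window containing its R wave (beat start).

    Beats outside every window (e.g. in the trailing remainder) are dropped.
    """
    if not windows:
        return windows
    starts = np.array([w.span[0] for w in windows])
    for beat in beats:
        j = int(np.searchsorted(starts, beat.beat_span[0], side="right")) - 1
        if j < 0:
            continue
        w = windows[j]
        if w.span[0] <= beat.beat_span[0] < w.span[1] and w.subject_id == beat.subject_id:
            beat.window_id = w.window_id
            w.beats.append(beat)
    return windows


def segment_record(
    record: SignalRecord,
    peaks: RPeakList,
    window_s: float = 30.0,
    block_min: float | None = 5.0,
    target_len: int = TARGET_LEN,
) -> list[Window]:
    """Full segmentation of one record into labelled windows of beats.

    With ``block_min`` set (short-term protocol), one excerpt of that many
    minutes is cut per posture interval before windowing.  With
    ``block_min=None`` (overnight protocol), each posture interval is
    windowed over its whole extent.
    """
    if block_min is not None:
        blocks = cut_posture_blocks(record, block_min=block_min)
    else:
        blocks = []
        for iv in record.labels:
            end = min(iv.end_s, record.duration_s)
            if end - iv.start_s < window_s:
                continue
            blocks.append((iv.label, record.excerpt(iv.start_s, end, label=iv.label)))
    windows: list[Window] = []
    for label, block in blocks:
        wins = make_windows(block, window_s=window_s)
        peaks_local = _peaks_in_block(peaks, block)
        if len(peaks_local) >= 2:
            beats = make_beat_segments(block, peaks_local, target_len=target_len)
        else:
            beats = []
        windows.extend(assign_beats_to_windows(wins, beats))
    return windows


def _peaks_in_block(peaks: RPeakList, block: SignalRecord) -> RPeakList:
    """Re-index global peaks into a block's local sample coordinates."""
    t = peaks.times_s
    sel = (t >= block.start_s) & (t < block.start_s + block.duration_s)
    local = ((t[sel] - block.start_s) * block.fs).round().astype(np.int64)
    local = local[(local >= 0) & (local < block.n_samples)]
    return RPeakList(indices=local, channel_used=peaks.channel_used, fs=peaks.fs)
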