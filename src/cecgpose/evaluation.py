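"""Evaluation: confusion matrices, SEN/ACC/kappa, LOSOCV orchestration.

Metrics follow the usual definitions for a 3-class confusion matrix ``C``
(rows = truth, columns = prediction, fixed order supine/left/right):

* per-class sensitivity  SEN_k = TP_k / (TP_k + FN_k) x 100 %
  with TP/FN from the one-vs-rest collapse of class k;
* overall accuracy       ACC = trace(C) / total x 100 %;
* Cohen's kappa          kappa = (p_o - p_e) / (1 - p_e), with observed
  agreement p_o = trace/total and expected agreement
  p_e = sum_k row_k * col_k / total^2.

Leave-one-subject-out cross-validation trains on all subjects but one and
tests on the held-out subject, once per subject.  Every pipeline stage is
stateless (filters, excision, detection and segmentation have no fitted
parameters), so no information can leak from test to train by construction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ProtocolError
from .posture_model import (
    ModelSpec,
    PostureClassifier,
    PredictionSet,
    TrainConfig,
    build_model,
    predict,
    train,
    vote_window,
)
from .preprocess import bandpass, detect_r_peaks, excise_artifacts
from .records import POSTURE_ORDER, PostureLabel, SignalRecord
from .segmentation import BeatSegment, Window, segment_record

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics",
    "aggregate",
    "PipelineConfig",
    "prepare_record",
    "losocv",
    "LosocvResult",
    "overnight_eval",
]

log = logging.getLogger(__name__)

_CLASS_NAMES = tuple(p.value for p in POSTURE_ORDER)


@dataclass
class ConfusionMatrix:
    """3x3 counts, rows = true class, columns = predicted class (S, L, R)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3) or np.any(self.counts < 0):
            raise ValueError("confusion matrix must be 3x3 with nonnegative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for class index k."""
        tp = int(self.counts[k, k])
        fn = int(self.counts[k].sum() - tp)
        fp = int(self.counts[:, k].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fp, tn, fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


@dataclass
class MetricsReport:
    """SEN per class (%), overall ACC (%), Cohen's kappa, and agreements."""

    sen: dict[str, float | None]  # keyed "S","L","R"; None when class absent
    acc: float
    kappa: float
    p_o: float
    p_e: float
    unit: str = "beat"  # "beat" or "window"
    scope: str = ""  # e.g. subject id or "pooled"
    n: int = 0


def confusion(pred, truth) -> ConfusionMatrix:
    """Count label pairs into the fixed-order 3x3 matrix."""
    pred = list(pred)
    truth = list(truth)
    if len(pred) != len(truth) or not pred:
        raise ValueError("pred and truth must be equal-length and non-empty")
    counts = np.zeros((3, 3), dtype=np.int64)
    for p, t in zip(pred, truth):
        counts[t.index if isinstance(t, PostureLabel) else int(t),
               p.index if isinstance(p, PostureLabel) else int(p)] += 1
    return ConfusionMatrix(counts)


def metrics(cm: ConfusionMatrix, unit: str = "beat", scope: str = "") -> MetricsReport:
    """SEN/ACC/kappa from a confusion matrix.

    A class absent from the truth has undefined sensitivity; it is reported
    as None, logged, and excluded from any averaging.
    """
    total = cm.total
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    sen: dict[str, float | None] = {}
    for k, name in enumerate(_CLASS_NAMES):
        tp, _fp, _tn, fn = cm.one_vs_rest(k)
        if tp + fn == 0:
            log.info("class %s absent from truth in %s; SEN undefined", name, scope or "report")
            sen[name] = None
        else:
            sen[name] = 100.0 * tp / (tp + fn)
    p_o = float(np.trace(cm.counts)) / total
    row = cm.counts.sum(axis=1).astype(np.float64)
    col = cm.counts.sum(axis=0).astype(np.float64)
    p_e = float(np.dot(row, col)) / (total * total)
    if abs(1.0 - p_e) < 1e-15:
        kappa = 1.0 if abs(1.0 - p_o) < 1e-15 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return MetricsReport(
        sen=sen, acc=100.0 * p_o, kappa=kappa, p_o=p_o, p_e=p_e, unit=unit, scope=scope, n=total
    )


def aggregate(reports: list[MetricsReport], weights=None) -> MetricsReport:
    """Weighted arithmetic mean of per-report SEN, ACC and kappa.

    Default weight is 1 per report (one report per subject).  Undefined
    sensitivities are excluded from that class's average.  Rounding is left
    to the rendering layer.
    """
    if not reports:
        raise ValueError("nothing to aggregate")
    w = np.ones(len(reports)) if weights is None else np.asarray(weights, dtype=np.float64)
    if len(w) != len(reports):
        raise ValueError("weights length mismatch")
    sen: dict[str, float | None] = {}
    for name in _CLASS_NAMES:
        vals = [(r.sen[name], wi) for r, wi in zip(reports, w) if r.sen[name] is not None]
        sen[name] = (
            float(np.average([v for v, _ in vals], weights=[wi for _, wi in vals]))
            if vals
            else None
        )
    acc = float(np.average([r.acc for r in reports], weights=w))
    kappa = float(np.average([r.kappa for r in reports], weights=w))
    p_o = float(np.average([r.p_o for r in reports], weights=w))
    p_e = float(np.average([r.p_e for r in reports], weights=w))
    return MetricsReport(
        sen=sen, acc=acc, kappa=kappa, p_o=p_o, p_e=p_e,
        unit=reports[0].unit, scope="average", n=int(sum(r.n for r in reports)),
    )


# ------------------------------------------------------------------ pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the record -> report pipeline needs, in one place."""

    low_hz: float = 0.5
    high_hz: float = 40.0
    threshold_mv: float = 5.0
    pad_s: float = 0.5
    mmd_scales: tuple[int, ...] = (21, 31, 41)
    threshold_frac: float = 0.4
    window_s: float = 30.0
    block_min: float | None = 5.0
    target_len: int = 250
    model: ModelSpec = field(default_factory=ModelSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    model_seed: int = 0


_UNSET = object()


def prepare_record(record: SignalRecord, cfg: PipelineConfig,
                   block_min: float | None | object = _UNSET) -> list[Window]:
    """Preprocess one record and segment it into windows of labelled beats.

    Order of operations: artifact excision on raw amplitudes, zero-phase
    band-pass, MMD R-peak detection, posture-block extraction, windowing,
    beat segmentation.
    """
    _, clean_mask = excise_artifacts(record, threshold_mv=cfg.threshold_mv, pad_s=cfg.pad_s)
    filtered = bandpass(record, cfg.low_hz, cfg.high_hz)
    filtered.mask = clean_mask.valid.copy()
    peaks = detect_r_peaks(
        filtered, clean_mask, scales=cfg.mmd_scales, threshold_frac=cfg.threshold_frac
    )
    bm = cfg.block_min if block_min is _UNSET else block_min
    return segment_record(
        filtered, peaks, window_s=cfg.window_s, block_min=bm, target_len=cfg.target_len
    )


def _beats_of(windows: list[Window]) -> list[BeatSegment]:
    return [b for w in windows for b in w.beats]


def _score(
    model: PostureClassifier,
    windows: list[Window],
    scope: str,
) -> tuple[MetricsReport, MetricsReport, ConfusionMatrix, ConfusionMatrix, PredictionSet]:
    """Beat- and window-level reports for one evaluation set."""
    beats = _beats_of(windows)
    preds = predict(model, beats)
    beat_cm = confusion([preds.for_beat(b)[1] for b in beats], [b.label for b in beats])
    scored = [w for w in windows if w.beats]
    skipped = len(windows) - len(scored)
    if skipped:
        log.info("%d empty windows excluded from window-level scoring (%s)", skipped, scope)
    win_cm = confusion([vote_window(preds, w) for w in scored], [w.label for w in scored])
    return (
        metrics(beat_cm, unit="beat", scope=scope),
        metrics(win_cm, unit="window", scope=scope),
        beat_cm,
        win_cm,
        preds,
    )


@dataclass
class LosocvResult:
    beat_reports: list[MetricsReport]
    window_reports: list[MetricsReport]
    pooled_beat: MetricsReport
    pooled_window: MetricsReport
    pooled_beat_cm: ConfusionMatrix
    pooled_window_cm: ConfusionMatrix
    fold_subjects: list[str]


def losocv(records: list[SignalRecord], cfg: PipelineConfig) -> LosocvResult:
    """Leave-one-subject-out cross-validation over a cohort of records.

    Each subject is the test set exactly once; the model is re-initialized
    and re-trained from scratch for every fold with the same seeds, so folds
    are independent and the whole run is deterministic.
    """
    subjects = [r.subject_id for r in records]
    if len(set(subjects)) != len(subjects):
        raise ProtocolError("duplicate subject ids in cohort")
    if len(records) < 2:
        raise ProtocolError("LOSOCV needs at least 2 subjects")

    windows_by_subject = {r.subject_id: prepare_record(r, cfg) for r in records}

    beat_reports, window_reports = [], []
    pooled_beat_cm = ConfusionMatrix(np.zeros((3, 3), dtype=np.int64))
    pooled_window_cm = ConfusionMatrix(np.zeros((3, 3), dtype=np.int64))
    for held_out in subjects:
        train_beats = [
            b
            for sid, wins in windows_by_subject.items()
            if sid != held_out
            for b in _beats_of(wins)
        ]
        assert all(b.subject_id != held_out for b in train_beats)
        model = build_model(cfg.model, seed=cfg.model_seed)
        train(model, train_beats, cfg.train)
        rb, rw, cb, cw, _ = _score(model, windows_by_subject[held_out], scope=held_out)
        beat_reports.append(rb)
        window_reports.append(rw)
        pooled_beat_cm = pooled_beat_cm + cb
        pooled_window_cm = pooled_window_cm + cw
        log.info(
            "fold %s: beat ACC %.1f%%, window ACC %.1f%%", held_out, rb.acc, rw.acc
        )
    return LosocvResult(
        beat_reports=beat_reports,
        window_reports=window_reports,
        pooled_beat=metrics(pooled_beat_cm, unit="beat", scope="pooled"),
        pooled_window=metrics(pooled_window_cm, unit="window", scope="pooled"),
        pooled_beat_cm=pooled_beat_cm,
        pooled_window_cm=pooled_window_cm,
        fold_subjects=subjects,
    )


def overnight_eval(
    train_records: list[SignalRecord],
    overnight_record: SignalRecord,
    cfg: PipelineConfig,
) -> tuple[MetricsReport, MetricsReport]:
    """Train on the short-term cohort, evaluate on an overnight recording.

    The overnight record is artifact-excised and windowed over entire
    posture intervals (no 5-min block extraction); excised stretches
    contribute no scored beats.  Returns (beat-level, window-level) reports.
    """
    train_beats = [
        b for r in train_records for b in _beats_of(prepare_record(r, cfg))
    ]
    model = build_model(cfg.model, seed=cfg.model_seed)
    train(model, train_beats, cfg.train)
    windows = prepare_record(overnight_record, cfg, block_min=None)
    rb, rw, _, _, _ = _score(model, windows, scope=overnight_record.subject_id)
    return rb, rw
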