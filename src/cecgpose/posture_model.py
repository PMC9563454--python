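"""Sleep-posture classifier: a 3-layer bidirectional LSTM over beat segments.

Architecture (defaults): three stacked biLSTM layers of 200/100/50 hidden
units per direction over the 250-sample, two-feature beat sequence, a dense
softmax head over {supine, left, right} reading the concatenated final
forward and final backward states of the top layer; tanh state activations,
sigmoid gate activations, cross-entropy loss, Adam, 150 epochs.

A scaled-down configuration (64/32/16 units, 30 epochs) is provided for
desk-scale experiments and continuous testing; it trades accuracy headroom
for an order of magnitude less compute while preserving every structural
property of the full model.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDataError, ShapeError
from .nn import Adam, BiLSTMNet
from .records import POSTURE_ORDER, PostureLabel
from .segmentation import BeatSegment, Window

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "PredictionSet",
    "SCALED_SPEC",
    "SCALED_TRAIN",
    "build_model",
    "train",
    "predict",
    "vote_window",
    "PostureClassifier",
]


@dataclass(frozen=True)
class ModelSpec:
    """biLSTM architecture; sizes are hidden units per direction."""

    layer_sizes: tuple[int, ...] = (200, 100, 50)
    seq_len: int = 250
    n_features: int = 2
    n_classes: int = 3


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; every source of randomness flows from seed."""

    epochs: int = 150
    learning_rate: float = 1e-3
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


#: Desk-scale defaults: same depth and structure, smaller layers and budget.
SCALED_SPEC = ModelSpec(layer_sizes=(64, 32, 16))
SCALED_TRAIN = TrainConfig(epochs=30)


@dataclass
class PredictionSet:
    """Per-beat class probabilities and argmax labels, keyed by provenance."""

    keys: list[tuple[str, str, int]]  # (subject_id, window_id, beat_idx)
    probs: np.ndarray  # (n, 3) rows sum to 1
    labels: list[PostureLabel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = [POSTURE_ORDER[int(j)] for j in np.argmax(self.probs, axis=1)]
        self._by_key = {k: i for i, k in enumerate(self.keys)}

    def for_beat(self, beat: BeatSegment) -> tuple[np.ndarray, PostureLabel]:
        i = self._by_key[(beat.subject_id, beat.window_id, beat.beat_idx)]
        return self.probs[i], self.labels[i]

    def __len__(self) -> int:
        return len(self.keys)


class PostureClassifier:
    """Model handle bundling the network with its spec."""

    def __init__(self, spec: ModelSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        self.net = BiLSTMNet(
            n_in=spec.n_features,
            layer_sizes=spec.layer_sizes,
            n_classes=spec.n_classes,
            seed=seed,
        )
        self.loss_trace: list[float] = []

    def _stack(self, segments: list[BeatSegment]) -> np.ndarray:
        if not segments:
            raise ShapeError("no segments given")
        T, F = self.spec.seq_len, self.spec.n_features
        mats = []
        for s in segments:
            if s.matrix.shape != (F, T):
                raise ShapeError(f"segment shape {s.matrix.shape}, expected {(F, T)}")
            mats.append(s.matrix.T)  # (T, F): time-major steps, channels as features
        return np.stack(mats).astype(np.float32)


def build_model(spec: ModelSpec, seed: int) -> PostureClassifier:
    """Deterministically initialized classifier for the given architecture."""
    return PostureClassifier(spec, seed)


def train(model: PostureClassifier, segments: list[BeatSegment], cfg: TrainConfig) -> list[float]:
    """Minimize mean cross-entropy with Adam; returns per-epoch training loss.

    Shuffling and initialization are governed entirely by ``cfg.seed`` and the
    model seed, so repeated runs produce identical parameters.
    """
    y = np.array([s.label.index for s in segments], dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("training data contains a single class")
    X = model._stack(segments)
    n = len(y)
    opt = Adam(model.net.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % (2**31), 4242]))
    trace: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        sizes = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            loss, grads = model.net.loss_and_grad(X[sel], y[sel])
            opt.step(model.net.parameters(), grads)
            losses.append(loss)
            sizes.append(len(sel))
        trace.append(float(np.average(losses, weights=sizes)))
    model.loss_trace = trace
    return trace


def predict(model: PostureClassifier, segments: list[BeatSegment], batch_size: int = 512) -> PredictionSet:
    """Per-beat probability triples and argmax labels.

    Inference is a pure feed-forward pass; results do not depend on how the
    segments are partitioned into batches.
    """
    X = model._stack(segments)
    probs = np.empty((len(segments), model.spec.n_classes), dtype=np.float64)
    for start in range(0, len(segments), batch_size):
        xb = X[start : start + batch_size]
        probs[start : start + len(xb)] = model.net.softmax(model.net.forward(xb))
    keys = [(s.subject_id, s.window_id, s.beat_idx) for s in segments]
    return PredictionSet(keys=keys, probs=probs)


def vote_window(preds: PredictionSet, window: Window) -> PostureLabel:
    """Majority vote over a window's per-beat predictions.

    Ties are broken by the larger summed probability, then by the fixed class
    order (supine, left, right).
    """
    if not window.beats:
        raise DegenerateDataError(f"window {window.window_id} has no predicted beats")
    counts = np.zeros(len(POSTURE_ORDER))
    prob_sums = np.zeros(len(POSTURE_ORDER))
    for beat in window.beats:
        p, lab = preds.for_beat(beat)
        counts[lab.index] += 1
        prob_sums += p
    best = np.flatnonzero(counts == counts.max())
    if len(best) > 1:
        sub = prob_sums[best]
        best = best[np.flatnonzero(sub == sub.max())]
    return POSTURE_ORDER[int(best[0])]
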