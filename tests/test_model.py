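import numpy as np
import pytest

import cecgpose as cp
from cecgpose.errors import DegenerateDataError, ShapeError
from cecgpose.nn import BiLSTMNet
from cecgpose.records import POSTURE_ORDER
from cecgpose.segmentation import BeatSegment, Window

TINY = cp.ModelSpec(layer_sizes=(8, 6, 4))


def synthetic_beats(n_per_class=20, seed=0, noise=0.0, subject="s"):
    """Well-separated class templates: three phase-shifted tones per channel."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, 250)
    beats = []
    for ci, label in enumerate(POSTURE_ORDER):
        base = np.stack(
            [np.sin(2 * np.pi * (3 + ci) * t), np.cos(2 * np.pi * (2 + 2 * ci) * t)]
        )
        for k in range(n_per_class):
            m = base + noise * rng.normal(size=base.shape)
            m = (m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, keepdims=True)
            beats.append(
                BeatSegment(
                    matrix=m.astype(np.float32),
                    label=label,
                    subject_id=subject,
                    window_id=f"w{k % 3}",
                    beat_span=(float(k), float(k) + 0.8,),
                    beat_idx=ci * n_per_class + k,
                )
            )
    return beats


class TestBuild:
    def test_same_seed_identical_parameters(self):
        a = cp.build_model(TINY, seed=3).net.parameters()
        b = cp.build_model(TINY, seed=3).net.parameters()
        assert a.keys() == b.keys()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_architecture_shape(self):
        model = cp.build_model(cp.ModelSpec(), seed=0)
        assert len(model.net.layers) == 3
        assert model.net.W_d.shape == (2 * 50, 3)  # concat fwd+bwd final states

    def test_forward_probabilities_sum_to_one(self):
        model = cp.build_model(TINY, seed=0)
        preds = cp.predict(model, synthetic_beats(n_per_class=2))
        np.testing.assert_allclose(preds.probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(preds.probs >= 0)


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        rng = np.random.default_rng(0)
        net = BiLSTMNet(2, (4, 3), 3, seed=7, dtype=np.float64)
        x = rng.normal(size=(3, 6, 2))
        y = np.array([0, 1, 2])
        _, grads = net.loss_and_grad(x, y)
        params = net.parameters()
        eps = 1e-6
        for name, p in params.items():
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = net.loss_and_grad(x, y)
                p[idx] = orig - eps
                lm, _ = net.loss_and_grad(x, y)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, rel=1e-3, abs=1e-9)


class TestTrain:
    def test_overfits_separable_data(self):
        beats = synthetic_beats(n_per_class=67, noise=0.05)[:200]
        model = cp.build_model(TINY, seed=1)
        trace = cp.train(model, beats, cp.TrainConfig(epochs=50, batch_size=64, seed=1))
        assert all(np.isfinite(trace))
        preds = cp.predict(model, beats)
        acc = np.mean([lab is b.label for b, lab in zip(beats, preds.labels)])
        assert acc >= 0.99

    def test_loss_trace_finite_and_reproducible(self):
        beats = synthetic_beats(n_per_class=10, noise=0.2)
        t1 = cp.train(cp.build_model(TINY, seed=2), beats, cp.TrainConfig(epochs=3, seed=5))
        t2 = cp.train(cp.build_model(TINY, seed=2), beats, cp.TrainConfig(epochs=3, seed=5))
        assert t1 == t2
        assert all(np.isfinite(t1))

    def test_single_class_rejected(self):
        beats = [b for b in synthetic_beats(5) if b.label is cp.PostureLabel.SUPINE]
        with pytest.raises(DegenerateDataError):
            cp.train(cp.build_model(TINY, seed=0), beats, cp.TrainConfig(epochs=1))


class TestPredict:
    def test_duplicated_segment_identical_predictions(self):
        beats = synthetic_beats(n_per_class=2)
        twin = BeatSegment(
            matrix=beats[0].matrix.copy(),
            label=beats[0].label,
            subject_id="s",
            window_id="w9",
            beat_span=(99.0, 99.8),
            beat_idx=999,
        )
        model = cp.build_model(TINY, seed=0)
        preds = cp.predict(model, beats + [twin])
        np.testing.assert_array_equal(preds.probs[0], preds.probs[-1])

    def test_batch_partitioning_invariance(self):
        beats = synthetic_beats(n_per_class=7)
        model = cp.build_model(TINY, seed=0)
        a = cp.predict(model, beats, batch_size=4)
        b = cp.predict(model, beats, batch_size=21)
        np.testing.assert_allclose(a.probs, b.probs, atol=1e-5)
        assert a.labels == b.labels

    def test_wrong_segment_length_rejected(self):
        bad = BeatSegment(
            matrix=np.zeros((2, 100), np.float32),
            label=cp.PostureLabel.SUPINE,
            subject_id="s",
            window_id="w",
            beat_span=(0, 1),
            beat_idx=0,
        )
        model = cp.build_model(TINY, seed=0)
        with pytest.raises(ShapeError):
            cp.predict(model, [bad])


class TestVoting:
    def _window_with(self, preds_labels, probs=None):
        beats = []
        keys = []
        p = []
        for j, lab in enumerate(preds_labels):
            b = BeatSegment(
                matrix=np.zeros((2, 250), np.float32),
                label=cp.PostureLabel.SUPINE,
                subject_id="s",
                window_id="w0",
                beat_span=(j * 1.0, j + 0.8),
                beat_idx=j,
            )
            beats.append(b)
            keys.append(("s", "w0", j))
            if probs is None:
                row = np.full(3, 0.05)
                row[lab.index] = 0.9
            else:
                row = np.asarray(probs[j])
            p.append(row)
        w = Window(window_id="w0", span=(0.0, 30.0), label=cp.PostureLabel.SUPINE,
                   subject_id="s", beats=beats)
        return cp.PredictionSet(keys=keys, probs=np.array(p)), w

    def test_plurality(self):
        S, L = cp.PostureLabel.SUPINE, cp.PostureLabel.LEFT
        preds, w = self._window_with([S, S, L])
        assert cp.vote_window(preds, w) is S

    def test_unanimous(self):
        R = cp.PostureLabel.RIGHT
        preds, w = self._window_with([R, R, R])
        assert cp.vote_window(preds, w) is R

    def test_tie_broken_by_summed_probability(self):
        S, L = cp.PostureLabel.SUPINE, cp.PostureLabel.LEFT
        probs = [
            [0.60, 0.35, 0.05],
            [0.55, 0.40, 0.05],
            [0.05, 0.90, 0.05],
            [0.10, 0.85, 0.05],
        ]
        preds, w = self._window_with([S, S, L, L], probs=probs)
        assert cp.vote_window(preds, w) is L  # 2-2 tie, L has larger mass

    def test_empty_window_rejected(self):
        preds, w = self._window_with([cp.PostureLabel.SUPINE])
        w.beats = []
        with pytest.raises(DegenerateDataError):
            cp.vote_window(preds, w)


class TestEndToEndDeterminism:
    def test_same_seeds_same_metrics(self):
        beats = synthetic_beats(n_per_class=8, noise=0.3)
        outs = []
        for _ in range(2):
            model = cp.build_model(TINY, seed=4)
            cp.train(model, beats, cp.TrainConfig(epochs=2, seed=4))
            outs.append(cp.predict(model, beats).probs)
        np.testing.assert_array_equal(outs[0], outs[1])
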