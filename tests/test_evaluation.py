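import numpy as np
import pytest

import cecgpose as cp
from cecgpose.errors import ProtocolError
from cecgpose.evaluation import ConfusionMatrix
from cecgpose.records import POSTURE_ORDER

S, L, R = POSTURE_ORDER


def brute_force_metrics(counts: np.ndarray):
    """Independent oracle: explicit loops over label pairs."""
    total = counts.sum()
    p_o = sum(counts[k, k] for k in range(3)) / total
    p_e = 0.0
    for k in range(3):
        row = sum(counts[k, j] for j in range(3))
        col = sum(counts[j, k] for j in range(3))
        p_e += (row / total) * (col / total)
    kappa = (p_o - p_e) / (1 - p_e) if p_e != 1 else 1.0
    sen = {}
    for k, name in enumerate("SLR"):
        tp = counts[k, k]
        fn = sum(counts[k, j] for j in range(3)) - tp
        sen[name] = 100.0 * tp / (tp + fn) if tp + fn else None
    return sen, 100.0 * p_o, kappa


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        cm = cp.confusion([S, L, R], [S, L, R])
        np.testing.assert_array_equal(cm.counts, np.eye(3, dtype=int))

    def test_systematic_error_single_cell(self):
        cm = cp.confusion([S] * 5, [L] * 5)
        expected = np.zeros((3, 3), int)
        expected[L.index, S.index] = 5
        np.testing.assert_array_equal(cm.counts, expected)

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        pred = [POSTURE_ORDER[i] for i in rng.integers(0, 3, 57)]
        truth = [POSTURE_ORDER[i] for i in rng.integers(0, 3, 57)]
        assert cp.confusion(pred, truth).total == 57

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cp.confusion([S], [S, L])


class TestMetrics:
    def test_perfect_prediction(self):
        rep = cp.metrics(ConfusionMatrix(np.diag([10, 20, 30])))
        assert rep.acc == pytest.approx(100.0)
        assert rep.kappa == pytest.approx(1.0)
        assert all(v == pytest.approx(100.0) for v in rep.sen.values())

    def test_margin_product_matrix_gives_zero_kappa(self):
        # rows proportional to column margins: observed = expected agreement
        col = np.array([0.5, 0.3, 0.2])
        counts = np.round(np.outer([100, 200, 100], col)).astype(int)
        rep = cp.metrics(ConfusionMatrix(counts))
        assert rep.kappa == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_against_brute_force(self):
        counts = np.array([[40, 5, 5], [4, 44, 2], [6, 3, 41]])
        rep = cp.metrics(ConfusionMatrix(counts))
        sen, acc, kappa = brute_force_metrics(counts)
        assert rep.acc == pytest.approx(acc)
        assert rep.kappa == pytest.approx(kappa, abs=1e-12)
        for name in "SLR":
            assert rep.sen[name] == pytest.approx(sen[name])

    def test_sklearn_kappa_agrees(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        pred = rng.integers(0, 3, 500)
        truth = rng.integers(0, 3, 500)
        cm = cp.confusion(
            [POSTURE_ORDER[i] for i in pred], [POSTURE_ORDER[i] for i in truth]
        )
        ours = cp.metrics(cm).kappa
        ref = sklearn_metrics.cohen_kappa_score(truth, pred)
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_absent_class_sensitivity_undefined(self):
        cm = cp.confusion([S, S, L], [S, S, L])  # no RIGHT in truth
        rep = cp.metrics(cm)
        assert rep.sen["R"] is None
        assert rep.sen["S"] == pytest.approx(100.0)


class TestAggregate:
    def test_unweighted_mean(self):
        reps = [
            cp.metrics(ConfusionMatrix(np.diag([5, 5, 5]))),
            cp.metrics(ConfusionMatrix(np.array([[5, 0, 0], [0, 5, 0], [5, 0, 0]]))),
        ]
        agg = cp.aggregate(reps)
        assert agg.acc == pytest.approx((100.0 + reps[1].acc) / 2)

    def test_undefined_sen_excluded(self):
        full = cp.metrics(cp.confusion([S, L, R], [S, L, R]))
        partial = cp.metrics(cp.confusion([S, L], [S, L]))  # no R
        agg = cp.aggregate([full, partial])
        assert agg.sen["R"] == pytest.approx(100.0)  # only the defined report counts

    def test_weights(self):
        a = cp.metrics(ConfusionMatrix(np.diag([10, 10, 10])))
        b = cp.metrics(ConfusionMatrix(np.array([[0, 10, 0], [10, 0, 0], [0, 0, 10]])))
        agg = cp.aggregate([a, b], weights=[3, 1])
        assert agg.acc == pytest.approx((3 * 100.0 + 1 * b.acc) / 4)


class TestLosocv:
    def test_requires_two_subjects(self, small_cohort):
        cfg = cp.PipelineConfig(block_min=1.0, model=cp.ModelSpec((4, 3, 2)),
                                train=cp.TrainConfig(epochs=1))
        with pytest.raises(ProtocolError):
            cp.losocv(small_cohort[:1], cfg)

    def test_duplicate_subjects_rejected(self, small_cohort):
        cfg = cp.PipelineConfig(block_min=1.0)
        with pytest.raises(ProtocolError):
            cp.losocv([small_cohort[0], small_cohort[0]], cfg)

    def test_identical_noiseless_subjects_recovered(self):
        """Three clones of one noiseless subject: every fold's test
        distribution equals its training distribution, so beat accuracy must
        be near-perfect even with a small model and few epochs."""
        subj = cp.make_subject(12).without_noise()
        geometry = cp.DEFAULT_GEOMETRY
        records = []
        for k in range(3):
            sched = cp.PostureSchedule(
                [(i * 40.0, (i + 1) * 40.0, p) for i, p in enumerate(POSTURE_ORDER)]
            )
            from dataclasses import replace

            clone = replace(subj, subject_id=f"clone{k}")
            records.append(cp.synthesize(clone, geometry, sched, fs=500, seed=31 + k))
        cfg = cp.PipelineConfig(
            block_min=0.5,
            window_s=10.0,
            model=cp.ModelSpec((8, 6, 4)),
            train=cp.TrainConfig(epochs=25, batch_size=64, seed=0),
            model_seed=0,
        )
        res = cp.losocv(records, cfg)
        assert res.fold_subjects == [r.subject_id for r in records]
        for rep in res.beat_reports:
            assert rep.acc >= 99.0

    def test_pooled_counts_conserve_fold_counts(self):
        subj = cp.make_subject(12).without_noise()
        from dataclasses import replace

        records = []
        for k in range(2):
            sched = cp.PostureSchedule(
                [(i * 30.0, (i + 1) * 30.0, p) for i, p in enumerate(POSTURE_ORDER)]
            )
            records.append(
                cp.synthesize(replace(subj, subject_id=f"c{k}"), cp.DEFAULT_GEOMETRY,
                              sched, fs=500, seed=k)
            )
        cfg = cp.PipelineConfig(
            block_min=0.5, window_s=10.0, model=cp.ModelSpec((4, 3, 2)),
            train=cp.TrainConfig(epochs=2, batch_size=64, seed=0),
        )
        res = cp.losocv(records, cfg)
        assert res.pooled_beat.n == sum(r.n for r in res.beat_reports)
        assert res.pooled_window.n == sum(r.n for r in res.window_reports)
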