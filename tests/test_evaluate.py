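"""Metric identities, paired t-test, cross-validation and embeddings."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import accuracy_score, f1_score

from wavemaml.data import ImageSet
from wavemaml.evaluate import (
    ConfusionCounts,
    FoldResults,
    accuracy,
    confusion,
    embed_features,
    f1,
    kfold_cv,
    paired_ttest,
    student_t_sf_df4,
)


class TestConfusion:
    def test_perfect_prediction(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.FP == 0 and c.FN == 0 and c.TP == 2 and c.TN == 1

    def test_hand_enumeration(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.TP, c.FN, c.TN, c.FP) == (1, 1, 1, 1)

    def test_positive_class_swap_symmetry(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        c1 = confusion(y, p, positive_class=1)
        c0 = confusion(y, p, positive_class=0)
        assert (c1.TP, c1.TN, c1.FP, c1.FN) == (c0.TN, c0.TP, c0.FN, c0.FP)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])


class TestMetricFormulas:
    def test_accuracy_hand_values(self):
        assert accuracy(ConfusionCounts(5, 5, 0, 0)) == 1.0
        assert accuracy(ConfusionCounts(3, 2, 1, 2)) == 0.625

    def test_f1_hand_values(self):
        assert f1(ConfusionCounts(TP=3, TN=0, FP=1, FN=2)) == pytest.approx(6 / 9)
        assert f1(ConfusionCounts(TP=4, TN=1, FP=0, FN=0)) == 1.0

    def test_f1_degenerate_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="F1 undefined"):
            assert f1(ConfusionCounts(TP=0, TN=5, FP=0, FN=0)) == 0.0

    def test_brute_force_and_sklearn_agreement(self, rng):
        # formula path vs direct counting vs the sklearn reference, 300 draws
        for _ in range(300):
            n = rng.integers(4, 40)
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            c = confusion(y, p)
            assert accuracy(c) == pytest.approx(np.mean(y == p))
            assert accuracy(c) == pytest.approx(accuracy_score(y, p))
            if 2 * c.TP + c.FP + c.FN > 0:
                assert f1(c) == pytest.approx(f1_score(y, p, zero_division=0))

    def test_metric_identities_hold_for_arbitrary_label_vectors(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @given(
            st.lists(
                st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=60
            )
        )
        @settings(max_examples=200, deadline=None, derandomize=True)
        def check(pairs):
            y = np.array([a for a, _ in pairs])
            p = np.array([b for _, b in pairs])
            c = confusion(y, p)
            assert c.total == len(pairs)
            assert accuracy(c) == pytest.approx(np.mean(y == p))
            if 2 * c.TP + c.FP + c.FN > 0:
                assert 0.0 <= f1(c) <= 1.0

        check()

    def test_f1_is_harmonic_mean_of_precision_recall(self, rng):
        for _ in range(200):
            y = rng.integers(0, 2, 30)
            p = rng.integers(0, 2, 30)
            c = confusion(y, p)
            if c.TP == 0:
                continue
            prec = c.TP / (c.TP + c.FP)
            rec = c.TP / (c.TP + c.FN)
            assert f1(c) == pytest.approx(2 * prec * rec / (prec + rec))


class TestPairedTTest:
    def test_identical_folds_give_t0_p1(self):
        a = FoldResults((90.0, 91.0, 92.0, 93.0, 94.0))
        r = paired_ttest(a, a)
        assert (r.t, r.df, r.p) == (0.0, 4, 1.0)

    def test_constant_nonzero_difference_is_undefined(self):
        a = FoldResults((90.0, 91.0, 92.0))
        b = FoldResults((89.0, 90.0, 91.0))
        with pytest.raises(ValueError, match="zero variance"):
            paired_ttest(a, b)

    def test_published_fold_table_hand_computation(self):
        # dual vs CNN-Transformer accuracy folds: differences (8,8,5,6,2),
        # mean 5.8, sd 2.4899 -> t = 5.209, df = 4
        dual = FoldResults((93, 95, 91, 94, 92), "dual", "accuracy")
        cnntr = FoldResults((85, 87, 86, 88, 90), "cnn_transformer", "accuracy")
        r = paired_ttest(dual, cnntr)
        assert r.df == 4
        assert r.t == pytest.approx(5.209, abs=5e-3)
        assert 0 < r.p < 0.05

    def test_critical_value_quantile(self):
        # published two-sided 5% critical value for df=4 is t = 2.776
        assert 2 * student_t_sf_df4(2.776) == pytest.approx(0.05, abs=1e-3)
        assert 2 * stats.t.sf(2.776, 4) == pytest.approx(0.05, abs=1e-3)

    def test_antisymmetry(self, rng):
        a = FoldResults(tuple(rng.normal(90, 3, 5)))
        b = FoldResults(tuple(rng.normal(88, 3, 5)))
        r1, r2 = paired_ttest(a, b), paired_ttest(b, a)
        assert r2.t == pytest.approx(-r1.t)
        assert r2.p == pytest.approx(r1.p)

    def test_df4_closed_form_matches_t_distribution(self):
        for t in np.linspace(-6, 9.6, 61):
            assert student_t_sf_df4(t) == pytest.approx(stats.t.sf(t, 4), abs=1e-12)


def _toy_imageset(n_per_class=20, n_subjects=10, seed=0):
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    images = rng.random((n, 8, 8)).astype(np.float32)
    labels = np.array([0, 1] * n_per_class)
    subjects = [f"s{(i // 4) % n_subjects}" for i in range(n)]
    return ImageSet(images, labels, pd.DataFrame({"subject": subjects}))


class TestKFoldCV:
    def _run(self, ds, k=5, group=False, seed=0):
        folds_seen = []

        def train_fn(train_set):
            return {"n": len(train_set)}

        def eval_fn(model, test_set):
            folds_seen.append(test_set)
            return {"accuracy": 1.0, "f1": 1.0}

        res = kfold_cv(ds, k, train_fn, eval_fn, seed=seed, group_by_subject=group)
        return res, folds_seen

    def test_five_disjoint_folds_cover_dataset(self):
        ds = _toy_imageset()
        res, folds = self._run(ds, k=5)
        assert res["accuracy"].k == 5
        total = sum(len(f) for f in folds)
        assert total == len(ds)
        seen = set()
        for f in folds:
            keys = {x.tobytes() for x in f.images}
            assert not keys & seen
            seen |= keys

    def test_stratification_balance(self):
        ds = _toy_imageset()
        _, folds = self._run(ds, k=5)
        for f in folds:
            n0, n1 = np.sum(f.labels == 0), np.sum(f.labels == 1)
            assert abs(int(n0) - int(n1)) <= 1

    def test_seeded_assignment_is_reproducible(self):
        ds = _toy_imageset()
        _, f1_ = self._run(ds, seed=3)
        _, f2_ = self._run(ds, seed=3)
        for a, b in zip(f1_, f2_):
            assert np.array_equal(a.images, b.images)

    def test_subject_grouping_never_splits_a_subject(self):
        ds = _toy_imageset()
        _, folds = self._run(ds, k=3, group=True)
        assigned = {}
        for i, f in enumerate(folds):
            for s in f.meta["subject"]:
                assigned.setdefault(s, set()).add(i)
        assert all(len(v) == 1 for v in assigned.values())

    def test_metric_values_are_percentages(self):
        ds = _toy_imageset()
        res, _ = self._run(ds, k=2)
        assert all(v == 100.0 for v in res["accuracy"].values)


class TestEmbedFeatures:
    @pytest.fixture(scope="class")
    def tiny_state(self, micro_arch):
        from wavemaml.maml import DualWeights, MetaState
        from wavemaml.models import init_cnn_transformer, init_resnet
        import wavemaml.autodiff as ad

        return MetaState(
            init_resnet(micro_arch, seed=0),
            init_cnn_transformer(micro_arch, seed=1),
            DualWeights(ad.Tensor(np.array([0.2, -0.2], dtype=np.float32), requires_grad=True)),
        )

    def test_row_count_and_duplication(self, tiny_state, rng):
        x = rng.random((5, 8, 8)).astype(np.float32)
        emb = embed_features(tiny_state, x)
        assert emb.shape[0] == 5
        emb2 = embed_features(tiny_state, np.concatenate([x, x]))
        assert np.allclose(emb2[:5], emb2[5:], atol=1e-6)

    def test_training_improves_class_mean_separation(self, desk_arch32):
        from wavemaml.maml import DualWeights, MetaConfig, MetaState, dual_meta_train
        from wavemaml.models import init_cnn_transformer, init_resnet
        from wavemaml.synth import generate_scalogram_dataset
        import wavemaml.autodiff as ad

        ds = generate_scalogram_dataset(20, image_size=32, separation=4.0, seed=8)
        cfg = MetaConfig(
            n_tasks=1, inner_lr=0.02, outer_lr=0.05, adaptation_steps=1,
            grad_order="first", seed=5, n_iterations=20, k_shot=5,
        )
        trained = dual_meta_train(ds, cfg, desk_arch32)
        untrained = MetaState(
            init_resnet(desk_arch32, seed=100),
            init_cnn_transformer(desk_arch32, seed=101),
            DualWeights.balanced(),
        )

        def cosine_gap(state):
            emb = embed_features(state, ds.images)
            m0 = emb[ds.labels == 0].mean(axis=0)
            m1 = emb[ds.labels == 1].mean(axis=0)
            return 1.0 - np.dot(m0, m1) / (np.linalg.norm(m0) * np.linalg.norm(m1) + 1e-12)

        assert cosine_gap(trained) > cosine_gap(untrained)
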