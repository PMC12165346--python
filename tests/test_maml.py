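"""Episodic training mechanics: task sampling, adaptation, meta-gradients."""

import numpy as np
import pytest

import wavemaml.autodiff as ad
from wavemaml.data import ImageSet
from wavemaml.maml import (
    DualWeights,
    EpisodeTask,
    MetaConfig,
    MetaState,
    adapt,
    dual_forward,
    dual_meta_train,
    inner_adapt,
    meta_step,
    meta_test,
    sample_tasks,
)
from wavemaml.models import init_cnn_transformer, init_resnet
from wavemaml.synth import generate_scalogram_dataset


@pytest.fixture(scope="module")
def dataset16():
    return generate_scalogram_dataset(30, image_size=16, separation=4.0, seed=2)


def micro_task(rng, n=4, size=8):
    x = rng.random((2 * n, size, size)).astype(np.float32)
    y = np.array([0, 1] * n)
    return EpisodeTask(x[:n], y[:n], x[n:], y[n:], task_id=0)


class TestSampleTasks:
    def test_episode_composition(self, dataset16):
        cfg = MetaConfig(k_shot=10, query_per_class=5, n_tasks=20, seed=0)
        tasks = sample_tasks(dataset16, cfg)
        assert len(tasks) == 20
        for t in tasks:
            assert len(t.support_x) == 20 and len(t.query_x) == 10
            assert np.sum(t.support_y == 0) == np.sum(t.support_y == 1) == 10
            assert np.sum(t.query_y == 0) == np.sum(t.query_y == 1) == 5

    def test_support_query_disjoint(self, dataset16):
        cfg = MetaConfig(k_shot=5, query_per_class=5, n_tasks=5, seed=1)
        for t in sample_tasks(dataset16, cfg):
            s = {x.tobytes() for x in t.support_x}
            q = {x.tobytes() for x in t.query_x}
            assert not s & q

    def test_seed_determinism(self, dataset16):
        cfg = MetaConfig(n_tasks=4, seed=9)
        a = sample_tasks(dataset16, cfg, rng=3)
        b = sample_tasks(dataset16, cfg, rng=3)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.support_x, tb.support_x)
            assert np.array_equal(ta.query_x, tb.query_x)

    def test_insufficient_examples_error(self, dataset16):
        cfg = MetaConfig(k_shot=25, query_per_class=10, n_tasks=1)
        with pytest.raises(ValueError, match="required"):
            sample_tasks(dataset16, cfg)


class TestInnerAdapt:
    def test_quadratic_hand_case(self):
        # L(theta) = theta^2, theta=1, alpha=0.1, one step -> 0.8
        params = {"theta": ad.Tensor(np.array(1.0), requires_grad=True)}
        adapted = adapt(lambda p: p["theta"] ** 2, params, lr=0.1, steps=1)
        assert adapted["theta"].data == pytest.approx(0.8, abs=1e-12)

    def test_zero_steps_identity(self):
        params = {"theta": ad.Tensor(np.array(1.0), requires_grad=True)}
        adapted = adapt(lambda p: p["theta"] ** 2, params, lr=0.1, steps=0)
        assert adapted["theta"] is params["theta"]

    def test_originals_untouched_and_descent(self, micro_arch, rng):
        m = init_resnet(micro_arch, seed=0)
        task = micro_task(rng)
        before = {k: v.data.copy() for k, v in m.params.items()}

        def support_loss(p):
            return float(
                ad.cross_entropy(
                    __import__("wavemaml.models", fromlist=["forward"]).forward(
                        m, task.support_x, params=p
                    ),
                    task.support_y,
                ).data
            )

        adapted = inner_adapt(m, task.support_x, task.support_y, lr=0.05, steps=3)
        assert all(np.array_equal(before[k], m.params[k].data) for k in before)
        assert support_loss(adapted) <= support_loss(m.params) + 1e-6


class TestMetaStep:
    def test_zero_outer_lr_is_identity(self, micro_arch, rng):
        m = init_resnet(micro_arch, seed=1)
        cfg = MetaConfig(outer_lr=0.0, inner_lr=0.01, adaptation_steps=1, grad_order="first")
        new, loss = meta_step(m, [micro_task(rng)], cfg)
        assert np.isfinite(loss)
        assert all(np.array_equal(new.params[k].data, m.params[k].data) for k in m.params)

    def test_steps_zero_equals_plain_gradient_descent(self, micro_arch, rng):
        from wavemaml.models import forward

        m = init_resnet(micro_arch, seed=2)
        task = micro_task(rng)
        cfg = MetaConfig(outer_lr=0.1, adaptation_steps=0, grad_order="second")
        new, _ = meta_step(m, [task], cfg)
        # oracle: one direct gradient step on the query loss
        loss = ad.cross_entropy(forward(m, task.query_x), task.query_y)
        grads = ad.grad(loss, list(m.params.values()))
        for (k, p), g in zip(m.params.items(), grads):
            assert np.allclose(new.params[k].data, p.data - 0.1 * g.data, atol=1e-12)

    def test_first_and_second_order_coincide_at_zero_steps(self, micro_arch, rng):
        m = init_resnet(micro_arch, seed=3)
        task = micro_task(rng)
        outs = {}
        for order in ("first", "second"):
            cfg = MetaConfig(outer_lr=0.05, adaptation_steps=0, grad_order=order)
            outs[order], _ = meta_step(m, [task], cfg)
        for k in m.params:
            assert np.allclose(
                outs["first"].params[k].data, outs["second"].params[k].data, atol=1e-10
            )

    def test_empty_task_batch_rejected(self, micro_arch):
        m = init_resnet(micro_arch, seed=0)
        with pytest.raises(ValueError, match="empty"):
            meta_step(m, [], MetaConfig())


class TestMetaGradientOracle:
    def test_linear_softmax_second_order_matches_hand_chain_rule(self, rng):
        # Single task, one inner step, linear-softmax model: the full
        # meta-gradient is (I - alpha * H_support) @ grad_query(theta'),
        # with H the analytic Hessian of softmax cross-entropy.
        d, n = 3, 12
        alpha = 0.25
        Xs = rng.standard_normal((n, d))
        ys = rng.integers(0, 2, n)
        Xq = rng.standard_normal((n, d))
        yq = rng.integers(0, 2, n)
        W0 = rng.standard_normal((d, 2)) * 0.5

        def np_softmax(z):
            e = np.exp(z - z.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)

        def np_grad(W, X, y):
            P = np_softmax(X @ W)
            Y = np.eye(2)[y]
            return X.T @ (P - Y) / len(y)

        def np_hessian(W, X, y):
            # H[(i,c),(j,e)] = sum_n X_ni X_nj (P_nc delta_ce - P_nc P_ne)/n
            P = np_softmax(X @ W)
            H = np.zeros((d * 2, d * 2))
            for k in range(len(y)):
                x = X[k]
                p = P[k]
                S = np.diag(p) - np.outer(p, p)
                H += np.kron(np.outer(x, x), S) / len(y)
            return H

        # hand-written two-level chain rule (row-major flatten: (i, c))
        W1 = W0 - alpha * np_grad(W0, Xs, ys)
        gq = np_grad(W1, Xq, yq).reshape(-1)
        hand = gq - alpha * (np_hessian(W0, Xs, ys) @ gq)

        # engine path
        Wt = ad.Tensor(W0.copy(), requires_grad=True)
        inner_loss = ad.cross_entropy(ad.matmul(ad.Tensor(Xs), Wt), ys)
        (gi,) = ad.grad(inner_loss, [Wt], create_graph=True)
        Wadapted = ad.sub(Wt, ad.mul(gi, alpha))
        outer_loss = ad.cross_entropy(ad.matmul(ad.Tensor(Xq), Wadapted), yq)
        (mg,) = ad.grad(outer_loss, [Wt])
        assert np.abs(mg.data.reshape(-1) - hand).max() < 1e-6


class TestDualForward:
    def _state(self, micro_arch, logits):
        return MetaState(
            init_resnet(micro_arch, seed=0),
            init_cnn_transformer(micro_arch, seed=1),
            DualWeights(ad.Tensor(np.asarray(logits, dtype=np.float32), requires_grad=True)),
        )

    def test_endpoint_weight_reduces_to_model_a(self, micro_arch, rng):
        from wavemaml.models import forward

        state = self._state(micro_arch, [100.0, 0.0])  # softmax underflows to (1, 0)
        x = rng.random((4, 8, 8)).astype(np.float32)
        assert np.array_equal(
            dual_forward(state, x).data, forward(state.params_a, x).data
        )

    def test_equal_logits_invariant_under_weights(self, micro_arch):
        state = self._state(micro_arch, [0.3, -0.7])
        w = state.weights.weight_tensors().data
        z = np.array([[2.0, 0.0]])
        combined = w[0] * z + w[1] * z
        assert np.allclose(combined, z)

    def test_hand_mix(self):
        w = DualWeights(ad.Tensor(np.zeros(2), requires_grad=True))
        assert np.allclose(w.weights, [0.5, 0.5])
        la, lb = np.array([2.0, 0.0]), np.array([0.0, 2.0])
        assert np.allclose(w.weights[0] * la + w.weights[1] * lb, [1.0, 1.0])

    def test_weights_always_normalized(self, rng):
        for _ in range(20):
            w = DualWeights(ad.Tensor(rng.standard_normal(2) * 10, requires_grad=True))
            assert w.weights.sum() == pytest.approx(1.0)
            assert np.all(w.weights >= 0) and np.all(w.weights <= 1)


class TestDualMetaTrain:
    @pytest.fixture(scope="class")
    def trained(self, desk_arch32):
        ds = generate_scalogram_dataset(30, image_size=32, separation=4.0, seed=6)
        cfg = MetaConfig(
            n_tasks=1, inner_lr=0.02, outer_lr=0.05, adaptation_steps=2,
            grad_order="first", seed=7, n_iterations=25,
        )
        return ds, cfg, dual_meta_train(ds, cfg, desk_arch32)

    def test_history_is_complete_and_monotone_in_iteration(self, trained):
        _, cfg, state = trained
        assert [r["iteration"] for r in state.history] == list(range(cfg.n_iterations))
        assert all(np.isfinite(r["meta_loss"]) for r in state.history)

    def test_weights_stay_normalized_through_training(self, trained):
        _, _, state = trained
        for r in state.history:
            assert r["w1"] + r["w2"] == pytest.approx(1.0, abs=1e-6)

    def test_loss_decreases_on_separable_data(self, trained):
        _, _, state = trained
        first5 = np.mean([r["meta_loss"] for r in state.history[:5]])
        last5 = np.mean([r["meta_loss"] for r in state.history[-5:]])
        assert last5 < first5

    def test_meta_test_purity_and_aggregate(self, trained, desk_arch32):
        ds, cfg, state = trained
        tasks = sample_tasks(ds, MetaConfig(n_tasks=4, seed=3), rng=4)
        r1 = meta_test(state, tasks, cfg)
        r2 = meta_test(state, tasks, cfg)
        assert r1 == r2
        assert r1["accuracy"] == pytest.approx(
            np.mean([t["accuracy"] for t in r1["per_task"]])
        )

    def test_divergence_guard_raises_with_iteration(self, desk_arch32):
        ds = generate_scalogram_dataset(16, image_size=32, separation=1.0, seed=1)
        cfg = MetaConfig(
            n_tasks=1, inner_lr=50.0, outer_lr=50.0, adaptation_steps=3,
            grad_order="first", seed=0, n_iterations=30,
        )
        with pytest.raises((RuntimeError, FloatingPointError)):
            dual_meta_train(ds, cfg, desk_arch32)
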