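"""Episodic meta-training: MAML and the adaptively weighted dual variant.

The optimization-based meta-learner maintains initial parameters theta that
are adapted per task by a few steps of gradient descent on the support loss
(inner loop, learning rate alpha) and updated across tasks by descending the
post-adaptation query loss (outer loop, learning rate beta):

    inner:  theta_i' = theta - alpha * d/dtheta L(f_theta; support_i)
    outer:  theta   <- theta - beta * d/dtheta sum_i L(f_{theta_i'}; query_i)

``grad_order='second'`` differentiates the outer objective through the inner
updates (the full meta-gradient); ``'first'`` detaches the inner gradients,
which makes the outer gradient exactly the query gradient at the adapted
parameters (the standard first-order approximation).

The dual variant meta-trains two base networks jointly — a residual CNN and
a CNN-Transformer hybrid — plus two mixing logits. Each network inner-adapts
on its own support loss; the outer objective scores the convex combination
``w1 * logits_a + w2 * logits_b`` with ``(w1, w2) = softmax(mixing logits)``,
so the mixing weights are learned end to end, stay normalized by
construction, and shift toward whichever base model carries information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data import ImageSet
from .models import ArchitectureConfig, MetaParams, forward, init_cnn_transformer, init_resnet

__all__ = [
    "MetaConfig",
    "EpisodeTask",
    "DualWeights",
    "MetaState",
    "sample_tasks",
    "adapt",
    "inner_adapt",
    "meta_step",
    "dual_forward",
    "meta_train",
    "dual_meta_train",
    "meta_test",
    "predict_labels",
]


@dataclass(frozen=True)
class MetaConfig:
    """Episodic training hyperparameters.

    Defaults follow the reference protocol for this task: 10 shots, 20 tasks per
    meta-iteration batch, inner and outer learning rates 0.001, and 3
    inner-loop adaptation steps. ``n_iterations`` and ``query_per_class``
    are free desk-scale choices.
    """

    n_way: int = 2
    k_shot: int = 10
    query_per_class: int = 5
    n_tasks: int = 20
    inner_lr: float = 0.001
    outer_lr: float = 0.001
    adaptation_steps: int = 3
    grad_order: str = "second"
    seed: int = 0
    n_iterations: int = 100
    #: learning rate for the two mixing logits (they live on a different
    #: scale than the network weights); None reuses outer_lr
    weight_lr: float | None = 1.0

    def __post_init__(self) -> None:
        if min(self.n_way, self.k_shot, self.query_per_class, self.n_tasks) < 1:
            raise ValueError("all episode counts must be >= 1")
        if self.inner_lr < 0 or self.outer_lr < 0:
            raise ValueError("learning rates must be non-negative")
        if self.adaptation_steps < 0:
            raise ValueError("adaptation_steps must be >= 0")
        if self.grad_order not in ("first", "second"):
            raise ValueError("grad_order must be 'first' or 'second'")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "MetaConfig":
        import yaml
        from pathlib import Path

        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class EpisodeTask:
    """One N-way K-shot episode: disjoint support and query sets."""

    support_x: np.ndarray  # (N*K, H, W)
    support_y: np.ndarray  # (N*K,), values 0..N-1
    query_x: np.ndarray
    query_y: np.ndarray
    task_id: int = 0


@dataclass
class DualWeights:
    """Two mixing logits; the weights are their softmax, so they always lie
    in [0, 1] and sum to 1."""

    logits: Tensor

    @classmethod
    def balanced(cls, dtype=np.float32) -> "DualWeights":
        return cls(Tensor(np.zeros(2, dtype=dtype), requires_grad=True))

    @property
    def weights(self) -> np.ndarray:
        z = self.logits.data - self.logits.data.max()
        e = np.exp(z)
        return e / e.sum()

    def weight_tensors(self) -> Tensor:
        return ad.softmax(self.logits, axis=0)


@dataclass
class MetaState:
    """Meta-parameters of the dual learner plus its training history."""

    params_a: MetaParams  # residual CNN
    params_b: MetaParams  # CNN-Transformer hybrid
    weights: DualWeights
    history: list[dict] = field(default_factory=list)


# -- task sampling ---------------------------------------------------------

def sample_tasks(
    dataset: ImageSet,
    cfg: MetaConfig,
    rng: np.random.Generator | int | None = None,
) -> list[EpisodeTask]:
    """Draw ``cfg.n_tasks`` episodes, each N-way with K support and
    ``query_per_class`` query examples per class, sampled without
    replacement within a task; support and query are disjoint."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    classes = np.asarray(sorted(np.unique(dataset.labels)))
    if len(classes) < cfg.n_way:
        raise ValueError(f"dataset has {len(classes)} classes, need {cfg.n_way}")
    need = cfg.k_shot + cfg.query_per_class
    by_class = {c: np.flatnonzero(dataset.labels == c) for c in classes}
    for c, idx in by_class.items():
        if len(idx) < need:
            raise ValueError(
                f"class {c} has {len(idx)} examples; {need} required "
                f"(K={cfg.k_shot} support + {cfg.query_per_class} query)"
            )
    tasks = []
    for t in range(cfg.n_tasks):
        chosen = classes if len(classes) == cfg.n_way else np.sort(
            rng.choice(classes, size=cfg.n_way, replace=False)
        )
        sx, sy, qx, qy = [], [], [], []
        for slot, c in enumerate(chosen):
            pick = rng.choice(by_class[c], size=need, replace=False)
            sx.append(dataset.images[pick[: cfg.k_shot]])
            sy.append(np.full(cfg.k_shot, slot))
            qx.append(dataset.images[pick[cfg.k_shot :]])
            qy.append(np.full(cfg.query_per_class, slot))
        tasks.append(
            EpisodeTask(
                support_x=np.concatenate(sx),
                support_y=np.concatenate(sy),
                query_x=np.concatenate(qx),
                query_y=np.concatenate(qy),
                task_id=t,
            )
        )
    return tasks


# -- inner loop ------------------------------------------------------------

def adapt(
    loss_fn: Callable[[dict[str, Tensor]], Tensor],
    params: dict[str, Tensor],
    lr: float,
    steps: int,
    order: str = "second",
) -> dict[str, Tensor]:
    """Generic gradient-descent adaptation of a named parameter dict.

    With ``order='second'`` the update graph is retained so outer gradients
    flow through it; with ``'first'`` the inner gradients are detached (the
    adapted parameters are then the originals minus a constant, so an outer
    gradient equals the query gradient at the adapted point). ``steps=0``
    returns ``params`` unchanged. The input dict is never mutated.
    """
    if steps == 0:
        return params
    names = list(params)
    cur = dict(params)
    for _ in range(steps):
        loss = loss_fn(cur)
        if not np.isfinite(loss.data):
            raise FloatingPointError("non-finite inner-loop loss")
        grads = ad.grad(loss, [cur[n] for n in names], create_graph=(order == "second"))
        cur = {n: ad.sub(cur[n], ad.mul(g, lr)) for n, g in zip(names, grads)}
    return cur


def inner_adapt(
    meta: MetaParams,
    support_x: np.ndarray,
    support_y: np.ndarray,
    lr: float,
    steps: int,
    order: str = "second",
    params: dict[str, Tensor] | None = None,
) -> dict[str, Tensor]:
    """Task adaptation on the cross-entropy support loss."""

    def loss_fn(p: dict[str, Tensor]) -> Tensor:
        return ad.cross_entropy(forward(meta, support_x, params=p), support_y)

    return adapt(loss_fn, params if params is not None else meta.params, lr, steps, order)


# -- outer loop ------------------------------------------------------------

def predict_labels(logits: np.ndarray) -> np.ndarray:
    """Argmax with lowest-index preference on exact ties."""
    return np.argmax(logits, axis=1)


def _binary_f1(y_true: np.ndarray, y_pred: np.ndarray, positive: int = 1) -> float:
    tp = int(np.sum((y_pred == positive) & (y_true == positive)))
    fp = int(np.sum((y_pred == positive) & (y_true != positive)))
    fn = int(np.sum((y_pred != positive) & (y_true == positive)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def meta_step(
    meta: MetaParams, tasks: Sequence[EpisodeTask], cfg: MetaConfig
) -> tuple[MetaParams, float]:
    """One single-model outer update over a batch of tasks.

    Returns a new :class:`MetaParams` (the input is untouched) and the
    meta-loss. ``outer_lr=0`` reproduces the input parameters exactly.
    """
    if not tasks:
        raise ValueError("task batch is empty")
    names = list(meta.params)
    total = None
    for task in tasks:
        if len(task.query_x) == 0:
            raise ValueError(f"task {task.task_id} has an empty query set")
        adapted = inner_adapt(
            meta, task.support_x, task.support_y, cfg.inner_lr, cfg.adaptation_steps,
            order=cfg.grad_order,
        )
        loss = ad.cross_entropy(forward(meta, task.query_x, params=adapted), task.query_y)
        total = loss if total is None else ad.add(total, loss)
    meta_loss = ad.mul(total, 1.0 / len(tasks))
    if not np.isfinite(meta_loss.data):
        raise FloatingPointError("non-finite meta-loss")
    grads = ad.grad(meta_loss, [meta.params[n] for n in names])
    new_params = {
        n: Tensor(meta.params[n].data - cfg.outer_lr * g.data, requires_grad=True)
        for n, g in zip(names, grads)
    }
    return MetaParams(new_params, meta.architecture_id, meta.cfg), float(meta_loss.data)


def dual_forward(
    state: MetaState,
    images,
    adapted_a: dict[str, Tensor] | None = None,
    adapted_b: dict[str, Tensor] | None = None,
) -> Tensor:
    """Convex combination of the two base models' logits."""
    la = forward(state.params_a, images, params=adapted_a)
    lb = forward(state.params_b, images, params=adapted_b)
    if la.shape != lb.shape:
        raise ValueError(f"logit shape mismatch: {la.shape} vs {lb.shape}")
    w = state.weights.weight_tensors()
    return ad.add(ad.mul(la, w[0]), ad.mul(lb, w[1]))


def dual_meta_train(
    dataset: ImageSet,
    cfg: MetaConfig,
    arch_cfg: ArchitectureConfig | None = None,
    corrupt_model: str | None = None,
    callback: Callable[[dict], None] | None = None,
) -> MetaState:
    """Jointly meta-train both base models and their mixing weights.

    Per iteration: sample ``cfg.n_tasks`` episodes, inner-adapt both models
    on each support set, score the combined logits on each query set, and
    take one outer gradient step on both parameter sets and the mixing
    logits. The run is deterministic under ``cfg.seed``.

    ``corrupt_model='b'`` (or ``'a'``) decouples that model's inputs from
    the labels by permuting the images it sees within every episode — the
    model becomes uninformative, which the mixing weights should discover.
    """
    if corrupt_model not in (None, "a", "b"):
        raise ValueError("corrupt_model must be None, 'a' or 'b'")
    if arch_cfg is None:
        arch_cfg = ArchitectureConfig(input_size=dataset.images.shape[1:] + (1,))
    state = MetaState(
        params_a=init_resnet(arch_cfg, seed=cfg.seed),
        params_b=init_cnn_transformer(arch_cfg, seed=cfg.seed + 1),
        weights=DualWeights.balanced(),
    )
    rng = np.random.default_rng(cfg.seed + 2)
    names_a = list(state.params_a.params)
    names_b = list(state.params_b.params)
    for iteration in range(cfg.n_iterations):
        tasks = sample_tasks(dataset, cfg, rng)
        total = None
        n_correct = 0
        n_query = 0
        ys, preds = [], []
        for task in tasks:
            sx = {"a": task.support_x, "b": task.support_x}
            qx = {"a": task.query_x, "b": task.query_x}
            if corrupt_model is not None:
                # decouple the corrupted model's inputs from the labels
                sx[corrupt_model] = task.support_x[rng.permutation(len(task.support_x))]
                qx[corrupt_model] = task.query_x[rng.permutation(len(task.query_x))]
            adapted_a = inner_adapt(
                state.params_a, sx["a"], task.support_y, cfg.inner_lr,
                cfg.adaptation_steps, order=cfg.grad_order,
            )
            adapted_b = inner_adapt(
                state.params_b, sx["b"], task.support_y, cfg.inner_lr,
                cfg.adaptation_steps, order=cfg.grad_order,
            )
            la = forward(state.params_a, qx["a"], params=adapted_a)
            lb = forward(state.params_b, qx["b"], params=adapted_b)
            w = state.weights.weight_tensors()
            logits = ad.add(ad.mul(la, w[0]), ad.mul(lb, w[1]))
            loss = ad.cross_entropy(logits, task.query_y)
            total = loss if total is None else ad.add(total, loss)
            pred = predict_labels(logits.data)
            n_correct += int(np.sum(pred == task.query_y))
            n_query += len(task.query_y)
            ys.append(task.query_y)
            preds.append(pred)
        meta_loss = ad.mul(total, 1.0 / len(tasks))
        if not np.isfinite(meta_loss.data) or meta_loss.data > 1e6:
            raise RuntimeError(f"meta-training diverged at iteration {iteration}")
        leaves = (
            [state.params_a.params[n] for n in names_a]
            + [state.params_b.params[n] for n in names_b]
            + [state.weights.logits]
        )
        grads = ad.grad(meta_loss, leaves)
        cut = len(names_a)
        for n, g in zip(names_a, grads[:cut]):
            state.params_a.params[n] = Tensor(
                state.params_a.params[n].data - cfg.outer_lr * g.data, requires_grad=True
            )
        for n, g in zip(names_b, grads[cut : cut + len(names_b)]):
            state.params_b.params[n] = Tensor(
                state.params_b.params[n].data - cfg.outer_lr * g.data, requires_grad=True
            )
        w_lr = cfg.outer_lr if cfg.weight_lr is None else cfg.weight_lr
        state.weights = DualWeights(
            Tensor(state.weights.logits.data - w_lr * grads[-1].data, requires_grad=True)
        )
        w1, w2 = state.weights.weights
        record = {
            "iteration": iteration,
            "meta_loss": float(meta_loss.data),
            "accuracy": n_correct / n_query,
            "f1": _binary_f1(np.concatenate(ys), np.concatenate(preds)),
            "w1": float(w1),
            "w2": float(w2),
        }
        state.history.append(record)
        if callback is not None:
            callback(record)
    return state


def meta_train(
    dataset: ImageSet,
    cfg: MetaConfig,
    arch_cfg: ArchitectureConfig,
    architecture_id: str = "resnet8",
) -> tuple[MetaParams, list[dict]]:
    """Single-base-model MAML loop (ablation counterpart of the dual model)."""
    meta = (
        init_resnet(arch_cfg, seed=cfg.seed)
        if architecture_id == "resnet8"
        else init_cnn_transformer(arch_cfg, seed=cfg.seed)
    )
    rng = np.random.default_rng(cfg.seed + 2)
    history = []
    for iteration in range(cfg.n_iterations):
        tasks = sample_tasks(dataset, cfg, rng)
        meta, loss = meta_step(meta, tasks, cfg)
        history.append({"iteration": iteration, "meta_loss": loss})
    return meta, history


def meta_test(
    model: MetaState | MetaParams,
    tasks: Sequence[EpisodeTask],
    cfg: MetaConfig,
) -> dict:
    """Adapt on each held-out support set and score its query set.

    Pure: the stored parameters are never modified. Returns per-task
    accuracy/F1 plus their means.
    """
    per_task = []
    for task in tasks:
        if isinstance(model, MetaState):
            adapted_a = inner_adapt(
                model.params_a, task.support_x, task.support_y, cfg.inner_lr,
                cfg.adaptation_steps, order="first",
            )
            adapted_b = inner_adapt(
                model.params_b, task.support_x, task.support_y, cfg.inner_lr,
                cfg.adaptation_steps, order="first",
            )
            logits = dual_forward(model, task.query_x, adapted_a, adapted_b).data
        else:
            adapted = inner_adapt(
                model, task.support_x, task.support_y, cfg.inner_lr,
                cfg.adaptation_steps, order="first",
            )
            logits = forward(model, task.query_x, params=adapted).data
        pred = predict_labels(logits)
        per_task.append(
            {
                "task_id": task.task_id,
                "accuracy": float(np.mean(pred == task.query_y)),
                "f1": _binary_f1(task.query_y, pred),
            }
        )
    return {
        "per_task": per_task,
        "accuracy": float(np.mean([t["accuracy"] for t in per_task])),
        "f1": float(np.mean([t["f1"] for t in per_task])),
    }
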