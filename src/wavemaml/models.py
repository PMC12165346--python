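"""The two base architectures as pure functions of externally held parameters.

Both networks map a batch of grayscale scalogram images to class logits and
are expressed functionally: parameters live in a flat name -> Tensor dict
(:class:`MetaParams`) that the caller can replace wholesale, which is what
lets the episodic trainer adapt a copy of the parameters per task without
mutating the meta-parameters.

Architectures:

* ``cnn_transformer`` — a convolutional front end (two conv+ReLU stages with
  2x2 max pooling, batch normalization, dropout) whose spatial grid is
  average-pooled into a token sequence, projected, given a learned positional
  embedding, and passed through two transformer encoder layers
  (multi-head self-attention -> add & norm -> feed-forward -> add & norm),
  then mean-pooled into a linear classification head.
* ``resnet8`` — a strided stem convolution followed by eight residual blocks
  (two 3x3 convolutions with an identity skip: out = x + conv(relu(conv(x)))),
  interleaved max pooling, global average pooling and a linear head — a
  stem-plus-eight-block layout sometimes loosely called "ResNet-18".

Batch normalization always uses current-batch statistics (no running
averages) — the transductive convention standard in episodic meta-learning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "TransformerConfig",
    "ResNetConfig",
    "ArchitectureConfig",
    "MetaParams",
    "init_cnn_transformer",
    "init_resnet",
    "init_model",
    "forward",
    "residual_block",
    "count_parameters",
    "save_params",
    "load_params",
]


@dataclass(frozen=True)
class TransformerConfig:
    n_layers: int = 2
    n_heads: int = 4
    model_dim: int = 64
    ffn_dim: int = 128
    token_grid: int = 8  # conv features are average-pooled to at most this many tokens per side


@dataclass(frozen=True)
class ResNetConfig:
    n_blocks: int = 8
    width: int = 16
    pool_after: tuple[int, ...] = (2, 4)  # extra 2x2 max-pools after these blocks


@dataclass(frozen=True)
class ArchitectureConfig:
    """Hyperparameters shared by both base networks.

    ``faithful=True`` pins the reference structural counts (two
    transformer encoder layers, eight residual blocks).
    """

    input_size: tuple[int, int, int] = (64, 64, 1)  # H, W, channels
    n_classes: int = 2
    conv_channels: tuple[int, int] = (16, 32)
    dropout_rate: float = 0.25
    transformer: TransformerConfig = field(default_factory=TransformerConfig)
    resnet: ResNetConfig = field(default_factory=ResNetConfig)
    faithful: bool = True

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.faithful:
            if self.transformer.n_layers != 2:
                raise ValueError("faithful mode requires exactly 2 transformer encoder layers")
            if self.resnet.n_blocks != 8:
                raise ValueError("faithful mode requires exactly 8 residual blocks")
        h, w, _ = self.input_size
        if h % 4 or w % 4 or h < 8 or w < 8:
            raise ValueError(
                f"input {h}x{w} too small or not divisible by 4 for two pooling stages"
            )

    @classmethod
    def from_yaml(cls, path) -> "ArchitectureConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if "transformer" in raw:
            raw["transformer"] = TransformerConfig(**raw["transformer"])
        if "resnet" in raw:
            raw["resnet"] = ResNetConfig(**raw["resnet"])
        if "input_size" in raw:
            raw["input_size"] = tuple(raw["input_size"])
        if "conv_channels" in raw:
            raw["conv_channels"] = tuple(raw["conv_channels"])
        return cls(**raw)

    @classmethod
    def desk_scale(cls, input_size: tuple[int, int, int] = (64, 64, 1)) -> "ArchitectureConfig":
        """A small-capacity profile sized for single-CPU experiments."""
        return cls(
            input_size=input_size,
            conv_channels=(8, 8),
            dropout_rate=0.0,
            transformer=TransformerConfig(n_heads=2, model_dim=16, ffn_dim=32, token_grid=4),
            resnet=ResNetConfig(width=8),
        )


@dataclass
class MetaParams:
    """Named parameter collection for one architecture."""

    params: dict[str, Tensor]
    architecture_id: str
    cfg: ArchitectureConfig

    @property
    def shape_signature(self) -> dict[str, tuple[int, ...]]:
        return {k: tuple(v.shape) for k, v in self.params.items()}

    def copy(self) -> "MetaParams":
        return MetaParams(
            {k: Tensor(v.data.copy(), requires_grad=True) for k, v in self.params.items()},
            self.architecture_id,
            self.cfg,
        )

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())


def count_parameters(params: MetaParams) -> int:
    return params.n_parameters()


# -- initialization --------------------------------------------------------

def _he_conv(rng, out_c, in_c, k):
    std = np.sqrt(2.0 / (in_c * k * k))
    return rng.normal(0.0, std, size=(out_c, in_c, k, k))


def _xavier(rng, fan_in, fan_out):
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=(fan_in, fan_out))


def _p(d: dict, name: str, value: np.ndarray, dtype=np.float32) -> None:
    d[name] = Tensor(np.asarray(value, dtype=dtype), requires_grad=True)


def _typed_p(dtype):
    def inner(d: dict, name: str, value: np.ndarray) -> None:
        _p(d, name, value, dtype)
    return inner


def _token_count(cfg: ArchitectureConfig) -> tuple[int, int]:
    h, w, _ = cfg.input_size
    gh, gw = h // 4, w // 4  # after two 2x2 pools
    tg = cfg.transformer.token_grid
    th = min(gh, tg)
    tw = min(gw, tg)
    if gh % th or gw % tw:
        raise ValueError(f"conv grid {gh}x{gw} not divisible by token grid {th}x{tw}")
    return th, tw


def init_cnn_transformer(
    cfg: ArchitectureConfig, seed: int = 0, dtype=np.float32
) -> MetaParams:
    """Seeded parameters for the CNN-Transformer hybrid."""
    rng = np.random.default_rng(seed)
    h, w, c_in = cfg.input_size
    c1, c2 = cfg.conv_channels
    t = cfg.transformer
    d = {}
    _p = _typed_p(dtype)  # noqa: F841 - shadows module helper on purpose
    _p(d, "conv1.w", _he_conv(rng, c1, c_in, 3))
    _p(d, "conv1.b", np.zeros(c1))
    _p(d, "conv2.w", _he_conv(rng, c2, c1, 3))
    _p(d, "conv2.b", np.zeros(c2))
    _p(d, "bn.gamma", np.ones(c2))
    _p(d, "bn.beta", np.zeros(c2))
    th, tw = _token_count(cfg)
    _p(d, "tokens.proj", _xavier(rng, c2, t.model_dim))
    _p(d, "tokens.pos", rng.normal(0.0, 0.02, size=(th * tw, t.model_dim)))
    for layer in range(t.n_layers):
        pre = f"enc{layer}"
        for name in ("wq", "wk", "wv", "wo"):
            _p(d, f"{pre}.attn.{name}", _xavier(rng, t.model_dim, t.model_dim))
            _p(d, f"{pre}.attn.{name[1]}b", np.zeros(t.model_dim))
        _p(d, f"{pre}.ln1.gamma", np.ones(t.model_dim))
        _p(d, f"{pre}.ln1.beta", np.zeros(t.model_dim))
        _p(d, f"{pre}.ffn.w1", _xavier(rng, t.model_dim, t.ffn_dim))
        _p(d, f"{pre}.ffn.b1", np.zeros(t.ffn_dim))
        _p(d, f"{pre}.ffn.w2", _xavier(rng, t.ffn_dim, t.model_dim))
        _p(d, f"{pre}.ffn.b2", np.zeros(t.model_dim))
        _p(d, f"{pre}.ln2.gamma", np.ones(t.model_dim))
        _p(d, f"{pre}.ln2.beta", np.zeros(t.model_dim))
    _p(d, "head.w", _xavier(rng, t.model_dim, cfg.n_classes))
    _p(d, "head.b", np.zeros(cfg.n_classes))
    return MetaParams(d, "cnn_transformer", cfg)


def init_resnet(cfg: ArchitectureConfig, seed: int = 0, dtype=np.float32) -> MetaParams:
    """Seeded parameters for the stem + eight-residual-block network."""
    rng = np.random.default_rng(seed)
    _, _, c_in = cfg.input_size
    r = cfg.resnet
    d = {}
    _p = _typed_p(dtype)
    _p(d, "stem.w", _he_conv(rng, r.width, c_in, 3))
    _p(d, "stem.b", np.zeros(r.width))
    _p(d, "stem.bn.gamma", np.ones(r.width))
    _p(d, "stem.bn.beta", np.zeros(r.width))
    for i in range(r.n_blocks):
        _p(d, f"block{i}.conv_a.w", _he_conv(rng, r.width, r.width, 3))
        _p(d, f"block{i}.conv_a.b", np.zeros(r.width))
        _p(d, f"block{i}.bn_a.gamma", np.ones(r.width))
        _p(d, f"block{i}.bn_a.beta", np.zeros(r.width))
        _p(d, f"block{i}.conv_b.w", _he_conv(rng, r.width, r.width, 3))
        _p(d, f"block{i}.conv_b.b", np.zeros(r.width))
        _p(d, f"block{i}.bn_b.gamma", np.ones(r.width))
        _p(d, f"block{i}.bn_b.beta", np.zeros(r.width))
    _p(d, "head.w", _xavier(rng, r.width, cfg.n_classes))
    _p(d, "head.b", np.zeros(cfg.n_classes))
    return MetaParams(d, "resnet8", cfg)


def init_model(
    architecture_id: str, cfg: ArchitectureConfig, seed: int = 0, dtype=np.float32
) -> MetaParams:
    if architecture_id == "cnn_transformer":
        return init_cnn_transformer(cfg, seed, dtype)
    if architecture_id == "resnet8":
        return init_resnet(cfg, seed, dtype)
    raise ValueError(f"unknown architecture {architecture_id!r}")


# -- forward passes --------------------------------------------------------

def _to_nchw(images, c_in: int) -> Tensor:
    if isinstance(images, Tensor):
        x = images
    else:
        arr = np.asarray(images)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        x = Tensor(arr)
    if x.ndim == 3:  # (B, H, W) -> (B, 1, H, W)
        x = ad.reshape(x, (x.shape[0], 1, x.shape[1], x.shape[2]))
    elif x.ndim == 4 and x.shape[-1] == c_in and x.shape[1] != c_in:
        x = ad.transpose(x, (0, 3, 1, 2))
    return x


def _avgpool_to(x: Tensor, th: int, tw: int) -> Tensor:
    b, c, h, w = x.shape
    fh, fw = h // th, w // tw
    x = ad.reshape(x, (b, c, th, fh, tw, fw))
    return ad.gmean(x, axis=(3, 5))


def _attention(x: Tensor, p: dict, pre: str, n_heads: int) -> Tensor:
    b, s, d = x.shape
    dh = d // n_heads

    def split(t):
        t = ad.reshape(t, (b, s, n_heads, dh))
        return ad.transpose(t, (0, 2, 1, 3))  # (B, h, S, dh)

    q = split(ad.linear(x, p[f"{pre}.attn.wq"], p[f"{pre}.attn.qb"]))
    k = split(ad.linear(x, p[f"{pre}.attn.wk"], p[f"{pre}.attn.kb"]))
    v = split(ad.linear(x, p[f"{pre}.attn.wv"], p[f"{pre}.attn.vb"]))
    att = ad.softmax(ad.mul(ad.matmul(q, ad.swapaxes(k, -1, -2)), dh**-0.5), axis=-1)
    out = ad.matmul(att, v)  # (B, h, S, dh)
    out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (b, s, d))
    return ad.linear(out, p[f"{pre}.attn.wo"], p[f"{pre}.attn.ob"])


def _forward_cnn_transformer(
    p: dict, x: Tensor, cfg: ArchitectureConfig, train: bool, rng
) -> tuple[Tensor, Tensor]:
    t = cfg.transformer
    x = ad.maxpool2x2(ad.relu(ad.conv2d(x, p["conv1.w"], p["conv1.b"], padding=1)))
    x = ad.maxpool2x2(ad.relu(ad.conv2d(x, p["conv2.w"], p["conv2.b"], padding=1)))
    x = ad.batchnorm(x, p["bn.gamma"], p["bn.beta"])
    x = ad.dropout(x, cfg.dropout_rate, rng, train)
    th, tw = _token_count(cfg)
    x = _avgpool_to(x, th, tw)  # (B, C, th, tw)
    b, c = x.shape[0], x.shape[1]
    x = ad.swapaxes(ad.reshape(x, (b, c, th * tw)), 1, 2)  # (B, S, C)
    x = ad.add(ad.matmul(x, p["tokens.proj"]), p["tokens.pos"])
    for layer in range(t.n_layers):
        pre = f"enc{layer}"
        attn = _attention(x, p, pre, t.n_heads)
        x = ad.layernorm(ad.add(x, attn), p[f"{pre}.ln1.gamma"], p[f"{pre}.ln1.beta"])
        ffn = ad.linear(
            ad.relu(ad.linear(x, p[f"{pre}.ffn.w1"], p[f"{pre}.ffn.b1"])),
            p[f"{pre}.ffn.w2"],
            p[f"{pre}.ffn.b2"],
        )
        x = ad.layernorm(ad.add(x, ffn), p[f"{pre}.ln2.gamma"], p[f"{pre}.ln2.beta"])
    features = ad.gmean(x, axis=1)  # (B, d)
    logits = ad.linear(features, p["head.w"], p["head.b"])
    return logits, features


def residual_block(x: Tensor, p: dict, pre: str) -> Tensor:
    """Identity skip around two batch-normalized convolutions.

    out = x + bn(conv_b(relu(bn(conv_a(x))))). With all-zero convolution
    weights the branch vanishes and the block is exactly the identity.
    """
    y = ad.conv2d(x, p[f"{pre}.conv_a.w"], p[f"{pre}.conv_a.b"], padding=1)
    y = ad.relu(ad.batchnorm(y, p[f"{pre}.bn_a.gamma"], p[f"{pre}.bn_a.beta"]))
    y = ad.conv2d(y, p[f"{pre}.conv_b.w"], p[f"{pre}.conv_b.b"], padding=1)
    y = ad.batchnorm(y, p[f"{pre}.bn_b.gamma"], p[f"{pre}.bn_b.beta"])
    return ad.add(x, y)


def _forward_resnet(
    p: dict, x: Tensor, cfg: ArchitectureConfig, train: bool, rng
) -> tuple[Tensor, Tensor]:
    r = cfg.resnet
    x = ad.conv2d(x, p["stem.w"], p["stem.b"], stride=2, padding=1)
    x = ad.relu(ad.batchnorm(x, p["stem.bn.gamma"], p["stem.bn.beta"]))
    if x.shape[2] % 2 == 0 and x.shape[2] >= 8:
        x = ad.maxpool2x2(x)
    for i in range(r.n_blocks):
        x = residual_block(x, p, f"block{i}")
        if (i + 1) in r.pool_after and x.shape[2] % 2 == 0 and x.shape[2] >= 4:
            x = ad.maxpool2x2(x)
    features = ad.gmean(x, axis=(2, 3))  # (B, width)
    logits = ad.linear(features, p["head.w"], p["head.b"])
    return logits, features


def forward(
    meta: MetaParams,
    images,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
    params: dict[str, Tensor] | None = None,
    return_features: bool = False,
):
    """Class logits for a batch of images under the given parameters.

    ``params`` overrides the stored parameter dict (task-adapted copies);
    ``mode='train'`` enables dropout (an ``rng`` is then required).
    Evaluation mode is deterministic and never mutates the parameters.
    """
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    train = mode == "train"
    if train and rng is None:
        rng = np.random.default_rng(0)
    p = meta.params if params is None else params
    cfg = meta.cfg
    x = _to_nchw(images, cfg.input_size[2])
    h, w = x.shape[2], x.shape[3]
    if (h, w) != tuple(cfg.input_size[:2]):
        raise ValueError(
            f"input stage: images are {h}x{w}, configuration expects "
            f"{cfg.input_size[0]}x{cfg.input_size[1]}"
        )
    if meta.architecture_id == "cnn_transformer":
        logits, features = _forward_cnn_transformer(p, x, cfg, train, rng)
    elif meta.architecture_id == "resnet8":
        logits, features = _forward_resnet(p, x, cfg, train, rng)
    else:
        raise ValueError(f"unknown architecture {meta.architecture_id!r}")
    if not np.all(np.isfinite(logits.data)):
        raise FloatingPointError("non-finite logits")
    return (logits, features) if return_features else logits


# -- persistence -----------------------------------------------------------

def save_params(meta: MetaParams, path: str | Path) -> None:
    """Save parameters as an .npz archive plus a JSON shape manifest."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **{k: v.data for k, v in meta.params.items()})
    manifest = {
        "architecture_id": meta.architecture_id,
        "shapes": {k: list(v) for k, v in meta.shape_signature.items()},
        "input_size": list(meta.cfg.input_size),
        "n_classes": meta.cfg.n_classes,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_params(path: str | Path, cfg: ArchitectureConfig) -> MetaParams:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as archive:
        params = {k: Tensor(archive[k].copy(), requires_grad=True) for k in archive.files}
    meta = MetaParams(params, manifest["architecture_id"], cfg)
    for name, shape in manifest["shapes"].items():
        if tuple(shape) != tuple(meta.params[name].shape):
            raise ValueError(f"shape mismatch for {name}")
    return meta
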