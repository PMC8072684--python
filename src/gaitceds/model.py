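"""Lightweight gait-recognition CNN with channel attention.

The backbone is a four-convolution feature extractor over a 6x128x1
input (six IMU channels as the image height, 128 time steps as width):

    Conv1 1x9/32 stride (1,2) same -> Pool 1x2 -> BN -> ReLU
    Conv2 1x3/64 same -> Conv3 1x3/128 same -> Pool 1x2 -> BN -> ReLU
    Conv4 6x1/128 valid -> BN -> ReLU            => feature map 1x16x128

Two channel-attention variants can follow the backbone:

``ceds``
    Context-encoding channel weights combined with a depthwise separable
    convolution.  A context encoding layer with K learnable codewords
    scores each channel; with K = 1 the score of channel i is the sum of
    residuals between the spatial descriptors and the single codeword,
    and the channel weight is w_i = e_i / sum_j e_j.  In parallel the
    feature map passes through a 1x3 depthwise convolution (valid
    padding, width 16 -> 14) followed twice by BatchNorm + Sigmoid, and
    the result is multiplied channel-wise by w.
``se``
    The squeeze-and-excitation reference design: global average pool,
    bottleneck dense pair (reduction r), sigmoid channel scales.

The enhanced map is flattened (1792 for ceds, 2048 otherwise) and fed to
a softmax classification head over subject identities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn

#: channels, time steps, image channels of one input sample
INPUT_SHAPE = (6, 128, 1)

#: expected feature-map shape (H, W, C) after each named backbone stage
BACKBONE_MAPS = {
    "Conv1": (6, 64, 32),
    "Pool1": (6, 32, 32),
    "Conv2": (6, 32, 64),
    "Conv3": (6, 32, 128),
    "Pool2": (6, 16, 128),
    "Conv4": (1, 16, 128),
}

EPS_WEIGHT_GUARD = 1e-8


class ArchitectureError(ValueError):
    """A layer's output shape disagrees with the declared architecture."""


@dataclass
class ConvSpec:
    name: str
    kernel: tuple[int, int]
    filters: int
    stride: tuple[int, int] = (1, 1)
    padding: str = "same"


def default_conv_specs() -> list[ConvSpec]:
    return [
        ConvSpec("Conv1", (1, 9), 32, stride=(1, 2), padding="same"),
        ConvSpec("Conv2", (1, 3), 64),
        ConvSpec("Conv3", (1, 3), 128),
        ConvSpec("Conv4", (6, 1), 128, padding="valid"),
    ]


@dataclass
class CedsConfig:
    """Context-encoding + depthwise-separable attention hyperparameters.

    ``n_codewords`` is K, the number of learnable codewords in the
    context encoding layer (1 in this architecture; larger K is a
    configuration stub only).  ``codeword_dim`` must equal the channel
    count of the attended feature map.
    """

    n_codewords: int = 1
    codeword_dim: int = 128
    dw_kernel: tuple[int, int] = (1, 3)
    dw_padding: str = "valid"

    def __post_init__(self) -> None:
        if self.n_codewords < 1:
            raise ValueError("n_codewords must be >= 1")
        if self.dw_kernel[0] != 1 or self.dw_kernel[1] < 1:
            raise ValueError("dw_kernel must be (1, k)")
        if self.dw_padding not in ("valid", "same"):
            raise ValueError("dw_padding must be 'valid' or 'same'")


@dataclass
class ModelConfig:
    """Full architecture description.

    attention: ``"none"``, ``"se"`` or ``"ceds"``.
    pool: ``"max"`` (default) or ``"avg"``.
    """

    n_classes: int
    attention: str = "none"
    input_shape: tuple[int, int, int] = INPUT_SHAPE
    conv_specs: list[ConvSpec] = field(default_factory=default_conv_specs)
    ceds: CedsConfig = field(default_factory=CedsConfig)
    se_reduction: int = 16
    pool: str = "max"

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.attention not in ("none", "se", "ceds"):
            raise ValueError(f"unknown attention {self.attention!r}")
        if self.pool not in ("max", "avg"):
            raise ValueError(f"unknown pool {self.pool!r}")
        if self.attention == "se" and 128 % self.se_reduction:
            raise ValueError("channel count 128 not divisible by se_reduction")


# ---------------------------------------------------------------------------
# context encoding (pure reference functions, single feature map)

def context_encode(
    feature_map: np.ndarray,
    codewords: np.ndarray,
    smoothing: np.ndarray | None = None,
) -> np.ndarray:
    """Aggregate spatial descriptors into one encoding value per channel.

    The H*W spatial positions of an (H, W, C) map are treated as N
    descriptors x_j of dimension C.  For codewords d_k (K x C) the
    residuals are r_jk = x_j - d_k; soft-assignment weights
    a_jk = softmax_k(-s_k * ||r_jk||^2) distribute each descriptor over
    codewords, and the encodings e_k = sum_j a_jk * r_jk are summed over
    k.  With K = 1 the assignment weights are identically 1 and the
    result reduces to sum_j (x_j - d).

    Returns a length-C vector.
    """
    fm = np.asarray(feature_map, dtype=float)
    if fm.ndim != 3:
        raise ValueError(f"feature map must be (H, W, C), got shape {fm.shape}")
    h, w, c = fm.shape
    d = np.atleast_2d(np.asarray(codewords, dtype=float))
    k = d.shape[0]
    if d.shape[1] != c:
        raise ValueError(f"codeword dim {d.shape[1]} != channel count {c}")
    x = fm.reshape(h * w, c)
    if k == 1:
        return (x - d[0]).sum(axis=0)
    s = np.ones(k) if smoothing is None else np.asarray(smoothing, dtype=float)
    r = x[:, None, :] - d[None, :, :]                      # (N, K, C)
    sq = (r ** 2).sum(axis=2)                              # (N, K)
    logits = -s * sq
    logits -= logits.max(axis=1, keepdims=True)
    a = np.exp(logits)
    a /= a.sum(axis=1, keepdims=True)
    return (a[:, :, None] * r).sum(axis=(0, 1))


def channel_weights(encoding: np.ndarray, eps: float = EPS_WEIGHT_GUARD) -> np.ndarray:
    """Normalize channel encodings to weights w_i = e_i / sum_j e_j.

    The denominator is guarded: when |sum| < eps it is replaced by eps
    carrying the sum's sign (+eps at exactly zero), so the output stays
    finite for degenerate encodings.  When the guard is untriggered the
    weights sum to 1.
    """
    e = np.asarray(encoding, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("encoding contains non-finite values")
    total = e.sum()
    if abs(total) < eps:
        total = eps if total >= 0 else -eps
    return e / total


# ---------------------------------------------------------------------------
# attention layers

class CedsAttention(nn.Layer):
    """Context-encoding channel weights x depthwise-separable branch.

    Forward, for a feature map F of shape (N, H, W, C):

        w = channel_weights(context_encode(F))          per sample
        A = sigmoid(BN2(sigmoid(BN1(depthwise_1x3(F)))))
        Y = A * w   (w broadcast over A's spatial grid)

    Learnables: the codeword d (K x C), smoothing factors s (K; inert in
    the forward pass when K = 1), the depthwise filter and bias, and the
    two independent batch-norm parameter sets.  Valid padding shrinks
    the width by 2 (16 -> 14).
    """

    def __init__(self, cfg: CedsConfig, rng=None, dtype=np.float32):
        super().__init__()
        if cfg.n_codewords != 1:
            raise NotImplementedError(
                "training with K > 1 codewords is a configuration stub"
            )
        rng = rng or np.random.default_rng(0)
        c = cfg.codeword_dim
        # "random decimals": uniform on (-0.5, 0.5); smoothing uniform (0, 1)
        self.p["codewords"] = rng.uniform(-0.5, 0.5, size=(cfg.n_codewords, c)).astype(dtype)
        self.p["smoothing"] = rng.uniform(0.0, 1.0, size=cfg.n_codewords).astype(dtype)
        self.dw = nn.DepthwiseConv1xK(
            c, k=cfg.dw_kernel[1], padding=cfg.dw_padding, rng=rng, dtype=dtype, name="dw"
        )
        self.bn1 = nn.BatchNorm(c, dtype=dtype, name="bn1")
        self.bn2 = nn.BatchNorm(c, dtype=dtype, name="bn2")
        self.sig1 = nn.Sigmoid()
        self.sig2 = nn.Sigmoid()
        self.children = [self.dw, self.bn1, self.bn2, self.sig1, self.sig2]
        self.eps = EPS_WEIGHT_GUARD

    def _encode(self, x: np.ndarray) -> np.ndarray:
        # K = 1 closed form, batched: e = sum_spatial(F) - N_spatial * d
        n_spatial = x.shape[1] * x.shape[2]
        return x.sum(axis=(1, 2)) - n_spatial * self.p["codewords"][0]

    def forward(self, x, training=False):
        e = self._encode(x)                                  # (N, C)
        total = e.sum(axis=1, keepdims=True)
        guard = np.abs(total) < self.eps
        safe = np.where(guard, np.where(total >= 0, self.eps, -self.eps), total)
        w = e / safe
        a = self.sig1.forward(self.bn1.forward(self.dw.forward(x, training), training))
        a = self.sig2.forward(self.bn2.forward(a, training), training)
        self._cache = (x.shape, e, safe, guard, w, a)
        return a * w[:, None, None, :]

    def backward(self, grad):
        x_shape, e, safe, guard, w, a = self._cache
        n_spatial = x_shape[1] * x_shape[2]
        dw_ch = (grad * a).sum(axis=(1, 2))                  # dL/dw, (N, C)
        da = grad * w[:, None, None, :]
        dx = self.dw.backward(
            self.bn1.backward(self.sig1.backward(self.bn2.backward(self.sig2.backward(da))))
        )
        # w = e / S; dL/de_i = dw_i/S - (sum_j dw_j e_j)/S^2 (guarded: S constant)
        de = dw_ch / safe
        unguarded = ~guard[:, 0]
        de[unguarded] -= (
            (dw_ch[unguarded] * e[unguarded]).sum(axis=1, keepdims=True)
            / safe[unguarded] ** 2
        )
        dx = dx + de[:, None, None, :].astype(dx.dtype)
        self.g["codewords"] = (-n_spatial * de.sum(axis=0))[None, :].astype(
            self.p["codewords"].dtype
        )
        self.g["smoothing"] = np.zeros_like(self.p["smoothing"])  # inert at K = 1
        return dx


class SEAttention(nn.Layer):
    """Squeeze-and-excitation channel attention (reduction-r bottleneck)."""

    def __init__(self, channels, reduction=16, rng=None, dtype=np.float32):
        super().__init__()
        if channels % reduction:
            raise ValueError(f"channels {channels} not divisible by reduction {reduction}")
        rng = rng or np.random.default_rng(0)
        hidden = channels // reduction
        self.fc1 = nn.Dense(channels, hidden, rng=rng, dtype=dtype, name="fc1")
        self.fc2 = nn.Dense(hidden, channels, rng=rng, dtype=dtype, name="fc2")
        self.relu = nn.ReLU()
        self.sig = nn.Sigmoid()
        self.children = [self.fc1, self.fc2, self.relu, self.sig]

    def forward(self, x, training=False):
        squeeze = x.mean(axis=(1, 2))                        # (N, C)
        scale = self.sig.forward(
            self.fc2.forward(self.relu.forward(self.fc1.forward(squeeze)))
        )
        self._cache = (x, scale)
        return x * scale[:, None, None, :]

    def backward(self, grad):
        x, scale = self._cache
        dscale = (grad * x).sum(axis=(1, 2))
        dsqueeze = self.fc1.backward(
            self.relu.backward(self.fc2.backward(self.sig.backward(dscale)))
        )
        n_spatial = x.shape[1] * x.shape[2]
        dx = grad * scale[:, None, None, :]
        dx += (dsqueeze / n_spatial)[:, None, None, :].astype(dx.dtype)
        return dx


# ---------------------------------------------------------------------------
# builders

def build_backbone(cfg: ModelConfig, rng=None, dtype=np.float32) -> list[nn.Layer]:
    """Construct the convolutional feature extractor as a layer list.

    Raises :class:`ArchitectureError` naming the offending layer if any
    stage's output shape deviates from the declared feature-map table.
    """
    rng = rng or np.random.default_rng(0)
    pool_cls = nn.MaxPool1x2 if cfg.pool == "max" else nn.AvgPool1x2
    c1, c2, c3, c4 = cfg.conv_specs
    layers: list[nn.Layer] = [
        nn.Conv2D(cfg.input_shape[2], c1.filters, c1.kernel, stride=c1.stride,
                  padding=c1.padding, rng=rng, dtype=dtype, name=c1.name),
        pool_cls(name="Pool1"),
        nn.BatchNorm(c1.filters, dtype=dtype, name="BN1"),
        nn.ReLU(),
        nn.Conv2D(c1.filters, c2.filters, c2.kernel, stride=c2.stride,
                  padding=c2.padding, rng=rng, dtype=dtype, name=c2.name),
        nn.Conv2D(c2.filters, c3.filters, c3.kernel, stride=c3.stride,
                  padding=c3.padding, rng=rng, dtype=dtype, name=c3.name),
        pool_cls(name="Pool2"),
        nn.BatchNorm(c3.filters, dtype=dtype, name="BN2"),
        nn.ReLU(),
        nn.Conv2D(c3.filters, c4.filters, c4.kernel, stride=c4.stride,
                  padding=c4.padding, rng=rng, dtype=dtype, name=c4.name),
        nn.BatchNorm(c4.filters, dtype=dtype, name="BN3"),
        nn.ReLU(),
    ]
    _check_backbone_shapes(layers, cfg)
    return layers


def _check_backbone_shapes(layers: list[nn.Layer], cfg: ModelConfig) -> None:
    x = np.zeros((1, *cfg.input_shape), dtype=np.float32)
    stage = {"Conv1": 0, "Pool1": 1, "Conv2": 4, "Conv3": 5, "Pool2": 6, "Conv4": 9}
    for i, layer in enumerate(layers):
        x = layer.forward(x, training=False)
        for name, idx in stage.items():
            if i == idx and x.shape[1:] != BACKBONE_MAPS[name]:
                raise ArchitectureError(
                    f"{name}: expected feature map {BACKBONE_MAPS[name]}, "
                    f"got {x.shape[1:]}"
                )


def backbone_output_shape(cfg: ModelConfig) -> tuple[int, int, int]:
    return BACKBONE_MAPS["Conv4"]


def flatten_width(cfg: ModelConfig) -> int:
    """Width of the flattened feature vector fed to the softmax head."""
    h, w, c = backbone_output_shape(cfg)
    if cfg.attention == "ceds":
        if cfg.ceds.dw_padding == "valid":
            w = w - (cfg.ceds.dw_kernel[1] - 1)
    return h * w * c


def build_classifier(cfg: ModelConfig, seed: int = 0, dtype=np.float32) -> nn.Network:
    """Backbone + optional attention + flatten + softmax head."""
    rng = np.random.default_rng(seed)
    layers = build_backbone(cfg, rng=rng, dtype=dtype)
    c = backbone_output_shape(cfg)[2]
    if cfg.attention == "ceds":
        if cfg.ceds.codeword_dim != c:
            raise ArchitectureError(
                f"codeword_dim {cfg.ceds.codeword_dim} != attended channels {c}"
            )
        layers.append(CedsAttention(cfg.ceds, rng=rng, dtype=dtype))
    elif cfg.attention == "se":
        layers.append(SEAttention(c, reduction=cfg.se_reduction, rng=rng, dtype=dtype))
    layers.append(nn.Flatten())
    layers.append(nn.Dense(flatten_width(cfg), cfg.n_classes, rng=rng, dtype=dtype,
                           name="Head"))
    return nn.Network(layers, name=f"gaitcnn[{cfg.attention}]")


# ---------------------------------------------------------------------------
# model persistence (weights in an array container + JSON sidecar config)

def save_model(path: str | Path, net: nn.Network, cfg: ModelConfig) -> None:
    path = Path(path)
    net.save_arrays(path)
    meta = asdict(cfg)
    meta["conv_specs"] = [asdict(s) for s in cfg.conv_specs]
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_model(path: str | Path) -> tuple[nn.Network, ModelConfig]:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    meta["conv_specs"] = [
        ConvSpec(name=s["name"], kernel=tuple(s["kernel"]), filters=s["filters"],
                 stride=tuple(s["stride"]), padding=s["padding"])
        for s in meta["conv_specs"]
    ]
    meta["ceds"] = CedsConfig(
        n_codewords=meta["ceds"]["n_codewords"],
        codeword_dim=meta["ceds"]["codeword_dim"],
        dw_kernel=tuple(meta["ceds"]["dw_kernel"]),
        dw_padding=meta["ceds"]["dw_padding"],
    )
    meta["input_shape"] = tuple(meta["input_shape"])
    cfg = ModelConfig(**meta)
    net = build_classifier(cfg)
    net.load_arrays(path)
    return net, cfg
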