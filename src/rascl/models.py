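"""Encoder and MLP-head construction.

The reference architecture is a standard-width ResNet-50 encoder followed by
an MLP of three fully connected layers of 512 nodes; the third layer is the
projection head during pre-training and feeds a fresh 2-way softmax layer
during fine-tuning.  A ``small_cnn`` encoder (four stride-2 conv blocks plus
global average pooling) provides the same contracts at desk scale, where the
whole pipeline trains in minutes on one CPU core.

Grayscale B-scans are replicated across the channel dimension the encoder
expects.  Checkpoints are self-describing ``.npz`` archives holding the
specs, weights and training history.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .exceptions import ConfigurationError, DomainError

__all__ = [
    "EncoderSpec",
    "HeadSpec",
    "Encoder",
    "MLPHead",
    "build_encoder",
    "build_head",
    "project",
    "classify",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class EncoderSpec:
    architecture: str = "small_cnn"  # small_cnn | resnet50_standard
    input_size: tuple[int, int, int] = (224, 224, 1)  # (H, W, channels)
    feature_dim: int = 64  # forced to 2048 for resnet50_standard
    initial_weights: str = "random"  # "random" or a checkpoint path
    pool_grid: int = 1  # small_cnn: average-pool onto a g x g grid (1 = global)

    def validate(self) -> None:
        if self.architecture not in ("small_cnn", "resnet50_standard"):
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if self.feature_dim <= 0:
            raise ConfigurationError("feature_dim must be > 0")
        if self.pool_grid < 1:
            raise ConfigurationError("pool_grid must be >= 1")
        h, w = self.input_size[0], self.input_size[1]
        if self.architecture == "small_cnn":
            if h < 32 or w < 32:
                raise ConfigurationError("small_cnn accepts inputs down to 32x32")
            g2 = self.pool_grid**2
            if self.feature_dim % (8 * g2):
                raise ConfigurationError(
                    "small_cnn feature_dim must be divisible by 8 * pool_grid^2"
                )


@dataclass
class HeadSpec:
    hidden_layers: int = 3
    hidden_width: int = 512
    mode: str = "projection"  # projection | classifier
    n_classes: int = 2

    def validate(self) -> None:
        if self.mode not in ("projection", "classifier"):
            raise ConfigurationError(f"unknown head mode {self.mode!r}")
        if self.hidden_layers < 1 or self.hidden_width < 1:
            raise ConfigurationError("head must have >= 1 layer of >= 1 node")


class Encoder:
    """A convolutional encoder mapping image batches to feature vectors."""

    def __init__(self, spec: EncoderSpec, net: nn.Sequential):
        self.spec = spec
        self.net = net
        self.feature_dim = spec.feature_dim

    @property
    def channels(self) -> int:
        return self.spec.input_size[2]

    def _to_nchw(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:  # (N, H, W) grayscale -> replicate channels
            x = np.repeat(x[:, None, :, :], self.channels, axis=1)
        if x.shape[2] != self.spec.input_size[0] or x.shape[3] != self.spec.input_size[1]:
            raise DomainError(
                f"input spatial shape {x.shape[2:]} != encoder input {self.spec.input_size[:2]}"
            )
        return x

    def features(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        """Forward pass to pooled feature vectors, one per image."""
        return self.net.forward(self._to_nchw(images), train=train)

    # convenience passthroughs
    def parameters(self):
        return self.net.parameters()

    def state_dict(self):
        return self.net.state_dict()

    def load_state(self, state):
        self.net.load_state(state)

    @property
    def n_params(self) -> int:
        return self.net.n_params


def _small_cnn(feature_dim: int, in_channels: int, rng: np.random.Generator,
               pool_grid: int = 1) -> nn.Sequential:
    # conv-BN-ReLU blocks: the normalisation decorrelates pooled features,
    # which the contrastive objective needs to avoid a mean-dominated
    # (collapsed-cosine) embedding.  pool_grid > 1 keeps coarse location
    # information in the feature vector (feature_dim = channels * grid^2).
    channels = feature_dim // pool_grid**2
    c = channels // 8
    widths = [c, 2 * c, 4 * c, channels]
    layers: list[nn.Module] = []
    prev = in_channels
    for w in widths:
        layers += [
            nn.Conv2d(prev, w, 3, rng, stride=2, padding=1, bias=False),
            nn.BatchNorm2d(w),
            nn.ReLU(),
        ]
        prev = w
    layers.append(nn.GridAvgPool(pool_grid) if pool_grid > 1 else nn.GlobalAvgPool())
    return nn.Sequential(*layers)


class _Bottleneck(nn.Module):
    """ResNet bottleneck block (1x1 -> 3x3 -> 1x1) with identity/projection skip."""

    def __init__(self, in_ch: int, mid: int, out_ch: int, stride: int, rng):
        self.conv1 = nn.Conv2d(in_ch, mid, 1, rng, bias=False)
        self.bn1 = nn.BatchNorm2d(mid)
        self.conv2 = nn.Conv2d(mid, mid, 3, rng, stride=stride, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(mid)
        self.conv3 = nn.Conv2d(mid, out_ch, 1, rng, bias=False)
        self.bn3 = nn.BatchNorm2d(out_ch)
        self.relu1, self.relu2, self.relu_out = nn.ReLU(), nn.ReLU(), nn.ReLU()
        if stride != 1 or in_ch != out_ch:
            self.down: nn.Sequential | None = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False),
                nn.BatchNorm2d(out_ch),
            )
        else:
            self.down = None

    def _modules(self):
        mods = [self.conv1, self.bn1, self.conv2, self.bn2, self.conv3, self.bn3]
        if self.down is not None:
            mods.append(self.down)
        return mods

    def parameters(self):
        out = []
        for m in self._modules():
            out.extend(m.parameters())
        return out

    def buffer_refs(self):
        out = []
        for m in self._modules():
            out.extend(m.buffer_refs())
        return out

    def forward(self, x, train=True):
        y = self.relu1(self.bn1(self.conv1(x, train), train), train)
        y = self.relu2(self.bn2(self.conv2(y, train), train), train)
        y = self.bn3(self.conv3(y, train), train)
        skip = self.down.forward(x, train) if self.down is not None else x
        return self.relu_out(y + skip, train)

    def backward(self, grad_out):
        g = self.relu_out.backward(grad_out)
        gskip = self.down.backward(g) if self.down is not None else g
        gy = self.bn3.backward(g)
        gy = self.conv3.backward(gy)
        gy = self.relu2.backward(gy)
        gy = self.bn2.backward(gy)
        gy = self.conv2.backward(gy)
        gy = self.relu1.backward(gy)
        gy = self.bn1.backward(gy)
        gy = self.conv1.backward(gy)
        return gy + gskip


def _resnet50(in_channels: int, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Module] = [
        nn.Conv2d(in_channels, 64, 7, rng, stride=2, padding=3, bias=False),
        nn.BatchNorm2d(64),
        nn.ReLU(),
        nn.MaxPool2d(3, 2),
    ]
    stage_cfg = [(64, 256, 3, 1), (128, 512, 4, 2), (256, 1024, 6, 2), (512, 2048, 3, 2)]
    in_ch = 64
    for mid, out_ch, blocks, stride in stage_cfg:
        for b in range(blocks):
            layers.append(_Bottleneck(in_ch, mid, out_ch, stride if b == 0 else 1, rng))
            in_ch = out_ch
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(*layers)


def build_encoder(spec: EncoderSpec, seed: int) -> Encoder:
    """Deterministically initialised encoder; external weights optional.

    ``initial_weights`` may name a checkpoint file (this is how an
    externally pre-trained encoder, e.g. ImageNet-derived weights converted
    to this format, is supplied); the default is random He initialisation.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    in_ch = spec.input_size[2]
    if spec.architecture == "small_cnn":
        net = _small_cnn(spec.feature_dim, in_ch, rng, spec.pool_grid)
    else:
        net = _resnet50(in_ch, rng)
        spec = EncoderSpec(spec.architecture, spec.input_size, 2048, spec.initial_weights)
    enc = Encoder(spec, net)
    if spec.initial_weights not in ("random", None):
        ckpt = load_checkpoint(spec.initial_weights)
        enc.load_state(ckpt["encoder_state"])
    return enc


class MLPHead(nn.Module):
    """The 3x512 trunk shared by projection and classifier heads.

    In ``projection`` mode the output is the (linear) final trunk layer; in
    ``classifier`` mode a fresh 2-way layer consumes it and ``forward``
    returns logits (use :func:`classify` for softmax scores).
    """

    def __init__(self, spec: HeadSpec, in_dim: int, rng: np.random.Generator):
        spec.validate()
        self.spec = spec
        layers: list[nn.Module] = []
        prev = in_dim
        for i in range(spec.hidden_layers):
            layers.append(nn.Linear(prev, spec.hidden_width, rng))
            prev = spec.hidden_width
            if i < spec.hidden_layers - 1:
                layers.append(nn.ReLU())
        self.trunk = nn.Sequential(*layers)
        self.out = (
            nn.Linear(prev, spec.n_classes, rng) if spec.mode == "classifier" else None
        )

    def parameters(self):
        params = self.trunk.parameters()
        if self.out is not None:
            params = params + self.out.parameters()
        return params

    def buffer_refs(self):
        refs = self.trunk.buffer_refs()
        if self.out is not None:
            refs = refs + self.out.buffer_refs()
        return refs

    def forward(self, x, train=True):
        z = self.trunk.forward(x, train=train)
        if self.out is not None:
            z = self.out.forward(z, train=train)
        return z

    def backward(self, grad_out):
        if self.out is not None:
            grad_out = self.out.backward(grad_out)
        return self.trunk.backward(grad_out)


def build_head(spec: HeadSpec, in_dim: int, seed: int) -> MLPHead:
    return MLPHead(spec, in_dim, np.random.default_rng(seed))


def project(encoder: Encoder, projection_head: MLPHead, images: np.ndarray) -> np.ndarray:
    """Projection vectors (one per image), evaluation mode."""
    feats = encoder.features(images, train=False)
    return projection_head.forward(feats, train=False)


def classify(encoder: Encoder, classifier_head: MLPHead, images: np.ndarray) -> np.ndarray:
    """Per-class softmax scores (rows sum to 1); class 1 is FTMH."""
    if classifier_head.spec.mode != "classifier":
        raise DomainError("head is not in classifier mode")
    feats = encoder.features(images, train=False)
    logits = classifier_head.forward(feats, train=False)
    return nn.softmax(logits)


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(
    path: str | Path,
    encoder: Encoder,
    heads: list[MLPHead] | None = None,
    history: dict | list | None = None,
) -> Path:
    """Self-describing archive: specs + weights + training history."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    for i, a in enumerate(encoder.state_dict()):
        arrays[f"enc_{i:04d}"] = a
    head_specs = []
    for h, head in enumerate(heads or []):
        head_specs.append(asdict(head.spec))
        for i, a in enumerate(head.state_dict()):
            arrays[f"head{h}_{i:04d}"] = a
    meta = {
        "encoder_spec": asdict(encoder.spec),
        "head_specs": head_specs,
        "history": history,
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path: str | Path) -> dict:
    """Returns encoder/head specs, weight lists and history from an archive."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        enc_keys = sorted(k for k in data.files if k.startswith("enc_"))
        out = {
            "encoder_spec": meta["encoder_spec"],
            "head_specs": meta["head_specs"],
            "history": meta["history"],
            "encoder_state": [data[k] for k in enc_keys],
            "head_states": [],
        }
        for h in range(len(meta["head_specs"])):
            keys = sorted(k for k in data.files if k.startswith(f"head{h}_"))
            out["head_states"].append([data[k] for k in keys])
    return out
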