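"""FPN segmentation network with residual or densely-connected encoders.

The forward pass is *functional*: all weights live in a flat, named
:class:`ModelParameters` mapping that is passed into :func:`forward` rather
than being owned by layer objects. This is what the meta-learning inner loop
requires — task-adapted parameters φ_τ are just another mapping with the same
names, evaluated without mutating the shared initialization θ.

Architecture. A stem convolution at full resolution feeds a pyramid of
encoder stages, each opening with a stride-2 convolution and followed by
residual blocks (y = F(x) + x, post-addition ReLU) or a dense block (each
layer consumes the concatenation of the stage input and all previous layers'
outputs). A top-down pathway upsamples the coarsest map ×2 per level and sums
it with 1×1 lateral projections of the encoder maps; a small head produces one
logit per pixel at full resolution. Normalization is group-norm throughout:
with 1–10 images per adaptation step, batch statistics would be degenerate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .io_formats import Micrograph, SegmentationMask

__all__ = [
    "BackboneConfig", "ModelParameters", "build_model", "forward",
    "residual_block", "dense_block", "group_norm", "predict_mask",
    "save_checkpoint", "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class BackboneConfig:
    """Structural description of the encoder + FPN decoder."""

    family: str = "residual"                    # "residual" | "dense"
    stage_channels: tuple[int, ...] = (8, 16, 32)
    blocks_per_stage: tuple[int, ...] = (1, 1, 1)
    growth_rate: int | None = None              # dense family only
    fpn_channels: int = 8
    out_classes: int = 1

    def __post_init__(self):
        if self.family not in ("residual", "dense"):
            raise ValueError(f"unknown backbone family {self.family!r}")
        if len(self.stage_channels) != len(self.blocks_per_stage):
            raise ValueError("stage_channels and blocks_per_stage lengths differ")
        if len(self.stage_channels) < 3:
            raise ValueError("an FPN needs >= 3 pyramid stages")
        if any(c < 1 for c in self.stage_channels) or \
           any(b < 1 for b in self.blocks_per_stage):
            raise ValueError("stage sizes must be positive")
        if self.family == "dense" and not self.growth_rate:
            raise ValueError("dense family requires growth_rate")
        if self.family == "residual" and self.growth_rate is not None:
            raise ValueError("growth_rate is only meaningful for the dense family")
        if self.out_classes != 1:
            raise ValueError("only single-class (crystalline vs. rest) heads supported")

    @property
    def n_stages(self) -> int:
        return len(self.stage_channels)

    @property
    def divisor(self) -> int:
        """Input sides must be divisible by this (2^n_stages)."""
        return 2 ** self.n_stages


@dataclass
class ModelParameters:
    """Flat named-tensor collection: θ (shared) or φ_τ (task-adapted)."""

    params: dict[str, Tensor]
    config: BackboneConfig

    def names(self) -> set[str]:
        return set(self.params)

    def copy(self) -> "ModelParameters":
        return ModelParameters({k: v.copy() for k, v in self.params.items()},
                               self.config)

    def detach(self) -> "ModelParameters":
        return ModelParameters({k: v.detach() for k, v in self.params.items()},
                               self.config)

    def requires_grad_(self, flag: bool = True) -> "ModelParameters":
        for v in self.params.values():
            v.requires_grad = flag
        return self

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def validate(self) -> None:
        expected = set(_parameter_shapes(self.config))
        if self.names() != expected:
            missing = expected - self.names()
            extra = self.names() - expected
            raise ValueError(f"parameter names do not match config "
                             f"(missing {sorted(missing)}, extra {sorted(extra)})")
        for k, v in self.params.items():
            if not np.all(np.isfinite(v.data)):
                raise ValueError(f"non-finite values in parameter {k}")


# ---------------------------------------------------------------------------
# parameter layout
# ---------------------------------------------------------------------------

def _gn_groups(channels: int) -> int:
    for g in (8, 4, 2, 1):
        if channels % g == 0:
            return g
    return 1


def _parameter_shapes(cfg: BackboneConfig) -> dict[str, tuple[int, ...]]:
    """The exact name -> shape layout implied by a config."""
    shapes: dict[str, tuple[int, ...]] = {}
    c0 = cfg.stage_channels[0]
    shapes["stem.conv.w"] = (c0, 1, 3, 3)
    shapes["stem.gn.w"] = (c0,)
    shapes["stem.gn.b"] = (c0,)
    prev = c0
    for i, (ch, nb) in enumerate(zip(cfg.stage_channels, cfg.blocks_per_stage)):
        shapes[f"stage{i}.down.w"] = (ch, prev, 3, 3)
        shapes[f"stage{i}.down.gn.w"] = (ch,)
        shapes[f"stage{i}.down.gn.b"] = (ch,)
        if cfg.family == "residual":
            for j in range(nb):
                shapes[f"stage{i}.block{j}.conv1.w"] = (ch, ch, 3, 3)
                shapes[f"stage{i}.block{j}.gn1.w"] = (ch,)
                shapes[f"stage{i}.block{j}.gn1.b"] = (ch,)
                shapes[f"stage{i}.block{j}.conv2.w"] = (ch, ch, 3, 3)
                shapes[f"stage{i}.block{j}.gn2.w"] = (ch,)
                shapes[f"stage{i}.block{j}.gn2.b"] = (ch,)
        else:
            g = cfg.growth_rate
            for j in range(nb):
                cin = ch + j * g
                shapes[f"stage{i}.dense{j}.w"] = (g, cin, 3, 3)
                shapes[f"stage{i}.dense{j}.gn.w"] = (g,)
                shapes[f"stage{i}.dense{j}.gn.b"] = (g,)
            shapes[f"stage{i}.trans.w"] = (ch, ch + nb * g, 1, 1)
        shapes[f"lateral{i}.w"] = (cfg.fpn_channels, ch, 1, 1)
        prev = ch
    f = cfg.fpn_channels
    shapes["head.conv.w"] = (f, f, 3, 3)
    shapes["head.gn.w"] = (f,)
    shapes["head.gn.b"] = (f,)
    shapes["head.out.w"] = (1, f, 1, 1)
    shapes["head.out.b"] = (1,)
    return shapes


def build_model(cfg: BackboneConfig, init_seed: int = 0) -> ModelParameters:
    """Initialize parameters: He-style normals for convolutions, identity
    group-norm (weight 1, bias 0), zero head bias. Reproducible from seed."""
    rng = np.random.default_rng(int(init_seed) & 0x7FFFFFFF)
    params: dict[str, Tensor] = {}
    for name, shape in _parameter_shapes(cfg).items():
        if name.endswith(".w") and len(shape) == 4:
            fan_in = shape[1] * shape[2] * shape[3]
            data = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)
        elif name.endswith("gn.w") or ".gn" in name and name.endswith(".w"):
            data = np.ones(shape)
        elif name.endswith(".b"):
            data = np.zeros(shape)
        else:
            data = np.ones(shape)
        params[name] = Tensor(data, requires_grad=True)
    mp = ModelParameters(params, cfg)
    mp.validate()
    return mp


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def group_norm(x: Tensor, weight: Tensor, bias: Tensor,
               groups: int | None = None, eps: float = 1e-5) -> Tensor:
    """Group normalization over (channel-group, H, W) per sample."""
    n, c, h, w = x.shape
    g = groups if groups is not None else _gn_groups(c)
    xg = ad.reshape(x, (n, g, (c // g) * h * w))
    mu = ad.tmean(xg, axis=2, keepdims=True)
    var = ad.tmean((xg - mu) ** 2, axis=2, keepdims=True)
    norm = (xg - mu) * ad.power(var + 1e-12 + eps, -0.5)
    norm = ad.reshape(norm, (n, c, h, w))
    wch = ad.reshape(weight, (1, c, 1, 1))
    bch = ad.reshape(bias, (1, c, 1, 1))
    return norm * wch + bch


def residual_block(x: Tensor, weights: Mapping[str, Tensor],
                   prefix: str = "") -> Tensor:
    """y = ReLU(F(x) + x) with F = conv→GN→ReLU→conv→GN.

    The skip is the identity; a 1×1 projection (key "proj.w") is applied to x
    when the block changes the channel count.
    """
    p = prefix
    h = ad.conv2d(x, weights[f"{p}conv1.w"], stride=1, padding=1)
    h = ad.relu(group_norm(h, weights[f"{p}gn1.w"], weights[f"{p}gn1.b"]))
    h = ad.conv2d(h, weights[f"{p}conv2.w"], stride=1, padding=1)
    h = group_norm(h, weights[f"{p}gn2.w"], weights[f"{p}gn2.b"])
    skip = x
    if f"{p}proj.w" in weights:
        skip = ad.conv2d(x, weights[f"{p}proj.w"], stride=1, padding=0)
    return ad.relu(h + skip)


def dense_block(x: Tensor, weights: Mapping[str, Tensor], layers: int,
                growth: int, prefix: str = "") -> Tensor:
    """Densely connected block: layer ℓ sees [x, y_0, ..., y_{ℓ-1}] concatenated.

    Output has channels(x) + layers·growth channels.
    """
    if layers < 1:
        raise ValueError("dense block needs >= 1 layer")
    feats = [x]
    for j in range(layers):
        inp = feats[0] if len(feats) == 1 else ad.concat(feats, axis=1)
        h = ad.conv2d(inp, weights[f"{prefix}dense{j}.w"], stride=1, padding=1)
        h = ad.relu(group_norm(h, weights[f"{prefix}dense{j}.gn.w"],
                               weights[f"{prefix}dense{j}.gn.b"]))
        feats.append(h)
    return ad.concat(feats, axis=1)


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def _as_batch(batch) -> np.ndarray:
    if isinstance(batch, Tensor):
        return batch
    if isinstance(batch, Micrograph):
        batch = [batch]
    if isinstance(batch, (list, tuple)) and batch and isinstance(batch[0], Micrograph):
        batch = np.stack([m.image for m in batch])
    arr = np.asarray(batch, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected (N, H, W) batch, got shape {arr.shape}")
    return Tensor(arr)


def forward(params: ModelParameters, batch) -> Tensor:
    """Per-pixel logits, shape (N, H, W), for a batch of micrograph images.

    H and W must be divisible by 2^n_stages (pad beforehand if needed).
    """
    cfg = params.config
    x = _as_batch(batch)
    n, h, w = x.shape
    d = cfg.divisor
    if h % d or w % d:
        raise ValueError(
            f"input sides ({h}, {w}) must be divisible by {d} for {cfg.n_stages} stages")
    wts = params.params
    t = ad.reshape(x, (n, 1, h, w))
    t = ad.conv2d(t, wts["stem.conv.w"], stride=1, padding=1)
    t = ad.relu(group_norm(t, wts["stem.gn.w"], wts["stem.gn.b"]))

    pyramid = []
    for i, (ch, nb) in enumerate(zip(cfg.stage_channels, cfg.blocks_per_stage)):
        t = ad.conv2d(t, wts[f"stage{i}.down.w"], stride=2, padding=1)
        t = ad.relu(group_norm(t, wts[f"stage{i}.down.gn.w"],
                               wts[f"stage{i}.down.gn.b"]))
        if cfg.family == "residual":
            for j in range(nb):
                t = residual_block(t, wts, prefix=f"stage{i}.block{j}.")
        else:
            t = dense_block(t, wts, layers=nb, growth=cfg.growth_rate,
                            prefix=f"stage{i}.")
            t = ad.conv2d(t, wts[f"stage{i}.trans.w"], stride=1, padding=0)
        pyramid.append(t)

    # top-down pathway with lateral connections, summed
    top = ad.conv2d(pyramid[-1], wts[f"lateral{cfg.n_stages - 1}.w"],
                    stride=1, padding=0)
    for i in range(cfg.n_stages - 2, -1, -1):
        lat = ad.conv2d(pyramid[i], wts[f"lateral{i}.w"], stride=1, padding=0)
        top = ad.upsample_nearest2x(top) + lat

    # head at the finest pyramid level (1/2 resolution), then full-res logits
    head = ad.conv2d(top, wts["head.conv.w"], stride=1, padding=1)
    head = ad.relu(group_norm(head, wts["head.gn.w"], wts["head.gn.b"]))
    logits = ad.conv2d(head, wts["head.out.w"], stride=1, padding=0)
    logits = logits + ad.reshape(wts["head.out.b"], (1, 1, 1, 1))
    logits = ad.upsample_nearest2x(logits)
    return ad.reshape(logits, (n, h, w))


def predict_mask(logits, threshold: float = 0.5) -> SegmentationMask:
    """Binarize logits: foreground where sigmoid(logit) >= threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    arr = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite logits")
    logit_thr = math.log(threshold / (1.0 - threshold))
    return SegmentationMask(mask=(arr >= logit_thr).astype(np.uint8))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: ModelParameters) -> None:
    """Named-tensor archive (.npz) with the config and a format version."""
    cfg = params.config
    meta = json.dumps({
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "family": cfg.family,
        "stage_channels": list(cfg.stage_channels),
        "blocks_per_stage": list(cfg.blocks_per_stage),
        "growth_rate": cfg.growth_rate,
        "fpn_channels": cfg.fpn_channels,
        "out_classes": cfg.out_classes,
    })
    arrays = {f"param/{k}": v.data for k, v in params.params.items()}
    np.savez(str(path), __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> ModelParameters:
    with np.load(str(path)) as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format: "
                             f"{meta.get('format_version')}")
        cfg = BackboneConfig(
            family=meta["family"],
            stage_channels=tuple(meta["stage_channels"]),
            blocks_per_stage=tuple(meta["blocks_per_stage"]),
            growth_rate=meta["growth_rate"],
            fpn_channels=meta["fpn_channels"],
            out_classes=meta["out_classes"],
        )
        params = {k[len("param/"):]: Tensor(f[k], requires_grad=True)
                  for k in f.files if k.startswith("param/")}
    mp = ModelParameters(params, cfg)
    mp.validate()
    return mp
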