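"""PixelBNN architecture: two parallel convolutional input streams feeding
gated residual blocks through a strided-conv encoder and a transposed-conv
decoder with paired long skip connections.

The encoder runs ``num_stages`` stages of [gated ResNet block -> stride-2
downsampling conv -> batch norm -> dropout], doubling the feature width at
each downsampling from ``base_features`` (capped so a 3-stage default sees
widths 16/32/64 down the encoder and a deepest 32x32 map at width 64 for a
256x256 input). The decoder mirrors with stride-2 transposed convolutions and
halving widths; every encoder gated ResNet feeds a long skip (channel
concatenation + 1x1 NIN width restoration) to its mirror-paired decoder unit.
The head concatenates both final streams and applies a 1x1 convolution to a
single sigmoid channel, so the output probability map matches the input size.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import BatchNorm, Conv2d, ConvTranspose2d, GatedResNetUnit, Module

__all__ = [
    "NetworkConfig",
    "SMOKE_NETWORK",
    "ConfigError",
    "PixelBNN",
    "build_network",
    "forward",
    "crelu",
    "gated_resnet",
    "segmentation_loss",
    "save_checkpoint",
    "load_checkpoint",
]


class ConfigError(ValueError):
    """Architectural constraint violated (shapes, divisibility, widths)."""


@dataclass(frozen=True)
class NetworkConfig:
    base_features: int = 16
    num_stages: int = 3
    resnets_per_block: int = 4
    stream1_kernel: int = 7
    stream2_kernel: int = 3
    body_kernel: int = 3
    down_stride: int = 2
    dropout_keep: float = 0.6
    bn_epsilon: float = 1e-5
    bn_decay: float = 0.9

    def __post_init__(self):
        if self.base_features < 1 or self.num_stages < 1 or self.resnets_per_block < 1:
            raise ConfigError("base_features, num_stages, resnets_per_block must be >= 1")
        if not 0.0 < self.dropout_keep <= 1.0:
            raise ConfigError("dropout_keep must be in (0, 1]")

    def stage_width(self, depth: int) -> int:
        """Feature width of the gated ResNet block at encoder depth `depth`."""
        return self.base_features * 2 ** min(depth, self.num_stages - 1)

    def check_input_side(self, side: int) -> None:
        if side % self.down_stride**self.num_stages != 0:
            raise ConfigError(
                f"input side {side} not divisible by "
                f"{self.down_stride}^{self.num_stages}"
            )


#: scaled-down profile for CPU smoke training and CI (see training module)
SMOKE_NETWORK = NetworkConfig(base_features=8, num_stages=2, resnets_per_block=2)


class _EncoderStage(Module):
    def __init__(self, cfg, depth, *, rng):
        w = cfg.stage_width(depth)
        w_next = cfg.stage_width(depth + 1) if depth + 1 < cfg.num_stages else w
        self.units = [GatedResNetUnit(w, rng=rng) for _ in range(cfg.resnets_per_block)]
        self.down1 = Conv2d(w, w_next, cfg.body_kernel, stride=cfg.down_stride, rng=rng)
        self.down2 = Conv2d(w, w_next, cfg.body_kernel, stride=cfg.down_stride, rng=rng)
        self.bn1 = BatchNorm(w_next, cfg.bn_epsilon, cfg.bn_decay)
        self.bn2 = BatchNorm(w_next, cfg.bn_epsilon, cfg.bn_decay)


class _DecoderStage(Module):
    def __init__(self, cfg, depth, *, rng):
        # decoder stage d mirrors encoder stage (num_stages-1-d)
        mirror = cfg.num_stages - 1 - depth
        w = cfg.stage_width(mirror)
        w_in = cfg.stage_width(mirror + 1) if mirror + 1 < cfg.num_stages else w
        self.up1 = ConvTranspose2d(w_in, w, cfg.body_kernel, cfg.down_stride, rng=rng)
        self.up2 = ConvTranspose2d(w_in, w, cfg.body_kernel, cfg.down_stride, rng=rng)
        self.bn1 = BatchNorm(w, cfg.bn_epsilon, cfg.bn_decay)
        self.bn2 = BatchNorm(w, cfg.bn_epsilon, cfg.bn_decay)
        self.units = [GatedResNetUnit(w, rng=rng) for _ in range(cfg.resnets_per_block)]
        self.skip_nin1 = [Conv2d(2 * w, w, 1, rng=rng) for _ in range(cfg.resnets_per_block)]
        self.skip_nin2 = [Conv2d(2 * w, w, 1, rng=rng) for _ in range(cfg.resnets_per_block)]


class PixelBNN(Module):
    """Assembled two-stream network. Build via :func:`build_network`."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        b = cfg.base_features
        self.stem1 = Conv2d(3, b, cfg.stream1_kernel, rng=rng)
        self.stem2 = Conv2d(3, b, cfg.stream2_kernel, rng=rng)
        self.encoder = [_EncoderStage(cfg, d, rng=rng) for d in range(cfg.num_stages)]
        self.decoder = [_DecoderStage(cfg, d, rng=rng) for d in range(cfg.num_stages)]
        self.head = Conv2d(2 * b, 1, 1, rng=rng)

    # -- forward -----------------------------------------------------------
    def forward_logits(self, batch, training=False, rng=None):
        """(N,H,W,3) continuous-space batch -> (N,H,W) vessel logits."""
        x = np.asarray(batch, dtype=np.float32)
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ConfigError(f"expected (N,H,W,3) batch, got {x.shape}")
        if x.shape[1] != x.shape[2]:
            raise ConfigError("inputs must be square")
        self.cfg.check_input_side(x.shape[1])
        if training and rng is None:
            rng = np.random.default_rng(0)

        inp = Tensor(x)
        s1 = self.stem1(inp)
        s2 = self.stem2(inp)

        trace = {"encoder_blocks": [], "after_downsample": [], "decoder_blocks": []}
        skips: list[list[tuple[Tensor, Tensor]]] = []
        for stage in self.encoder:
            trace["encoder_blocks"].append(s1.shape)
            stage_skips = []
            for unit in stage.units:
                s1, s2 = unit(s1, s2)
                stage_skips.append((s1, s2))
            skips.append(stage_skips)
            s1 = stage.bn1(stage.down1(s1), training)
            s2 = stage.bn2(stage.down2(s2), training)
            s1 = ad.dropout(s1, self.cfg.dropout_keep, rng, training)
            s2 = ad.dropout(s2, self.cfg.dropout_keep, rng, training)
            trace["after_downsample"].append(s1.shape)

        for d, stage in enumerate(self.decoder):
            s1 = stage.bn1(stage.up1(s1), training)
            s2 = stage.bn2(stage.up2(s2), training)
            mirror_skips = skips[self.cfg.num_stages - 1 - d]
            trace["decoder_blocks"].append(s1.shape)
            for r, unit in enumerate(stage.units):
                sk1, sk2 = mirror_skips[len(mirror_skips) - 1 - r]
                s1 = stage.skip_nin1[r](ad.concat(s1, sk1))
                s2 = stage.skip_nin2[r](ad.concat(s2, sk2))
                s1, s2 = unit(s1, s2)

        self.last_trace = trace  # shape bookkeeping for architecture checks
        logits = self.head(ad.concat(s1, s2))
        # drop the trailing singleton channel
        out = Tensor(logits.data[..., 0], (logits,))

        def _bw(g):
            logits.accumulate(g[..., None])

        out._backward = _bw
        return out

    def forward(self, batch, training=False, rng=None) -> np.ndarray:
        """Batch of continuous images -> batch of probability maps in (0, 1)."""
        logits = self.forward_logits(batch, training=training, rng=rng)
        probs = 1.0 / (1.0 + np.exp(-np.clip(logits.data, -60.0, 60.0)))
        eps = np.finfo(np.float32).tiny
        return np.clip(probs, eps, 1.0 - eps)

    def num_gated_resnets(self) -> int:
        return sum(len(s.units) for s in self.encoder) + sum(
            len(s.units) for s in self.decoder
        )


def build_network(cfg: NetworkConfig | None = None, seed: int = 0) -> PixelBNN:
    return PixelBNN(cfg or NetworkConfig(), seed=seed)


def forward(model: PixelBNN, batch, training: bool = False, rng=None) -> np.ndarray:
    return model.forward(batch, training=training, rng=rng)


def crelu(features: np.ndarray) -> np.ndarray:
    """Concatenated ReLU on a channel-last array: [max(x,0), max(-x,0)]."""
    x = np.asarray(features)
    return np.concatenate([np.maximum(x, 0), np.maximum(-x, 0)], axis=-1)


def gated_resnet(
    stream1: np.ndarray, stream2: np.ndarray, unit: GatedResNetUnit
) -> tuple[np.ndarray, np.ndarray]:
    """Functional application of a gated residual unit to ndarray streams."""
    o1, o2 = unit(Tensor(np.asarray(stream1, np.float32)), Tensor(np.asarray(stream2, np.float32)))
    return o1.data, o2.data


def segmentation_loss(pred, truth) -> float:
    """Mean per-pixel binary cross-entropy between a probability map and a
    binary mask."""
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean())


# -- checkpoints ------------------------------------------------------------


def save_checkpoint(model: PixelBNN, path, extra: dict | None = None) -> None:
    """Single-file checkpoint: all arrays + embedded JSON config."""
    state = model.state_arrays()
    meta = {"config": asdict(model.cfg), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[PixelBNN, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = NetworkConfig(**meta["config"])
        model = PixelBNN(cfg, seed=0)
        model.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta["extra"]
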