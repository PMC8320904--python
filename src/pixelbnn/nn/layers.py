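"""Layer modules over the autodiff core: convolutions with Xavier init,
batch norm with running statistics, dropout, and the gated residual unit."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm",
    "GatedResNetUnit",
]


class Module:
    """Parameter container with recursive traversal."""

    def parameters(self) -> list[Parameter]:
        params = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array map of parameters and buffers (for checkpoints)."""
        out = {}

        def walk(mod, prefix):
            for name, v in vars(mod).items():
                key = f"{prefix}{name}"
                if isinstance(v, Parameter):
                    out[key] = v.data
                elif isinstance(v, np.ndarray):
                    out[key] = v
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing arrays: {sorted(missing)[:5]} ...")
        for key, arr in own.items():
            src = np.asarray(state[key])
            if src.shape != arr.shape:
                raise ValueError(f"shape mismatch for {key}: {src.shape} vs {arr.shape}")
            arr[...] = src


def xavier_uniform(shape, fan_in, fan_out, rng) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2d(Module):
    """Same-padded convolution, kernel k, stride 1 or 2; k=1 is the NIN layer."""

    def __init__(self, cin, cout, k, stride=1, *, rng):
        self.stride = stride
        self.weight = Parameter(
            xavier_uniform((k, k, cin, cout), k * k * cin, k * k * cout, rng)
        )
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride)


class ConvTranspose2d(Module):
    """Stride-2 transposed convolution doubling each spatial side."""

    def __init__(self, cin, cout, k=3, stride=2, *, rng):
        self.stride = stride
        self.weight = Parameter(
            xavier_uniform((k, k, cout, cin), k * k * cin, k * k * cout, rng)
        )
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.9):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ad.batch_norm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.eps,
            self.momentum,
            training,
        )


class GatedResNetUnit(Module):
    """Two-stream gated residual unit at width F.

    Stream 1: conv3 -> CReLU -> conv3 producing a 2F pre-activation, to which a
    1x1 NIN projection of the CReLU'd stream-2 features is added; the result is
    split into halves (a, b) and gated as a * sigmoid(b), with a residual
    connection from the stream-1 input. Stream 2 runs an identical conv path
    (its own parameters) with its own gate and residual. With all weights at
    zero both streams reduce to the identity.
    """

    def __init__(self, width, *, rng):
        self.width = width
        self.s1_conv1 = Conv2d(width, width, 3, rng=rng)
        self.s1_conv2 = Conv2d(2 * width, 2 * width, 3, rng=rng)
        self.nin_gate = Conv2d(2 * width, 2 * width, 1, rng=rng)
        self.s2_conv1 = Conv2d(width, width, 3, rng=rng)
        self.s2_conv2 = Conv2d(2 * width, 2 * width, 3, rng=rng)

    def __call__(self, x1: Tensor, x2: Tensor) -> tuple[Tensor, Tensor]:
        if x1.shape != x2.shape:
            raise ValueError(f"stream shape mismatch: {x1.shape} vs {x2.shape}")
        h1 = self.s1_conv2(ad.crelu(self.s1_conv1(x1)))
        h1 = ad.add(h1, self.nin_gate(ad.crelu(x2)))
        a, b = ad.split_half(h1)
        out1 = ad.add(x1, ad.mul(a, ad.sigmoid(b)))

        h2 = self.s2_conv2(ad.crelu(self.s2_conv1(x2)))
        a2, b2 = ad.split_half(h2)
        out2 = ad.add(x2, ad.mul(a2, ad.sigmoid(b2)))
        return out1, out2
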