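"""Minimal reverse-mode automatic differentiation on numpy arrays.

Tensors are NHWC float32 throughout. The op set is exactly what the
segmentation network needs: 2-D convolution (stride 1 and 2, "same"
padding), its adjoint (transposed convolution), batch normalization,
dropout, CReLU, sigmoid gating, channel concat/split, and a fused
sigmoid cross-entropy loss. Convolutions are im2col + matmul; the
column scatter in the backward pass loops only over the k*k kernel
offsets, so everything heavy is BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "conv2d",
    "conv_transpose2d",
    "crelu",
    "sigmoid",
    "concat",
    "split_half",
    "add",
    "mul",
    "dropout",
    "batch_norm",
    "sigmoid_cross_entropy",
]


class Tensor:
    """Node in the autodiff graph holding a float32 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._backward = None
        self._parents = tuple(parents)

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g, fresh=False):
        """Add `g` into the gradient. `fresh=True` promises `g` is newly
        allocated and unaliased, letting us take ownership without a copy."""
        if self.grad is None:
            self.grad = g if fresh and g.dtype == np.float32 else g.astype(np.float32)
        else:
            self.grad += g

    def backward(self):
        """Reverse-mode sweep from this (scalar) tensor."""
        topo: list[Tensor] = []
        seen = set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            # free intermediate grads lazily; parameters keep theirs

    def item(self):
        return float(self.data)


class Parameter(Tensor):
    """Trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def zero_grad(self):
        self.grad = None


# ---------------------------------------------------------------------------
# im2col machinery


def _im2col(x, k, stride, pad):
    """(N,H,W,C) -> (N,Ho,Wo,C,k,k) copy of sliding windows.

    Channel-major window order matches the raw layout of
    ``sliding_window_view`` so the copy needs no axis transpose.
    """
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (N, H', W', C, k, k)
    if stride > 1:
        win = win[:, ::stride, ::stride]
    return np.ascontiguousarray(win)


def _col2im(cols, x_shape, k, stride, pad):
    """Adjoint of _im2col: scatter-add (N,Ho,Wo,C,k,k) windows onto the grid."""
    n, h, w, c = x_shape
    ho, wo = cols.shape[1], cols.shape[2]
    xp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, i : i + ho * stride : stride, j : j + wo * stride : stride, :] += cols[
                :, :, :, :, i, j
            ]
    if pad:
        return np.ascontiguousarray(xp[:, pad : pad + h, pad : pad + w, :])
    return xp


def _wmat(weight):
    """(k,k,Cin,Cout) -> (Cin*k*k, Cout) matching _im2col's (C,k,k) order."""
    k, _, cin, cout = weight.shape
    return np.ascontiguousarray(weight.data.transpose(2, 0, 1, 3)).reshape(
        cin * k * k, cout
    )


def _wmat_grad(dw_mat, weight_shape):
    k, _, cin, cout = weight_shape
    return np.ascontiguousarray(
        dw_mat.reshape(cin, k, k, cout).transpose(1, 2, 0, 3)
    )


def conv2d(x: Tensor, weight: Parameter, bias: Parameter, stride: int = 1) -> Tensor:
    """Same-padded conv; weight (k,k,Cin,Cout). Even sides halve exactly at stride 2."""
    k = weight.shape[0]
    pad = k // 2
    cols = _im2col(x.data, k, stride, pad)
    n, ho, wo = cols.shape[:3]
    cin = x.shape[3]
    cmat = cols.reshape(n * ho * wo, -1)
    wmat = _wmat(weight)
    y = cmat @ wmat + bias.data
    out = Tensor(y.reshape(n, ho, wo, -1), (x, weight, bias))

    def _bw(g):
        gmat = g.reshape(n * ho * wo, -1)
        if weight.requires_grad:
            weight.accumulate(_wmat_grad(cmat.T @ gmat, weight.shape), fresh=True)
        if bias.requires_grad:
            bias.accumulate(gmat.sum(axis=0), fresh=True)
        if x.requires_grad:
            dcols = (gmat @ wmat.T).reshape(n, ho, wo, cin, k, k)
            x.accumulate(_col2im(dcols, x.shape, k, stride, pad), fresh=True)

    out._backward = _bw
    return out


def conv_transpose2d(x: Tensor, weight: Parameter, bias: Parameter, stride: int = 2) -> Tensor:
    """Transposed conv doubling each spatial side; weight (k,k,Cout,Cin).

    Implemented as the exact adjoint of ``conv2d(stride=2)`` from the output
    grid back to the input grid, so shapes mirror the encoder path.
    """
    k = weight.shape[0]
    pad = k // 2
    n, h, w, cin = x.shape
    cout = weight.shape[2]
    out_shape = (n, h * stride, w * stride, cout)
    wmat = _wmat(weight)  # (Cout*k*k, Cin) in (C,k,k) window order
    dcols = (x.data.reshape(-1, cin) @ wmat.T).reshape(n, h, w, cout, k, k)
    y = _col2im(dcols, out_shape, k, stride, pad) + bias.data
    out = Tensor(y, (x, weight, bias))

    def _bw(g):
        gcols = _im2col(g, k, stride, pad)  # (N,h,w,Cout,k,k)
        gmat = gcols.reshape(n * h * w, -1)
        if weight.requires_grad:
            weight.accumulate(
                _wmat_grad(gmat.T @ x.data.reshape(-1, cin), weight.shape), fresh=True
            )
        if bias.requires_grad:
            bias.accumulate(g.sum(axis=(0, 1, 2)), fresh=True)
        if x.requires_grad:
            x.accumulate((gmat @ wmat).reshape(x.shape), fresh=True)

    out._backward = _bw
    return out


def crelu(x: Tensor) -> Tensor:
    """Concatenated ReLU: channel-concat of max(x,0) and max(-x,0)."""
    pos = np.maximum(x.data, 0.0)
    neg = np.maximum(-x.data, 0.0)
    out = Tensor(np.concatenate([pos, neg], axis=-1), (x,))
    c = x.shape[-1]

    def _bw(g):
        x.accumulate(g[..., :c] * (x.data > 0) - g[..., c:] * (x.data < 0), fresh=True)

    out._backward = _bw
    return out


def _stable_sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def sigmoid(x: Tensor) -> Tensor:
    s = _stable_sigmoid(x.data)
    out = Tensor(s, (x,))

    def _bw(g):
        x.accumulate(g * s * (1.0 - s), fresh=True)

    out._backward = _bw
    return out


def concat(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(np.concatenate([a.data, b.data], axis=-1), (a, b))
    ca = a.shape[-1]

    def _bw(g):
        a.accumulate(g[..., :ca])
        b.accumulate(g[..., ca:])

    out._backward = _bw
    return out


def split_half(x: Tensor) -> tuple[Tensor, Tensor]:
    """Split channels into two equal halves (gate pre-activation -> (a, b))."""
    c = x.shape[-1]
    if c % 2:
        raise ValueError("split_half needs an even channel count")
    h = c // 2
    a = Tensor(x.data[..., :h].copy(), (x,))
    b = Tensor(x.data[..., h:].copy(), (x,))

    def _bw_a(g):
        full = np.zeros_like(x.data)
        full[..., :h] = g
        x.accumulate(full, fresh=True)

    def _bw_b(g):
        full = np.zeros_like(x.data)
        full[..., h:] = g
        x.accumulate(full, fresh=True)

    a._backward = _bw_a
    b._backward = _bw_b
    return a, b


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def _bw(g):
        a.accumulate(g)
        b.accumulate(g)

    out._backward = _bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))

    def _bw(g):
        a.accumulate(g * b.data, fresh=True)
        b.accumulate(g * a.data, fresh=True)

    out._backward = _bw
    return out


def dropout(x: Tensor, keep_prob: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or keep_prob >= 1.0:
        return x
    mask = (rng.random(x.shape) < keep_prob).astype(np.float32) / keep_prob
    out = Tensor(x.data * mask, (x,))

    def _bw(g):
        x.accumulate(g * mask, fresh=True)

    out._backward = _bw
    return out


def batch_norm(
    x: Tensor,
    gamma: Parameter,
    beta: Parameter,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    eps: float,
    momentum: float,
    training: bool,
) -> Tensor:
    """Per-channel normalization over (N,H,W); updates running stats in place."""
    if training:
        mean = x.data.mean(axis=(0, 1, 2))
        var = x.data.var(axis=(0, 1, 2))
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mean
        running_var *= momentum
        running_var += (1.0 - momentum) * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv_std
    out = Tensor(xhat * gamma.data + beta.data, (x, gamma, beta))
    m = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]

    def _bw(g):
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=(0, 1, 2)))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=(0, 1, 2)))
        if x.requires_grad or x._parents:
            if training:
                gsum = g.sum(axis=(0, 1, 2))
                gx = (g * xhat).sum(axis=(0, 1, 2))
                dx = (gamma.data * inv_std / m) * (m * g - gsum - xhat * gx)
            else:
                dx = g * gamma.data * inv_std
            x.accumulate(dx.astype(np.float32), fresh=True)

    out._backward = _bw
    return out


def sigmoid_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on sigmoid(logits), numerically fused.

    loss = mean( softplus(z) - t*z ), d/dz = (sigmoid(z) - t) / n.
    """
    z = logits.data
    t = np.asarray(targets, dtype=np.float32)
    if t.shape != z.shape:
        raise ValueError(f"target shape {t.shape} != logit shape {z.shape}")
    softplus = np.logaddexp(0.0, z)
    out = Tensor(np.float32((softplus - t * z).mean()), (logits,))
    n = z.size

    def _bw(g):
        s = _stable_sigmoid(z)
        logits.accumulate((g * (s - t) / n).astype(np.float32), fresh=True)

    out._backward = _bw
    return out
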