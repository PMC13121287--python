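"""Neural-network layers built on the autodiff core.

Parameters are float32 by default.  Initialization follows the usual
fan-in scaled schemes; every layer draws from the ``numpy.random.Generator``
passed at construction so whole models are reproducible from one seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "Conv2d",
    "max_pool2d",
    "upsample_nearest2x",
    "Sequential",
]


class Module:
    """Base class: recursive parameter discovery and flat state dicts."""

    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[name] = v
            elif isinstance(v, Module):
                out.update(v.named_parameters(prefix=name + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{name}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{name}.{i}"] = item
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(arr: np.ndarray) -> Tensor:
    return Tensor(arr.astype(np.float32), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = np.sqrt(1.0 / in_features)
        self.weight = _param(rng.uniform(-scale, scale, size=(in_features, out_features)))
        self.bias = _param(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = _param(np.ones(dim))
        self.beta = _param(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gamma + self.beta


class Conv2d(Module):
    """3x3 (or kxk) stride-1 'same' convolution via im2col matmul."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("Conv2d supports odd kernel sizes only")
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU chains
        self.weight = _param(rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel)))
        self.bias = _param(np.zeros(out_ch))
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        k = self.kernel
        pad = k // 2
        B, C, H, W = x.data.shape
        F = self.weight.data.shape[0]
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # win: (B, C, H, W, k, k) -> cols (B, H*W, C*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * k * k)
        Wmat = self.weight.data.reshape(F, C * k * k)
        out_data = (cols @ Wmat.T + self.bias.data).transpose(0, 2, 1).reshape(B, F, H, W)

        weight, bias = self.weight, self.bias

        def backward(g):
            gmat = g.reshape(B, F, H * W).transpose(0, 2, 1)  # (B, HW, F)
            if weight.requires_grad:
                gw = np.einsum("bpf,bpc->fc", gmat, cols, optimize=True)
                weight._accum(gw.reshape(weight.data.shape))
                bias._accum(gmat.sum(axis=(0, 1)))
            if x.requires_grad:
                gcols = gmat @ Wmat  # (B, HW, C*k*k)
                gcols = gcols.reshape(B, H, W, C, k, k)
                gx = np.zeros_like(xp)
                for di in range(k):
                    for dj in range(k):
                        gx[:, :, di:di + H, dj:dj + W] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
                x._accum(gx[:, :, pad:pad + H, pad:pad + W])

        return Tensor._make(out_data, (x, weight, bias), backward)


def max_pool2d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling; spatial dims must be divisible by size."""
    B, C, H, W = x.data.shape
    if H % size or W % size:
        raise ValueError(f"spatial dims {(H, W)} not divisible by pool size {size}")
    h, w = H // size, W // size
    blocks = x.data.reshape(B, C, h, size, w, size).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(B, C, h, w, size * size)
    out_data = flat.max(axis=-1)
    # break ties deterministically: route gradient to the first max per block
    eq = flat == out_data[..., None]
    mask = eq & (np.cumsum(eq, axis=-1) == 1)

    def backward(g):
        gb = mask * g[..., None]
        gb = gb.reshape(B, C, h, w, size, size).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gb.reshape(B, C, H, W))

    return Tensor._make(out_data, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        gb = g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5))
        x._accum(gb)

    return Tensor._make(out_data, (x,), backward)


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x) if isinstance(m, Module) else m(x)
        return x
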