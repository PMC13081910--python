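"""Neural-network building blocks on top of :mod:`epigat.autodiff`.

Generic layers only — everything specific to the masked-graph-attention
architecture (gates, MSA blocks, graph attention) lives in
:mod:`epigat.mga_model`.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, masked_softmax


class Module:
    """Tiny module system: registers parameters and submodules by attribute."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name if prefix else name), p
        for name, m in self._modules.items():
            sub = (prefix + name if prefix else name) + "."
            yield from m.named_parameters(sub)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict, strict: bool = True):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if strict and (missing or extra):
            raise KeyError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, p in own.items():
            if name in state:
                arr = np.asarray(state[name], dtype=np.float64)
                if arr.shape != p.data.shape:
                    raise ValueError(f"shape mismatch for parameter {name}: {arr.shape} vs {p.data.shape}")
                p.data = arr.copy()


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = _param(rng, (d_in, d_out), np.sqrt(2.0 / (d_in + d_out)))
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        object.__setattr__(self, "eps", eps)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Self-attention over the second-to-last axis of ``[..., T, D]`` inputs.

    ``key_mask`` (bool, broadcastable to ``[..., T]``) marks valid keys;
    masked keys receive exactly zero attention weight, and fully masked
    queries produce a zero context vector.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ValueError(f"embedding dim {dim} not divisible by {heads} heads")
        object.__setattr__(self, "heads", heads)
        object.__setattr__(self, "dh", dim // heads)
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray):
        *lead, T, D = x.shape
        H, dh = self.heads, self.dh

        def split(t: Tensor) -> Tensor:
            # [..., T, D] -> [..., H, T, dh]
            t = t.reshape(*lead, T, H, dh)
            return t.swapaxes(-2, -3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) / np.sqrt(dh)
        km = np.broadcast_to(np.asarray(key_mask, dtype=bool), tuple(lead) + (T,))
        attn = masked_softmax(scores, km[..., None, None, :])
        ctx = attn @ v  # [..., H, T, dh]
        ctx = ctx.swapaxes(-2, -3).reshape(*lead, T, D)
        return self.wo(ctx), attn


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class Dropout(Module):
    """Inverted dropout driven by an explicit generator for reproducibility."""

    def __init__(self, rate: float):
        super().__init__()
        object.__setattr__(self, "rate", float(rate))

    def __call__(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        if not self.training or self.rate <= 0.0 or rng is None:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep).astype(np.float64) / keep
        return x * Tensor(mask)
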