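"""Neural-network building blocks on top of :mod:`odorgraph.autodiff`.

Layers are deliberately plain: a module owns named parameter tensors, exposes
``__call__`` for the forward pass, and enumerates its parameters for the
optimizer and for checkpointing.  Initialization is fully determined by the
NumPy Generator handed in, so a fixed seed reproduces a network bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Module:
    def named_parameters(self) -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((name, value))
            elif isinstance(value, Module):
                out.extend((f"{name}.{sub}", p) for sub, p in value.named_parameters())
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(
                            (f"{name}.{i}.{sub}", p) for sub, p in item.named_parameters()
                        )
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int, bias: bool = True):
        self.weight = Tensor(glorot(rng, d_in, d_out), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps
        self.dim = dim

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return self.gamma * (centered * (var + self.eps) ** -0.5) + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, rng: np.random.Generator, d_model: int, n_heads: int, bias: bool = True):
        if d_model % n_heads:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q_proj = Linear(rng, d_model, d_model, bias)
        self.k_proj = Linear(rng, d_model, d_model, bias)
        self.v_proj = Linear(rng, d_model, d_model, bias)
        self.out_proj = Linear(rng, d_model, d_model, bias)

    def _split(self, x: Tensor, batch: int, seq: int) -> Tensor:
        # (B, S, D) -> (B, H, S, Dh)
        return x.reshape(batch, seq, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        batch, seq, d_model = x.shape
        q = self._split(self.q_proj(x), batch, seq)
        k = self._split(self.k_proj(x), batch, seq)
        v = self._split(self.v_proj(x), batch, seq)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (self.d_head ** -0.5)
        attn = scores.softmax()
        mixed = (attn @ v).transpose(0, 2, 1, 3).reshape(batch, seq, d_model)
        return self.out_proj(mixed)


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: attention and feed-forward, each with a residual."""

    def __init__(
        self,
        rng: np.random.Generator,
        d_model: int,
        n_heads: int,
        d_ff: int,
        bias: bool = True,
    ):
        self.attn = MultiHeadSelfAttention(rng, d_model, n_heads, bias)
        self.norm1 = LayerNorm(d_model)
        self.ff1 = Linear(rng, d_model, d_ff, bias)
        self.ff2 = Linear(rng, d_ff, d_model, bias)
        self.norm2 = LayerNorm(d_model)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x))
        return self.norm2(x + self.ff2(self.ff1(x).selu()))


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
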