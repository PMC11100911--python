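"""Small neural-network toolkit on top of :mod:`keydiff.autodiff`.

Provides parameter containers, linear layers and MLPs with seeded Xavier
initialisation, an Adam optimiser, and radial-basis distance expansion.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, silu

__all__ = ["Module", "Linear", "MLP", "Adam", "clip_gradients", "rbf_expand", "RBF_NUM", "RBF_MAX"]

RBF_NUM = 16
RBF_MAX = 10.0  # Å


class Module:
    """Base class: anything whose attributes are Tensors or sub-Modules."""

    def parameters(self) -> list[Tensor]:
        def collect(value, out):
            if isinstance(value, Tensor):
                if value.requires_grad:
                    out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    collect(item, out)

        params: list[Tensor] = []
        for value in self.__dict__.values():
            collect(value, params)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class MLP(Module):
    """Two-layer perceptron with SiLU activation (optionally on the output)."""

    def __init__(
        self,
        n_in: int,
        n_hidden: int,
        n_out: int,
        rng: np.random.Generator,
        out_activation: bool = False,
    ):
        self.lin1 = Linear(n_in, n_hidden, rng)
        self.lin2 = Linear(n_hidden, n_out, rng)
        self.out_activation = out_activation

    def __call__(self, x: Tensor) -> Tensor:
        h = silu(self.lin1(x))
        h = self.lin2(h)
        return silu(h) if self.out_activation else h


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def clip_gradients(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``.

    The denoising loss carries a (α_t/σ_t)² weight that is very large at
    small t, so occasional batches produce outsized gradients; clipping
    keeps optimisation stable without changing the loss itself.  Returns
    the pre-clip norm.
    """
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad**2))
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


_RBF_CENTERS = np.linspace(0.0, RBF_MAX, RBF_NUM)
_RBF_GAMMA = (RBF_MAX / (RBF_NUM - 1)) ** -2


def rbf_expand(dist: Tensor) -> Tensor:
    """Expand distances (E,1) into Gaussian radial basis features (E, 16).

    Centres span 0–10 Å; widths equal the centre spacing.  Differentiable in
    the distances so coordinate gradients flow through edge features.
    """
    centers = Tensor(_RBF_CENTERS.reshape(1, -1))
    diff = dist - centers
    return (-(diff * diff) * _RBF_GAMMA).exp()
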