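"""Equivariant message-passing backbones: EGNN-style and GVP-style layers.

Both layers consume only relative geometry (distances, relative directions),
so scalar outputs are invariant and geometric outputs equivariant under
rigid motions of the input:

* EGNN: each node carries scalar features ``h`` and one position ``x``.
  Messages m_ij = φ_e(h_i, h_j, ‖x_i−x_j‖²); positions update along relative
  directions, x_i ← x_i + Σ_j (x_i−x_j)·φ_x(m_ij)/(‖x_i−x_j‖+1); features
  update as h_i ← h_i + φ_h(h_i, Σ_j m_ij).

* GVP: nodes additionally carry ``c`` vector features v ∈ R^{c×3}.  Message
  and update functions are geometric vector perceptrons: vector channels are
  mixed by rotation-equivariant linear maps and gated by sigmoids of
  invariant scalars; vector norms feed back into the scalar track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concat, segment_sum, silu, take_rows, vecmix
from .nn import MLP, Linear, Module, RBF_NUM, rbf_expand

__all__ = ["NodeState", "EGNNLayer", "GVP", "GVPLayer", "egnn_layer", "gvp_layer"]

_D2_SCALE = 0.01  # squared distances (Å²) scaled to O(1) before the MLPs
_EPS = 1e-12


@dataclass
class NodeState:
    """Per-node state: scalars h, position x, optional vector features v."""

    h: np.ndarray  # (d,)
    x: np.ndarray  # (3,)
    v: np.ndarray | None = None  # (c, 3)


def _stack_states(states: list[NodeState]):
    h = Tensor(np.stack([s.h for s in states]))
    x = Tensor(np.stack([s.x for s in states]))
    v = None
    if states[0].v is not None:
        v = Tensor(np.stack([s.v for s in states]))
    return h, x, v


def _unstack_states(h, x, v) -> list[NodeState]:
    n = h.data.shape[0]
    return [
        NodeState(
            h=h.data[i].copy(),
            x=x.data[i].copy(),
            v=None if v is None else v.data[i].copy(),
        )
        for i in range(n)
    ]


def _edge_arrays(edges) -> tuple[np.ndarray, np.ndarray]:
    e = np.asarray(edges, dtype=np.intp).reshape(-1, 2)
    return e[:, 0], e[:, 1]


def _incoming_counts(dst: np.ndarray, n: int) -> np.ndarray:
    counts = np.bincount(dst, minlength=n).astype(np.float64)
    return np.maximum(counts, 1.0)


class EGNNLayer(Module):
    """One E(3)-equivariant graph convolution."""

    def __init__(self, d: int, rng: np.random.Generator, d_msg: int | None = None):
        d_msg = d_msg or d
        self.d = d
        self.phi_e = MLP(2 * d + 1 + RBF_NUM, d_msg, d_msg, rng, out_activation=True)
        self.phi_x = Linear(d_msg, 1, rng, bias=False)
        self.phi_h = MLP(d + d_msg, d_msg, d, rng)

    def __call__(
        self,
        h: Tensor,
        x: Tensor,
        edges,
        movable_mask: np.ndarray | None = None,
        update_mask: np.ndarray | None = None,
    ) -> tuple[Tensor, Tensor]:
        h, x = as_tensor(h), as_tensor(x)
        n = h.shape[0]
        src, dst = _edge_arrays(edges)
        if src.size == 0:
            return h, x
        xi, xj = take_rows(x, dst), take_rows(x, src)
        diff = xi - xj
        d2 = (diff * diff).sum(axis=-1, keepdims=True)
        dist = (d2 + _EPS).sqrt()
        m = self.phi_e(
            concat([take_rows(h, dst), take_rows(h, src), d2 * _D2_SCALE, rbf_expand(dist)])
        )
        # position update along relative directions (only for movable nodes)
        w = self.phi_x(m)
        dx = segment_sum(diff * (w / (dist + 1.0)), dst, n)
        if movable_mask is not None:
            dx = dx * Tensor(np.asarray(movable_mask, dtype=np.float64).reshape(-1, 1))
        x_new = x + dx
        # feature update
        agg = segment_sum(m, dst, n)
        dh = self.phi_h(concat([h, agg]))
        if update_mask is not None:
            dh = dh * Tensor(np.asarray(update_mask, dtype=np.float64).reshape(-1, 1))
        return h + dh, x_new


class GVP(Module):
    """Geometric vector perceptron: (s, V) → (s', V').

    Vector channels are mixed linearly (rotation-equivariant), their norms
    join the scalar track, and output vectors are gated by sigmoids of the
    scalar output.
    """

    def __init__(
        self,
        s_in: int,
        v_in: int,
        s_out: int,
        v_out: int,
        rng: np.random.Generator,
        activate: bool = True,
    ):
        v_hidden = max(v_in, v_out)
        self.w_h = Tensor(rng.normal(0.0, np.sqrt(1.0 / v_in), size=(v_hidden, v_in)), requires_grad=True)
        self.w_mu = Tensor(rng.normal(0.0, np.sqrt(1.0 / v_hidden), size=(v_out, v_hidden)), requires_grad=True)
        self.scalar = Linear(s_in + v_hidden, s_out, rng)
        self.gate = Linear(s_out, v_out, rng)
        self.activate = activate

    def __call__(self, s: Tensor, v: Tensor) -> tuple[Tensor, Tensor]:
        vh = vecmix(self.w_h, v)
        norms = ((vh * vh).sum(axis=-1) + 1e-8).sqrt()
        s_pre = self.scalar(concat([s, norms]))
        v_mu = vecmix(self.w_mu, vh)
        gates = self.gate(s_pre).sigmoid()
        n, c = gates.shape
        v_out = v_mu * gates.reshape(n, c, 1)
        s_out = silu(s_pre) if self.activate else s_pre
        return s_out, v_out


class GVPLayer(Module):
    """Message passing with GVP message and update functions.

    Positions are never updated; relative geometry enters through the unit
    inter-node direction (an extra vector channel) and RBF-expanded
    distances.  Incoming messages are mean-aggregated.
    """

    def __init__(self, d: int, c: int, rng: np.random.Generator):
        self.d, self.c = d, c
        self.message = GVP(2 * d + RBF_NUM, c + 1, d, c, rng, activate=True)
        self.update = GVP(2 * d, 2 * c, d, c, rng, activate=False)

    def __call__(
        self,
        h: Tensor,
        x: Tensor,
        v: Tensor,
        edges,
        update_mask: np.ndarray | None = None,
    ) -> tuple[Tensor, Tensor]:
        h, x, v = as_tensor(h), as_tensor(x), as_tensor(v)
        n = h.shape[0]
        src, dst = _edge_arrays(edges)
        if src.size == 0:
            return h, v
        diff = take_rows(x, dst) - take_rows(x, src)
        dist = ((diff * diff).sum(axis=-1, keepdims=True) + _EPS).sqrt()
        unit = diff / dist
        e = src.size
        s_edge = concat([take_rows(h, dst), take_rows(h, src), rbf_expand(dist)])
        v_edge = concat([take_rows(v, src), unit.reshape(e, 1, 3)], axis=1)
        s_msg, v_msg = self.message(s_edge, v_edge)
        inv_counts = (1.0 / _incoming_counts(dst, n)).reshape(-1, 1)
        s_agg = segment_sum(s_msg, dst, n) * Tensor(inv_counts)
        v_agg = segment_sum(v_msg, dst, n) * Tensor(inv_counts.reshape(-1, 1, 1))
        ds, dv = self.update(concat([h, s_agg]), concat([v, v_agg], axis=1))
        if update_mask is not None:
            mask = np.asarray(update_mask, dtype=np.float64)
            ds = ds * Tensor(mask.reshape(-1, 1))
            dv = dv * Tensor(mask.reshape(-1, 1, 1))
        return h + ds, v + dv


def egnn_layer(states: list[NodeState], edges, params: EGNNLayer) -> list[NodeState]:
    """Functional wrapper over :class:`EGNNLayer` on per-node states."""
    h, x, _ = _stack_states(states)
    h_new, x_new = params(h, x, edges)
    return _unstack_states(h_new, x_new, None)


def gvp_layer(states: list[NodeState], edges, params: GVPLayer) -> list[NodeState]:
    """Functional wrapper over :class:`GVPLayer` on per-node states."""
    if states[0].v is None:
        raise ValueError("GVP layer requires vector features on every node")
    h, x, v = _stack_states(states)
    h_new, v_new = params(h, x, v, edges)
    return [
        NodeState(h=h_new.data[i].copy(), x=states[i].x.copy(), v=v_new.data[i].copy())
        for i in range(len(states))
    ]
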