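"""Pocket encoder: compress an all-atom pocket into K learned keypoints.

Pipeline (in order): message passing between pocket atoms → attention-based
keypoint placement → graph rewiring (keep only the nearest pocket atoms per
keypoint) → pocket→keypoint message passing to give keypoints spatially
localized features.

Keypoint positions are attention-weighted convex combinations of pocket atom
positions, computed from K learned queries per head against keys derived
from the (rotation-invariant) pocket embeddings.  Placement is therefore
rigid-motion equivariant and every keypoint lies inside the convex hull of
the pocket atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .autodiff import Tensor, concat, softmax_rows
from .core import AtomCloud, ElementVocabulary
from .nets import EGNNLayer, GVPLayer
from .nn import Linear, Module, RBF_NUM, rbf_expand
from ._graphs import cloud_cutoff_edges

__all__ = [
    "EncoderConfig",
    "KeypointCloud",
    "AttentionWeights",
    "PocketEncoder",
    "place_keypoints",
    "rewire",
    "encode_pocket",
]


@dataclass(frozen=True)
class EncoderConfig:
    n_keypoints: int = 40  # K
    n_heads: int = 4
    n_rewire: int = 8  # nearest pocket atoms feeding each keypoint
    placement_rounds: int = 2  # attention rounds; later rounds see distances
    pocket_rounds: int = 2
    keypoint_rounds: int = 2
    backbone: str = "gvp"  # or "egnn"
    d: int = 64  # scalar feature width
    c: int = 16  # vector channels (gvp backbone)
    d_key: int = 16  # attention key/query width
    pocket_cutoff: float = 4.5  # Å, pocket-pocket edges

    def __post_init__(self):
        if self.n_keypoints < 1:
            raise ValueError("need at least one keypoint")
        if self.n_rewire < 1:
            raise ValueError("n_rewire must be >= 1")
        if self.backbone not in ("egnn", "gvp"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


@dataclass
class KeypointCloud:
    """Fixed-size latent pocket representation: K nodes with positions (Å),
    scalar features and (GVP backbone) vector features."""

    positions: np.ndarray  # (K, 3)
    scalars: np.ndarray  # (K, d)
    vectors: np.ndarray | None = None  # (K, c, 3)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        self.scalars = np.asarray(self.scalars, dtype=np.float64)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("keypoint positions must be finite")
        if self.scalars.shape[0] != self.positions.shape[0]:
            raise ValueError("positions/scalars disagree on K")

    @property
    def n_keypoints(self) -> int:
        return self.positions.shape[0]


@dataclass
class AttentionWeights:
    """Row-stochastic K×N matrix of placement weights."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if np.any(w < -1e-12):
            raise ValueError("attention weights must be nonnegative")
        if not np.allclose(w.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("attention rows must sum to 1")
        self.weights = w


def rewire(keypoint_positions: np.ndarray, pocket: AtomCloud, n_rewire: int) -> np.ndarray:
    """Pocket→keypoint edges from the ``min(n_rewire, N)`` nearest atoms.

    Returns an (E, 2) array of (pocket_index, keypoint_index) pairs; ties in
    distance break by pocket atom index (stable sort), so the edge set is
    deterministic.
    """
    kp = np.asarray(getattr(keypoint_positions, "positions", keypoint_positions), dtype=np.float64)
    d = cdist(kp, pocket.positions)
    n_keep = min(n_rewire, pocket.n_atoms)
    pairs = []
    for i in range(kp.shape[0]):
        nearest = np.argsort(d[i], kind="stable")[:n_keep]
        for j in sorted(nearest):
            pairs.append((j, i))
    return np.asarray(pairs, dtype=np.intp).reshape(-1, 2)


class PocketEncoder(Module):
    """E_θ: all-atom pocket cloud → fixed-size keypoint cloud."""

    def __init__(self, vocab: ElementVocabulary, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.vocab = vocab
        d, c, K = cfg.d, cfg.c, cfg.n_keypoints
        self.embed = Linear(vocab.size, d, rng)
        if cfg.backbone == "egnn":
            self.pocket_layers = [EGNNLayer(d, rng) for _ in range(cfg.pocket_rounds)]
            self.keypoint_layers = [EGNNLayer(d, rng) for _ in range(cfg.keypoint_rounds)]
        else:
            self.pocket_layers = [GVPLayer(d, c, rng) for _ in range(cfg.pocket_rounds)]
            self.keypoint_layers = [GVPLayer(d, c, rng) for _ in range(cfg.keypoint_rounds)]
        # one learned query per keypoint per head and per placement round;
        # keys from pocket node embeddings.  Rounds after the first add a
        # learned function of the distance to the provisional placement to
        # the attention logits (edge-featured graph attention), which lets a
        # keypoint weigh "local patch" against "far counterweight" atoms and
        # sharpen its position.
        self.queries = Tensor(
            rng.normal(0.0, 1.0, size=(cfg.placement_rounds, cfg.n_heads, K, cfg.d_key)),
            requires_grad=True,
        )
        self.keys = [
            [Linear(d, cfg.d_key, rng, bias=False) for _ in range(cfg.n_heads)]
            for _ in range(cfg.placement_rounds)
        ]
        self.dist_logits = [
            [Linear(RBF_NUM, 1, rng, bias=False) for _ in range(cfg.n_heads)]
            for _ in range(max(0, cfg.placement_rounds - 1))
        ]
        self.keypoint_embed = Tensor(rng.normal(0.0, 0.1, size=(K, d)), requires_grad=True)

    # ------------------------------------------------------------- placement
    def place_keypoints(self, embeddings: Tensor, positions: Tensor) -> tuple[Tensor, Tensor]:
        """Dot-product attention placement, iterated over placement rounds.

        Every round computes row-stochastic weights over pocket atoms and
        sets each keypoint to the weighted mean position (hence always
        inside the convex hull).  The first round scores atoms by content
        alone; later rounds add a learned function of the RBF-expanded
        distance between each atom and the keypoint's provisional position,
        so placements can sharpen around (or counterbalance against) the
        previous estimate.  Returns the final ``(positions (K,3),
        weights (K,N))`` with weights averaged over heads.
        """
        cfg = self.cfg
        K = cfg.n_keypoints
        n = positions.shape[0]
        scale = 1.0 / np.sqrt(cfg.d_key)
        kp_pos = None
        weights = None
        for rnd in range(cfg.placement_rounds):
            head_weights = []
            for head in range(cfg.n_heads):
                keys = self.keys[rnd][head](embeddings)  # (N, d_key)
                logits = (self.queries[rnd, head] @ _transpose(keys)) * scale  # (K, N)
                if rnd > 0:
                    diff = kp_pos.reshape(K, 1, 3) - positions.reshape(1, n, 3)
                    dist = ((diff * diff).sum(axis=-1, keepdims=True) + 1e-12).sqrt()
                    dfeat = self.dist_logits[rnd - 1][head](rbf_expand(dist.reshape(K * n, 1)))
                    logits = logits + dfeat.reshape(K, n)
                head_weights.append(softmax_rows(logits))
            weights = head_weights[0]
            for w in head_weights[1:]:
                weights = weights + w
            weights = weights * (1.0 / cfg.n_heads)
            kp_pos = weights @ positions
        return kp_pos, weights

    # -------------------------------------------------------------- pipeline
    def encode_tensors(self, pocket: AtomCloud):
        """Full pipeline returning autodiff tensors (used in training)."""
        cfg = self.cfg
        n = pocket.n_atoms
        K = cfg.n_keypoints
        x = Tensor(pocket.positions)
        h = self.embed(Tensor(pocket.features))
        v = Tensor(np.zeros((n, cfg.c, 3))) if cfg.backbone == "gvp" else None
        pocket_edges = cloud_cutoff_edges(pocket, cfg.pocket_cutoff)
        for layer in self.pocket_layers:
            if cfg.backbone == "egnn":
                h, _ = layer(h, x, pocket_edges, movable_mask=np.zeros(n))
            else:
                h, v = layer(h, x, v, pocket_edges)
        kp_pos, weights = self.place_keypoints(h, x)

        bip = rewire(kp_pos.data, pocket, cfg.n_rewire)
        # combined node array: [pocket | keypoints]; edges pocket→keypoint only
        edges = np.stack([bip[:, 0], bip[:, 1] + n], axis=1)
        h_all = concat([h, self.keypoint_embed], axis=0)
        x_all = concat([x, kp_pos], axis=0)
        update_mask = np.concatenate([np.zeros(n), np.ones(K)])
        if cfg.backbone == "gvp":
            v_all = concat([v, Tensor(np.zeros((K, cfg.c, 3)))], axis=0)
            for layer in self.keypoint_layers:
                h_all, v_all = layer(h_all, x_all, v_all, edges, update_mask=update_mask)
            kp_v = h_all[n:], v_all[n:]
            return kp_pos, kp_v[0], kp_v[1], weights
        for layer in self.keypoint_layers:
            h_all, _ = layer(
                h_all, x_all, edges, movable_mask=np.zeros(n + K), update_mask=update_mask
            )
        return kp_pos, h_all[n:], None, weights

    def encode_tensors_batch(self, pockets: list[AtomCloud]):
        """Encode several pockets in one pass over a disjoint union graph.

        Message passing runs once on the concatenated node arrays (edges
        offset per pocket); only the attention placement loops over pockets.
        Returns a list of ``(kp_pos, kp_scalars, kp_vectors, weights)``
        tensor tuples, one per pocket, equal to per-pocket encoding.
        """
        cfg = self.cfg
        K = cfg.n_keypoints
        sizes = [p.n_atoms for p in pockets]
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        n_tot = int(offsets[-1])
        x = Tensor(np.vstack([p.positions for p in pockets]))
        h = self.embed(Tensor(np.vstack([p.features for p in pockets])))
        v = Tensor(np.zeros((n_tot, cfg.c, 3))) if cfg.backbone == "gvp" else None
        edges = np.concatenate(
            [cloud_cutoff_edges(p, cfg.pocket_cutoff) + offsets[b] for b, p in enumerate(pockets)],
            axis=0,
        )
        for layer in self.pocket_layers:
            if cfg.backbone == "egnn":
                h, _ = layer(h, x, edges, movable_mask=np.zeros(n_tot))
            else:
                h, v = layer(h, x, v, edges)

        kp_pos_list, weights_list = [], []
        bip_edges = []
        for b, pocket in enumerate(pockets):
            lo, hi = int(offsets[b]), int(offsets[b + 1])
            kp_pos_b, w_b = self.place_keypoints(h[lo:hi], x[lo:hi])
            kp_pos_list.append(kp_pos_b)
            weights_list.append(w_b)
            bip = rewire(kp_pos_b.data, pocket, cfg.n_rewire)
            bip_edges.append(
                np.stack([bip[:, 0] + lo, bip[:, 1] + n_tot + b * K], axis=1)
            )
        all_edges = np.concatenate(bip_edges, axis=0)
        h_all = concat([h] + [self.keypoint_embed] * len(pockets), axis=0)
        x_all = concat([x] + kp_pos_list, axis=0)
        update_mask = np.concatenate([np.zeros(n_tot), np.ones(K * len(pockets))])
        if cfg.backbone == "gvp":
            v_all = concat([v, Tensor(np.zeros((K * len(pockets), cfg.c, 3)))], axis=0)
            for layer in self.keypoint_layers:
                h_all, v_all = layer(h_all, x_all, v_all, all_edges, update_mask=update_mask)
        else:
            for layer in self.keypoint_layers:
                h_all, _ = layer(
                    h_all,
                    x_all,
                    all_edges,
                    movable_mask=np.zeros(n_tot + K * len(pockets)),
                    update_mask=update_mask,
                )
        out = []
        for b in range(len(pockets)):
            lo = n_tot + b * K
            kp_h = h_all[lo : lo + K]
            kp_v = v_all[lo : lo + K] if cfg.backbone == "gvp" else None
            out.append((kp_pos_list[b], kp_h, kp_v, weights_list[b]))
        return out

    def __call__(self, pocket: AtomCloud) -> KeypointCloud:
        kp_pos, kp_h, kp_v, _ = self.encode_tensors(pocket)
        return KeypointCloud(
            positions=kp_pos.data.copy(),
            scalars=kp_h.data.copy(),
            vectors=None if kp_v is None else kp_v.data.copy(),
        )


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, requires_grad=t.requires_grad, parents=(t,))

    def backward(g):
        if t.requires_grad:
            t._accumulate(g.T)

    out._backward = backward
    return out


def place_keypoints(
    pocket: AtomCloud, pocket_embeddings, params: PocketEncoder, cfg: EncoderConfig | None = None
) -> tuple[np.ndarray, AttentionWeights]:
    """Functional surface over :meth:`PocketEncoder.place_keypoints`."""
    emb = pocket_embeddings if isinstance(pocket_embeddings, Tensor) else Tensor(pocket_embeddings)
    pos, weights = params.place_keypoints(emb, Tensor(pocket.positions))
    return pos.data.copy(), AttentionWeights(weights.data.copy())


def encode_pocket(
    pocket: AtomCloud, params: PocketEncoder, cfg: EncoderConfig | None = None
) -> KeypointCloud:
    """Encode a pocket with a given (trained or freshly initialised) encoder."""
    if pocket.n_atoms < 1:
        raise ValueError("empty pocket")
    return params(pocket)
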