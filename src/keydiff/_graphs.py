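"""Shared edge-list helpers for the network modules."""

from __future__ import annotations

import numpy as np

from .core import _complete_pairs, _cutoff_pairs


def cutoff_edges(positions: np.ndarray, cutoff: float) -> np.ndarray:
    """All ordered pairs (j, i), j != i, with distance strictly under cutoff."""
    positions = np.asarray(positions, dtype=np.float64)
    return _cutoff_pairs(positions, positions, cutoff, same=True)


def cloud_cutoff_edges(cloud, cutoff: float) -> np.ndarray:
    """Cutoff edges for an AtomCloud, memoised on the cloud (the cache is
    shared across translated copies, since translation preserves edges)."""
    cache = cloud.__dict__.setdefault("_edge_cache", {})
    if cutoff not in cache:
        cache[cutoff] = cutoff_edges(cloud.positions, cutoff)
    return cache[cutoff]


def complete_edges(n: int) -> np.ndarray:
    """All ordered pairs (j, i), j != i."""
    return _complete_pairs(n, n, same=True)


def complete_bipartite_edges(n_a: int, n_b: int, offset_a: int, offset_b: int) -> np.ndarray:
    """Both directions of the complete bipartite edge set, in a combined
    node indexing where set A starts at ``offset_a`` and B at ``offset_b``."""
    a = np.arange(n_a) + offset_a
    b = np.arange(n_b) + offset_b
    ab = np.stack(np.meshgrid(a, b, indexing="ij"), axis=-1).reshape(-1, 2)
    return np.concatenate([ab, ab[:, ::-1]], axis=0)
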