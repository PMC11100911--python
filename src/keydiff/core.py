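"""Point-cloud and heterogeneous-graph data model.

Molecules and binding pockets are geometric point clouds: per-atom 3D
positions in Å and a categorical type feature per node (one-hot when clean,
real-valued once noised by the diffusion process).  Graphs over these clouds
are purely geometric — edges exist between nodes closer than a per-edge-type
cutoff, with no notion of chemical bonds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ElementVocabulary",
    "AtomCloud",
    "HeteroGraph",
    "GraphBuildConfig",
    "build_hetero_graph",
    "center_on_pocket",
]


@dataclass(frozen=True)
class ElementVocabulary:
    """Ordered categorical label set; its size is the feature dimension."""

    symbols: tuple[str, ...]

    def __post_init__(self):
        if len(self.symbols) < 1:
            raise ValueError("vocabulary must contain at least one symbol")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("vocabulary symbols must be unique")
        object.__setattr__(self, "symbols", tuple(self.symbols))

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise KeyError(f"element {symbol!r} not in vocabulary {self.symbols}") from None

    def one_hot(self, symbols: list[str]) -> np.ndarray:
        out = np.zeros((len(symbols), self.size))
        for i, s in enumerate(symbols):
            out[i, self.index(s)] = 1.0
        return out

    def decode(self, features: np.ndarray) -> list[str]:
        return [self.symbols[i] for i in np.argmax(np.asarray(features), axis=1)]


LIGAND_VOCAB = ElementVocabulary(("C", "N", "O", "F"))
PROTEIN_VOCAB = ElementVocabulary(("C", "N", "O", "S"))


@dataclass
class AtomCloud:
    """N atoms with 3D positions (Å) and per-node categorical features."""

    positions: np.ndarray  # (N, 3)
    features: np.ndarray  # (N, f)
    kind: str = "ligand"  # "ligand" or "pocket"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if self.positions.shape[0] < 1:
            raise ValueError("cloud must contain at least one atom")
        if self.features.shape[0] != self.positions.shape[0]:
            raise ValueError("positions and features disagree on N")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.kind not in ("ligand", "pocket"):
            raise ValueError("kind must be 'ligand' or 'pocket'")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def translated(self, offset: np.ndarray) -> "AtomCloud":
        out = replace(self, positions=self.positions + np.asarray(offset, dtype=np.float64))
        # distance graphs are translation invariant; share the edge cache
        out.__dict__["_edge_cache"] = self.__dict__.setdefault("_edge_cache", {})
        return out

    def is_one_hot(self, atol: float = 1e-8) -> bool:
        f = self.features
        if not np.allclose(f.sum(axis=1), 1.0, atol=atol):
            return False
        return bool(np.all((np.abs(f) < atol) | (np.abs(f - 1.0) < atol)))


@dataclass
class HeteroGraph:
    """Typed node sets and typed directed edge lists.

    Edge lists are keyed by ``(src_kind, dst_kind)``; each is an (E, 2) int
    array of (src_index, dst_index) pairs into the respective node sets.
    Pocket→keypoint edges are unidirectional by construction.
    """

    node_counts: dict[str, int]
    edges: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for key, e in self.edges.items():
            e = np.asarray(e, dtype=np.intp).reshape(-1, 2)
            self.edges[key] = e
            src_kind, dst_kind = key
            if e.size:
                if e[:, 0].min() < 0 or e[:, 0].max() >= self.node_counts[src_kind]:
                    raise ValueError(f"edge source index out of range for {key}")
                if e[:, 1].min() < 0 or e[:, 1].max() >= self.node_counts[dst_kind]:
                    raise ValueError(f"edge destination index out of range for {key}")
                if src_kind == dst_kind and np.any(e[:, 0] == e[:, 1]):
                    raise ValueError(f"self-edges not allowed in {key}")
        if ("keypoint", "pocket") in self.edges and self.edges[("keypoint", "pocket")].size:
            raise ValueError("keypoint→pocket edges are not allowed")

    def n_edges(self, key: tuple[str, str] | None = None) -> int:
        if key is not None:
            return int(self.edges.get(key, np.empty((0, 2))).shape[0])
        return int(sum(e.shape[0] for e in self.edges.values()))


@dataclass(frozen=True)
class GraphBuildConfig:
    """Distance rules per edge type.

    Edges are created where the Euclidean distance is strictly below the
    cutoff.  ``None`` cutoffs with the corresponding ``*_complete`` flag give
    fully connected subgraphs; ligands are small enough that a complete
    ligand subgraph (and complete cross edges to the conditioning context)
    is the default.
    """

    pocket_pocket_cutoff: float = 4.5  # Å
    pocket_ligand_cutoff: float | None = None  # None → fully connected
    ligand_complete: bool = True
    ligand_ligand_cutoff: float = 4.5  # used when ligand_complete is False
    keypoint_ligand_complete: bool = True
    keypoint_ligand_cutoff: float = 5.0
    keypoint_keypoint_complete: bool = True

    def __post_init__(self):
        for c in (
            self.pocket_pocket_cutoff,
            self.pocket_ligand_cutoff,
            self.ligand_ligand_cutoff,
            self.keypoint_ligand_cutoff,
        ):
            if c is not None and c <= 0:
                raise ValueError("cutoffs must be positive")


def _cutoff_pairs(a: np.ndarray, b: np.ndarray, cutoff: float, same: bool) -> np.ndarray:
    """All (i, j) with ||a_i − b_j|| < cutoff, via KD-trees; excludes i==j if same."""
    tree_a, tree_b = cKDTree(a), cKDTree(b)
    # query_ball_tree returns closed-ball neighbours; shrink by a hair for the
    # strict inequality, then filter exactly.
    neighbours = tree_a.query_ball_tree(tree_b, cutoff)
    pairs = []
    for i, js in enumerate(neighbours):
        for j in sorted(js):
            if same and i == j:
                continue
            if np.linalg.norm(a[i] - b[j]) < cutoff:
                pairs.append((i, j))
    return np.asarray(pairs, dtype=np.intp).reshape(-1, 2)


def _complete_pairs(n_a: int, n_b: int, same: bool) -> np.ndarray:
    src, dst = np.meshgrid(np.arange(n_a), np.arange(n_b), indexing="ij")
    pairs = np.stack([src.ravel(), dst.ravel()], axis=1)
    if same:
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    return pairs.astype(np.intp)


def build_hetero_graph(
    pocket: AtomCloud,
    ligand: AtomCloud,
    keypoints=None,
    cfg: GraphBuildConfig | None = None,
) -> HeteroGraph:
    """Build the typed distance graph over pocket, ligand and keypoint nodes.

    Cross edges are emitted in both directions; pocket→keypoint edges (the
    encoder's rewired edges) are *not* built here — they come from
    :func:`keydiff.encoder.rewire` — so the keypoint node set only connects
    to the ligand (and itself) in this graph.
    """
    cfg = cfg or GraphBuildConfig()
    if pocket.n_atoms < 1 or ligand.n_atoms < 1:
        raise ValueError("empty cloud")
    node_counts = {"pocket": pocket.n_atoms, "ligand": ligand.n_atoms}
    edges: dict[tuple[str, str], np.ndarray] = {}

    edges[("pocket", "pocket")] = _cutoff_pairs(
        pocket.positions, pocket.positions, cfg.pocket_pocket_cutoff, same=True
    )
    if cfg.ligand_complete:
        edges[("ligand", "ligand")] = _complete_pairs(ligand.n_atoms, ligand.n_atoms, same=True)
    else:
        edges[("ligand", "ligand")] = _cutoff_pairs(
            ligand.positions, ligand.positions, cfg.ligand_ligand_cutoff, same=True
        )
    if cfg.pocket_ligand_cutoff is None:
        pl = _complete_pairs(pocket.n_atoms, ligand.n_atoms, same=False)
    else:
        pl = _cutoff_pairs(
            pocket.positions, ligand.positions, cfg.pocket_ligand_cutoff, same=False
        )
    edges[("pocket", "ligand")] = pl
    edges[("ligand", "pocket")] = pl[:, ::-1].copy()

    if keypoints is not None:
        kp_pos = getattr(keypoints, "positions", None)
        if kp_pos is None:
            raise ValueError("keypoints supplied without positions")
        kp_pos = np.asarray(kp_pos, dtype=np.float64)
        node_counts["keypoint"] = kp_pos.shape[0]
        if cfg.keypoint_ligand_complete:
            kl = _complete_pairs(kp_pos.shape[0], ligand.n_atoms, same=False)
        else:
            kl = _cutoff_pairs(kp_pos, ligand.positions, cfg.keypoint_ligand_cutoff, same=False)
        edges[("keypoint", "ligand")] = kl
        edges[("ligand", "keypoint")] = kl[:, ::-1].copy()
        if cfg.keypoint_keypoint_complete:
            edges[("keypoint", "keypoint")] = _complete_pairs(
                kp_pos.shape[0], kp_pos.shape[0], same=True
            )
    return HeteroGraph(node_counts=node_counts, edges=edges)


def center_on_pocket(pocket: AtomCloud, ligand: AtomCloud):
    """Translate both clouds so the pocket centroid sits at the origin.

    Returns ``(pocket, ligand, offset)``; adding ``-offset`` back restores the
    original frame.  The conditional diffusion model is trained and sampled
    in this pocket-centred frame.
    """
    offset = -pocket.positions.mean(axis=0)
    return pocket.translated(offset), ligand.translated(offset), offset
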