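"""Desk-scale quality and efficiency proxies for generated ligands.

Force-field minimisation and docking scores need external binaries, so
sample quality is summarised by in-repo geometric proxies: in-place RMSD to
a reference pose (no superposition — poses share the pocket frame), the
fraction of ligand atoms clashing with the pocket, cavity containment, and
element frequencies.  The inference-speed claim is made hardware-independent
by counting conditioning nodes and per-denoiser-call directed edges instead
of wall-clock time (which is logged, never asserted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._graphs import cutoff_edges
from .core import AtomCloud, ElementVocabulary, GraphBuildConfig

__all__ = [
    "QualityReport",
    "rmsd_in_place",
    "clash_fraction",
    "cavity_containment",
    "graph_size_report",
    "evaluate_run",
]


def rmsd_in_place(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean squared per-atom displacement, without superposition.

    Both poses must list corresponding atoms in the same order and share a
    coordinate frame (e.g. the pocket frame before/after relaxation).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"atom count mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def clash_fraction(ligand: AtomCloud, pocket: AtomCloud, threshold: float = 2.0) -> float:
    """Fraction of ligand atoms with any pocket atom closer than threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    d = cdist(ligand.positions, pocket.positions)
    return float(np.mean(d.min(axis=1) < threshold))


def cavity_containment(ligand: AtomCloud, center: np.ndarray, radius: float) -> float:
    """Fraction of ligand atoms inside the cavity ball."""
    r = np.linalg.norm(ligand.positions - np.asarray(center, dtype=np.float64), axis=1)
    return float(np.mean(r <= radius))


def graph_size_report(
    pocket: AtomCloud,
    ligand_size: int,
    representation: str,
    n_keypoints: int = 40,
    cfg: GraphBuildConfig | None = None,
) -> dict:
    """Conditioning-node and per-denoiser-call edge counts.

    ``pocket`` is the context cloud in the stated representation (for the
    Cα representation pass the Cα cloud); for ``representation="keypoint"``
    the context has ``n_keypoints`` nodes and a complete context subgraph,
    while atom contexts use the distance-cutoff rule.  Cross
    (context↔ligand, both directions) and ligand subgraphs are complete
    under the default build rules.
    """
    cfg = cfg or GraphBuildConfig()
    if representation == "keypoint":
        n_ctx = n_keypoints
        ctx_edges = n_ctx * (n_ctx - 1) if cfg.keypoint_keypoint_complete else 0
    elif representation in ("all-atom", "calpha"):
        n_ctx = pocket.n_atoms
        ctx_edges = int(cutoff_edges(pocket.positions, cfg.pocket_pocket_cutoff).shape[0])
    else:
        raise ValueError(f"unknown representation {representation!r}")
    cross = 2 * n_ctx * ligand_size
    lig = ligand_size * (ligand_size - 1)
    return {
        "representation": representation,
        "conditioning_nodes": int(n_ctx),
        "context_edges": int(ctx_edges),
        "cross_edges": int(cross),
        "ligand_edges": int(lig),
        "edges_per_step": int(ctx_edges + cross + lig),
    }


@dataclass
class QualityReport:
    """Aggregated per-sample metrics; serialisable to JSON."""

    rmsd: list[float] = field(default_factory=list)
    clash: list[float] = field(default_factory=list)
    element_counts: dict[str, int] = field(default_factory=dict)
    graph_sizes: dict = field(default_factory=dict)
    wall_time_s: float | None = None  # logged only, never asserted

    @property
    def mean_rmsd(self) -> float | None:
        return float(np.mean(self.rmsd)) if self.rmsd else None

    @property
    def mean_clash(self) -> float | None:
        return float(np.mean(self.clash)) if self.clash else None

    def element_frequencies(self) -> dict[str, float]:
        total = sum(self.element_counts.values())
        if total == 0:
            return {}
        return {k: v / total for k, v in self.element_counts.items()}

    def to_dict(self) -> dict:
        return {
            "n_samples": len(self.clash),
            "mean_rmsd": self.mean_rmsd,
            "per_sample_rmsd": self.rmsd,
            "mean_clash_fraction": self.mean_clash,
            "per_sample_clash_fraction": self.clash,
            "element_frequencies": self.element_frequencies(),
            "element_counts": self.element_counts,
            "graph_sizes": self.graph_sizes,
            "wall_time_s": self.wall_time_s,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_run(
    samples: list[AtomCloud],
    references: list[AtomCloud] | None,
    pocket: AtomCloud,
    vocab: ElementVocabulary,
    clash_threshold: float = 2.0,
    representation: str = "keypoint",
    n_keypoints: int = 40,
    wall_time_s: float | None = None,
) -> QualityReport:
    """Score a batch of decoded samples against one pocket.

    RMSD is reported only when matched references exist (same atom counts,
    same order); clash fractions and element frequencies always.
    """
    if not samples:
        raise ValueError("empty sample set")
    report = QualityReport(wall_time_s=wall_time_s)
    for i, sample in enumerate(samples):
        if not sample.is_one_hot():
            raise ValueError("samples must be decoded to one-hot before evaluation")
        report.clash.append(clash_fraction(sample, pocket, clash_threshold))
        if references is not None:
            report.rmsd.append(rmsd_in_place(sample.positions, references[i].positions))
        for symbol in vocab.decode(sample.features):
            report.element_counts[symbol] = report.element_counts.get(symbol, 0) + 1
    mean_size = int(round(np.mean([s.n_atoms for s in samples])))
    report.graph_sizes = graph_size_report(pocket, mean_size, representation, n_keypoints)
    return report
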