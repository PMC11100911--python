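"""Synthetic protein/ligand complexes for desk-scale training and testing.

Each toy complex is a concave "pocket" — atoms scattered over a hemispherical
shell — enclosing a cavity ball that holds a small ligand.  The shell/cavity
radii are chosen so ligand–pocket contacts within the 5 Å interface cutoff
are geometrically achievable, and a draw is rejected until at least one such
contact exists.

Like a real binding site, each complex has a *binding hotspot*: a random
rim-ward direction where the wall is enriched in polar atom types and a few
pocket atoms protrude into the cavity like side chains; the ligand packs
against them (not in mid-cavity), with steric margins from every pocket
atom and from the cavity wall.  The hotspot makes the protein/ligand
interface predictable from the pocket alone, so conditioning and keypoint
placement have a learnable target.  Ligand atom types follow a fixed
carbon-rich categorical law.

The construction frame puts the cavity centre at the origin with the shell
covering the z > 0 hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import AtomCloud, ElementVocabulary, LIGAND_VOCAB

__all__ = ["ToyComplexConfig", "ToyComplex", "generate_toy_complex", "generate_dataset"]

CONTACT_CUTOFF = 5.0  # Å, the interface definition


@dataclass(frozen=True)
class ToyComplexConfig:
    shell_radius: float = 8.0  # Å, pocket hemisphere radius R
    cavity_radius: float = 3.5  # Å, ligand ball radius r
    n_pocket: int = 60
    ligand_size_range: tuple[int, int] = (5, 10)
    vocab: ElementVocabulary = LIGAND_VOCAB
    min_spacing: float = 1.2  # Å, within-cloud rejection radius
    shell_jitter: float = 0.3  # Å, radial thickness of the shell
    hotspot_halfwidth_deg: float = 40.0  # angular size of the polar patch
    hotspot_polar_range_deg: tuple[float, float] = (70.0, 90.0)  # near the rim
    ligand_bias: float = 3.0  # cosine power pulling ligand atoms toward the hotspot
    n_anchor: int = 4  # hotspot side-chain atoms protruding into the cavity
    anchor_offset: float = 1.3  # Å beyond the cavity radius for anchor atoms
    anchor_halfwidth_deg: float = 15.0
    clash_distance: float = 1.5  # Å, minimum ligand–pocket separation
    wall_margin: float = 0.5  # Å, atom centres keep a van-der-Waals margin from the cavity surface
    retry_budget: int = 100

    def __post_init__(self):
        if not self.cavity_radius < self.shell_radius:
            raise ValueError("cavity must fit inside the shell (r < R)")
        if self.shell_radius - self.cavity_radius >= CONTACT_CUTOFF:
            raise ValueError("shell too far from cavity for 5 Å contacts (R - r must be < 5)")
        if self.ligand_size_range[0] < 1:
            raise ValueError("minimum ligand size must be >= 1")
        if self.ligand_size_range[0] > self.ligand_size_range[1]:
            raise ValueError("ligand size range inverted")


@dataclass
class ToyComplex:
    pocket: AtomCloud
    ligand: AtomCloud
    hotspot: np.ndarray | None = None  # unit vector, construction frame

    def min_contact_distance(self) -> float:
        return float(cdist(self.ligand.positions, self.pocket.positions).min())


def _sample_spaced(
    n: int, draw, min_spacing: float, rng: np.random.Generator, budget: int = 20000
) -> np.ndarray:
    """Rejection-sample n points with pairwise spacing >= min_spacing."""
    points: list[np.ndarray] = []
    attempts = 0
    while len(points) < n:
        if attempts > budget:
            raise RuntimeError("spacing rejection budget exhausted; config over-constrained")
        attempts += 1
        p = draw(rng)
        if p is None:
            continue
        if all(np.linalg.norm(p - q) >= min_spacing for q in points):
            points.append(p)
    return np.asarray(points)


def _hemisphere_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    v[2] = abs(v[2])
    return v


def _hotspot_direction(rng: np.random.Generator, polar_range=(70.0, 90.0)) -> np.ndarray:
    """Hotspot near the rim of the shell: ligands pack against the pocket
    wall toward the opening, as they would when entering a real site."""
    theta = np.deg2rad(rng.uniform(*polar_range))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)])


def _jittered_direction(axis: np.ndarray, halfwidth_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Unit vector within roughly ``halfwidth_deg`` of ``axis``."""
    g = rng.normal(size=3)
    perp = g - (g @ axis) * axis
    norm = np.linalg.norm(perp)
    if norm < 1e-12:
        return axis.copy()
    perp /= norm
    theta = abs(rng.normal(0.0, np.deg2rad(halfwidth_deg) / 2.0))
    return np.cos(theta) * axis + np.sin(theta) * perp


def _categorical(logits: np.ndarray, rng: np.random.Generator) -> int:
    p = np.exp(logits - logits.max())
    p /= p.sum()
    return int(rng.choice(len(p), p=p))


def _pocket_types(
    positions: np.ndarray, hotspot: np.ndarray, cfg: ToyComplexConfig, rng
) -> np.ndarray:
    """Carbon-rich shell with polar (non-carbon) enrichment in the hotspot
    patch; a mild height tilt keeps a radial-position correlation as well."""
    f = cfg.vocab.size
    cos_hw = np.cos(np.deg2rad(cfg.hotspot_halfwidth_deg))
    feats = np.zeros((positions.shape[0], f))
    for i, pos in enumerate(positions):
        direction = pos / np.linalg.norm(pos)
        logits = np.full(f, -1.0)
        logits[0] = 2.5  # strongly hydrophobic (carbon) wall
        u = pos[2] / cfg.shell_radius
        logits[1 % f] += 0.5 * u  # mild radial-position correlation
        if float(direction @ hotspot) > cos_hw:
            for j in range(1, f):
                logits[j] += 4.0  # polar hotspot patch
        feats[i, _categorical(logits, rng)] = 1.0
    return feats


def _ligand_types(positions: np.ndarray, cfg: ToyComplexConfig, rng) -> np.ndarray:
    """Fixed carbon-rich categorical law for ligand atoms (drug-like mix)."""
    f = cfg.vocab.size
    base = np.array([0.45, 0.2, 0.2, -0.05][:f])
    feats = np.zeros((positions.shape[0], f))
    for i in range(positions.shape[0]):
        feats[i, _categorical(base, rng)] = 1.0
    return feats


def generate_toy_complex(cfg: ToyComplexConfig, rng: np.random.Generator) -> ToyComplex:
    """Draw one complex; positions are retried until the contact invariant
    holds.  The ligand size is drawn once, *before* the retry loop, so the
    contact rejection cannot bias the size distribution."""
    n_lig = int(rng.integers(cfg.ligand_size_range[0], cfg.ligand_size_range[1] + 1))
    for _ in range(cfg.retry_budget):
        hotspot = _hotspot_direction(rng, cfg.hotspot_polar_range_deg)

        def shell_draw(r):
            radius = cfg.shell_radius + r.normal(0.0, cfg.shell_jitter)
            return radius * _hemisphere_direction(r)

        # hotspot side chains protruding from the wall toward the cavity —
        # the pocket atoms the ligand actually packs against
        def anchor_draw(r):
            axis = _jittered_direction(hotspot, cfg.anchor_halfwidth_deg, r)
            radius = cfg.cavity_radius + cfg.anchor_offset + r.normal(0.0, 0.2)
            return radius * axis

        n_shell = max(cfg.n_pocket - cfg.n_anchor, 1)
        shell_pos = _sample_spaced(n_shell, shell_draw, cfg.min_spacing, rng)
        anchor_pos = _sample_spaced(cfg.n_anchor, anchor_draw, cfg.min_spacing, rng)
        pocket_pos = np.vstack([shell_pos, anchor_pos]) if cfg.n_anchor else shell_pos

        def cavity_draw(r):
            reach = cfg.cavity_radius - cfg.wall_margin
            p = r.uniform(-reach, reach, size=3)
            rad = np.linalg.norm(p)
            if rad > reach or rad == 0.0:
                return None
            if np.linalg.norm(p - pocket_pos, axis=1).min() < cfg.clash_distance:
                return None  # steric clash with the pocket
            # pack toward the hotspot direction (the anchors guarantee the
            # 5 Å contacts, so no radial bias is needed)
            w = (0.5 * (1.0 + float(p / rad @ hotspot))) ** cfg.ligand_bias
            return p if r.random() < w else None

        ligand_pos = _sample_spaced(n_lig, cavity_draw, cfg.min_spacing, rng)

        if cdist(ligand_pos, pocket_pos).min() >= CONTACT_CUTOFF:
            continue  # no interface — reject the draw

        pocket = AtomCloud(
            pocket_pos, _pocket_types(pocket_pos, hotspot, cfg, rng), kind="pocket"
        )
        ligand = AtomCloud(ligand_pos, _ligand_types(ligand_pos, cfg, rng), kind="ligand")
        return ToyComplex(pocket=pocket, ligand=ligand, hotspot=hotspot)
    raise RuntimeError("retry budget exhausted: no complex satisfied the contact invariant")


def generate_dataset(n: int, cfg: ToyComplexConfig, rng: np.random.Generator) -> list[ToyComplex]:
    if n < 1:
        raise ValueError("n must be >= 1")
    return [generate_toy_complex(cfg, rng) for _ in range(n)]
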