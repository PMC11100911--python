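"""Variance-preserving diffusion: schedules, forward process, losses,
ancestral reverse step and the ligand-size sampler.

The forward process is q(z_t | z_0) = N(α_t z_0, σ_t² I) with α_t² + σ_t² = 1,
applied identically to atom positions and (continuous-relaxed one-hot) atom
type features.  α_t runs from ≈1 at t=0 to ≈0 at t=T.  The reverse process is
the Gaussian ancestral step implied by the schedule and the predicted noise;
the final step (t=1→0) adds no noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor
from .core import AtomCloud

__all__ = [
    "NoiseSchedule",
    "DiffusionState",
    "NoisePrediction",
    "make_schedule",
    "diffuse_values",
    "forward_diffuse",
    "denoising_loss",
    "reverse_step",
    "sample_ligand_size",
]


@dataclass
class NoiseSchedule:
    """Per-step (α_t, σ_t) pairs for t = 0…T, variance preserving."""

    alpha: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.alpha.shape != self.sigma.shape or self.alpha.ndim != 1:
            raise ValueError("alpha and sigma must be equal-length 1D arrays")
        dev = np.abs(self.alpha**2 + self.sigma**2 - 1.0)
        if dev.max() >= 1e-9:
            raise ValueError("schedule is not variance preserving (α² + σ² ≠ 1)")
        if np.any(np.diff(self.alpha) > 0):
            raise ValueError("α must be non-increasing")
        if self.alpha[0] < 0.999:
            raise ValueError("α_0 must be ≈ 1 (≥ 0.999)")
        if self.alpha[-1] > 1e-3:
            raise ValueError("α_T must be ≈ 0 (≤ 1e-3)")

    @property
    def n_steps(self) -> int:
        return self.alpha.shape[0] - 1


@dataclass
class DiffusionState:
    """Noised ligand z_t = (positions x_t, features s_t) at timestep t."""

    positions: np.ndarray  # (N, 3)
    features: np.ndarray  # (N, f)
    t: int

    def __post_init__(self):
        self.positions = np.asarray(getattr(self.positions, "data", self.positions), dtype=np.float64)
        self.features = np.asarray(getattr(self.features, "data", self.features), dtype=np.float64)
        if self.t < 0:
            raise ValueError("t must be >= 0")


@dataclass
class NoisePrediction:
    """ε̂ split into the equivariant position part and invariant feature part.

    Fields may be numpy arrays or autodiff Tensors (during training)."""

    eps_x: object  # (N, 3)
    eps_s: object | None = None  # (N, f)

    def numpy(self) -> "NoisePrediction":
        x = getattr(self.eps_x, "data", self.eps_x)
        s = None if self.eps_s is None else getattr(self.eps_s, "data", self.eps_s)
        return NoisePrediction(np.asarray(x), None if s is None else np.asarray(s))


_CLIP = 1e-7  # keeps α_0 < 1 and α_T > 0 so every ancestral step is defined


def make_schedule(n_steps: int, kind: str = "polynomial") -> NoiseSchedule:
    """Build a variance-preserving schedule with T = ``n_steps``.

    ``polynomial``: α_t² ∝ (1 − (t/T)²)², the convention of equivariant
    diffusion models for molecules; ``cosine``: α_t² ∝ cos²(π/2·(t/T+s)/(1+s)).
    Both are affinely clipped away from 0 and 1 at the endpoints.
    """
    if n_steps < 1:
        raise ValueError("need at least one step")
    t = np.arange(n_steps + 1) / n_steps
    if kind == "polynomial":
        a2 = (1.0 - t**2) ** 2
    elif kind == "cosine":
        s = 0.008
        a2 = np.cos(0.5 * np.pi * (t + s) / (1 + s)) ** 2
        a2 = a2 / a2[0]
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    a2 = a2 * (1.0 - 2.0 * _CLIP) + _CLIP
    alpha = np.sqrt(a2)
    sigma = np.sqrt(1.0 - a2)
    return NoiseSchedule(alpha=alpha, sigma=sigma)


def diffuse_values(
    x0: np.ndarray, t: int, schedule: NoiseSchedule, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """x_t = α_t x_0 + σ_t ε with ε ~ N(0, I); returns (x_t, ε)."""
    if not 0 <= t <= schedule.n_steps:
        raise ValueError("t outside the schedule")
    x0 = np.asarray(x0, dtype=np.float64)
    eps = rng.standard_normal(x0.shape)
    return schedule.alpha[t] * x0 + schedule.sigma[t] * eps, eps


def forward_diffuse(
    z0: AtomCloud, t: int, schedule: NoiseSchedule, rng: np.random.Generator
) -> tuple[DiffusionState, NoisePrediction]:
    """Noise a clean ligand's positions and features to timestep t.

    Returns the noised state and the drawn noise (as a NoisePrediction so the
    loss can compare like with like).
    """
    x_t, eps_x = diffuse_values(z0.positions, t, schedule, rng)
    s_t, eps_s = diffuse_values(z0.features, t, schedule, rng)
    return DiffusionState(x_t, s_t, t), NoisePrediction(eps_x, eps_s)


def denoising_loss(eps: NoisePrediction, eps_hat: NoisePrediction, w_x: float = 1.0, w_s: float = 1.0):
    """Mean squared error between drawn and predicted noise.

    The mean runs over all nodes and channels (positions and features
    together); ``w_x``/``w_s`` rescale the squared position/feature residuals
    before averaging.  Returns an autodiff Tensor if either input carries
    one, else a float.
    """
    terms = []
    count = 0
    has_tensor = False
    for a, b, w in ((eps.eps_x, eps_hat.eps_x, w_x), (eps.eps_s, eps_hat.eps_s, w_s)):
        if a is None or b is None:
            continue
        has_tensor = has_tensor or isinstance(a, Tensor) or isinstance(b, Tensor)
        a, b = as_tensor(a), as_tensor(b)
        if a.shape != b.shape:
            raise ValueError("noise shapes disagree")
        diff = a - b
        terms.append((diff * diff).sum() * w)
        count += int(np.prod(a.shape))
    if not terms:
        raise ValueError("nothing to compare")
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    total = total / float(count)
    return total if has_tensor else float(total.data)


def reverse_step(
    z_t: DiffusionState,
    eps_hat: NoisePrediction,
    schedule: NoiseSchedule,
    rng: np.random.Generator,
) -> DiffusionState:
    """One Gaussian ancestral step z_t → z_{t−1}.

    Uses the ε-parameterised posterior mean
    μ = (z_t − (σ²_{t|t−1}/σ_t)·ε̂)/α_{t|t−1} with variance
    σ²_{t|t−1}·σ²_{t−1}/σ²_t; the t=1→0 step is deterministic.
    """
    t = z_t.t
    if t < 1:
        raise ValueError("reverse step requires t >= 1")
    s = t - 1
    a_t, a_s = schedule.alpha[t], schedule.alpha[s]
    sig_t, sig_s = schedule.sigma[t], schedule.sigma[s]
    a_ts = a_t / a_s
    var_ts = sig_t**2 - a_ts**2 * sig_s**2
    std = 0.0 if s == 0 else np.sqrt(max(var_ts, 0.0) * sig_s**2 / sig_t**2)
    eh = eps_hat.numpy()
    out = []
    for z, e in ((z_t.positions, eh.eps_x), (z_t.features, eh.eps_s)):
        mean = (z - (var_ts / sig_t) * e) / a_ts
        noise = 0.0 if std == 0.0 else std * rng.standard_normal(z.shape)
        out.append(mean + noise)
    return DiffusionState(out[0], out[1], s)


def sample_ligand_size(pocket_node_count: int, histogram, rng: np.random.Generator) -> int:
    """Draw a ligand atom count from a size histogram.

    ``histogram`` is either a flat ``{size: weight}`` table or a list of
    ``(pocket_lo, pocket_hi, {size: weight})`` bins; the bin containing the
    pocket node count is used (falling back to the last bin).  Results are
    floored at 1.
    """
    if isinstance(histogram, dict):
        table = histogram
    else:
        table = None
        for lo, hi, tab in histogram:
            if lo <= pocket_node_count < hi:
                table = tab
                break
        if table is None:
            if not histogram:
                raise ValueError("empty histogram")
            table = histogram[-1][2]
    if not table:
        raise ValueError("empty histogram")
    sizes = np.array(sorted(table), dtype=int)
    weights = np.array([table[s] for s in sizes], dtype=np.float64)
    weights = weights / weights.sum()
    return max(1, int(rng.choice(sizes, p=weights)))
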