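"""Interface points and the optimal-transport keypoint-alignment loss.

The protein/ligand interface is summarised by the midpoints of every
ligand-atom/pocket-atom pair closer than 5 Å.  The alignment loss is the
exact optimal-transport cost, under uniform marginals, between the keypoint
positions and these interface points; during training the transport plan is
solved in the forward pass and treated as a constant in the backward pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial.distance import cdist

from .autodiff import Tensor
from .core import AtomCloud

__all__ = [
    "OTConfig",
    "InterfacePointSet",
    "OTProblem",
    "EmptyInterfaceError",
    "compute_interface_points",
    "solve_uniform_ot",
    "ot_align_loss",
    "ot_align_loss_tensor",
]


class EmptyInterfaceError(ValueError):
    """Raised when a complex has no ligand–pocket pair under the cutoff."""


@dataclass(frozen=True)
class OTConfig:
    contact_cutoff: float = 5.0  # Å
    solver: str = "exact-emd"
    squared: bool = True  # cost = squared Euclidean distance

    def __post_init__(self):
        if self.contact_cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.solver != "exact-emd":
            raise ValueError(f"unknown solver {self.solver!r}")


@dataclass
class InterfacePointSet:
    positions: np.ndarray  # (S, 3)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    @property
    def is_empty(self) -> bool:
        return self.n_points == 0


@dataclass
class OTProblem:
    cost: np.ndarray  # (S, K)
    plan: np.ndarray  # (S, K), uniform marginals

    def __post_init__(self):
        S, K = self.cost.shape
        if self.plan.shape != (S, K):
            raise ValueError("plan/cost shape mismatch")
        if np.any(self.cost < -1e-12) or np.any(self.plan < -1e-9):
            raise ValueError("cost and plan must be nonnegative")
        if not np.allclose(self.plan.sum(axis=1), 1.0 / S, atol=1e-6):
            raise ValueError("plan row marginals are not uniform")
        if not np.allclose(self.plan.sum(axis=0), 1.0 / K, atol=1e-6):
            raise ValueError("plan column marginals are not uniform")


def compute_interface_points(
    ligand: AtomCloud, pocket: AtomCloud, cfg: OTConfig | None = None
) -> InterfacePointSet:
    """Midpoints of all ligand/pocket atom pairs strictly under the cutoff.

    Order is deterministic: ligand-major, pocket-minor.  Duplicate midpoints
    (possible with symmetric inputs) are kept — the definition enumerates
    pairs, not unique locations.  An empty set signals a contact-free
    complex; downstream training omits the alignment loss for it.
    """
    cfg = cfg or OTConfig()
    d = cdist(ligand.positions, pocket.positions)
    li, pj = np.nonzero(d < cfg.contact_cutoff)
    order = np.lexsort((pj, li))  # ligand-major, pocket-minor
    li, pj = li[order], pj[order]
    mids = 0.5 * (ligand.positions[li] + pocket.positions[pj])
    return InterfacePointSet(mids.reshape(-1, 3))


def solve_uniform_ot(cost: np.ndarray) -> np.ndarray:
    """Exact OT plan with uniform marginals (1/S rows, 1/K columns).

    For S == K the optimum is a scaled permutation (Birkhoff), found by the
    Hungarian algorithm; otherwise the transportation LP is solved exactly
    with HiGHS.
    """
    cost = np.asarray(cost, dtype=np.float64)
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix must be finite")
    S, K = cost.shape
    if S == K:
        rows, cols = linear_sum_assignment(cost)
        plan = np.zeros((S, K))
        plan[rows, cols] = 1.0 / K
        return plan
    # transportation LP: S row-sum constraints, K-1 column sums (last redundant)
    a_eq = np.zeros((S + K - 1, S * K))
    b_eq = np.zeros(S + K - 1)
    for s in range(S):
        a_eq[s, s * K : (s + 1) * K] = 1.0
        b_eq[s] = 1.0 / S
    for k in range(K - 1):
        a_eq[S + k, k::K] = 1.0
        b_eq[S + k] = 1.0 / K
    res = linprog(cost.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"OT solver failed: {res.message}")
    return res.x.reshape(S, K)


def _cost_matrix(kp: np.ndarray, ip: np.ndarray, cfg: OTConfig) -> np.ndarray:
    metric = "sqeuclidean" if cfg.squared else "euclidean"
    return cdist(ip, kp, metric=metric)


def ot_align_loss(
    keypoint_positions: np.ndarray, interface: InterfacePointSet, cfg: OTConfig | None = None
) -> tuple[float, OTProblem]:
    """Exact OT cost between keypoints and interface points.

    Returns the optimal ⟨T, C⟩ together with the problem (cost matrix and the
    achieving plan).
    """
    cfg = cfg or OTConfig()
    kp = np.asarray(getattr(keypoint_positions, "positions", keypoint_positions), dtype=np.float64)
    if interface.is_empty:
        raise EmptyInterfaceError("no interface points (no contacts under the cutoff)")
    if kp.shape[0] < 1:
        raise ValueError("need at least one keypoint")
    if not np.all(np.isfinite(kp)) or not np.all(np.isfinite(interface.positions)):
        raise ValueError("non-finite coordinates")
    cost = _cost_matrix(kp, interface.positions, cfg)
    plan = solve_uniform_ot(cost)
    loss = float(np.sum(plan * cost))
    return loss, OTProblem(cost=cost, plan=plan)


def ot_align_loss_tensor(
    keypoint_positions: Tensor, interface: InterfacePointSet, cfg: OTConfig | None = None
) -> Tensor:
    """Differentiable OT loss with the plan held fixed in the backward pass.

    The plan is solved on detached coordinates; the returned Tensor is
    ⟨T_const, C(x^(KP))⟩ so gradients reach the keypoints only through the
    cost matrix.
    """
    cfg = cfg or OTConfig()
    if interface.is_empty:
        warnings.warn("empty interface: OT loss omitted for this example")
        return Tensor(0.0)
    plan = solve_uniform_ot(_cost_matrix(keypoint_positions.data, interface.positions, cfg))
    K = keypoint_positions.shape[0]
    S = interface.n_points
    ip = Tensor(interface.positions).reshape(S, 1, 3)
    kp = keypoint_positions.reshape(1, K, 3)
    diff = kp - ip
    sq = (diff * diff).sum(axis=-1)  # (S, K)
    cost = sq if cfg.squared else (sq + 1e-12).sqrt()
    return (Tensor(plan) * cost).sum()
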