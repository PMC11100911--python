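"""Pocket-conditioned ligand diffusion model.

Assembles the pocket encoder, the noise-prediction network and the
variance-preserving schedule into one trainable model.  The conditioning
context is either the learned keypoint cloud (the default), the all-atom
pocket, or a Cα cloud; context nodes are never moved by the denoiser — only
ligand atoms diffuse.

Frames: every complex is first centred on the pocket centroid; the diffusion
itself runs in a frame anchored at the context centroid (for the keypoint
model, the keypoint centroid), which is also where the standard-normal prior
is placed at sampling time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._graphs import complete_bipartite_edges, complete_edges, cutoff_edges
from .autodiff import Tensor, concat
from .core import AtomCloud, ElementVocabulary, center_on_pocket
from .diffusion import (
    DiffusionState,
    NoisePrediction,
    NoiseSchedule,
    denoising_loss,
    forward_diffuse,
    make_schedule,
    reverse_step,
)
from .encoder import EncoderConfig, KeypointCloud, PocketEncoder
from .interface import OTConfig, compute_interface_points, ot_align_loss_tensor
from .nets import EGNNLayer, GVP, GVPLayer
from .nn import Adam, Linear, Module, clip_gradients

__all__ = [
    "DenoiserConfig",
    "TrainConfig",
    "ModelConfig",
    "Denoiser",
    "KeypointDiffusionModel",
    "train_model",
]


@dataclass(frozen=True)
class DenoiserConfig:
    backbone: str = "gvp"  # or "egnn"
    d: int = 64
    c: int = 16
    n_layers: int = 4
    context_cutoff: float = 4.5  # Å, context-context edges for atom contexts

    def __post_init__(self):
        if self.backbone not in ("egnn", "gvp"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


@dataclass(frozen=True)
class TrainConfig:
    ot_weight: float = 1.0  # λ_OT multiplying the keypoint-alignment loss
    learning_rate: float = 1e-3
    batch_size: int = 8
    seed: int = 0
    w_x: float = 1.0  # position part of the denoising loss
    w_s: float = 1.0  # feature part
    clip_norm: float | None = 10.0  # global gradient-norm clip
    ema_decay: float | None = None  # weight EMA used for evaluation/sampling
    final_learning_rate: float | None = None  # per-epoch geometric decay target

    def __post_init__(self):
        if self.ot_weight < 0:
            raise ValueError("λ_OT must be nonnegative")


@dataclass
class ModelConfig:
    ligand_vocab: tuple[str, ...] = ("C", "N", "O", "F")
    pocket_vocab: tuple[str, ...] = ("C", "N", "O", "F")
    representation: str = "keypoint"  # or "all-atom" / "calpha"
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    denoiser: DenoiserConfig = field(default_factory=DenoiserConfig)
    n_steps: int = 1000
    schedule_kind: str = "polynomial"
    feature_scale: float = 2.0  # one-hot amplitude in the diffusion space

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ligand_vocab"] = list(self.ligand_vocab)
        d["pocket_vocab"] = list(self.pocket_vocab)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["ligand_vocab"] = tuple(d["ligand_vocab"])
        d["pocket_vocab"] = tuple(d["pocket_vocab"])
        d["encoder"] = EncoderConfig(**d["encoder"])
        d["denoiser"] = DenoiserConfig(**d["denoiser"])
        return cls(**d)


class Denoiser(Module):
    """Noise-prediction network ε̂_θ over the context+ligand graph."""

    def __init__(
        self,
        ligand_dim: int,
        context_dim: int,
        cfg: DenoiserConfig,
        rng: np.random.Generator,
        feature_scale: float = 1.0,
    ):
        self.cfg = cfg
        d, c = cfg.d, cfg.c
        self.lig_in = Linear(ligand_dim + 1, d, rng)
        self.ctx_in = Linear(context_dim + 1, d, rng)
        if cfg.backbone == "egnn":
            self.layers = [EGNNLayer(d, rng) for _ in range(cfg.n_layers)]
            self.out_s = Linear(d, ligand_dim, rng)
        else:
            self.layers = [GVPLayer(d, c, rng) for _ in range(cfg.n_layers)]
            self.readout = GVP(d, c, ligand_dim, 1, rng, activate=False)
        # neutral feature head: an untrained (or weakly-trained high-noise)
        # network predicts the uniform categorical, so the reverse chain
        # accumulates no systematic atom-type drift.  The position head
        # keeps its random init — large conditional displacements have to
        # be learned quickly and a zeroed head slows that down.
        out_scalar = self.out_s if cfg.backbone == "egnn" else self.readout.scalar
        out_scalar.weight.data[:] = 0.0
        out_scalar.bias.data[:] = feature_scale / ligand_dim

    def _edges(self, ctx_pos: np.ndarray, n_lig: int, ctx_is_atoms: bool) -> np.ndarray:
        n_ctx = ctx_pos.shape[0]
        if ctx_is_atoms:
            ctx_edges = cutoff_edges(ctx_pos, self.cfg.context_cutoff)
        else:
            ctx_edges = complete_edges(n_ctx)
        cross = complete_bipartite_edges(n_ctx, n_lig, 0, n_ctx)
        lig = complete_edges(n_lig) + n_ctx
        return np.concatenate([ctx_edges.reshape(-1, 2), cross, lig.reshape(-1, 2)], axis=0)

    def __call__(
        self,
        ctx_pos: Tensor,
        ctx_scal: Tensor,
        ctx_vec: Tensor | None,
        lig_pos: Tensor,
        lig_feat: Tensor,
        t_norm: float,
        alpha_t: float,
        sigma_t: float,
        ctx_is_atoms: bool = False,
    ) -> tuple[Tensor, Tensor]:
        """Predict ε̂ for the ligand nodes.

        Internally the network predicts the clean state ẑ_0 — positions as an
        equivariant offset from the noisy position, features directly — and
        ε̂ = (z_t − α_t ẑ_0)/σ_t.  This keeps the reverse chain numerically
        stable at high noise levels, where ε̂ must track z_t closely.  The
        computation is centred on the context centroid, so predictions only
        depend on geometry relative to the conditioning context.
        """
        cfg = self.cfg
        n_ctx, n_lig = ctx_pos.shape[0], lig_pos.shape[0]
        centroid = ctx_pos.mean(axis=0, keepdims=True)
        ctx_pos = ctx_pos - centroid
        lig_pos = lig_pos - centroid
        tc = Tensor(np.full((n_ctx, 1), t_norm))
        tl = Tensor(np.full((n_lig, 1), t_norm))
        h = concat(
            [self.ctx_in(concat([ctx_scal, tc])), self.lig_in(concat([lig_feat, tl]))], axis=0
        )
        x = concat([ctx_pos, lig_pos], axis=0)
        edges = self._edges(ctx_pos.data, n_lig, ctx_is_atoms)
        if cfg.backbone == "egnn":
            movable = np.concatenate([np.zeros(n_ctx), np.ones(n_lig)])
            for layer in self.layers:
                h, x = layer(h, x, edges, movable_mask=movable)
            x0_hat = x[n_ctx:]
            s0_hat = self.out_s(h[n_ctx:])
        else:
            if ctx_vec is None:
                ctx_vec = Tensor(np.zeros((n_ctx, cfg.c, 3)))
            v = concat([ctx_vec, Tensor(np.zeros((n_lig, cfg.c, 3)))], axis=0)
            for layer in self.layers:
                h, v = layer(h, x, v, edges)
            s0_hat, v_out = self.readout(h[n_ctx:], v[n_ctx:])
            x0_hat = lig_pos + v_out.reshape(n_lig, 3)
        eps_x = (lig_pos - alpha_t * x0_hat) * (1.0 / sigma_t)
        eps_s = (lig_feat - alpha_t * s0_hat) * (1.0 / sigma_t)
        return eps_x, eps_s

    def batched(self, items: list[dict], ctx_is_atoms: bool = False):
        """Run the denoiser once over the disjoint union of several
        context+ligand systems.

        Each item carries ``ctx_pos/ctx_scal/ctx_vec`` tensors, noisy
        ``lig_pos/lig_feat`` tensors and scalars ``t_norm/alpha/sigma``.
        Equivalent to calling the layer per system; returns a list of
        (eps_x, eps_s) tensor pairs.
        """
        cfg = self.cfg
        n_ctx_list = [it["ctx_pos"].shape[0] for it in items]
        n_lig_list = [it["lig_pos"].shape[0] for it in items]
        ctx_off = np.concatenate([[0], np.cumsum(n_ctx_list)])
        lig_off = np.concatenate([[0], np.cumsum(n_lig_list)])
        n_ctx_tot, n_lig_tot = int(ctx_off[-1]), int(lig_off[-1])

        ctx_pos_parts, lig_pos_parts = [], []
        for it in items:
            centroid = it["ctx_pos"].mean(axis=0, keepdims=True)
            ctx_pos_parts.append(it["ctx_pos"] - centroid)
            lig_pos_parts.append(it["lig_pos"] - centroid)
        ctx_pos = concat(ctx_pos_parts, axis=0)
        lig_pos = concat(lig_pos_parts, axis=0)
        ctx_scal = concat([it["ctx_scal"] for it in items], axis=0)
        lig_feat = concat([it["lig_feat"] for it in items], axis=0)
        tc = Tensor(np.repeat([it["t_norm"] for it in items], n_ctx_list).reshape(-1, 1))
        tl = Tensor(np.repeat([it["t_norm"] for it in items], n_lig_list).reshape(-1, 1))
        h = concat(
            [self.ctx_in(concat([ctx_scal, tc])), self.lig_in(concat([lig_feat, tl]))], axis=0
        )
        x = concat([ctx_pos, lig_pos], axis=0)

        edge_parts = []
        for b, it in enumerate(items):
            e = self._edges(ctx_pos_parts[b].data, n_lig_list[b], ctx_is_atoms)
            # local indices: ctx 0..K-1, lig K..K+n-1 → global blocks
            is_lig_src = e[:, 0] >= n_ctx_list[b]
            is_lig_dst = e[:, 1] >= n_ctx_list[b]
            g = e.copy()
            g[:, 0] = np.where(
                is_lig_src,
                e[:, 0] - n_ctx_list[b] + n_ctx_tot + lig_off[b],
                e[:, 0] + ctx_off[b],
            )
            g[:, 1] = np.where(
                is_lig_dst,
                e[:, 1] - n_ctx_list[b] + n_ctx_tot + lig_off[b],
                e[:, 1] + ctx_off[b],
            )
            edge_parts.append(g)
        edges = np.concatenate(edge_parts, axis=0)

        if cfg.backbone == "egnn":
            movable = np.concatenate([np.zeros(n_ctx_tot), np.ones(n_lig_tot)])
            for layer in self.layers:
                h, x = layer(h, x, edges, movable_mask=movable)
            x0_hat = x[n_ctx_tot:]
            s0_hat = self.out_s(h[n_ctx_tot:])
        else:
            vec_parts = []
            for b, it in enumerate(items):
                if it.get("ctx_vec") is None:
                    vec_parts.append(Tensor(np.zeros((n_ctx_list[b], cfg.c, 3))))
                else:
                    vec_parts.append(it["ctx_vec"])
            v = concat(vec_parts + [Tensor(np.zeros((n_lig_tot, cfg.c, 3)))], axis=0)
            for layer in self.layers:
                h, v = layer(h, x, v, edges)
            s0_hat, v_out = self.readout(h[n_ctx_tot:], v[n_ctx_tot:])
            x0_hat = lig_pos + v_out.reshape(n_lig_tot, 3)
        alpha = Tensor(np.repeat([it["alpha"] for it in items], n_lig_list).reshape(-1, 1))
        inv_sigma = Tensor(
            np.repeat([1.0 / it["sigma"] for it in items], n_lig_list).reshape(-1, 1)
        )
        eps_x = (lig_pos - alpha * x0_hat) * inv_sigma
        eps_s = (lig_feat - alpha * s0_hat) * inv_sigma
        out = []
        for b in range(len(items)):
            lo, hi = int(lig_off[b]), int(lig_off[b + 1])
            out.append((eps_x[lo:hi], eps_s[lo:hi]))
        return out


class KeypointDiffusionModel(Module):
    """Encoder + denoiser + schedule, with training and sampling loops."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.ligand_vocab = ElementVocabulary(config.ligand_vocab)
        self.pocket_vocab = ElementVocabulary(config.pocket_vocab)
        self.schedule: NoiseSchedule = make_schedule(config.n_steps, config.schedule_kind)
        if config.representation == "keypoint":
            self.encoder = PocketEncoder(self.pocket_vocab, config.encoder, rng)
            ctx_dim = config.encoder.d
        else:
            self.encoder = None
            ctx_dim = self.pocket_vocab.size
        self.denoiser = Denoiser(
            self.ligand_vocab.size, ctx_dim, config.denoiser, rng, config.feature_scale
        )

    # ----------------------------------------------------------- conditioning
    @property
    def _ctx_is_atoms(self) -> bool:
        return self.config.representation != "keypoint"

    def encode(self, pocket: AtomCloud) -> KeypointCloud:
        if self.encoder is None:
            raise ValueError("model has no encoder (non-keypoint representation)")
        return self.encoder(pocket)

    def _context_tensors(self, context):
        """Context as (positions, scalars, vectors) tensors."""
        if isinstance(context, KeypointCloud):
            vec = None if context.vectors is None else Tensor(context.vectors)
            return Tensor(context.positions), Tensor(context.scalars), vec
        return Tensor(context.positions), Tensor(context.features), None

    # ------------------------------------------------------------- prediction
    def predict_noise(self, z_t: DiffusionState, context, t: int | None = None) -> NoisePrediction:
        """ε̂ for a noised ligand given the (fixed) conditioning context.

        ``context`` is a :class:`KeypointCloud` or a context
        :class:`AtomCloud`; its nodes are never moved.
        """
        t = z_t.t if t is None else t
        ctx_pos, ctx_scal, ctx_vec = self._context_tensors(context)
        if z_t.features.shape[1] != self.ligand_vocab.size:
            raise ValueError("ligand feature dimension does not match the vocabulary")
        eps_x, eps_s = self.denoiser(
            ctx_pos,
            ctx_scal,
            ctx_vec,
            Tensor(z_t.positions),
            Tensor(z_t.features),
            t / self.schedule.n_steps,
            self.schedule.alpha[t],
            self.schedule.sigma[t],
            ctx_is_atoms=self._ctx_is_atoms,
        )
        return NoisePrediction(eps_x, eps_s).numpy()

    # --------------------------------------------------------------- training
    def train_step(
        self,
        batch: list[tuple[AtomCloud, AtomCloud]],
        optimizer: Adam,
        cfg: TrainConfig,
        rng: np.random.Generator,
        ot_cfg: OTConfig | None = None,
    ) -> dict:
        """One optimisation step on a batch of (pocket, ligand) pairs.

        Per example: centre on the pocket, encode keypoints, draw a uniform
        timestep, noise the ligand, predict the noise, and combine the
        denoising loss with λ_OT times the keypoint-alignment loss.  The
        transport plan is constant in the backward pass; gradients flow
        end-to-end through denoiser and encoder.
        """
        ot_cfg = ot_cfg or OTConfig()
        optimizer.zero_grad()
        n_b = len(batch)
        centered = [center_on_pocket(p, l)[:2] for p, l in batch]
        ot_losses: list[Tensor] = []
        items: list[dict] = []
        eps_targets: list[NoisePrediction] = []
        if self.encoder is not None:
            encoded = self.encoder.encode_tensors_batch([p for p, _ in centered])
        for b, (pocket, ligand) in enumerate(centered):
            if self.encoder is not None:
                kp_pos, kp_h, kp_v, _ = encoded[b]
                if cfg.ot_weight > 0:
                    interface = compute_interface_points(ligand, pocket, ot_cfg)
                    ot_losses.append(ot_align_loss_tensor(kp_pos, interface, ot_cfg))
                frame = kp_pos.data.mean(axis=0)  # detached diffusion frame
                ctx_pos = kp_pos - Tensor(frame)
                ctx_scal, ctx_vec = kp_h, kp_v
            else:
                frame = pocket.positions.mean(axis=0)
                ctx_pos = Tensor(pocket.positions - frame)
                ctx_scal, ctx_vec = Tensor(pocket.features), None
            t = int(rng.integers(1, self.schedule.n_steps + 1))
            shifted = ligand.translated(-frame)
            scaled = AtomCloud(
                shifted.positions, shifted.features * self.config.feature_scale, kind="ligand"
            )
            z_t, eps = forward_diffuse(scaled, t, self.schedule, rng)
            eps_targets.append(eps)
            items.append(
                dict(
                    ctx_pos=ctx_pos,
                    ctx_scal=ctx_scal,
                    ctx_vec=ctx_vec,
                    lig_pos=Tensor(z_t.positions),
                    lig_feat=Tensor(z_t.features),
                    t_norm=t / self.schedule.n_steps,
                    alpha=self.schedule.alpha[t],
                    sigma=self.schedule.sigma[t],
                )
            )
        preds = self.denoiser.batched(items, ctx_is_atoms=self._ctx_is_atoms)
        dsm_vals, ot_vals = [], []
        total = Tensor(0.0)
        for b, ((eps_x, eps_s), eps) in enumerate(zip(preds, eps_targets)):
            l_dsm = denoising_loss(eps, NoisePrediction(eps_x, eps_s), cfg.w_x, cfg.w_s)
            total = total + l_dsm
            dsm_vals.append(float(l_dsm.data))
        for l_ot in ot_losses:
            total = total + cfg.ot_weight * l_ot
            ot_vals.append(float(l_ot.data))
        total = total * (1.0 / n_b)
        if not np.isfinite(total.data):
            raise FloatingPointError(
                f"non-finite loss (dsm={dsm_vals}, ot={ot_vals})"
            )
        total.backward()
        if cfg.clip_norm is not None:
            clip_gradients(optimizer.params, cfg.clip_norm)
        optimizer.step()
        return {
            "dsm": float(np.mean(dsm_vals)),
            "ot": float(np.mean(ot_vals)) if ot_vals else 0.0,
            "total": float(total.data),
        }

    # --------------------------------------------------------------- sampling
    def sample_ligand(
        self,
        context,
        n_atoms: int,
        rng: np.random.Generator,
        schedule: NoiseSchedule | None = None,
    ) -> AtomCloud:
        """Generate one ligand conditioned on a fixed context.

        Starts from a standard-normal prior centred on the context centroid,
        runs all reverse steps, and decodes features to exact one-hot by
        argmax.  Returned positions are in the context's frame.
        """
        if n_atoms < 1:
            raise ValueError("need at least one atom")
        schedule = schedule or self.schedule
        ctx_pos, ctx_scal, ctx_vec = self._context_tensors(context)
        frame = ctx_pos.data.mean(axis=0)
        ctx_pos = Tensor(ctx_pos.data - frame)
        f = self.ligand_vocab.size
        z = DiffusionState(
            rng.standard_normal((n_atoms, 3)), rng.standard_normal((n_atoms, f)), schedule.n_steps
        )
        for t in range(schedule.n_steps, 0, -1):
            eps_x, eps_s = self.denoiser(
                ctx_pos,
                ctx_scal,
                ctx_vec,
                Tensor(z.positions),
                Tensor(z.features),
                t / schedule.n_steps,
                schedule.alpha[t],
                schedule.sigma[t],
                ctx_is_atoms=self._ctx_is_atoms,
            )
            z = reverse_step(z, NoisePrediction(eps_x, eps_s).numpy(), schedule, rng)
        one_hot = np.zeros((n_atoms, f))
        one_hot[np.arange(n_atoms), np.argmax(z.features, axis=1)] = 1.0
        return AtomCloud(z.positions + frame, one_hot, kind="ligand")

    def sample_ligands_batch(
        self,
        contexts: list,
        n_atoms_list: list[int],
        rng: np.random.Generator,
        schedule: NoiseSchedule | None = None,
    ) -> list[AtomCloud]:
        """Sample one ligand per context, running the reverse chains jointly
        on a disjoint union graph (same result class as
        :meth:`sample_ligand`, much faster for many contexts)."""
        schedule = schedule or self.schedule
        f = self.ligand_vocab.size
        ctx_items = []
        frames = []
        for context in contexts:
            ctx_pos, ctx_scal, ctx_vec = self._context_tensors(context)
            frame = ctx_pos.data.mean(axis=0)
            frames.append(frame)
            ctx_items.append((Tensor(ctx_pos.data - frame), ctx_scal, ctx_vec))
        states = [
            DiffusionState(
                rng.standard_normal((n, 3)), rng.standard_normal((n, f)), schedule.n_steps
            )
            for n in n_atoms_list
        ]
        for t in range(schedule.n_steps, 0, -1):
            items = [
                dict(
                    ctx_pos=cp,
                    ctx_scal=cs,
                    ctx_vec=cv,
                    lig_pos=Tensor(z.positions),
                    lig_feat=Tensor(z.features),
                    t_norm=t / schedule.n_steps,
                    alpha=schedule.alpha[t],
                    sigma=schedule.sigma[t],
                )
                for (cp, cs, cv), z in zip(ctx_items, states)
            ]
            preds = self.denoiser.batched(items, ctx_is_atoms=self._ctx_is_atoms)
            states = [
                reverse_step(z, NoisePrediction(ex, es).numpy(), schedule, rng)
                for z, (ex, es) in zip(states, preds)
            ]
        out = []
        for z, frame, n in zip(states, frames, n_atoms_list):
            one_hot = np.zeros((n, f))
            one_hot[np.arange(n), np.argmax(z.features, axis=1)] = 1.0
            out.append(AtomCloud(z.positions + frame, one_hot, kind="ligand"))
        return out

    def sample_from_pocket(
        self,
        pocket: AtomCloud,
        n_atoms: int,
        rng: np.random.Generator,
    ) -> AtomCloud:
        """Centre the pocket, build the context, sample, and map back to the
        pocket's original frame."""
        offset = -pocket.positions.mean(axis=0)
        centered = pocket.translated(offset)
        context = self.encode(centered) if self.encoder is not None else centered
        ligand = self.sample_ligand(context, n_atoms, rng)
        return ligand.translated(-offset)

    # ------------------------------------------------------------ persistence
    def save(self, path) -> None:
        from . import __version__

        meta = {"format_version": 1, "keydiff_version": __version__, "config": self.config.to_dict()}
        arrays = {f"param_{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, __config__=np.bytes_(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "KeypointDiffusionModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__config__"]).decode())
            config = ModelConfig.from_dict(meta["config"] if "config" in meta else meta)
            model = cls(config, np.random.default_rng(0))
            arrays = [data[f"param_{i}"] for i in range(len(model.parameters()))]
        model.load_state_arrays(arrays)
        return model


def train_model(
    model: KeypointDiffusionModel,
    dataset: list,
    cfg: TrainConfig,
    n_epochs: int,
    rng: np.random.Generator,
    log_every: int = 0,
) -> list[dict]:
    """Adam training over a dataset of toy complexes or (pocket, ligand)
    pairs; returns the per-step loss reports."""
    pairs = [
        (c.pocket, c.ligand) if hasattr(c, "pocket") else tuple(c) for c in dataset
    ]
    params = model.parameters()
    optimizer = Adam(params, lr=cfg.learning_rate)
    ema = [p.data.copy() for p in params] if cfg.ema_decay is not None else None
    history: list[dict] = []
    for epoch in range(n_epochs):
        if cfg.final_learning_rate is not None and n_epochs > 1:
            frac = epoch / (n_epochs - 1)
            optimizer.lr = cfg.learning_rate * (cfg.final_learning_rate / cfg.learning_rate) ** frac
        order = rng.permutation(len(pairs))
        for lo in range(0, len(pairs), cfg.batch_size):
            batch = [pairs[i] for i in order[lo : lo + cfg.batch_size]]
            report = model.train_step(batch, optimizer, cfg, rng)
            if ema is not None:
                d = cfg.ema_decay
                for e, p in zip(ema, params):
                    e *= d
                    e += (1.0 - d) * p.data
            history.append(report)
            if log_every and len(history) % log_every == 0:
                print(
                    f"step {len(history)}: total={report['total']:.4f} "
                    f"dsm={report['dsm']:.4f} ot={report['ot']:.4f}"
                )
    if ema is not None:
        # evaluate and sample with the averaged weights (standard practice
        # for diffusion models; smooths late-training oscillations)
        for p, e in zip(params, ema):
            p.data = e
    return history
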