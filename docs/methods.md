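# Methods

`keydiff` implements pocket-conditioned ligand generation with a conditional
equivariant diffusion model whose protein context is compressed into a
small, learned *keypoint* point cloud. This note records the model, the
numerical choices behind it, what the synthetic data does and does not
emulate, and the known limitations.

## Model

**Representation.** A molecule with N atoms is a point cloud
z = [x, s] with positions x ∈ R^{N×3} (Å) and one-hot atom-type features
s ∈ R^{N×f}. Pockets and ligands are both such clouds; graphs over them are
purely geometric (edges where the Euclidean distance is strictly below a
per-edge-type cutoff; ligand and context↔ligand subgraphs are complete by
default because ligands are small and every ligand atom must see the
conditioning context).

**Forward diffusion.** A variance-preserving process
q(z_t | z_0) = N(α_t z_0, σ_t² I) with α_t² + σ_t² = 1, applied identically
to positions and (continuously relaxed) type features. The default schedule
is the polynomial α_t² ∝ (1 − (t/T)²)², affinely clipped so α_0 ≈ 1−10⁻⁷
and α_T ≈ 3·10⁻⁴; a cosine schedule is available. One upstream description
of this process equates α_t with 1 − σ_t², which contradicts variance
preservation; we read it as α_t² = 1 − σ_t² (the convention of equivariant
diffusion models) and treat the other form as a typo.

**Noise prediction.** The denoiser ε̂_θ(z_t^{(L)}, context, t) sees the noisy
ligand plus a fixed conditioning context — the keypoint cloud (default), the
all-atom pocket, or a Cα cloud — as a heterogeneous graph. Context nodes
never move. Two E(3)-backbones are provided:

* **EGNN**: scalar features per node plus the position; messages
  m_ij = φ_e(h_i, h_j, ‖x_i−x_j‖², RBF(d_ij)), coordinate updates along
  relative directions with the canonical 1/(d+1) damping, residual scalar
  updates. Only ligand coordinates are updated.
* **GVP**: nodes carry c additional vector features; message and update
  functions are geometric vector perceptrons (rotation-equivariant channel
  mixing, norm feedback into the scalar track, sigmoid vector gating); mean
  aggregation. Positions are never updated; an output GVP reads the noise
  vector off the vector channels.

Internally the network predicts the clean state: positions as an
equivariant offset from the noisy position (ẑ0 = z_t + Δ), features
directly, and ε̂ = (z_t − α_t ẑ0)/σ_t. This is algebraically the same
ε-objective but numerically far better behaved: near t = T the ancestral
sampler divides by α-ratios, and a free-form ε̂ whose error is O(δ) produces
O(δ/α) excursions (pilot chains diverged by three orders of magnitude). In
the ẑ0 form, ε̂ → z_t as α → 0 holds structurally. The categorical output
head is initialised neutrally (zero weights, bias 1/f) so the
weakly-trained high-noise regime predicts the uniform categorical and the
reverse chain accumulates no atom-type drift; the position head keeps its
random initialisation — zeroing it was found to slow the learning of large
conditional displacements.

The timestep enters as t/T appended to every node's scalar input. All
computations are centred on the context centroid, making predictions
invariant to joint translations and equivariant to rotations (tested to
1e-8 in float64 over random rigid motions).

**Loss.** L = ‖ε − ε̂‖² averaged over all nodes and channels (positions and
features together, with optional reweighting), with the timestep drawn
uniformly from {1..T} per example, plus λ_OT times the keypoint-alignment
loss below (λ_OT = 1 by default; the combination weight is not prescribed
upstream).

**Reverse process.** Gaussian ancestral steps with the ε-parameterised
posterior mean μ = (z_t − (σ²_{t|t−1}/σ_t)ε̂)/α_{t|t−1} and the standard
(lower) posterior variance; the final step adds no noise. Sampling starts
from a standard normal prior centred on the context centroid; features are
decoded to one-hot by argmax at t = 0.

## Pocket encoder

The encoder maps an all-atom pocket to exactly K keypoints (positions,
scalar features, and — with the GVP backbone — vector features):

1. two rounds of message passing between pocket atoms;
2. attention placement: K learned queries per head (4 heads) score pocket
   embeddings via scaled dot products; each keypoint is the
   attention-weighted convex combination of atom positions, so keypoints
   cannot leave the pocket's convex hull and placement is rigid-motion
   equivariant (weights depend only on invariant embeddings and distances).
   Placement runs for two rounds: the second round adds a learned function
   of the RBF-expanded distance to the provisional placement to the logits,
   letting keypoints balance "local patch" against "far counterweight"
   atoms (the exact upstream placement equations are not public; this is
   our reconstruction within the dot-product-attention family);
3. graph rewiring: each keypoint keeps incoming edges from its n_rw = 8
   nearest pocket atoms only (ties break by atom index);
4. two rounds of pocket→keypoint message passing endow keypoints with
   spatially localized features. Keypoint scalars start from learned
   per-keypoint embeddings; vector features start at zero.

**Interface alignment.** For each training complex the interface points are
the midpoints of all ligand/pocket atom pairs strictly closer than 5 Å
("median point" of a two-point pair is read as the midpoint). The alignment
loss is the exact optimal-transport cost, under uniform marginals, between
keypoints and interface points with squared Euclidean cost (a config switch
selects the plain distance). The plan is solved exactly in the forward pass
— Hungarian when S = K (the uniform-marginal optimum is a scaled
permutation), otherwise the transportation LP via HiGHS; no entropic
regularisation, since S and K are at most a few hundred — and is held
constant in the backward pass. Complexes with no 5 Å contact contribute
zero alignment loss with a warning.

## Frames and translation handling

Each complex is centred on the pocket centroid. The diffusion itself is
anchored at the *context* centroid (for the keypoint model, the keypoint
centroid, detached from the autodiff graph): training noises
x_0 − centroid, and sampling places the prior there. This conditional-frame
anchoring replaces the zero-centre-of-mass subspace construction needed by
unconditional equivariant diffusion models.

## Synthetic complexes

The generator emulates, at desk scale, the statistical structure the model
assumes about real complexes:

* a concave pocket: ~56 atoms on a hemispherical shell (R = 8 Å, light
  radial jitter, 1.2 Å minimum spacing) around a cavity ball (r = 3.5 Å);
* a *binding hotspot*: a random rim-ward direction where the wall is
  enriched in polar atom types and four pocket atoms protrude toward the
  cavity like side chains (at r + 1.3 Å). The ligand (5–10 atoms, uniform
  sizes, iid carbon-rich types) packs toward the hotspot inside the cavity
  with steric margins — ≥ 1.5 Å from every pocket atom and atom centres at
  least 0.5 Å (a van-der-Waals margin) inside the cavity surface; draws
  without a sub-5 Å contact are rejected (the ligand size is drawn before
  the retry loop so rejection cannot bias the size distribution).

The hotspot is the load-bearing design choice: it makes the protein/ligand
interface *predictable from the pocket alone*, which is precisely the
property of real binding sites (chemically marked subpockets, protruding
hotspot residues) that lets a pocket encoder learn anything about interface
geometry. Without it — ligands placed uniformly in the cavity — the
interface position is statistically independent of the pocket and no
encoder, however good, can align keypoints to it.

What the toy data does **not** emulate: bonded structure, realistic
stereochemistry and torsions, residue-level structure, side-chain rotamers,
solvent, or binding energetics. Passing the recovery experiment therefore
demonstrates that the architecture and losses can extract and use this
class of geometric/chemical signal end-to-end — not that the model attains
useful accuracy on experimental complexes.

## Recovery experiment (reduced scale)

The end-to-end check trains the GVP keypoint model (K = 8, T = 200, widths
d = 32 / c = 8, 4 denoiser layers) on 2,000 generated complexes for 7
epochs with Adam (batch 8, lr 5·10⁻³ decayed geometrically to 1.25·10⁻³,
global gradient-norm clip 10 — the ε-loss carries (α/σ)² weights that spike
at small t — and the feature part of the loss weighted 2×, which improves
the calibration of sampled atom-type frequencies). It then measures, on held-out pockets: the mean
keypoint-to-nearest-interface-point distance before vs after training,
the fraction of sampled ligand atoms inside the cavity ball, and sampled
element frequencies against the training marginals. These problem sizes are
the package's reduced-scale stand-in for database-scale training and
keep one run within a few CPU-minutes.

## Numerical choices

* Float64 throughout; equivariance identities hold to ~1e-10.
* One-hot features are scaled by 2 in the diffusion space (argmax decoding
  is scale-invariant): the larger amplitude lets atom types resolve earlier
  in the reverse chain, where the network is better trained, and improves
  type-marginal calibration.
* Distances are expanded in 16 Gaussians over 0–10 Å; squared distances are
  scaled by 0.01 before entering MLPs.
* Strict inequality at every distance cutoff (consistent with the 5 Å
  interface rule); k-nearest ties break by node index.
* Gradient flows end-to-end through encoder and denoiser; the OT plan and
  the diffusion frame are the only detached quantities.
* Batched training and sampling run on disjoint-union graphs and are
  verified to match per-example execution to 1e-10.
* Empty edge lists leave node states unchanged; single-atom pockets place
  every keypoint on that atom (convex combination of one point).

## Limitations

* No bond perception: generated SDF files carry coordinates and elements
  only; valence-aware post-processing is out of scope.
* Evaluation proxies (in-place RMSD, clash fraction, cavity containment,
  graph-size accounting) replace force-field minimisation and docking
  scores, which need external binaries; wall-clock time is logged but never
  asserted — the inference-cost claim is made through conditioning-node and
  per-step edge counts.
* The joint pocket+ligand diffusion / inpainting variant, classifier-free
  guidance, and accelerated (DDIM-style) samplers are not implemented.
* The autodiff engine is minimal by design (no GPU, no kernel fusion);
  training beyond desk scale is out of scope.
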