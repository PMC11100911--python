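"""Compress a pocket into a fixed-size keypoint cloud.

The encoder runs message passing over the pocket atoms, places K keypoints
by dot-product attention (convex combinations of atom positions), rewires
the graph to the nearest pocket atoms and extracts local features.  The
output always has exactly K nodes, whatever the pocket size.
"""

import numpy as np

from keydiff import EncoderConfig, LIGAND_VOCAB, PocketEncoder, ToyComplexConfig, generate_toy_complex

rng = np.random.default_rng(1)
cx = generate_toy_complex(ToyComplexConfig(), rng)

encoder = PocketEncoder(LIGAND_VOCAB, EncoderConfig(n_keypoints=8, d=32, c=8), rng)
kp = encoder(cx.pocket)

print(f"pocket: {cx.pocket.n_atoms} atoms  →  keypoints: {kp.n_keypoints}")
print(f"keypoint scalar features: {kp.scalars.shape}, vector features: {kp.vectors.shape}")
centroid = cx.pocket.positions.mean(axis=0)
for i, pos in enumerate(kp.positions):
    print(f"  keypoint {i}: ({pos[0]: .2f}, {pos[1]: .2f}, {pos[2]: .2f}) Å, "
          f"{np.linalg.norm(pos - centroid):.2f} Å from the pocket centroid")

# Untrained keypoints cluster near the pocket centroid (attention weights are
# near-uniform before training); training with the optimal-transport
# alignment loss pulls them to the protein/ligand interface.
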