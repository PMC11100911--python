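"""Train a small keypoint diffusion model, sample ligands, and score them.

Uses a deliberately tiny configuration (200 complexes, 2 epochs) so the
script finishes in about a minute; the full-scale recovery experiment lives
in `keydiff.recovery` and `scripts/acceptance.py`.
"""

import numpy as np

from keydiff import (
    DenoiserConfig,
    EncoderConfig,
    KeypointDiffusionModel,
    ModelConfig,
    ToyComplexConfig,
    TrainConfig,
    evaluate_run,
    generate_dataset,
    train_model,
)

rng = np.random.default_rng(0)
toy = ToyComplexConfig()
train_set = generate_dataset(200, toy, rng)
test_set = generate_dataset(4, toy, rng)

model = KeypointDiffusionModel(
    ModelConfig(
        encoder=EncoderConfig(n_keypoints=8, d=24, c=6),
        denoiser=DenoiserConfig(d=24, c=6, n_layers=3),
        n_steps=100,
    ),
    rng,
)
history = train_model(model, train_set, TrainConfig(batch_size=8, learning_rate=5e-3), 2, rng)
print(f"trained {len(history)} steps; loss {history[0]['total']:.2f} → {history[-1]['total']:.2f}")

# sample three ligands for one held-out pocket and score them
pocket = test_set[0].pocket
samples = [model.sample_from_pocket(pocket, test_set[0].ligand.n_atoms, rng) for _ in range(3)]
report = evaluate_run(samples, None, pocket, model.ligand_vocab, representation="keypoint", n_keypoints=8)
ref_report = evaluate_run([test_set[0].ligand], None, pocket, model.ligand_vocab, n_keypoints=8)
print(f"mean clash fraction: {report.mean_clash:.3f} "
      f"(reference ligand: {ref_report.mean_clash:.3f}; atoms closer than 2 Å to the pocket)")
print(f"element frequencies: {report.element_frequencies()}")
print(f"conditioning nodes: {report.graph_sizes['conditioning_nodes']} "
      f"(vs {pocket.n_atoms} pocket atoms)")
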