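"""Generate brain-CT-like phantoms with lesion masks and paired soft
degradations.

Each phantom carries a skull ring, textured parenchyma and a subtle
hypodense lesion (darker core inside a penumbra). The paired dataset
degrades each slice with the mild augmentations used to train the
preprocessor and reports which transforms fired.
"""

from ctprep import build_paired_dataset, generate_phantom, ssim

sample = generate_phantom(seed=7, size=256)
core_px = int(sample.masks.core.sum())
pen_px = int(sample.masks.penumbra.sum())
print(f"phantom 256x256: core {core_px} px, penumbra {pen_px} px "
      f"(disjoint: {not (sample.masks.core & sample.masks.penumbra).any()})")

pairs = build_paired_dataset(5, seed=21, size=256,
                             spec=None)
for s in pairs:
    fired = sorted(set(s.params_applied) - {"redraws"})
    print(f"seed {s.seed}: SSIM(clean, degraded) = "
          f"{ssim(s.clean, s.degraded):.3f}  transforms: {fired}")
print("SSIM close to 1 means the degradation kept structure (soft by design);")
print("the preprocessor is trained to undo exactly this photometric damage.")
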