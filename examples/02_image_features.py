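"""Build the visuo-semantic feature space for a synthetic image gallery.

Extracts the four feature blocks (Gabor, HSV, dense-SIFT bag of words,
word-vector semantics) for 12 synthetic stimulus images, fuses them with
range normalisation + PCA, and prints the dimensionalities involved.
"""

from eegretrieve.config import Config
from eegretrieve.pipeline import build_feature_space
from eegretrieve.synthetic import synth_images, synth_lexicon

images, manifest = synth_images(12, seed=1)
names = {row["stimulus_id"]: row["name"] for row in manifest}
print("gallery:", ", ".join(sorted(names.values())[:6]), "...")

lexicon = synth_lexicon(sorted(set(names.values())), dim=50, seed=1)
print(f"lexicon: {len(lexicon.vectors)} tokens x {lexicon.dim} dims")

cfg = Config()
cfg.images.resize = 64              # small images: keep the demo quick
cfg.images.sift.codebook_size = 30
fused, codebook = build_feature_space(images, names, lexicon, cfg)

print(f"codebook: {codebook.k} visual words")
for block, (lo, hi) in fused.block_slices.items():
    print(f"  block {block:<5s}: columns {lo:4d}-{hi - 1:4d} "
          f"({hi - lo} features)")
print(f"fused space: {fused.matrix.shape[0]} stimuli x "
      f"{fused.n_components} PCA components "
      f"(>=99% of the concatenated variance)")

# Each stimulus is now one row of fused.matrix: the regression target the
# EEG decoder tries to predict.
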