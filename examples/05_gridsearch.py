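"""Screen the ridge penalty and the EEG-feature count on one recording.

Runs the zero-shot cross-validation over a small alpha x k grid and prints
the score table, mirroring how the decoding hyper-parameters are tuned on a
single recording before being applied to the rest of a dataset.
"""

import numpy as np

import eegretrieve as er
from eegretrieve.config import Config
from eegretrieve.decoder import GridSearchSpec
from eegretrieve.imagefeatures import FusedFeatureSpace
from eegretrieve.synthetic import SyntheticSpec, stimulus_ids, synth_recording

rng = np.random.default_rng(0)
n_stimuli = 15
fused = FusedFeatureSpace(
    matrix=rng.normal(size=(n_stimuli, 8)),
    stimulus_ids=stimulus_ids(n_stimuli),
    loadings=np.eye(8), mean=np.zeros(8), blocks=["sem"],
    block_slices={"sem": (0, 8)}, explained_variance=np.ones(8))
spec = SyntheticSpec(n_stimuli=n_stimuli, n_presentations=5, n_channels=16,
                     srate=250.0, snr=2.0, seeds={"eeg": 6, "schedule": 7})
epochs, _ = er.preprocess(synth_recording(fused, spec), Config())

grid = GridSearchSpec(alphas=(1e-1, 1e0, 1e1, 5e1),
                      eeg_feature_counts=(100, 250, 500, 1000),
                      keep_fraction=0.5)
(best_alpha, best_k), table = er.grid_search(epochs, fused, grid)

print(f"{'alpha':>8s} {'k':>6s} {'CMC AUC %':>10s}")
for row in table:
    marker = "  <- best" if (row["alpha"], row["k"]) == (best_alpha, best_k) \
        else ""
    print(f"{row['alpha']:8.2g} {row['k']:6d} {row['auc']:10.2f}{marker}")
print(f"\nselected: alpha={best_alpha:g}, k={best_k} "
      f"(ties resolved towards smaller k, then smaller alpha)")
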