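"""Shared fixtures: a small synthetic study reused across integration tests."""

from __future__ import annotations

import numpy as np
import pytest

from eegretrieve.config import Config
from eegretrieve.imagefeatures import FusedFeatureSpace
from eegretrieve.pipeline import build_feature_space
from eegretrieve.recording import EpochArray
from eegretrieve.synthetic import (
    SyntheticSpec,
    hemisphere_layout,
    stimulus_ids,
    synth_images,
    synth_lexicon,
    synth_recording,
)


def fake_fused(n_stimuli: int, n_components: int, seed: int = 0,
               ) -> FusedFeatureSpace:
    """A stand-in fused feature space with random orthonormal-ish scores.

    Synthetic: lets decoder and forward-model tests run without paying for
    image feature extraction.
    """
    rng = np.random.default_rng(seed)
    ids = stimulus_ids(n_stimuli)
    return FusedFeatureSpace(
        matrix=rng.normal(size=(n_stimuli, n_components)),
        stimulus_ids=ids,
        loadings=np.eye(n_components),
        mean=np.zeros(n_components),
        blocks=["sem"],
        block_slices={"sem": (0, n_components)},
        explained_variance=np.ones(n_components),
    )


def linear_epochs(fused: FusedFeatureSpace, n_presentations: int,
                  n_channels: int, n_times: int = 120,
                  noise: float = 0.0, seed: int = 0,
                  permute_labels: int | None = None) -> EpochArray:
    """Epochs realising the noiseless(-ish) linear forward model directly.

    Each epoch of stimulus s is reshape(W @ f_s) plus optional Gaussian
    noise; skips the continuous-recording stage entirely.  When
    ``permute_labels`` is a seed, stimulus labels are shuffled to destroy
    the EEG-feature association while keeping the marginals.
    """
    rng = np.random.default_rng(seed)
    ids = list(fused.stimulus_ids)
    p = fused.n_components
    W = rng.normal(size=(n_channels * n_times, p))
    labels = [s for s in ids for _ in range(n_presentations)]
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    data = np.stack([
        (W @ fused.matrix[fused.index_of(s)]).reshape(n_channels, n_times)
        for s in labels])
    if noise > 0:
        data = data + rng.normal(0, noise * data.std(), size=data.shape)
    if permute_labels is not None:
        perm_rng = np.random.default_rng(permute_labels)
        labels = [labels[i] for i in perm_rng.permutation(len(labels))]
    return EpochArray(data=data, srate=120.0, stimulus_ids=labels,
                      channel_names=[f"ch{i}" for i in range(n_channels)],
                      layout=hemisphere_layout(n_channels))


@pytest.fixture(scope="session")
def small_config() -> Config:
    cfg = Config()
    cfg.images.resize = 64
    cfg.images.sift.codebook_size = 30
    return cfg


@pytest.fixture(scope="session")
def small_study(small_config):
    """12-stimulus gallery with real feature extraction on 64x64 images."""
    n_s = 12
    images, manifest = synth_images(n_s, seed=1)
    names = {r["stimulus_id"]: r["name"] for r in manifest}
    lexicon = synth_lexicon(sorted(set(names.values())), seed=1)
    fused, codebook = build_feature_space(images, names, lexicon,
                                          small_config)
    return {"images": images, "manifest": manifest, "names": names,
            "lexicon": lexicon, "fused": fused, "codebook": codebook,
            "n_stimuli": n_s}


@pytest.fixture(scope="session")
def small_recording(small_study):
    """High-SNR forward-model recording for the 12-stimulus study."""
    spec = SyntheticSpec(n_stimuli=small_study["n_stimuli"],
                         n_presentations=4, n_channels=16, srate=250.0,
                         snr=10.0, seeds={"eeg": 2, "schedule": 3})
    return synth_recording(small_study["fused"], spec), spec
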