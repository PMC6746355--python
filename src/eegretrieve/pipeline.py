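"""End-to-end orchestration: clean EEG -> image features -> decode -> bundle.

``run_pipeline`` chains the stages on in-memory objects and returns a
self-describing :class:`ResultsBundle` whose saved form (JSON/CSV + config
snapshot with hash) is enough to reproduce the decoding exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import Config
from .decoder import DecodingResult, zero_shot_cv
from .imagefeatures import (
    Codebook,
    WordVectorTable,
    build_gabor_bank,
    dense_sift,
    extract_blocks,
    fuse,
    train_codebook,
)
from .preprocessing import PreprocessReport, preprocess
from .recording import RawRecording

logger = logging.getLogger(__name__)


def config_hash(config: Config) -> str:
    text = yaml.safe_dump(json.loads(json.dumps(config.to_dict())),
                          sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    """Decoding result + cleaning report + the exact config that made them."""

    decoding: DecodingResult
    report: PreprocessReport
    config: Config
    versions: dict

    def save(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        chash = config_hash(self.config)
        summary = {
            "auc": self.decoding.auc,
            "n_stimuli": self.decoding.n_stimuli,
            "n_trials": int(len(self.decoding.ranks)),
            "eeg_feature_count": self.decoding.eeg_feature_count,
            "image_features_kept": int(self.decoding.image_feature_mask.sum()),
            "decoder_config": self.decoding.config,
            "config_hash": chash,
            "versions": self.versions,
        }
        (outdir / "results.json").write_text(json.dumps(summary, indent=1))
        pd.DataFrame({
            "trial_id": np.arange(len(self.decoding.ranks)),
            "stimulus_id": self.decoding.trial_stimuli,
            "rank": self.decoding.ranks,
        }).to_csv(outdir / "ranks.csv", index=False)
        pd.DataFrame({
            "top_x": np.arange(1, len(self.decoding.cmc) + 1),
            "fraction": self.decoding.cmc,
            "config_hash": chash,
        }).to_csv(outdir / "cmc.csv", index=False)
        report = self.report.to_dict()
        report["config_hash"] = chash
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        self.config.save(outdir / "config.yaml")
        return outdir / "results.json"


def build_feature_space(images: dict[str, np.ndarray],
                        names: dict[str, str],
                        word_table: WordVectorTable | None,
                        config: Config,
                        codebook: Codebook | None = None):
    """Extract the configured feature blocks for a gallery and fuse them.

    Trains a gallery-scale codebook on the fly when the SIFT block is
    requested without one (sampling every dense descriptor of the gallery).
    """
    icfg = config.images
    blocks = tuple(icfg.blocks)
    if "sift" in blocks and codebook is None:
        descs = np.vstack([
            dense_sift(np.asarray(img, dtype=float), icfg.sift.grid_step,
                       icfg.sift.patch_size)
            for img in images.values()])
        k = min(icfg.sift.codebook_size, max(2, len(descs) // 4))
        logger.info("training gallery codebook: k=%d from %d descriptors",
                    k, len(descs))
        codebook = train_codebook(descs, k=k, seed=config.seeds.codebook,
                                  corpus_id="gallery")
    bank = build_gabor_bank(
        n_orientations=icfg.gabor.n_orientations, sigmas=icfg.gabor.sigmas,
        ksize=icfg.gabor.ksize, lam=icfg.gabor.lam, gamma=icfg.gabor.gamma,
        psi=icfg.gabor.psi, orientation_spacing=icfg.gabor.orientation_spacing)
    feature_blocks = extract_blocks(
        images, names, bank=bank, codebook=codebook, word_table=word_table,
        blocks=blocks, grid_step=icfg.sift.grid_step, resize=icfg.resize)
    return fuse(feature_blocks, pca_components=icfg.pca_components,
                pca_variance=icfg.pca_variance), codebook


def run_pipeline(raw: RawRecording, images: dict[str, np.ndarray],
                 names: dict[str, str],
                 word_table: WordVectorTable | None = None,
                 config: Config | None = None,
                 codebook: Codebook | None = None) -> ResultsBundle:
    """Preprocess a recording, build the gallery feature space and decode."""
    config = config or Config()
    epochs, report = preprocess(raw, config)
    logger.info("cleaned: %d epochs, %d channels, %d timepoints; "
                "%d channels interpolated, %d epochs rejected, "
                "%d components removed",
                epochs.n_epochs, epochs.n_channels, epochs.n_times,
                len(report.bad_channels), len(report.rejected_epoch_indices),
                len(report.removed_components))
    fused, _ = build_feature_space(images, names, word_table, config,
                                   codebook=codebook)
    d = config.decoder
    decoding = zero_shot_cv(
        epochs, fused, alpha=d.alpha,
        n_eeg_features=min(d.n_eeg_features,
                           epochs.n_channels * epochs.n_times),
        keep_fraction=d.keep_fraction,
        stability_on_zscored=d.stability_on_zscored)
    logger.info("decoded %d trials over %d stimuli: CMC AUC %.2f%%",
                len(decoding.ranks), decoding.n_stimuli, decoding.auc)
    versions = {"eegretrieve": __version__, "numpy": np.__version__}
    return ResultsBundle(decoding=decoding, report=report, config=config,
                         versions=versions)
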