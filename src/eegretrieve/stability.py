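"""Correlation-stability scoring and selection of EEG features.

Each (channel, timepoint) sample of an epoch is treated as one candidate
feature.  A feature is *stable* if its value pattern across stimuli is
reproducible across repeated presentations: arrange the epochs as a tensor
``D`` of shape nF x nP x nS (features x presentations x stimuli) and score

    stability(f) = mean over presentation pairs (i, j) of
                   PearsonR(D[f, i, :], D[f, j, :])

with nP*(nP-1)/2 pairs.  High-stability features carry stimulus-specific
signal rather than noise, and only the top-k enter the decoder.

Epoch rejection can leave stimuli with unequal presentation counts; missing
presentation slots are stored as NaN and every pair correlation is computed
over the stimuli where both presentations exist (pairwise-complete), with
``n_pairs_used`` recording how many pairs survived per feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import EpochArray


@dataclass
class TrialTensor:
    """EEG features rearranged as nF x nP x nS; NaN marks absent slots."""

    D: np.ndarray
    stimulus_order: list[str]
    presentation_counts: dict[str, int]

    @property
    def n_features(self) -> int:
        return self.D.shape[0]

    @property
    def n_presentations(self) -> int:
        return self.D.shape[1]

    @property
    def n_stimuli(self) -> int:
        return self.D.shape[2]


@dataclass
class StabilityScores:
    """Per-feature stability in [-1, 1]; NaN where no pair was usable."""

    scores: np.ndarray
    n_pairs_used: np.ndarray


def build_trial_tensor(epochs, stimulus_ids=None) -> TrialTensor:
    """Rearrange epochs x features into the nF x nP x nS stability tensor.

    Accepts an :class:`EpochArray` (flattened channel-major, so feature
    ``f = channel * nT + time``) or an already-flat (nE x nF) matrix plus
    ``stimulus_ids``.  Stimuli keep their order of first appearance.
    Stimuli with fewer than two surviving presentations are excluded with a
    warning; missing presentation slots of retained stimuli are NaN.
    """
    if isinstance(epochs, EpochArray):
        X = epochs.flatten_features()
        stimulus_ids = epochs.stimulus_ids
    else:
        X = np.asarray(epochs, dtype=np.float64)
        if stimulus_ids is None:
            raise ValueError("stimulus_ids required with a plain matrix")
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(stimulus_ids):
        if s not in groups:
            groups[s] = []
            order.append(s)
        groups[s].append(i)
    dropped = [s for s in order if len(groups[s]) < 2]
    if dropped:
        warnings.warn(f"stimuli with <2 presentations excluded: {dropped}")
    order = [s for s in order if len(groups[s]) >= 2]
    if len(order) == 0:
        raise ValueError("no stimulus has 2+ presentations")
    n_p = max(len(groups[s]) for s in order)
    n_f = X.shape[1]
    D = np.full((n_f, n_p, len(order)), np.nan)
    for s_idx, s in enumerate(order):
        for p_idx, epoch_idx in enumerate(groups[s]):
            D[:, p_idx, s_idx] = X[epoch_idx]
    return TrialTensor(D=D, stimulus_order=order,
                       presentation_counts={s: len(groups[s]) for s in order})


def stability_scores(D: TrialTensor | np.ndarray) -> StabilityScores:
    """Mean pairwise-presentation Pearson correlation per feature.

    Pairs are dropped (and ``n_pairs_used`` decremented) when fewer than
    three stimuli are jointly present or either row has zero variance over
    the jointly present stimuli.  Features with no usable pair get NaN.
    """
    arr = D.D if isinstance(D, TrialTensor) else np.asarray(D, dtype=np.float64)
    n_f, n_p, n_s = arr.shape
    if n_s < 3:
        raise ValueError("need at least 3 stimuli for Pearson correlation")
    total = np.zeros(n_f)
    used = np.zeros(n_f, dtype=int)
    for i in range(n_p):
        for j in range(i + 1, n_p):
            a, b = arr[:, i, :], arr[:, j, :]
            valid = np.isfinite(a) & np.isfinite(b)
            cnt = valid.sum(axis=1)
            av = np.where(valid, a, 0.0)
            bv = np.where(valid, b, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                ma = av.sum(1) / cnt
                mb = bv.sum(1) / cnt
                da = np.where(valid, a - ma[:, None], 0.0)
                db = np.where(valid, b - mb[:, None], 0.0)
                cov = (da * db).sum(1)
                va = (da ** 2).sum(1)
                vb = (db ** 2).sum(1)
                r = cov / np.sqrt(va * vb)
            ok = (cnt >= 3) & (va > 0) & (vb > 0)
            total[ok] += r[ok]
            used[ok] += 1
    with np.errstate(invalid="ignore"):
        scores = np.where(used > 0, total / np.maximum(used, 1), np.nan)
    return StabilityScores(scores=scores, n_pairs_used=used)


def select_features(scores: StabilityScores | np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k most stable features.

    Ties at the cut are broken towards the lower feature index; NaN-scored
    features are never selected.
    """
    vals = scores.scores if isinstance(scores, StabilityScores) else np.asarray(scores)
    n_scored = int(np.isfinite(vals).sum())
    if not 1 <= k <= len(vals):
        raise ValueError(f"k must be in [1, {len(vals)}]")
    if k > n_scored:
        raise ValueError(f"k={k} exceeds the {n_scored} scored features")
    # stable sort on -score keeps ascending index order within ties
    keyed = np.where(np.isfinite(vals), vals, -np.inf)
    order = np.argsort(-keyed, kind="stable")
    mask = np.zeros(len(vals), dtype=bool)
    mask[order[:k]] = True
    return mask


@dataclass
class ZScaler:
    """Per-feature standardisation fitted on training epochs only."""

    mean: np.ndarray
    std: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        out = X - self.mean
        nz = self.std > 0
        out[:, nz] /= self.std[nz]
        out[:, ~nz] = 0.0              # degenerate columns carry no signal
        return out


def fit_scaler(train_flat: np.ndarray) -> ZScaler:
    X = np.asarray(train_flat, dtype=np.float64)
    if X.size == 0:
        raise ValueError("empty training set")
    return ZScaler(mean=X.mean(axis=0), std=X.std(axis=0))


def apply_scaler(scaler: ZScaler, flat: np.ndarray) -> np.ndarray:
    return scaler.transform(flat)


def stability_topography(scores, n_times: int, srate: float = 120.0,
                         window_start_ms: float = 0.0,
                         channel_names: list[str] | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarise a channel-major score vector over time and over channels.

    Returns (time_table, channel_table): the mean stability across channels
    at each time offset, and across timepoints for each channel.
    """
    vals = scores.scores if isinstance(scores, StabilityScores) else np.asarray(scores)
    if len(vals) % n_times:
        raise ValueError("score length not divisible by n_times")
    grid = vals.reshape(-1, n_times)           # nC x nT, channel-major
    time_ms = window_start_ms + np.arange(n_times) / srate * 1000.0
    time_table = pd.DataFrame({
        "time_ms": time_ms,
        "mean_stability": np.nanmean(grid, axis=0),
    })
    names = channel_names or [f"ch{i}" for i in range(grid.shape[0])]
    channel_table = pd.DataFrame({
        "channel": names,
        "mean_stability": np.nanmean(grid, axis=1),
    })
    return time_table, channel_table
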