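"""Zero-shot EEG -> image-feature decoding and retrieval scoring.

A ridge regression maps selected EEG features to the fused visuo-semantic
feature space.  Evaluation is leave-one-class-out: every stimulus is
withheld in turn, the map is trained on the remaining stimuli's epochs
(scaler, stability selection and ridge all fitted on training data only),
and the withheld epochs' predicted feature vectors are ranked against the
full image gallery by Euclidean distance.  Retrieval quality is summarised
by the cumulative match characteristic (CMC) curve and its normalised area
(AUC): 100% for always rank 1, 50% at chance.

Before ranking, image-feature columns that the EEG cannot predict are
dropped: each fold's training R-squared per column is averaged across folds
and only the best-fit fraction of columns is kept.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .imagefeatures import FusedFeatureSpace
from .recording import EpochArray
from .stability import (
    build_trial_tensor,
    fit_scaler,
    select_features,
    stability_scores,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ridge mapping
# ---------------------------------------------------------------------------

@dataclass
class RidgeModel:
    """Linear EEG->feature map: weights (n_eeg x n_img) plus intercept."""

    weights: np.ndarray
    intercept: np.ndarray
    alpha: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.weights + self.intercept


def fit_ridge(X: np.ndarray, Y: np.ndarray, alpha: float) -> RidgeModel:
    """L2-penalised least squares per output column, intercept unpenalised.

    With alpha = 0 and a rank-deficient design the minimum-norm
    (pseudo-inverse) solution is returned with a warning.
    """
    import warnings as _warnings

    X = np.asarray(X, dtype=np.float64)
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y must be row-aligned")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    xm = X.mean(axis=0)
    ym = Y.mean(axis=0)
    Xc = X - xm
    Yc = Y - ym
    if alpha == 0:
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            _warnings.warn("alpha=0 with rank-deficient design: "
                           "using the pseudo-inverse solution")
        W = np.linalg.pinv(Xc) @ Yc
    else:
        n_f = X.shape[1]
        A = Xc.T @ Xc + alpha * np.eye(n_f)
        W = np.linalg.solve(A, Xc.T @ Yc)
    return RidgeModel(weights=W, intercept=ym - xm @ W, alpha=float(alpha))


def r2_per_column(Y_true: np.ndarray, Y_pred: np.ndarray) -> np.ndarray:
    """Coefficient of determination per output column.

    R2 = 1 - SS_res / SS_tot; columns with zero variance in the truth are
    reported as 0 by convention.
    """
    Y_true = np.atleast_2d(np.asarray(Y_true, dtype=np.float64))
    Y_pred = np.atleast_2d(np.asarray(Y_pred, dtype=np.float64))
    if Y_true.shape != Y_pred.shape:
        raise ValueError("shape mismatch")
    ss_res = ((Y_true - Y_pred) ** 2).sum(axis=0)
    ss_tot = ((Y_true - Y_true.mean(axis=0)) ** 2).sum(axis=0)
    out = np.zeros(Y_true.shape[1])
    nz = ss_tot > 0
    out[nz] = 1.0 - ss_res[nz] / ss_tot[nz]
    return out


def feature_mask_from_r2(mean_r2: np.ndarray, keep_fraction: float,
                         ) -> np.ndarray:
    """Boolean mask keeping the ceil(keep_fraction * p) best-fit columns.

    Ties at the cut go to the lower column index.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    mean_r2 = np.asarray(mean_r2, dtype=np.float64)
    p = len(mean_r2)
    n_keep = int(np.ceil(keep_fraction * p))
    order = np.argsort(-mean_r2, kind="stable")
    mask = np.zeros(p, dtype=bool)
    mask[order[:n_keep]] = True
    return mask


# ---------------------------------------------------------------------------
# retrieval scoring
# ---------------------------------------------------------------------------

def rank_target(pred_vector: np.ndarray, gallery_matrix: np.ndarray,
                target_index: int, mask: np.ndarray | None = None) -> int:
    """Rank of the target image when the gallery is sorted by distance.

    Euclidean distance from the predicted vector; rank 1 is a perfect
    retrieval.  Ties are resolved deterministically: gallery rows with the
    same distance as the target but a lower index precede it.
    """
    gallery = np.asarray(gallery_matrix, dtype=np.float64)
    pred = np.asarray(pred_vector, dtype=np.float64)
    if not 0 <= target_index < len(gallery):
        raise IndexError("target not in gallery")
    if mask is not None:
        gallery = gallery[:, mask]
        pred = pred[mask]
    d = np.linalg.norm(gallery - pred, axis=1)
    dt = d[target_index]
    closer = int((d < dt).sum())
    tied_before = int(sum(1 for g in range(target_index) if d[g] == dt))
    return 1 + closer + tied_before


def cmc_curve(ranks, n_stimuli: int) -> np.ndarray:
    """curve[x-1] = fraction of trials whose target is within the top x."""
    ranks = np.asarray(ranks, dtype=int)
    if ranks.size == 0:
        raise ValueError("no ranks given")
    if ranks.min() < 1 or ranks.max() > n_stimuli:
        raise ValueError("ranks must lie in [1, n_stimuli]")
    counts = np.bincount(ranks, minlength=n_stimuli + 1)[1:]
    return np.cumsum(counts) / len(ranks)


def cmc_auc(ranks, n_stimuli: int) -> float:
    """Normalised area under the CMC curve, as a percentage.

    Equals the mean over trials of (nS - rank + 0.5) / nS, i.e. the
    trapezoidal area under the curve anchored at (0, 0) divided by nS.
    100 means every trial ranked first; uniformly random ranks give 50.
    """
    ranks = np.asarray(ranks, dtype=float)
    if ranks.size == 0:
        raise ValueError("no ranks given")
    return float(100.0 * np.mean((n_stimuli - ranks + 0.5) / n_stimuli))


# ---------------------------------------------------------------------------
# leave-one-class-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    """One cross-validation fold: the withheld stimulus and its predictions."""

    stimulus_id: str
    predictions: np.ndarray            # test epochs x image features
    train_r2: np.ndarray               # per image-feature column


@dataclass
class DecodingResult:
    """Per-trial retrieval ranks and their CMC summary for one recording."""

    ranks: np.ndarray
    trial_stimuli: list[str]
    cmc: np.ndarray
    auc: float
    n_stimuli: int
    eeg_feature_count: int
    image_feature_mask: np.ndarray
    mean_r2: np.ndarray
    config: dict = field(default_factory=dict)
    folds: list[FoldResult] = field(default_factory=list)


def zero_shot_cv(epochs: EpochArray, fused: FusedFeatureSpace,
                 alpha: float = 10.0, n_eeg_features: int = 500,
                 keep_fraction: float = 0.5,
                 stability_on_zscored: bool = True,
                 keep_folds: bool = False) -> DecodingResult:
    """Leave-one-class-out zero-shot decoding of a recording.

    Per fold (one per stimulus): fit the z-scaler on the training epochs,
    score EEG-feature stability on the (z-scored) training epochs, select
    the top ``n_eeg_features``, fit the ridge map to the fused image
    features, and predict the withheld epochs.  Training R-squared per image
    column is averaged across folds into a single mask keeping the best
    ``keep_fraction``; every withheld epoch's prediction is then ranked
    against the full gallery and the rank set scored by CMC AUC.  Withheld
    epochs never influence their own fold's scaler, stability or ridge fit.
    """
    X_all = epochs.flatten_features()
    stim_ids = list(epochs.stimulus_ids)
    gallery_ids = list(fused.stimulus_ids)
    missing = sorted(set(stim_ids) - set(gallery_ids))
    if missing:
        raise ValueError(f"epoch stimuli missing from the gallery: {missing}")
    classes = [s for s in gallery_ids if s in set(stim_ids)]
    excluded = sorted(set(gallery_ids) - set(stim_ids))
    if excluded:
        logger.warning("stimuli with zero epochs excluded from CV: %s",
                       excluded)
    n_f = X_all.shape[1]
    k = min(n_eeg_features, n_f)
    Y_all = np.stack([fused.matrix[fused.index_of(s)] for s in stim_ids])

    folds: list[FoldResult] = []
    r2_sum = np.zeros(fused.n_components)
    for held in classes:
        test_idx = [i for i, s in enumerate(stim_ids) if s == held]
        train_idx = [i for i, s in enumerate(stim_ids) if s != held]
        scaler = fit_scaler(X_all[train_idx])
        Xtr = scaler.transform(X_all[train_idx])
        Xte = scaler.transform(X_all[test_idx])
        stab_input = Xtr if stability_on_zscored else X_all[train_idx]
        tensor = build_trial_tensor(stab_input,
                                    [stim_ids[i] for i in train_idx])
        scores = stability_scores(tensor)
        mask = select_features(scores, k)
        model = fit_ridge(Xtr[:, mask], Y_all[train_idx], alpha)
        r2 = r2_per_column(Y_all[train_idx], model.predict(Xtr[:, mask]))
        r2_sum += r2
        folds.append(FoldResult(stimulus_id=held,
                                predictions=model.predict(Xte[:, mask]),
                                train_r2=r2))

    mean_r2 = r2_sum / len(classes)
    img_mask = feature_mask_from_r2(mean_r2, keep_fraction)
    ranks, trial_stimuli = [], []
    for fold in folds:
        tgt = gallery_ids.index(fold.stimulus_id)
        for pred in fold.predictions:
            ranks.append(rank_target(pred, fused.matrix, tgt, img_mask))
            trial_stimuli.append(fold.stimulus_id)
    ranks = np.asarray(ranks)
    n_s = len(gallery_ids)
    return DecodingResult(
        ranks=ranks, trial_stimuli=trial_stimuli,
        cmc=cmc_curve(ranks, n_s), auc=cmc_auc(ranks, n_s),
        n_stimuli=n_s, eeg_feature_count=k, image_feature_mask=img_mask,
        mean_r2=mean_r2,
        config={"alpha": alpha, "n_eeg_features": k,
                "keep_fraction": keep_fraction,
                "stability_on_zscored": stability_on_zscored},
        folds=folds if keep_folds else [])


# ---------------------------------------------------------------------------
# hyper-parameter gridsearch
# ---------------------------------------------------------------------------

#: ridge penalties screened during parameter optimisation
DEFAULT_ALPHA_GRID = (1e-2, 1e-1, 1e0, 1e1, 5e1, 1e2)
#: EEG-feature counts screened during parameter optimisation
DEFAULT_K_GRID = (25, 50, 75, 100, 125, 150, 175, 200, 250, 500, 750, 1000,
                  1500, 2000, 2500, 3000)


@dataclass
class GridSearchSpec:
    alphas: tuple = DEFAULT_ALPHA_GRID
    eeg_feature_counts: tuple = DEFAULT_K_GRID
    keep_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.alphas or not self.eeg_feature_counts:
            raise ValueError("grids must be non-empty")


def grid_search(epochs: EpochArray, fused: FusedFeatureSpace,
                spec: GridSearchSpec | None = None,
                ) -> tuple[tuple[float, int], list[dict]]:
    """Exhaustive CMC-AUC evaluation over alpha x feature-count.

    Returns the argmax (alpha, k) — ties towards smaller k, then smaller
    alpha — and the full score table (one row per grid point).
    """
    spec = spec or GridSearchSpec()
    n_f = epochs.n_channels * epochs.n_times
    table: list[dict] = []
    for alpha, k in itertools.product(spec.alphas, spec.eeg_feature_counts):
        res = zero_shot_cv(epochs, fused, alpha=alpha,
                           n_eeg_features=min(int(k), n_f),
                           keep_fraction=spec.keep_fraction)
        table.append({"alpha": float(alpha), "k": int(k), "auc": res.auc})
        logger.info("gridsearch alpha=%g k=%d -> AUC %.2f", alpha, k, res.auc)
    best = max(table, key=lambda r: (r["auc"], -r["k"], -r["alpha"]))
    return (best["alpha"], best["k"]), table
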