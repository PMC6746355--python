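"""Visuo-semantic stimulus feature space.

Each gallery image is described by four feature blocks spanning the levels
of the ventral visual hierarchy plus lexical semantics:

* ``gabor`` — 32 summed responses of a Gabor filter bank (8 orientations x
  4 envelope widths), modelling V1/V2 edge detectors;
* ``hsv``   — a 48-bin global colour histogram (16 bins per HSV channel);
* ``sift``  — a visual bag-of-words histogram of dense SIFT descriptors
  quantised against a k-means codebook;
* ``sem``   — a word-embedding vector for the depicted object's name
  (multi-word names average their component words' vectors).

Each block is range-normalised per row to [0, 1], the blocks are
concatenated and PCA reduces the joint space; the resulting per-stimulus
vectors are the regression targets for EEG decoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as spsignal
from scipy.spatial.distance import cdist

# ITU-R BT.601 luma weights for grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


# ---------------------------------------------------------------------------
# Gabor filter bank
# ---------------------------------------------------------------------------

@dataclass
class GaborBank:
    """A list of 2-D Gabor kernels and the (theta, sigma, ...) per kernel."""

    filters: list[np.ndarray]
    params: list[dict]

    def __len__(self) -> int:
        return len(self.filters)


def gabor_kernel(ksize: int, sigma: float, theta: float, lam: float,
                 gamma: float, psi: float) -> np.ndarray:
    """Real part of the Gabor function sampled on a ksize x ksize grid.

        g(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2))
                  * cos(2 pi x' / lambda + psi)

    with x' = x cos(theta) + y sin(theta), y' = -x sin(theta) + y cos(theta),
    centred on the kernel (so ksize must be odd).
    """
    if ksize % 2 == 0:
        raise ValueError("ksize must be odd (kernel needs a centre pixel)")
    half = ksize // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    env = np.exp(-(xr ** 2 + gamma ** 2 * yr ** 2) / (2.0 * sigma ** 2))
    return env * np.cos(2.0 * np.pi * xr / lam + psi)


def build_gabor_bank(n_orientations: int = 8,
                     sigmas=(2.0, 3.0, 4.0, 5.0),
                     ksize: int = 31, lam: float = 6.0,
                     gamma: float = 0.5, psi: float = 0.0,
                     orientation_spacing: str = "pi_over_8") -> GaborBank:
    """Bank of n_orientations x len(sigmas) kernels (default 8 x 4 = 32).

    ``orientation_spacing`` "pi_over_8" places the orientations evenly on
    [0, pi) (spacing pi/n); "pi_over_7" instead spans [0, pi] inclusive
    (spacing pi/(n-1)), an alternative reading of evenly spaced angles.
    """
    if n_orientations < 1:
        raise ValueError("need at least one orientation")
    if orientation_spacing == "pi_over_8":
        thetas = np.arange(n_orientations) * np.pi / n_orientations
    elif orientation_spacing == "pi_over_7":
        thetas = np.arange(n_orientations) * np.pi / max(n_orientations - 1, 1)
    else:
        raise ValueError(f"unknown orientation_spacing {orientation_spacing!r}")
    filters, params = [], []
    for sigma in sigmas:             # sigma-major: all orientations per sigma
        for theta in thetas:
            filters.append(gabor_kernel(ksize, sigma, theta, lam, gamma, psi))
            params.append({"theta": float(theta), "sigma": float(sigma),
                           "lambda": lam, "gamma": gamma, "psi": psi,
                           "ksize": ksize})
    return GaborBank(filters=filters, params=params)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Float grayscale via BT.601 luma weights; passes grayscale through."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        return img[..., :3] @ _LUMA
    raise ValueError(f"cannot interpret image of shape {img.shape}")


def gabor_features(image: np.ndarray, bank: GaborBank,
                   aggregate: str = "real", standardize: bool = True,
                   ) -> np.ndarray:
    """One summed filter response per bank kernel (length 32 by default).

    The grayscale image is standardised (zero mean, unit variance) unless
    ``standardize=False``; each kernel is convolved over it ("same" size,
    zero padding) and the response summed over pixels.  ``aggregate``
    "real" sums the signed cosine-phase response; "magnitude" sums |response|.
    """
    gray = to_grayscale(image)
    if gray.size == 0:
        raise ValueError("empty image")
    if standardize:
        sd = gray.std()
        gray = (gray - gray.mean()) / sd if sd > 0 else gray - gray.mean()
    out = np.empty(len(bank))
    for j, kern in enumerate(bank.filters):
        resp = spsignal.fftconvolve(gray, kern, mode="same")
        out[j] = np.abs(resp).sum() if aggregate == "magnitude" else resp.sum()
    return out


# ---------------------------------------------------------------------------
# dense SIFT + visual bag of words
# ---------------------------------------------------------------------------

def _sift_descriptor(mag: np.ndarray, ori: np.ndarray, cx: int, cy: int,
                     patch: int) -> np.ndarray:
    """128-d gradient-orientation histogram of the patch centred at (cy, cx).

    The patch is a 4 x 4 grid of cells, 8 orientation bins per cell,
    gradient magnitudes weighted by a Gaussian over the patch; the vector is
    L2-normalised, clipped at 0.2 and renormalised (standard SIFT photometric
    normalisation).
    """
    half = patch // 2
    cell = patch // 4
    m = mag[cy - half:cy + half, cx - half:cx + half]
    o = ori[cy - half:cy + half, cx - half:cx + half]
    yy, xx = np.mgrid[-half:half, -half:half] + 0.5
    w = np.exp(-(xx ** 2 + yy ** 2) / (2 * (0.5 * patch) ** 2))
    wm = m * w
    desc = np.zeros((4, 4, 8))
    bins = np.floor(o / (2 * np.pi) * 8).astype(int) % 8
    for gy in range(4):
        for gx in range(4):
            sl = np.s_[gy * cell:(gy + 1) * cell, gx * cell:(gx + 1) * cell]
            np.add.at(desc[gy, gx], bins[sl].ravel(), wm[sl].ravel())
    v = desc.ravel()
    n = np.linalg.norm(v)
    if n > 0:
        v = np.minimum(v / n, 0.2)
        n2 = np.linalg.norm(v)
        if n2 > 0:
            v = v / n2
    return v


def dense_sift(image: np.ndarray, grid_step: int = 8,
               patch_size: int = 16) -> np.ndarray:
    """SIFT descriptors on a regular grid (no keypoint detection).

    Returns an (n_keypoints, 128) array; keypoints are patch centres spaced
    ``grid_step`` pixels apart, keeping the support window inside the image.
    An image smaller than one patch yields an empty array with a warning.
    """
    gray = to_grayscale(image)
    h, w = gray.shape
    if h < patch_size or w < patch_size:
        warnings.warn("image smaller than the descriptor support; no keypoints")
        return np.empty((0, 128))
    gy, gx = np.gradient(gray)
    mag = np.hypot(gx, gy)
    ori = np.mod(np.arctan2(gy, gx), 2 * np.pi)
    half = patch_size // 2
    centres_y = range(half, h - half + 1, grid_step)
    centres_x = range(half, w - half + 1, grid_step)
    descs = [_sift_descriptor(mag, ori, cx, cy, patch_size)
             for cy in centres_y for cx in centres_x]
    return np.array(descs)


@dataclass
class Codebook:
    """K-means centroids quantising 128-d SIFT descriptors into visual words."""

    centroids: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def train_codebook(descriptor_sample: np.ndarray, k: int = 1000,
                   seed: int = 0, corpus_id: str = "unspecified") -> Codebook:
    """Cluster a descriptor sample into a k-word codebook (k-means++)."""
    from sklearn.cluster import KMeans

    X = np.asarray(descriptor_sample, dtype=np.float64)
    if len(X) < k:
        raise ValueError(f"need at least k={k} descriptors, got {len(X)}")
    if len(np.unique(X, axis=0)) < k:
        raise ValueError("fewer than k distinct descriptors in the sample")
    km = KMeans(n_clusters=k, init="k-means++", n_init=3,
                random_state=int(seed)).fit(X)
    return Codebook(centroids=km.cluster_centers_,
                    meta={"corpus_id": corpus_id, "seed": int(seed),
                          "sample_size": int(len(X))})


def vbow_histogram(descriptors: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Count of descriptors assigned to each visual word (nearest centroid).

    Euclidean assignment; ties go to the lowest centroid index.  The
    histogram sums to the number of descriptors.
    """
    hist = np.zeros(codebook.k)
    descriptors = np.asarray(descriptors, dtype=np.float64)
    if descriptors.size == 0:
        return hist
    if descriptors.shape[1] != codebook.centroids.shape[1]:
        raise ValueError("descriptor / centroid dimensionality mismatch")
    assign = np.argmin(cdist(descriptors, codebook.centroids), axis=1)
    np.add.at(hist, assign, 1)
    return hist


# ---------------------------------------------------------------------------
# HSV colour histogram
# ---------------------------------------------------------------------------

def hsv_histogram(image: np.ndarray, bins_per_channel: int = 16) -> np.ndarray:
    """Global HSV histogram: 16 bins per channel, concatenated H, S, V (48-d).

    4-bit quantisation per channel: each channel in [0, 1] maps to
    ``floor(value * 16)`` clipped to bin 15.  Each channel's bins sum to the
    pixel count.  Grayscale input is promoted to RGB first (saturation 0).
    """
    from skimage.color import rgb2hsv

    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        warnings.warn("grayscale image: promoting to RGB for the HSV histogram")
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError(f"cannot interpret image of shape {img.shape}")
    img = img[..., :3]
    if img.max() > 1.0:
        img = img / 255.0
    hsv = rgb2hsv(img)
    out = np.empty(3 * bins_per_channel)
    for c in range(3):
        q = np.minimum((hsv[..., c] * bins_per_channel).astype(int),
                       bins_per_channel - 1)
        out[c * bins_per_channel:(c + 1) * bins_per_channel] = np.bincount(
            q.ravel(), minlength=bins_per_channel)
    return out


# ---------------------------------------------------------------------------
# word-vector semantics
# ---------------------------------------------------------------------------

@dataclass
class WordVectorTable:
    """token -> M-dimensional embedding; tokens stored case-folded."""

    vectors: dict[str, np.ndarray]
    dim: int

    @classmethod
    def from_file(cls, path) -> "WordVectorTable":
        """Whitespace-delimited text: token followed by M floats per line."""
        vectors: dict[str, np.ndarray] = {}
        dim = None
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split()
                if not parts:
                    continue
                token = parts[0].lower()
                vec = np.array([float(x) for x in parts[1:]])
                if dim is None:
                    dim = len(vec)
                elif len(vec) != dim:
                    raise ValueError(
                        f"token {token!r} has {len(vec)} dims, expected {dim}")
                vectors[token] = vec
        if dim is None:
            raise ValueError("empty word-vector file")
        return cls(vectors=vectors, dim=dim)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for token, vec in self.vectors.items():
                fh.write(token + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")


def tokenize_name(name: str) -> list[str]:
    """Lower-case tokens of a stimulus name; whitespace and hyphens split."""
    return [t for t in name.lower().replace("-", " ").split() if t]


def semantic_vector(name: str, table: WordVectorTable) -> np.ndarray:
    """Embedding for a stimulus name.

    Single-word names look up their vector; multi-word expressions use the
    mean of the vectors of the words that are present in the table.
    """
    tokens = tokenize_name(name)
    present = [t for t in tokens if t in table.vectors]
    if not present:
        raise KeyError(f"no token of {name!r} in the word-vector table "
                       f"(missing: {tokens})")
    return np.mean([table.vectors[t] for t in present], axis=0)


# ---------------------------------------------------------------------------
# block assembly, normalisation, fusion
# ---------------------------------------------------------------------------

@dataclass
class FeatureBlock:
    """Per-stimulus feature matrix for one descriptor family."""

    matrix: np.ndarray
    name: str
    stimulus_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if self.matrix.shape[0] != len(self.stimulus_ids):
            raise ValueError("one row per stimulus required")


def range_normalize_rows(block: FeatureBlock) -> FeatureBlock:
    """Scale every row to [0, 1] by its own range; constant rows become 0."""
    M = block.matrix
    lo = M.min(axis=1, keepdims=True)
    hi = M.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(M)
    nz = (span > 0).ravel()
    out[nz] = (M[nz] - lo[nz]) / span[nz]
    return FeatureBlock(matrix=out, name=block.name,
                        stimulus_ids=list(block.stimulus_ids))


@dataclass
class FusedFeatureSpace:
    """PCA scores of the concatenated, range-normalised feature blocks."""

    matrix: np.ndarray                 # nS x p
    stimulus_ids: list[str]
    loadings: np.ndarray               # p x total_d
    mean: np.ndarray                   # total_d
    blocks: list[str]
    block_slices: dict[str, tuple[int, int]]
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.matrix.shape[1]

    def index_of(self, stimulus_id: str) -> int:
        return self.stimulus_ids.index(stimulus_id)


def fuse(blocks: list[FeatureBlock], pca_components: int | None = None,
         pca_variance: float = 0.99, normalize: bool = True,
         ) -> FusedFeatureSpace:
    """Range-normalise, concatenate and PCA-reduce the feature blocks.

    Blocks must share stimulus ids and order.  ``pca_components`` counts
    retained components; when None, enough components to explain
    ``pca_variance`` of the variance are kept (capped at nS - 1).  A request
    beyond the feasible rank is clipped with a warning.
    """
    from sklearn.decomposition import PCA

    if not blocks:
        raise ValueError("no feature blocks given")
    ids = list(blocks[0].stimulus_ids)
    for b in blocks[1:]:
        if list(b.stimulus_ids) != ids:
            raise ValueError("blocks disagree on stimulus ids/order")
    if normalize:
        blocks = [range_normalize_rows(b) for b in blocks]
    mats, slices, pos = [], {}, 0
    for b in blocks:
        mats.append(b.matrix)
        slices[b.name] = (pos, pos + b.matrix.shape[1])
        pos += b.matrix.shape[1]
    X = np.hstack(mats)
    n_s, total_d = X.shape
    cap = min(n_s, total_d)
    if pca_components is None:
        pca_full = PCA(n_components=min(n_s - 1, total_d)).fit(X)
        cum = np.cumsum(pca_full.explained_variance_ratio_)
        n_comp = int(np.searchsorted(cum, pca_variance) + 1)
        n_comp = min(n_comp, len(cum))
    else:
        n_comp = int(pca_components)
        if n_comp > cap:
            warnings.warn(f"pca_components={n_comp} clipped to {cap}")
            n_comp = cap
    pca = PCA(n_components=n_comp).fit(X)
    return FusedFeatureSpace(
        matrix=pca.transform(X), stimulus_ids=ids,
        loadings=pca.components_, mean=pca.mean_,
        blocks=[b.name for b in blocks], block_slices=slices,
        explained_variance=pca.explained_variance_)


def extract_blocks(images: dict[str, np.ndarray], names: dict[str, str],
                   *, bank: GaborBank | None = None,
                   codebook: Codebook | None = None,
                   word_table: WordVectorTable | None = None,
                   blocks=("gabor", "hsv", "sift", "sem"),
                   grid_step: int = 8, resize: int = 256,
                   ) -> list[FeatureBlock]:
    """Compute the requested feature blocks for a stimulus gallery.

    ``images`` maps stimulus id -> RGB array; ``names`` maps stimulus id ->
    object name.  Images are resized to ``resize`` x ``resize`` (bilinear)
    before the Gabor and SIFT extractors.
    """
    from skimage.transform import resize as sk_resize

    ids = sorted(images)
    out: list[FeatureBlock] = []
    resized: dict[str, np.ndarray] = {}
    if {"gabor", "sift"} & set(blocks):
        for s in ids:
            img = np.asarray(images[s], dtype=np.float64)
            if img.shape[:2] != (resize, resize):
                img = sk_resize(img, (resize, resize), order=1,
                                anti_aliasing=True, preserve_range=True)
            resized[s] = img
    if "gabor" in blocks:
        if bank is None:
            bank = build_gabor_bank()
        out.append(FeatureBlock(
            matrix=np.stack([gabor_features(resized[s], bank) for s in ids]),
            name="gabor", stimulus_ids=ids))
    if "hsv" in blocks:
        out.append(FeatureBlock(
            matrix=np.stack([hsv_histogram(images[s]) for s in ids]),
            name="hsv", stimulus_ids=ids))
    if "sift" in blocks:
        if codebook is None:
            raise ValueError("sift block requested but no codebook given")
        out.append(FeatureBlock(
            matrix=np.stack([
                vbow_histogram(dense_sift(resized[s], grid_step), codebook)
                for s in ids]),
            name="sift", stimulus_ids=ids))
    if "sem" in blocks:
        if word_table is None:
            raise ValueError("sem block requested but no word table given")
        out.append(FeatureBlock(
            matrix=np.stack([semantic_vector(names[s], word_table)
                             for s in ids]),
            name="sem", stimulus_ids=ids))
    return out
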