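# Methods

This note records the models, parameter choices and numerical conventions
behind `eegretrieve`, and what the synthetic benchmarks do and do not show.

## Model and assumptions

The decoding model assumes a *linear* relationship between the evoked EEG
response and a fixed per-stimulus feature vector: epoch `x` of stimulus `s`
satisfies `E[x] = T_s` with `T_s` a spatiotemporal template that is linear
in the stimulus's fused image features. Under this assumption a ridge
regression from (selected, z-scored) EEG features to image features is the
natural estimator, and zero-shot generalisation — predicting the features
of a stimulus absent from training — reduces to linear extrapolation in
the shared feature space. Nothing in the pipeline models nonlinear or
latency-variable responses; that is a stated limitation, not an oversight.

Retrieval is nearest-neighbour by Euclidean distance in the masked PCA
space, and accuracy is the cumulative match characteristic area,
`100 * mean((nS - rank + 0.5) / nS)`. This closed form equals the
trapezoidal area under the CMC curve anchored at (0, 0) and normalised by
the gallery size; a property test holds the two formulations to 1e-10.

## Cleaning chain

Stage order: band-pass → bad-channel interpolation → epoching/baselining →
epoch rejection → ICA artefact removal → within-epoch repair → polyphase
resampling to 120 Hz. Choices the underlying method description leaves
open, and how they are resolved here:

- **Filter design.** Zero-phase windowed-sinc FIR (Hamming, ≈53 dB
  stopband), length set by a transition band of max(low/4, 0.5) Hz and
  applied in one pass with the group delay compensated, so ERP latencies
  are not shifted. Default band 1–40 Hz.
- **Outlier rule.** All detectors share `flag_outliers`: |metric − mean| /
  SD **at or beyond** the threshold (default 3) is flagged, two-sided,
  with the plain population SD. The "at or beyond" boundary matters: with
  n units the largest attainable z is sqrt(n−1), and a lone extreme value
  among ten sits at exactly z = 3. A corollary worth knowing: at z = 3
  each metric can flag at most ~n/10 units, so the "more than half the
  epochs flagged" abort guard can only fire at lower thresholds.
- **Hurst exponent.** Classical rescaled-range (R/S) over dyadic block
  sizes (≥16), slope of the log–log fit. Small-sample bias puts white
  noise near 0.55 rather than 0.50; detectors only use it comparatively
  across channels/components, where the bias cancels.
- **Spherical spline.** Perrin-style kernel (stiffness m = 4, 50 Legendre
  terms, ridge 1e-5 on the Gram matrix). A test pins the interpolation
  operator to MNE's implementation at 1e-9.
- **ICA.** FastICA on the epoched, rejection-cleaned data, with
  nIC = nC − (#interpolated channels) and a fixed seed. Component
  detectors: |correlation| with the ocular proxy channel (the sensor with
  the largest anterior coordinate; ties to lower index), spatial kurtosis
  of the mixing column, Hurst exponent and mean absolute gradient of the
  source. Caveat: ICA is undetermined on a rotation-invariant (iid
  Gaussian) background, so component-level tests use non-Gaussian mixed
  backgrounds; on real EEG this is not a constraint.
- **Within-epoch repair.** Variance, median |first difference|, amplitude
  range, and |channel mean − grand mean| per channel within the epoch;
  flagged channels are re-interpolated from that epoch's data alone. At
  z = 3 across 32+ channels the rule has a small per-epoch false-positive
  rate (~0.3% per channel per metric); repairs of clean channels are
  harmless smoothing, which is the usual trade of automated thresholds.
- **Resampling.** Polyphase (`resample_poly`, linear-ramp padding), never
  bare decimation; 500→120 Hz and 1000→120 Hz are exact rational ratios.

## EEG feature stability

Features are flattened channel-major (`f = channel * nT + time`), fixed and
documented so masks decode to (channel, time) pairs. Stability is the mean
pairwise-presentation Pearson correlation of each feature's per-stimulus
pattern. Epoch rejection leaves unequal presentation counts, so missing
slots are NaN and every pair correlates over the jointly observed stimuli
(pairwise-complete), requiring ≥3 shared stimuli and nonzero variance;
`n_pairs_used` records the surviving pair count. Zero-filling absent
presentations would bias scores toward zero, hence the NaN bookkeeping.
Stability is computed after z-scoring by default (`stability_on_zscored`
switches it); Pearson correlation is affine-invariant per row, so the
choice only matters through degenerate-column handling.

## Image feature space

- Gabor bank: 8 orientations × 4 sigmas {2,3,4,5}, ksize 31, λ = 6,
  γ = 0.5, ψ = 0. Orientations default to [0, π) at π/8 spacing; a config
  switch (`pi_over_7`) spans [0, π] inclusive for the alternative reading
  of "evenly spaced". The summed response uses the real (cosine-phase)
  part; `aggregate="magnitude"` is available. Images are converted to
  grayscale with BT.601 luma weights, resized to 256×256 (bilinear) and
  standardised before filtering.
- Dense SIFT: descriptors on a regular grid (step 8 px, one scale,
  16×16 patch = 4×4 cells × 8 orientation bins, Gaussian-weighted,
  L2-normalised with 0.2 clipping). Codebook: k-means++ (fixed seed) on a
  descriptor sample; k = 1000 by default, gallery-scale codebooks
  (k ≈ 25–50) in the tests and examples.
- HSV histogram: 16 bins per channel over H, S, V in [0, 1],
  `floor(16v)` clipped to bin 15; grayscale input is promoted to RGB.
- Semantics: whitespace/hyphen tokenisation, case-folded; multi-word names
  use the mean of their in-vocabulary tokens' vectors.
- Fusion: each block is row range-normalised to [0,1] **per feature set**
  (not across the concatenation), blocks are concatenated in the order
  gabor, hsv, sift, sem, centred, and PCA-projected. The component count
  defaults to the smallest number explaining 99% of variance, capped at
  nS − 1. PCA is fitted on the full gallery: gallery image features are
  legitimately available at retrieval time and no EEG enters the fit, so
  this is not leakage.

## Decoder

Ridge is solved in closed form per output column with an unpenalised
intercept; α = 0 with a rank-deficient design falls back to the
pseudo-inverse with a warning. Per fold, the training R² per image-feature
column is recorded; after all folds the fold-averaged R² builds a single
mask keeping the best ⌈keep_fraction · p⌉ columns (default 0.5) applied at
ranking time. Withheld epochs never touch the scaler, stability scores,
ridge fit or R² of their own fold. Distance ties in ranking resolve by
gallery index (measure-zero for continuous features, but deterministic);
ranking is per single epoch, with no averaging over repeated
presentations. The gridsearch screens α ∈ {1e-2, 1e-1, 1, 10, 50, 100} and
k ∈ {25, 50, …, 3000}, ties toward smaller k then smaller α.

## Synthetic data

The generators emulate the two paradigm shapes the pipeline targets
(60 stimuli × 6 presentations at 64 ch/500 Hz; 72 × 12 at 128 ch/1 kHz)
plus smaller configurations. Per stimulus, a template
`T_s = reshape(W f_s)` (W Gaussian, drawn once per seed) is confined to
100–600 ms post-onset, Hann-tapered and smoothed so it survives the 1–40 Hz
band, then scaled so the pooled template SD is `snr` times the 10 µV
sensor-noise SD. Planted artefacts: a blink source with an
exponentially-decaying anterior topography (200 µV lobes, ~one per 5 s), a
dead channel, and 50 Hz line noise. Because the generator realises exactly
the linearity the decoder assumes, the recovery benchmark measures
parameter recovery, not model adequacy: real EEG adds 1/f background,
volume-conducted correlated noise, latency jitter and nonlinearity, none of
which the generator emulates, so passing tests bound implementation
correctness rather than real-data performance.

## Benchmark scales and expected numbers

Tests run the recovery benchmark at 30 stimuli × 6 presentations ×
32 channels (250 Hz, SNR 10), chosen to keep the full suite in a few
minutes on one CPU: the full pipeline reaches CMC AUC ≈ 97% (threshold
≥95%), and label-permuted runs average 50 ± 3% over 20 seeds. Structural
constants (32 Gabor responses, 48 HSV bins, 128-d SIFT, 7680 EEG features
for 64 ch × 120 Hz × 1 s, 864-event 72 × 12 schedule) are checked exactly.
Zero-shot accuracy at small galleries is intrinsically limited: with nS
training classes the regression sees only nS − 1 distinct targets, so
recovery AUC rises with gallery size even at fixed SNR.

## Known limitations

- Linear decoder and linear forward model only; no nonlinear or
  across-subject transfer.
- ICA component flagging inherits FastICA's indeterminacy on
  near-Gaussian data and the z-rule's small-n cap (nothing can be flagged
  among fewer than ~10 components).
- The codebook trainer is corpus-agnostic; web-scale corpora are out of
  scope, and small codebooks trained on the gallery itself are used in
  tests.
- Readers for EEGLAB/BrainVision/EDF containers are thin MNE adapters and
  are exercised only against the packed format in tests.
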