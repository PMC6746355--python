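"""Fully automated statistical-threshold EEG cleaning.

The cleaning chain takes a continuous recording to z-score-ready epochs:

1. band-pass filter (default 1-40 Hz) to strip drift and mains interference,
2. bad-channel detection (variance, mean correlation, Hurst exponent) and
   spherical-spline replacement,
3. epoching on stimulus onsets with pre-stimulus baseline subtraction,
4. epoch rejection (amplitude range, variance, channel deviation),
5. ICA decomposition with automatic artefact-component flagging (ocular
   proxy correlation, spatial kurtosis, Hurst exponent, mean gradient) and
   signal reconstruction from the remaining components,
6. within-epoch single-channel repair,
7. polyphase downsampling (default to 120 Hz).

Every detector shares the same rule: a metric is computed per unit
(channel / epoch / component) and units whose metric lies at or beyond
``z_threshold`` (default 3) standard deviations from the mean across units
are flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal, stats

from . import spherical
from .recording import (
    ConfigurationError,
    DataQualityError,
    EpochArray,
    RawRecording,
)

logger = logging.getLogger(__name__)

#: axis of the sensor layout pointing towards the front of the head
ANTERIOR_AXIS = 1


# ---------------------------------------------------------------------------
# filtering and resampling
# ---------------------------------------------------------------------------

def _design_bandpass(low_hz: float, high_hz: float, srate: float,
                     max_taps: int | None = None) -> np.ndarray:
    """Linear-phase windowed-sinc (Hamming) band-pass kernel.

    The Hamming window gives ~53 dB stopband attenuation.  The length is set
    from the narrower transition band (a quarter of the low cutoff, floored
    at 0.5 Hz) so the 1 Hz edge is actually resolved.
    """
    trans = max(0.25 * low_hz, 0.5)
    numtaps = int(round(3.3 * srate / trans)) | 1
    if max_taps is not None and numtaps > max_taps:
        numtaps = int(max_taps) | 1
        if numtaps < 3:
            raise ConfigurationError("signal too short to filter")
    return signal.firwin(numtaps, [low_hz, high_hz], pass_zero=False,
                         window="hamming", fs=srate)


def bandpass_filter(raw: RawRecording, low_hz: float = 1.0,
                    high_hz: float = 40.0) -> RawRecording:
    """Zero-phase FIR band-pass.

    The symmetric kernel is applied in a single pass with the group delay
    compensated, so ERP latencies are not shifted.
    """
    nyq = raw.srate / 2.0
    if not (0 < low_hz < high_hz):
        raise ConfigurationError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ConfigurationError(
            f"high cutoff {high_hz} Hz >= Nyquist {nyq} Hz")
    n = raw.n_samples
    h = _design_bandpass(low_hz, high_hz, raw.srate, max_taps=n - 1)
    pad = len(h) // 2
    padded = np.pad(raw.data, ((0, 0), (pad, pad)), mode="reflect")
    out = signal.fftconvolve(padded, h[None, :], mode="same", axes=1)
    return raw.copy_with(data=out[:, pad:pad + n])


def downsample(epochs: EpochArray, target_hz: float = 120.0) -> EpochArray:
    """Polyphase resampling of every epoch to ``target_hz``.

    Anti-alias filtering is part of the polyphase design; naive decimation is
    never used, so non-integer ratios (e.g. 500 -> 120 Hz) are exact.
    """
    if target_hz >= epochs.srate:
        if target_hz == epochs.srate:
            return epochs
        raise ConfigurationError("target rate must be below current rate")
    frac = Fraction(target_hz / epochs.srate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(epochs.data, up, down, axis=2, padtype="line")
    want = int(round(epochs.n_times * target_hz / epochs.srate))
    data = data[:, :, :want]
    return EpochArray(data=data, srate=float(target_hz),
                      stimulus_ids=list(epochs.stimulus_ids),
                      window=epochs.window,
                      channel_names=epochs.channel_names,
                      layout=epochs.layout)


# ---------------------------------------------------------------------------
# statistical flagging primitives
# ---------------------------------------------------------------------------

def flag_outliers(scores, z_threshold: float = 3.0) -> list[int]:
    """Indices whose score lies at or beyond ``z_threshold`` SDs from the mean.

    Uses the plain (population) mean/SD of the scores themselves.  A zero
    spread means nothing can be an outlier, so the empty list is returned.
    Non-finite scores are treated as maximally deviant and always flagged.
    """
    scores = np.asarray(scores, dtype=np.float64)
    finite = np.isfinite(scores)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite scores")
    mu = scores[finite].mean()
    sd = scores[finite].std()
    out = list(np.nonzero(~finite)[0])
    if sd > 0:
        z = np.abs(scores[finite] - mu) / sd
        # ">= threshold" so that a score at exactly z sigma is caught
        out.extend(np.nonzero(finite)[0][z >= z_threshold])
    return sorted(int(i) for i in out)


def hurst_rs(x: np.ndarray, min_block: int = 16) -> float:
    """Rescaled-range (R/S) Hurst exponent estimate.

    The series is cut into non-overlapping blocks at dyadic sizes; per block
    the range of the mean-corrected cumulative sum is divided by the block SD,
    and the slope of log(mean R/S) against log(block size) is the estimate.
    White noise gives ~0.5, persistent (integrated) series approach 1.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n < 4 * min_block:
        return np.nan
    sizes = []
    m = min_block
    while m <= n // 4:
        sizes.append(m)
        m *= 2
    log_m, log_rs = [], []
    for m in sizes:
        nblk = n // m
        blocks = x[:nblk * m].reshape(nblk, m)
        centred = blocks - blocks.mean(axis=1, keepdims=True)
        cum = np.cumsum(centred, axis=1)
        rng = cum.max(axis=1) - cum.min(axis=1)
        sd = blocks.std(axis=1)
        ok = sd > 0
        if not ok.any():
            continue
        rs = (rng[ok] / sd[ok]).mean()
        if rs > 0:
            log_m.append(np.log(m))
            log_rs.append(np.log(rs))
    if len(log_m) < 2:
        return np.nan
    slope, _ = np.polyfit(log_m, log_rs, 1)
    return float(slope)


# ---------------------------------------------------------------------------
# channel-level cleaning
# ---------------------------------------------------------------------------

def channel_scores(raw: RawRecording) -> dict[str, np.ndarray]:
    """Per-channel quality metrics: variance, mean |correlation|, Hurst.

    ``mean_correlation`` of a channel is the mean absolute Pearson
    correlation with every other channel; a channel that correlates with
    nothing has lost scalp contact.  Constant channels get correlation 0
    (undefined, reported with a warning).
    """
    if raw.n_channels < 3:
        raise ValueError("need at least 3 channels")
    if raw.n_samples < 512:
        raise ValueError("need at least 512 samples")
    data = raw.data
    variance = data.var(axis=1)
    sd = data.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn("constant channel(s): correlation reported as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.corrcoef(data))
    # undefined pairs (constant partner) contribute 0
    corr = np.where(np.isnan(corr), 0.0, corr)
    np.fill_diagonal(corr, 0.0)
    mean_corr = corr.sum(axis=1) / (raw.n_channels - 1)
    mean_corr[const] = 0.0
    hurst = np.array([hurst_rs(ch) for ch in data])
    return {"variance": variance, "mean_correlation": mean_corr, "hurst": hurst}


def flag_bad_channels(raw: RawRecording, z_threshold: float = 3.0) -> list[int]:
    """Union of outlier channels over the three channel metrics."""
    scores = channel_scores(raw)
    bad: set[int] = set()
    for vals in scores.values():
        bad.update(flag_outliers(vals, z_threshold))
    return sorted(bad)


def interpolate_channels(obj, bad_indices, layout: np.ndarray | None = None):
    """Spherical-spline replacement of bad channels; clean channels untouched.

    Works on a :class:`RawRecording` or an :class:`EpochArray` (interpolating
    across all epochs at once).  Returns the same type.
    """
    bad = sorted(set(int(i) for i in bad_indices))
    if layout is None:
        layout = obj.layout
    if layout is None:
        raise ValueError("sensor layout required for interpolation")
    n_ch = obj.data.shape[0] if isinstance(obj, RawRecording) else obj.data.shape[1]
    if bad and len(bad) >= n_ch - 3:
        raise DataQualityError("too many bad channels to interpolate")
    if not bad:
        return obj
    if isinstance(obj, RawRecording):
        return obj.copy_with(data=spherical.interpolate(obj.data, layout, bad))
    flat = np.moveaxis(obj.data, 1, 0).reshape(n_ch, -1)
    fixed = spherical.interpolate(flat, layout, bad)
    data = np.moveaxis(fixed.reshape(n_ch, obj.n_epochs, obj.n_times), 0, 1)
    return EpochArray(data=data, srate=obj.srate,
                      stimulus_ids=list(obj.stimulus_ids), window=obj.window,
                      channel_names=obj.channel_names, layout=obj.layout)


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def epoch_and_baseline(raw: RawRecording, events=None,
                       window_ms: tuple[float, float] = (0.0, 1000.0),
                       baseline_ms: tuple[float, float] = (-500.0, 0.0),
                       ) -> EpochArray:
    """Cut stimulus-locked windows and subtract each channel's baseline mean.

    The epoch window is half-open ``[start, end)`` relative to onset.  Events
    without enough surrounding data are dropped with a warning.
    """
    if events is None:
        events = raw.events
    sr = raw.srate
    w0 = int(round(window_ms[0] / 1000.0 * sr))
    w1 = int(round(window_ms[1] / 1000.0 * sr))
    b0 = int(round(baseline_ms[0] / 1000.0 * sr))
    b1 = int(round(baseline_ms[1] / 1000.0 * sr))
    chunks, ids = [], []
    for onset, stim in events:
        lo = onset + min(w0, b0)
        hi = onset + max(w1, b1)
        if lo < 0 or hi > raw.n_samples:
            warnings.warn(f"event at sample {onset} too close to edge; dropped")
            continue
        epoch = raw.data[:, onset + w0:onset + w1]
        base = raw.data[:, onset + b0:onset + b1].mean(axis=1, keepdims=True)
        chunks.append(epoch - base)
        ids.append(stim)
    if not chunks:
        raise DataQualityError("no epochs could be extracted")
    return EpochArray(data=np.stack(chunks), srate=sr, stimulus_ids=ids,
                      window=(float(window_ms[0]), float(window_ms[1])),
                      channel_names=raw.channel_names, layout=raw.layout)


def _epoch_metrics(data: np.ndarray) -> dict[str, np.ndarray]:
    """Whole-epoch quality metrics over epochs x channels x timepoints."""
    amp_range = data.max(axis=(1, 2)) - data.min(axis=(1, 2))
    variance = data.var(axis=(1, 2))
    ch_means = data.mean(axis=2)                       # nE x nC
    grand = ch_means.mean(axis=1, keepdims=True)
    channel_dev = np.abs(ch_means - grand).mean(axis=1)
    return {"amplitude_range": amp_range, "variance": variance,
            "channel_deviation": channel_dev}


def reject_epochs(epochs: EpochArray, z_threshold: float = 3.0,
                  ) -> tuple[EpochArray, list[int]]:
    """Drop epochs that are outliers in amplitude range, variance or
    channel deviation (union over the three detectors)."""
    if epochs.n_epochs < 4:
        raise ValueError("need at least 4 epochs")
    metrics = _epoch_metrics(epochs.data)
    bad: set[int] = set()
    for vals in metrics.values():
        bad.update(flag_outliers(vals, z_threshold))
    if len(bad) > epochs.n_epochs / 2:
        raise DataQualityError(
            f"{len(bad)}/{epochs.n_epochs} epochs flagged; data unusable")
    keep = [i for i in range(epochs.n_epochs) if i not in bad]
    return epochs.subset(keep), sorted(bad)


# ---------------------------------------------------------------------------
# ICA artefact removal
# ---------------------------------------------------------------------------

@dataclass
class ICADecomposition:
    """Linear decomposition of epoched EEG into source components.

    ``mixing`` (nC x nIC) @ ``sources`` (nIC x samples) + ``mean`` recovers
    the concatenated epochs (channels x nE*nT).
    """

    mixing: np.ndarray
    sources: np.ndarray
    unmixing: np.ndarray
    mean: np.ndarray
    epochs_template: EpochArray
    flagged: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]


def run_ica(epochs: EpochArray, n_components: int | None = None,
            seed: int = 0) -> ICADecomposition:
    """FastICA on the concatenated epochs (channels x nE*nT)."""
    from sklearn.decomposition import FastICA

    n_ch = epochs.n_channels
    if n_components is None:
        n_components = n_ch
    n_components = min(n_components, n_ch)
    X = np.moveaxis(epochs.data, 1, 0).reshape(n_ch, -1)   # nC x samples
    ica = FastICA(n_components=n_components, random_state=int(seed),
                  whiten="unit-variance", max_iter=1000, tol=1e-3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sources = ica.fit_transform(X.T).T                  # nIC x samples
    return ICADecomposition(
        mixing=ica.mixing_, sources=sources,
        unmixing=ica.components_, mean=ica.mean_,
        epochs_template=epochs)


def anterior_channel(layout: np.ndarray) -> int:
    """Index of the sensor closest to the eyes: largest anterior coordinate,
    ties broken by lower channel index."""
    return int(np.argmax(layout[:, ANTERIOR_AXIS]))


def flag_components(ica: ICADecomposition, eog_proxy_channel: int | None = None,
                    z_threshold: float = 3.0) -> list[int]:
    """Flag artefact components by four statistics.

    Per component: |Pearson r| of its source with the ocular proxy channel,
    spatial kurtosis of its mixing column, Hurst exponent of its source, and
    mean absolute gradient of its source.  Each statistic is screened with
    the shared z-score rule; the union is returned.
    """
    if ica.n_components < 4:
        warnings.warn("fewer than 4 components; flagging skipped")
        return []
    epochs = ica.epochs_template
    if eog_proxy_channel is None:
        if epochs.layout is None:
            raise ValueError("layout needed to pick the ocular proxy channel")
        eog_proxy_channel = anterior_channel(epochs.layout)
    proxy = np.moveaxis(epochs.data, 1, 0).reshape(epochs.n_channels, -1)[
        eog_proxy_channel]
    src = ica.sources
    psd = proxy.std()
    ssd = src.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs((src - src.mean(axis=1, keepdims=True))
                      @ (proxy - proxy.mean()) / len(proxy)) / (ssd * psd + 1e-30)
    spat_kurt = stats.kurtosis(ica.mixing, axis=0, fisher=True, bias=True)
    hurst = np.array([hurst_rs(s) for s in src])
    grad = np.abs(np.diff(src, axis=1)).mean(axis=1)
    flagged: set[int] = set()
    for score in (corr, spat_kurt, hurst, grad):
        flagged.update(flag_outliers(score, z_threshold))
    return sorted(flagged)


def reconstruct_without(ica: ICADecomposition,
                        flagged: list[int]) -> EpochArray:
    """Rebuild epochs from all components except ``flagged``."""
    n_ic = ica.n_components
    flagged = sorted(set(int(i) for i in flagged))
    if any(i < 0 or i >= n_ic for i in flagged):
        raise ValueError("flagged index out of range")
    if len(flagged) == n_ic:
        raise DataQualityError("cannot remove every component")
    keep = [i for i in range(n_ic) if i not in flagged]
    X = ica.mixing[:, keep] @ ica.sources[keep] + ica.mean[:, None]
    tpl = ica.epochs_template
    data = np.moveaxis(X.reshape(tpl.n_channels, tpl.n_epochs, tpl.n_times), 0, 1)
    return EpochArray(data=data, srate=tpl.srate,
                      stimulus_ids=list(tpl.stimulus_ids), window=tpl.window,
                      channel_names=tpl.channel_names, layout=tpl.layout)


# ---------------------------------------------------------------------------
# within-epoch repair
# ---------------------------------------------------------------------------

def repair_epoch_channels(epochs: EpochArray, z_threshold: float = 3.0,
                          ) -> tuple[EpochArray, dict[int, list[int]], list[int]]:
    """Repair transiently bad channels inside single epochs.

    Within each epoch the four channel metrics (variance, median absolute
    gradient, amplitude range, deviation of the channel mean from the grand
    mean) are screened across channels; flagged channels are replaced by a
    spherical-spline interpolation using only that epoch's data.  Epochs
    where more than half the channels are flagged are dropped instead.

    Returns (repaired epochs, {kept-epoch index -> repaired channels},
    dropped epoch indices); the mapping keys index the *returned* array.
    """
    if epochs.layout is None:
        raise ValueError("sensor layout required for repair")
    n_ch = epochs.n_channels
    out, ids, repaired, dropped = [], [], {}, []
    for e in range(epochs.n_epochs):
        d = epochs.data[e]
        variance = d.var(axis=1)
        med_grad = np.median(np.abs(np.diff(d, axis=1)), axis=1)
        amp_range = d.max(axis=1) - d.min(axis=1)
        ch_mean = d.mean(axis=1)
        dev = np.abs(ch_mean - ch_mean.mean())
        bad: set[int] = set()
        for score in (variance, med_grad, amp_range, dev):
            bad.update(flag_outliers(score, z_threshold))
        if len(bad) > n_ch / 2:
            logger.warning("epoch %d: %d/%d channels bad; dropping epoch",
                           e, len(bad), n_ch)
            dropped.append(e)
            continue
        if bad:
            d = spherical.interpolate(d, epochs.layout, sorted(bad))
            repaired[len(out)] = sorted(bad)
        out.append(d)
        ids.append(epochs.stimulus_ids[e])
    if not out:
        raise DataQualityError("all epochs dropped during repair")
    fixed = EpochArray(data=np.stack(out), srate=epochs.srate,
                       stimulus_ids=ids, window=epochs.window,
                       channel_names=epochs.channel_names, layout=epochs.layout)
    return fixed, repaired, dropped


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class PreprocessReport:
    """What the cleaning chain did: inputs to sanity-check any recording."""

    bad_channels: list[int] = field(default_factory=list)
    rejected_epoch_indices: list[int] = field(default_factory=list)
    removed_components: list[int] = field(default_factory=list)
    repaired_channels: dict[int, list[int]] = field(default_factory=dict)
    dropped_in_repair: list[int] = field(default_factory=list)
    excluded_stimuli: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bad_channels": self.bad_channels,
            "rejected_epoch_indices": self.rejected_epoch_indices,
            "removed_components": self.removed_components,
            "repaired_channels": {str(k): v for k, v in
                                  self.repaired_channels.items()},
            "dropped_in_repair": self.dropped_in_repair,
            "excluded_stimuli": self.excluded_stimuli,
            "thresholds": self.thresholds,
        }


def preprocess(raw: RawRecording, config=None,
               ) -> tuple[EpochArray, PreprocessReport]:
    """Run the full cleaning chain on a continuous recording.

    Stage order: band-pass -> bad-channel interpolation -> epoch & baseline
    -> epoch rejection -> ICA flag & reconstruct -> within-epoch repair ->
    downsample.  Deterministic given ``config.ica_seed``.
    """
    from .config import Config

    cfg = config or Config()
    p = cfg.preprocess
    report = PreprocessReport(thresholds={
        "z_threshold": p.z_threshold,
        "band_hz": [p.low_hz, p.high_hz],
        "target_hz": p.target_hz,
    })

    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as err:
            raise type(err)(f"[stage {name}] {err}") from err

    raw = stage("bandpass", bandpass_filter, raw, p.low_hz, p.high_hz)

    bad = stage("channel_flagging", flag_bad_channels, raw, p.z_threshold)
    report.bad_channels = bad
    raw = stage("channel_interpolation", interpolate_channels, raw, bad)

    epochs = stage("epoching", epoch_and_baseline, raw,
                   window_ms=p.window_ms, baseline_ms=p.baseline_ms)
    epochs, rejected = stage("epoch_rejection", reject_epochs, epochs,
                             p.z_threshold)
    report.rejected_epoch_indices = rejected

    if p.run_ica:
        n_ic = epochs.n_channels - len(bad)
        ica = stage("ica", run_ica, epochs, n_components=n_ic,
                    seed=cfg.seeds.ica)
        flagged = stage("component_flagging", flag_components, ica,
                        z_threshold=p.z_threshold)
        report.removed_components = flagged
        if flagged:
            epochs = stage("ica_reconstruction", reconstruct_without,
                           ica, flagged)

    epochs, repaired, dropped = stage("epoch_repair", repair_epoch_channels,
                                      epochs, p.z_threshold)
    report.repaired_channels = repaired
    report.dropped_in_repair = dropped

    epochs = stage("downsample", downsample, epochs, p.target_hz)

    counts: dict[str, int] = {}
    for s in epochs.stimulus_ids:
        counts[s] = counts.get(s, 0) + 1
    report.excluded_stimuli = sorted(
        s for s in {sid for _, sid in raw.events} if counts.get(s, 0) == 0)
    if report.excluded_stimuli:
        warnings.warn(
            f"stimuli with zero surviving trials: {report.excluded_stimuli}")
    logger.info("preprocess: %d bad channels, %d epochs rejected, "
                "%d components removed", len(bad), len(rejected),
                len(report.removed_components))
    return epochs, report
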