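"""Containers for continuous and epoched EEG data.

A :class:`RawRecording` holds a continuous multichannel recording in
microvolts together with the sensor layout (unit-sphere 3-D positions) and
stimulus-onset events.  An :class:`EpochArray` holds the stimulus-locked
windows cut from it.  Both are plain numpy-backed dataclasses so every
downstream stage (cleaning, feature scoring, decoding) can operate on them
without a heavyweight I/O dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class ConfigurationError(ValueError):
    """A parameter combination that can never be valid (e.g. cutoff >= Nyquist)."""


class DataQualityError(RuntimeError):
    """Raised when the data are too corrupted to clean automatically."""


@dataclass
class RawRecording:
    """Continuous EEG: ``data`` is channels x samples in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
    srate : float
        Sampling rate in Hz.
    channel_names : list of str
    layout : ndarray, shape (n_channels, 3)
        Sensor positions; normalised to the unit sphere on construction.
    events : list of (sample_index, stimulus_id)
        Stimulus onsets, sample index into ``data``.
    """

    data: np.ndarray
    srate: float
    channel_names: list[str]
    layout: np.ndarray | None
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        n_ch = self.data.shape[0]
        if len(self.channel_names) != n_ch:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_ch} channels"
            )
        if self.layout is not None:
            self.layout = np.asarray(self.layout, dtype=np.float64)
            if self.layout.shape != (n_ch, 3):
                raise ValueError("layout must be (n_channels, 3)")
            norms = np.linalg.norm(self.layout, axis=1)
            if np.any(norms == 0):
                raise ValueError("layout positions must be nonzero")
            self.layout = self.layout / norms[:, None]
        for sample, _ in self.events:
            if not 0 <= sample < self.data.shape[1]:
                raise ValueError(f"event sample {sample} outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "RawRecording":
        if "data" in kw and "events" not in kw:
            kw["events"] = list(self.events)
        return replace(self, **kw)


@dataclass
class EpochArray:
    """Stimulus-locked EEG windows: ``data`` is epochs x channels x timepoints (uV).

    ``window`` is (start_ms, end_ms) relative to stimulus onset, half-open
    ``[start, end)``.  ``stimulus_ids[i]`` labels epoch ``i``.
    """

    data: np.ndarray
    srate: float
    stimulus_ids: list[str]
    window: tuple[float, float] = (0.0, 1000.0)
    channel_names: list[str] | None = None
    layout: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x timepoints)")
        if len(self.stimulus_ids) != self.data.shape[0]:
            raise ValueError("one stimulus id per epoch required")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if self.layout is not None:
            self.layout = np.asarray(self.layout, dtype=np.float64)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def flatten_features(self) -> np.ndarray:
        """Epochs x (channels * timepoints), channel-major: f = c * nT + t."""
        return self.data.reshape(self.n_epochs, -1)

    def subset(self, idx) -> "EpochArray":
        idx = np.asarray(idx)
        return EpochArray(
            data=self.data[idx],
            srate=self.srate,
            stimulus_ids=[self.stimulus_ids[i] for i in idx],
            window=self.window,
            channel_names=self.channel_names,
            layout=self.layout,
        )
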