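"""Configuration for the full retrieval pipeline.

All tunables live in one nested dataclass tree with the defaults used
throughout: 1-40 Hz band, z threshold 3, 120 Hz target rate, the 32-filter
Gabor bank, ridge alpha and the EEG-feature count.  Configs round-trip
losslessly through YAML; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PreprocessParams:
    low_hz: float = 1.0
    high_hz: float = 40.0
    z_threshold: float = 3.0
    target_hz: float = 120.0
    window_ms: tuple[float, float] = (0.0, 1000.0)
    baseline_ms: tuple[float, float] = (-500.0, 0.0)
    run_ica: bool = True


@dataclass
class GaborParams:
    n_orientations: int = 8
    sigmas: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)
    ksize: int = 31
    lam: float = 6.0
    gamma: float = 0.5
    psi: float = 0.0
    # "pi_over_7" spans [0, pi] inclusive in 8 steps instead of [0, pi)
    orientation_spacing: str = "pi_over_8"
    aggregate: str = "real"            # or "magnitude"


@dataclass
class SiftParams:
    grid_step: int = 8
    patch_size: int = 16
    codebook_size: int = 1000


@dataclass
class ImageParams:
    resize: int = 256
    gabor: GaborParams = field(default_factory=GaborParams)
    sift: SiftParams = field(default_factory=SiftParams)
    blocks: tuple[str, ...] = ("gabor", "hsv", "sift", "sem")
    pca_components: int | None = None   # None -> keep 99% variance
    pca_variance: float = 0.99


@dataclass
class DecoderParams:
    alpha: float = 10.0
    n_eeg_features: int = 500
    keep_fraction: float = 0.5
    stability_on_zscored: bool = True


@dataclass
class Seeds:
    ica: int = 0
    codebook: int = 0
    images: int = 0
    lexicon: int = 0
    eeg: int = 0
    schedule: int = 0


@dataclass
class Config:
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    images: ImageParams = field(default_factory=ImageParams)
    decoder: DecoderParams = field(default_factory=DecoderParams)
    seeds: Seeds = field(default_factory=Seeds)

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        return _build(cls, d or {})

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_listify(self.to_dict()),
                                             sort_keys=False))

    @classmethod
    def load(cls, path) -> "Config":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


def _build(cls, d: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(fields)
    if unknown:
        raise KeyError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in d.items():
        ftype = fields[name].type
        sub = _DATACLASS_FIELDS.get((cls.__name__, name))
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _build(sub, value)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_DATACLASS_FIELDS = {
    ("Config", "preprocess"): PreprocessParams,
    ("Config", "images"): ImageParams,
    ("Config", "decoder"): DecoderParams,
    ("Config", "seeds"): Seeds,
    ("ImageParams", "gabor"): GaborParams,
    ("ImageParams", "sift"): SiftParams,
}
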