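"""Synthetic stimuli, lexicons, schedules and forward-model EEG recordings.

These generators let every pipeline stage run end-to-end with no external
downloads.  The paradigms they emulate present a gallery of nS images nP
times each in random order (e.g. 72 x 12 or 60 x 6) while multichannel EEG
is recorded.  The EEG forward model is deliberately the model the decoder
assumes: each stimulus evokes a fixed spatiotemporal template that is a
linear transform of the stimulus's fused image-feature vector, embedded in
i.i.d. Gaussian sensor noise, so that decoding accuracy measures parameter
recovery rather than model mismatch.  Optional planted artefacts (ocular
deflections on the anterior channel, one dead channel, 50 Hz line noise)
exercise the cleaning chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imagefeatures import FusedFeatureSpace, WordVectorTable
from .preprocessing import ANTERIOR_AXIS
from .recording import RawRecording

#: object names for synthetic galleries: land mammals and hand tools, with a
#: few multi-word expressions to exercise the compositional embedding rule
CONCEPT_NAMES = [
    "armadillo", "axe", "badger", "beaver", "bison", "camel", "chisel",
    "claw hammer", "deer", "drill", "elephant", "ferret", "fox", "gazelle",
    "giraffe", "goat", "hacksaw", "hand plane", "hedgehog", "hyena", "ibex",
    "jackal", "kangaroo", "koala", "lathe", "lemur", "leopard", "lion",
    "llama", "mallet", "marmot", "meerkat", "mole", "moose", "otter", "ox",
    "panda", "pangolin", "pliers", "plaster trowel", "porcupine", "rabbit",
    "raccoon", "rasp", "rhinoceros", "screwdriver", "shears", "sickle",
    "skunk", "sloth", "socket wrench", "spanner", "squirrel", "tapir",
    "tiger", "vise", "vole", "wallaby", "walrus", "warthog", "weasel",
    "wheelbarrow", "wolf", "wolverine", "wombat", "wrench", "yak", "zebra",
    "anvil", "awl", "bolt cutter", "crowbar", "file", "gimlet", "jigsaw",
    "level", "pickaxe", "pry bar", "putty knife", "sander", "scriber",
    "soldering iron", "staple gun", "tape measure", "tin snips", "trowel",
]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic recording."""

    n_stimuli: int = 60
    n_presentations: int = 6
    n_channels: int = 64
    srate: float = 500.0
    snr: float = 2.0                    # template std / sensor-noise std
    noise_uv: float = 10.0              # sensor noise SD in microvolts
    iti_ms: float = 1800.0
    artefacts: dict = field(default_factory=dict)   # blink/dead_channel/line_noise
    seeds: dict = field(default_factory=dict)       # images/lexicon/eeg/schedule

    def __post_init__(self) -> None:
        if self.n_stimuli < 3:
            raise ValueError("need at least 3 stimuli")
        if self.n_presentations < 2:
            raise ValueError("need at least 2 presentations")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")

    def seed(self, name: str) -> int:
        return int(self.seeds.get(name, 0))


def stimulus_ids(n_stimuli: int) -> list[str]:
    return [f"s{i:03d}" for i in range(n_stimuli)]


# ---------------------------------------------------------------------------
# images and lexicon
# ---------------------------------------------------------------------------

def synth_images(n_stimuli: int, seed: int = 0, size: int = 64,
                 ) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Gallery of images that all feature blocks can tell apart.

    Image i gets a distinct dominant hue (hue = i / nS), an oriented
    grating at a distinct angle and spatial frequency, and a simple centred
    shape, so the HSV, Gabor and SIFT blocks each discriminate the gallery.
    Returns (id -> uint8 RGB array, manifest rows of
    {stimulus_id, filename, name}); deterministic per seed.
    """
    from skimage.color import hsv2rgb

    if n_stimuli < 1:
        raise ValueError("need at least one image")
    rng = np.random.default_rng(seed)
    ids = stimulus_ids(n_stimuli)
    names = [CONCEPT_NAMES[i % len(CONCEPT_NAMES)] for i in range(n_stimuli)]
    yy, xx = np.mgrid[0:size, 0:size] / size
    images: dict[str, np.ndarray] = {}
    manifest = []
    for i, sid in enumerate(ids):
        hue = i / n_stimuli
        angle = i * np.pi / n_stimuli
        freq = 4 + (i % 5) * 3
        phase = rng.uniform(0, 2 * np.pi)
        grating = 0.5 + 0.5 * np.sin(
            2 * np.pi * freq * (xx * np.cos(angle) + yy * np.sin(angle))
            + phase)
        h = np.full((size, size), hue)
        s = np.full((size, size), 0.9)
        v = 0.35 + 0.6 * grating
        # centred shape: alternate discs and squares with varied radius
        cy, cx = 0.5, 0.5
        r = 0.12 + 0.08 * ((i // 2) % 3)
        if i % 2 == 0:
            inside = (yy - cy) ** 2 + (xx - cx) ** 2 < r ** 2
        else:
            inside = (np.abs(yy - cy) < r) & (np.abs(xx - cx) < r)
        v = np.where(inside, 1.0 - v, v)
        s = np.where(inside, 0.2, s)
        rgb = hsv2rgb(np.stack([h, s, v], axis=-1))
        images[sid] = (rgb * 255).astype(np.uint8)
        manifest.append({"stimulus_id": sid, "filename": f"{sid}.png",
                         "name": names[i]})
    return images, manifest


def synth_lexicon(names: list[str], dim: int = 50, seed: int = 0,
                  ) -> WordVectorTable:
    """Toy word-vector table: one unit-norm random vector per token.

    Tokens of multi-word names are included individually, so the
    mean-of-composites rule for multi-word expressions is exercised.
    """
    from .imagefeatures import tokenize_name

    if not names:
        raise ValueError("no names given")
    rng = np.random.default_rng(seed)
    tokens: list[str] = []
    for name in names:
        for tok in tokenize_name(name):
            if tok not in tokens:
                tokens.append(tok)
    vectors = {}
    for tok in tokens:
        v = rng.normal(size=dim)
        vectors[tok] = v / np.linalg.norm(v)
    return WordVectorTable(vectors=vectors, dim=dim)


# ---------------------------------------------------------------------------
# paradigm schedule and sensor layout
# ---------------------------------------------------------------------------

def paradigm_schedule(n_stimuli: int, n_presentations: int,
                      iti_ms: float = 1800.0, seed: int = 0,
                      ids: list[str] | None = None,
                      start_ms: float = 1000.0) -> list[tuple[float, str]]:
    """Randomly ordered presentation onsets: (onset_ms, stimulus_id).

    Every stimulus appears exactly ``n_presentations`` times; consecutive
    onsets are ``iti_ms`` apart (>= 1600 ms leaves room for the 500 ms
    baseline and the 1000 ms epoch).
    """
    if n_stimuli * n_presentations < 1:
        raise ValueError("empty schedule")
    if iti_ms < 1600:
        raise ValueError("iti_ms must be >= 1600 ms")
    ids = ids or stimulus_ids(n_stimuli)
    order = np.repeat(np.arange(n_stimuli), n_presentations)
    np.random.default_rng(seed).shuffle(order)
    return [(start_ms + i * iti_ms, ids[s]) for i, s in enumerate(order)]


def hemisphere_layout(n_channels: int) -> np.ndarray:
    """Quasi-uniform unit-sphere sensor positions on the upper hemisphere.

    Golden-spiral placement; axis ``ANTERIOR_AXIS`` points towards the face,
    so the ocular-proxy choice (most anterior sensor) is well defined.
    """
    idx = np.arange(n_channels) + 0.5
    z = idx / n_channels            # hemisphere: z in (0, 1)
    r = np.sqrt(1 - z ** 2)
    golden = np.pi * (3 - np.sqrt(5))
    phi = idx * golden
    pos = np.zeros((n_channels, 3))
    pos[:, 0] = r * np.cos(phi)
    pos[:, ANTERIOR_AXIS] = r * np.sin(phi)
    pos[:, 2] = z
    return pos


# ---------------------------------------------------------------------------
# forward-model EEG
# ---------------------------------------------------------------------------

#: template support relative to stimulus onset, seconds
TEMPLATE_WINDOW_S = (0.1, 0.6)


def synth_recording(fused: FusedFeatureSpace, spec: SyntheticSpec,
                    ) -> RawRecording:
    """Continuous EEG realising a linear feature-to-template forward model.

    Per stimulus s a spatiotemporal template ``T_s = reshape(W @ f_s)`` over
    channels x template-samples is drawn (W once per eeg seed) and added at
    every presentation of s, confined to 100-600 ms after onset.  Templates
    are globally scaled so their pooled SD is ``spec.snr`` times the sensor
    noise SD.  ``spec.artefacts`` may plant ``blink`` (low-frequency lobes
    on the anterior channel), ``dead_channel`` (one near-zero channel) and
    ``line_noise`` (50 Hz on all channels).
    """
    ids = list(fused.stimulus_ids)
    if len(ids) < spec.n_stimuli:
        raise ValueError("fused feature space does not cover all stimuli")
    ids = ids[:spec.n_stimuli]
    sr = spec.srate
    schedule = paradigm_schedule(spec.n_stimuli, spec.n_presentations,
                                 spec.iti_ms, spec.seed("schedule"), ids=ids)
    n_samples = int((schedule[-1][0] + 2000.0) / 1000.0 * sr)
    rng = np.random.default_rng(spec.seed("eeg"))

    t0 = int(TEMPLATE_WINDOW_S[0] * sr)
    t1 = int(TEMPLATE_WINDOW_S[1] * sr)
    n_tw = t1 - t0
    n_c = spec.n_channels
    p = fused.n_components
    W = rng.normal(size=(n_c * n_tw, p))
    F = np.stack([fused.matrix[fused.index_of(s)] for s in ids])
    templates = (F @ W.T).reshape(spec.n_stimuli, n_c, n_tw)
    # smooth the templates in time so they survive the 1-40 Hz band-pass
    from scipy.ndimage import gaussian_filter1d
    templates = gaussian_filter1d(templates, sigma=sr / 80.0, axis=2)
    taper = np.hanning(n_tw)
    templates = templates * taper
    pooled_sd = templates.std()
    if pooled_sd > 0 and spec.snr > 0:
        templates *= spec.snr * spec.noise_uv / pooled_sd
    else:
        templates[:] = 0.0

    data = rng.normal(0.0, spec.noise_uv, size=(n_c, n_samples))
    events: list[tuple[int, str]] = []
    tpl_index = {s: i for i, s in enumerate(ids)}
    for onset_ms, sid in schedule:
        onset = int(onset_ms / 1000.0 * sr)
        events.append((onset, sid))
        data[:, onset + t0:onset + t1] += templates[tpl_index[sid]]

    layout = hemisphere_layout(n_c)
    art = spec.artefacts
    frontal = int(np.argmax(layout[:, ANTERIOR_AXIS]))
    if art.get("blink"):
        # volume conduction: the ocular dipole projects to every sensor with
        # weight decaying away from the most anterior one
        dist = np.linalg.norm(layout - layout[frontal], axis=1)
        topography = np.exp(-2.0 * dist)
        blink_len = int(0.3 * sr)
        lobe = 200.0 * np.sin(np.linspace(0, np.pi, blink_len))
        n_blinks = max(1, int(n_samples / sr / 5.0))    # one per ~5 s
        starts = rng.integers(0, n_samples - blink_len, size=n_blinks)
        for s0 in starts:
            data[:, s0:s0 + blink_len] += topography[:, None] * lobe
    if art.get("dead_channel"):
        dead = frontal + 1 if frontal + 1 < n_c else frontal - 1
        data[dead] = rng.normal(0.0, 1e-4, size=n_samples)
    if art.get("line_noise"):
        t = np.arange(n_samples) / sr
        phases = rng.uniform(0, 2 * np.pi, size=n_c)
        data += 5.0 * np.sin(2 * np.pi * 50.0 * t[None, :] + phases[:, None])

    return RawRecording(
        data=data, srate=sr,
        channel_names=[f"ch{i:03d}" for i in range(n_c)],
        layout=layout, events=events)
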