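"""File readers and writers.

EEG comes in as EEGLAB ``.set``, BrainVision ``.vhdr`` or EDF (all read
through MNE, converted to microvolts), or as the self-contained "packed"
format: one ``.npy`` array (channels x samples, float32 microvolts) next to
a JSON sidecar with the sampling rate, channel names, sensor positions and
events.  Images are a directory of PNG/JPEG plus a CSV manifest
(stimulus_id, filename, name); word vectors are whitespace-delimited text.
Epoch arrays, codebooks and fused feature spaces round-trip through
HDF5/npy+JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .imagefeatures import Codebook, FusedFeatureSpace
from .recording import EpochArray, RawRecording


class FormatError(ValueError):
    """Input file does not match its declared format."""


# ---------------------------------------------------------------------------
# packed EEG format
# ---------------------------------------------------------------------------

def _sidecar_path(array_path: Path) -> Path:
    return array_path.with_suffix(".json")


def save_packed(raw: RawRecording, array_path) -> None:
    """Write a recording as <name>.npy + <name>.json sidecar."""
    array_path = Path(array_path)
    np.save(array_path, raw.data.astype(np.float32))
    sidecar = {
        "srate": raw.srate,
        "channel_names": list(raw.channel_names),
        "positions": None if raw.layout is None else raw.layout.tolist(),
        "events": [[int(s), str(sid)] for s, sid in raw.events],
    }
    _sidecar_path(array_path).write_text(json.dumps(sidecar, indent=1))


def load_packed(array_path) -> RawRecording:
    array_path = Path(array_path)
    data = np.load(array_path)
    meta = json.loads(_sidecar_path(array_path).read_text())
    if data.shape[0] != len(meta["channel_names"]):
        raise FormatError(
            f"array has {data.shape[0]} channels but sidecar lists "
            f"{len(meta['channel_names'])} channel names")
    layout = meta.get("positions")
    return RawRecording(
        data=np.asarray(data, dtype=np.float64),
        srate=float(meta["srate"]),
        channel_names=list(meta["channel_names"]),
        layout=None if layout is None else np.asarray(layout, dtype=float),
        events=[(int(s), str(sid)) for s, sid in meta.get("events", [])],
    )


def _from_mne(mne_raw) -> RawRecording:
    """Convert an MNE Raw object: volts -> microvolts, montage -> layout."""
    data = mne_raw.get_data() * 1e6
    montage = mne_raw.get_montage()
    layout = None
    if montage is not None:
        pos = montage.get_positions()["ch_pos"]
        if all(name in pos for name in mne_raw.ch_names):
            layout = np.array([pos[name] for name in mne_raw.ch_names])
            if np.all(np.linalg.norm(layout, axis=1) > 0):
                layout = layout / np.linalg.norm(layout, axis=1)[:, None]
            else:
                layout = None
    events = [(int(ann["onset"] * mne_raw.info["sfreq"]),
               str(ann["description"]))
              for ann in mne_raw.annotations]
    return RawRecording(data=data, srate=float(mne_raw.info["sfreq"]),
                        channel_names=list(mne_raw.ch_names),
                        layout=layout, events=events)


def load_recording(path) -> RawRecording:
    """Auto-detect the EEG container by extension and load it.

    Recordings without usable sensor positions load fine, but the
    spherical-spline stages will refuse to run on them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        return load_packed(path)
    import mne
    readers = {
        ".set": mne.io.read_raw_eeglab,
        ".vhdr": mne.io.read_raw_brainvision,
        ".edf": mne.io.read_raw_edf,
    }
    if suffix not in readers:
        raise FormatError(f"unsupported EEG container: {path.name}")
    return _from_mne(readers[suffix](path, preload=True, verbose="error"))


# ---------------------------------------------------------------------------
# epochs (HDF5)
# ---------------------------------------------------------------------------

def save_epochs(epochs: EpochArray, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.attrs["srate"] = epochs.srate
        f.attrs["window"] = epochs.window
        f.create_dataset("stimulus_ids",
                         data=np.array(epochs.stimulus_ids, dtype="S"))
        if epochs.channel_names is not None:
            f.create_dataset("channel_names",
                             data=np.array(epochs.channel_names, dtype="S"))
        if epochs.layout is not None:
            f.create_dataset("layout", data=epochs.layout)


def load_epochs(path) -> EpochArray:
    import h5py

    with h5py.File(path, "r") as f:
        return EpochArray(
            data=f["data"][()],
            srate=float(f.attrs["srate"]),
            stimulus_ids=[s.decode() for s in f["stimulus_ids"][()]],
            window=tuple(f.attrs["window"]),
            channel_names=([s.decode() for s in f["channel_names"][()]]
                           if "channel_names" in f else None),
            layout=f["layout"][()] if "layout" in f else None,
        )


# ---------------------------------------------------------------------------
# images and manifests
# ---------------------------------------------------------------------------

def save_images(images: dict[str, np.ndarray], manifest: list[dict],
                directory) -> Path:
    """Write PNGs + manifest.csv; returns the manifest path."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for row in manifest:
        Image.fromarray(images[row["stimulus_id"]]).save(
            directory / row["filename"])
    manifest_path = directory / "manifest.csv"
    pd.DataFrame(manifest).to_csv(manifest_path, index=False)
    return manifest_path


def load_images(manifest_path) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Read a manifest CSV and its image directory.

    Returns (stimulus_id -> RGB uint8 array, stimulus_id -> object name).
    """
    from PIL import Image

    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    need = {"stimulus_id", "filename", "name"}
    if not need <= set(table.columns):
        raise FormatError(f"manifest must have columns {sorted(need)}")
    images, names = {}, {}
    for row in table.itertuples():
        img = Image.open(manifest_path.parent / row.filename).convert("RGB")
        images[str(row.stimulus_id)] = np.asarray(img)
        names[str(row.stimulus_id)] = str(row.name)
    return images, names


# ---------------------------------------------------------------------------
# codebooks and feature spaces
# ---------------------------------------------------------------------------

def save_codebook(codebook: Codebook, path) -> None:
    path = Path(path)
    np.save(path, codebook.centroids)
    path.with_suffix(".json").write_text(json.dumps(codebook.meta, indent=1))


def load_codebook(path) -> Codebook:
    path = Path(path)
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Codebook(centroids=np.load(path), meta=meta)


def save_feature_space(fused: FusedFeatureSpace, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=fused.matrix)
        f.create_dataset("loadings", data=fused.loadings)
        f.create_dataset("mean", data=fused.mean)
        f.create_dataset("explained_variance", data=fused.explained_variance)
        f.create_dataset("stimulus_ids",
                         data=np.array(fused.stimulus_ids, dtype="S"))
        f.attrs["blocks"] = json.dumps(fused.blocks)
        f.attrs["block_slices"] = json.dumps(
            {k: list(v) for k, v in fused.block_slices.items()})


def load_feature_space(path) -> FusedFeatureSpace:
    import h5py

    with h5py.File(path, "r") as f:
        return FusedFeatureSpace(
            matrix=f["matrix"][()],
            stimulus_ids=[s.decode() for s in f["stimulus_ids"][()]],
            loadings=f["loadings"][()],
            mean=f["mean"][()],
            blocks=json.loads(f.attrs["blocks"]),
            block_slices={k: tuple(v) for k, v in
                          json.loads(f.attrs["block_slices"]).items()},
            explained_variance=f["explained_variance"][()],
        )
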