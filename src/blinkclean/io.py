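"""Recording and dataset I/O: EDF, delimited text, columnar containers.

Recordings travel as EDF (the EEG interchange standard) or delimited text
(header row of channel names, first column time in seconds).  Every write
leaves a JSON metadata sidecar (``<file>.json``) echoing the provenance —
generator config, seed, realized gains — so any artifact on disk can be
regenerated exactly.  Paired training datasets use a columnar binary ``.npz``
container plus the same style of sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from blinkclean import edf as edfmod
from blinkclean.recording import PairedWindowDataset, Recording

_TEXT_SUFFIXES = {".csv", ".txt", ".tsv"}


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_sidecar(path: Path, meta: dict) -> None:
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps(_jsonable(meta), indent=2))


def _read_sidecar(path: Path) -> dict:
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return {}


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as EDF or delimited text, plus a metadata sidecar."""
    path = Path(path)
    suffix = path.suffix.lower()
    path.parent.mkdir(parents=True, exist_ok=True)
    if suffix == ".edf":
        edfmod.write_edf(recording, path)
    elif suffix in _TEXT_SUFFIXES:
        sep = "\t" if suffix == ".tsv" else ","
        t = np.arange(recording.n_samples) / recording.sampling_rate
        frame = pd.DataFrame({"time": t})
        for idx, ch in enumerate(recording.channel_names):
            frame[ch] = recording.data[idx]
        frame.to_csv(path, sep=sep, index=False)
    else:
        raise ValueError(f"unsupported recording format {suffix!r}; "
                         f"use .edf or one of {sorted(_TEXT_SUFFIXES)}")
    meta = dict(recording.meta)
    meta.setdefault("sampling_rate", recording.sampling_rate)
    meta.setdefault("channel_names", list(recording.channel_names))
    _write_sidecar(path, meta)


def read_recording(path: str | Path, sampling_rate: float | None = None) -> Recording:
    """Read an EDF or delimited-text recording (μV).

    Text files must carry a header row of channel names; a leading ``time``
    column (seconds) supplies the sampling rate, otherwise pass
    ``sampling_rate`` explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        rec = edfmod.read_edf(path)
    elif suffix in _TEXT_SUFFIXES:
        rec = _read_text(path, "\t" if suffix == ".tsv" else ",", sampling_rate)
    else:
        raise ValueError(f"unknown recording format {suffix!r}; "
                         f"use .edf or one of {sorted(_TEXT_SUFFIXES)}")
    sidecar = _read_sidecar(path)
    if sidecar:
        rec.meta.update(sidecar)
    return rec


def _read_text(path: Path, sep: str, sampling_rate: float | None) -> Recording:
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: inconsistent row lengths: {exc}") from exc
    if frame.shape[1] == 0 or frame.shape[0] == 0:
        raise ValueError(f"{path}: empty recording file")

    def _numeric(name: object) -> bool:
        try:
            float(str(name))
            return True
        except ValueError:
            return False

    if any(_numeric(c) for c in frame.columns):
        raise ValueError(f"{path}: missing header row of channel names")
    cols = list(frame.columns)
    if cols[0].lower() in {"time", "t", "seconds", "s"}:
        t = frame[cols[0]].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError(f"{path}: need at least 2 samples to infer "
                             "the sampling rate")
        dt = np.diff(t)
        if np.ptp(dt) > 1e-6 or dt[0] <= 0:
            raise ValueError(f"{path}: time column is not uniformly sampled")
        fs = 1.0 / dt[0]
        channels = cols[1:]
    else:
        if sampling_rate is None:
            raise ValueError(f"{path}: no time column; pass sampling_rate")
        fs = sampling_rate
        channels = cols
    data = frame[channels].to_numpy(dtype=float).T
    return Recording(data, float(round(fs, 6)), list(channels),
                     {"source": str(path), "format": "text"})


def save_dataset(dataset: PairedWindowDataset, path: str | Path) -> None:
    """Write a paired-window dataset as .npz plus a JSON sidecar."""
    path = Path(path).with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path,
             inputs=dataset.inputs,
             targets=dataset.targets,
             channel_labels=np.array(dataset.channel_labels),
             train_indices=dataset.train_indices,
             val_indices=dataset.val_indices)
    meta = dict(dataset.meta)
    meta["n_examples"] = len(dataset)
    meta["n_train"] = int(len(dataset.train_indices))
    meta["n_val"] = int(len(dataset.val_indices))
    _write_sidecar(path, meta)


def load_dataset(path: str | Path) -> PairedWindowDataset:
    """Load a dataset written by :func:`save_dataset`."""
    path = Path(path).with_suffix(".npz")
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path, allow_pickle=False) as archive:
        try:
            inputs = archive["inputs"]
            targets = archive["targets"]
            labels = [str(s) for s in archive["channel_labels"]]
            train_idx = archive["train_indices"]
            val_idx = archive["val_indices"]
        except KeyError as exc:
            raise ValueError(f"{path}: not a paired-window dataset "
                             f"container: missing {exc}") from exc
    meta = _read_sidecar(path)
    return PairedWindowDataset(inputs=inputs, targets=targets,
                               channel_labels=labels,
                               train_indices=train_idx, val_indices=val_idx,
                               meta=meta)
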