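"""File formats for inter-stage data exchange.

Every pipeline stage reads and writes plain files so that stages are
independently runnable and byte-reproducible: recordings as raw float32
binaries with a JSON sidecar, event tables as TSV, epochs as a float32
tensor plus a JSON manifest, and everything tabular as CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .synth import Recording

__all__ = [
    "save_recording", "load_recording",
    "save_events", "load_events",
    "save_epochs", "load_epochs",
    "sha256_file",
]


def save_recording(directory, recording: Recording) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    recording.data.astype(np.float32).tofile(d / "recording.bin")
    meta = {
        "fs": recording.fs,
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "channel_names": list(recording.channel_names),
        "dtype": "float32",
        "order": "channels_x_samples",
    }
    (d / "recording.json").write_text(json.dumps(meta, indent=1))


def load_recording(directory) -> Recording:
    d = Path(directory)
    meta = json.loads((d / "recording.json").read_text())
    data = np.fromfile(d / "recording.bin", dtype=np.float32)
    data = data.reshape(meta["n_channels"], meta["n_samples"]).astype(float)
    return Recording(data=data, fs=float(meta["fs"]), channel_names=meta["channel_names"])


def save_events(path, events: pd.DataFrame) -> None:
    out = events.copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_events(path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    ev["rt_ms"] = pd.to_numeric(ev["rt_ms"], errors="coerce")
    return ev


def save_epochs(directory, epochs: EpochSet, name: str) -> None:
    """Store accepted epochs as a float32 tensor plus a JSON manifest.

    The manifest records the full per-trial bookkeeping (condition, reason,
    source trial index) for all trials, accepted or not.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    acc = np.flatnonzero(epochs.accepted)
    epochs.data[acc].astype(np.float32).tofile(d / f"{name}.bin")
    manifest = {
        "fs": epochs.fs,
        "times_ms": epochs.times_ms.tolist(),
        "accepted_index": acc.tolist(),
        "trials": [
            {
                "trial_index": int(epochs.trial_index[i]),
                "condition": str(epochs.condition[i]),
                "reason": str(epochs.reason[i]),
                "rt_ms": None if epochs.rt_ms is None or np.isnan(epochs.rt_ms[i])
                else float(epochs.rt_ms[i]),
            }
            for i in range(epochs.n_trials)
        ],
        "shape": [int(len(acc))] + list(epochs.data.shape[1:]),
    }
    (d / f"{name}.json").write_text(json.dumps(manifest))


def load_epochs(directory, name: str) -> EpochSet:
    d = Path(directory)
    manifest = json.loads((d / f"{name}.json").read_text())
    shape = manifest["shape"]
    data = np.fromfile(d / f"{name}.bin", dtype=np.float32).reshape(shape).astype(float)
    trials = manifest["trials"]
    acc = manifest["accepted_index"]
    cond = np.array([trials[i]["condition"] for i in acc], dtype=object)
    reason = np.array(["none"] * len(acc), dtype=object)
    tidx = np.array([trials[i]["trial_index"] for i in acc])
    rt = np.array([np.nan if trials[i]["rt_ms"] is None else trials[i]["rt_ms"]
                   for i in acc], float)
    return EpochSet(data=data, times_ms=np.asarray(manifest["times_ms"], float),
                    fs=float(manifest["fs"]), condition=cond, reason=reason,
                    trial_index=tidx, rt_ms=rt)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
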