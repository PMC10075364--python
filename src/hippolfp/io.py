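"""Reading and writing the on-disk session container.

An LFP session is stored either as an HDF5 file (group layout: ``/data``
float32 channels x samples, ``/fs`` scalar Hz, ``/channel_labels`` string
array, ``/ttl_s`` float seconds) or as a raw little-endian float32 binary
plus a JSON sidecar carrying the same keys.  Tracking is a plain CSV with
columns ``frame,t_s,x_m,y_m``; ground truth is JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


@dataclass
class LfpRecording:
    """Multichannel LFP: samples in microvolts, one row per channel."""

    data: np.ndarray            # (n_channels, n_samples), float
    fs: float                   # Hz
    channel_labels: list[str]   # e.g. "pyramidal", "radiatum", "other"
    ttl_s: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        self.ttl_s = np.asarray(self.ttl_s, dtype=float)
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} channels but "
                f"{len(self.channel_labels)} labels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label_or_index: int | str) -> np.ndarray:
        if isinstance(label_or_index, str):
            return self.data[self.channel_labels.index(label_or_index)]
        return self.data[label_or_index]


def write_lfp_h5(path: str | Path, rec: LfpRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data.astype(np.float32))
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset(
            "channel_labels",
            data=np.array(rec.channel_labels, dtype=h5py.string_dtype()),
        )
        f.create_dataset("ttl_s", data=rec.ttl_s.astype(np.float64))


def read_lfp_h5(path: str | Path) -> LfpRecording:
    with h5py.File(path, "r") as f:
        return LfpRecording(
            data=f["data"][()].astype(np.float64),
            fs=float(f["fs"][()]),
            channel_labels=[
                s.decode() if isinstance(s, bytes) else str(s)
                for s in f["channel_labels"][()]
            ],
            ttl_s=f["ttl_s"][()].astype(np.float64),
        )


def write_lfp_raw(path: str | Path, rec: LfpRecording) -> None:
    """Raw little-endian float32 (channel-major) + JSON sidecar."""
    path = Path(path)
    rec.data.astype("<f4").tofile(path)
    sidecar = {
        "fs": float(rec.fs),
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "channel_labels": list(rec.channel_labels),
        "ttl_s": rec.ttl_s.tolist(),
        "dtype": "<f4",
        "order": "channel_major",
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_lfp_raw(path: str | Path) -> LfpRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype="<f4").astype(np.float64)
    data = data.reshape(meta["n_channels"], meta["n_samples"])
    return LfpRecording(
        data=data,
        fs=meta["fs"],
        channel_labels=meta["channel_labels"],
        ttl_s=np.asarray(meta["ttl_s"], dtype=float),
    )


def write_tracking_csv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, columns=["frame", "t_s", "x_m", "y_m"])


def read_tracking_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"frame", "t_s", "x_m", "y_m"} - set(df.columns)
    if missing:
        raise ValueError(f"tracking CSV missing columns: {sorted(missing)}")
    return df
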