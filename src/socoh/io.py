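"""File formats used by the pipeline.

Three on-disk artefacts move between stages:

* pose-tracking tables in the DeepLabCut CSV dialect (three header rows:
  scorer / bodyparts / coords, one row per video frame),
* multichannel LFP sessions in a small HDF5 container (dataset ``lfp`` of
  shape channels x samples plus scalar/array attributes),
* region/bundle maps and ground-truth manifests as YAML/JSON.

Everything here is deliberately dumb plumbing: parsing and writing only,
no signal processing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LFPRecording",
    "read_track_csv",
    "write_track_csv",
    "read_lfp_h5",
    "write_lfp_h5",
    "read_region_map",
    "write_region_map",
    "read_json",
    "write_json",
]


@dataclass
class LFPRecording:
    """A multichannel LFP session.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Voltage traces (arbitrary units).
    fs_hz : float
        Sampling rate.
    channel_names : list of str
        One region label per channel.
    bundle_id : ndarray of int, shape (n_channels,)
        Cannula/bundle membership; wires implanted together share an id.
    t0 : float
        Time of the first sample in the shared behavioural clock (s).
    """

    signal: np.ndarray
    fs_hz: float
    channel_names: list = field(default_factory=list)
    bundle_id: np.ndarray = None
    t0: float = 0.0

    def __post_init__(self):
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.bundle_id is not None:
            self.bundle_id = np.asarray(self.bundle_id, dtype=int)
            if self.bundle_id.shape[0] != self.n_channels:
                raise ValueError("bundle_id length must match channel count")
        if self.channel_names and len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


# ---------------------------------------------------------------------------
# Pose-tracking CSV (DeepLabCut dialect)
# ---------------------------------------------------------------------------

def write_track_csv(path, track: pd.DataFrame, body_part: str = "snout",
                    scorer: str = "socoh") -> None:
    """Write a position track in the DeepLabCut CSV dialect.

    ``track`` must have columns ``x_mm``, ``y_mm`` and ``likelihood`` indexed
    by frame number.  The file carries a three-row header
    (scorer / bodyparts / coords) followed by one row per frame.
    """
    cols = pd.MultiIndex.from_product(
        [[scorer], [body_part], ["x", "y", "likelihood"]],
        names=["scorer", "bodyparts", "coords"],
    )
    out = pd.DataFrame(
        np.column_stack([track["x_mm"], track["y_mm"], track["likelihood"]]),
        index=pd.Index(np.asarray(track.index, dtype=int), name=None),
        columns=cols,
    )
    out.to_csv(path)


def read_track_csv(path, body_part: str | None = None) -> pd.DataFrame:
    """Read a DeepLabCut-style CSV into a frame-indexed table.

    Returns a DataFrame with columns ``x_mm``, ``y_mm``, ``likelihood``.
    When the file contains several body parts, ``body_part`` selects one
    (default: the first).
    """
    raw = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    parts = list(dict.fromkeys(raw.columns.get_level_values(1)))
    if body_part is None:
        body_part = parts[0]
    if body_part not in parts:
        raise ValueError(f"body part {body_part!r} not in file (has {parts})")
    sub = raw.xs(body_part, axis=1, level=1)
    sub.columns = sub.columns.get_level_values(-1)
    df = pd.DataFrame(
        {
            "x_mm": sub["x"].to_numpy(float),
            "y_mm": sub["y"].to_numpy(float),
            "likelihood": sub["likelihood"].to_numpy(float),
        },
        index=np.asarray(raw.index, dtype=int),
    )
    return df


# ---------------------------------------------------------------------------
# LFP HDF5 container
# ---------------------------------------------------------------------------

def write_lfp_h5(path, rec: LFPRecording, dtype=np.float32) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("lfp", data=rec.signal.astype(dtype))
        d.attrs["fs_hz"] = float(rec.fs_hz)
        d.attrs["channel_names"] = [str(c) for c in rec.channel_names]
        d.attrs["bundle_id"] = np.asarray(rec.bundle_id, dtype=int)
        d.attrs["t0"] = float(rec.t0)


def read_lfp_h5(path) -> LFPRecording:
    with h5py.File(path, "r") as f:
        d = f["lfp"]
        rec = LFPRecording(
            signal=d[()].astype(np.float64),
            fs_hz=float(d.attrs["fs_hz"]),
            channel_names=[str(c) for c in d.attrs["channel_names"]],
            bundle_id=np.asarray(d.attrs["bundle_id"], dtype=int),
            t0=float(d.attrs["t0"]),
        )
    return rec


# ---------------------------------------------------------------------------
# Region map and JSON helpers
# ---------------------------------------------------------------------------

def write_region_map(path, channel_names, bundle_id) -> None:
    doc = {
        "channels": [
            {"name": str(n), "bundle": int(b)}
            for n, b in zip(channel_names, bundle_id)
        ]
    }
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


def read_region_map(path):
    with open(path) as f:
        doc = yaml.safe_load(f)
    names = [c["name"] for c in doc["channels"]]
    bundles = np.array([c["bundle"] for c in doc["channels"]], dtype=int)
    return names, bundles


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, default=_default)
        f.write("\n")


def read_json(path):
    with open(path) as f:
        return json.load(f)
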