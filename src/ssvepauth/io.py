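"""EEG file I/O: CSV with a JSON sidecar.

The interchange dialect is a plain CSV with a ``time`` column and one
column per channel (``O1,Oz,O2`` or a subset), one row per sample, plus
a ``<name>.json`` sidecar carrying the sampling rate, montage and the
simulation configuration/seed that produced the data.  Plain text keeps
recordings diffable and auditable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ChannelMontage, EEGSegment, SimConfig


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_eeg(path: str | Path, segment: EEGSegment,
              montage: ChannelMontage | None = None,
              sim_config: SimConfig | None = None) -> Path:
    """Write ``segment`` as CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    names = segment.channel_names or tuple(
        f"ch{i}" for i in range(segment.n_channels))
    t = (np.arange(segment.n_samples) + segment.onset_index) / segment.fs
    df = pd.DataFrame({"time": t})
    for i, name in enumerate(names):
        df[name] = segment.samples[i]
    df.to_csv(path, index=False, float_format="%.6f")
    meta: dict = {"fs": segment.fs, "onset_index": segment.onset_index,
                  "channel_names": list(names)}
    if montage is not None:
        meta["montage"] = dataclasses.asdict(montage)
    if sim_config is not None:
        meta["sim_config"] = dataclasses.asdict(sim_config)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_eeg(path: str | Path) -> tuple[EEGSegment, dict]:
    """Read a CSV + sidecar pair back into an :class:`EEGSegment`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing JSON sidecar {sidecar.name} next to {path.name}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path)
    names = meta["channel_names"]
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise ValueError(f"CSV lacks channels listed in sidecar: {missing}")
    if len(df) >= 2:
        dt = np.diff(df["time"].to_numpy()[:2])[0]
        if abs(dt - 1.0 / meta["fs"]) > 1e-6:
            raise ValueError(
                f"time step {dt:.6g}s inconsistent with fs={meta['fs']} Hz")
    samples = df[names].to_numpy().T
    seg = EEGSegment(samples, meta["fs"],
                     onset_index=int(meta.get("onset_index", 0)),
                     channel_names=tuple(names))
    return seg, meta
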