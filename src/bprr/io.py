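"""Reading and writing recordings, tables, and maps.

Signals travel either as EDF (read through :mod:`mne`, if installed) or
as the flat binary format: raw float32 samples in channel-major order
plus a JSON sidecar ``{fs, n_channels, channel_ids, dtype, order}``.
Electrode and annotation tables are TSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import Recording

__all__ = ["write_binary_recording", "read_binary_recording", "read_edf_recording",
           "read_recording"]


def write_binary_recording(rec: Recording, path) -> None:
    """Write a recording as flat float32 binary + JSON sidecar."""
    path = Path(path)
    rec.samples.astype("<f4").tofile(path)
    sidecar = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "channel_ids": list(rec.channel_ids),
        "dtype": "float32",
        "order": "C",  # channel-major: all samples of channel 0, then channel 1, ...
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_binary_recording(path) -> Recording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=np.dtype(sidecar["dtype"]).newbyteorder("<"))
    n_ch = int(sidecar["n_channels"])
    data = data.reshape(n_ch, -1, order=sidecar.get("order", "C"))
    return Recording(data.astype(float), float(sidecar["fs"]), list(sidecar["channel_ids"]))


def read_edf_recording(path) -> Recording:
    """Read an EDF file (requires mne); amplitudes converted V → µV."""
    import mne
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names))


def read_recording(path) -> Recording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf_recording(path)
    return read_binary_recording(path)
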