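"""On-disk formats: chunked HDF5 recordings, TSV trial tables, WAV audio.

A recording container holds ``signal`` (channels x samples, float32,
chunked along time), root attributes ``fs`` and ``line_freq``, and one
attribute array per channel-metadata column.  Trial tables are plain
TSV with the documented column names; per-trial audio goes to 16-bit
WAV files named ``trial_<id>.wav``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io.wavfile

from .preprocess import Recording


def write_recording(path, rec: Recording) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        n_ch, n_samp = rec.signal.shape
        ds = f.create_dataset("signal", data=rec.signal.astype(np.float32),
                              chunks=(min(n_ch, 16), min(n_samp, 65536)))
        ds.attrs["units"] = "uV"
        f.attrs["fs"] = float(rec.fs)
        f.attrs["line_freq"] = float(rec.line_freq)
        meta = f.create_group("channels")
        for col in rec.channels.columns:
            vals = rec.channels[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            meta.create_dataset(col, data=vals)


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        sig = f["signal"][()]
        cols = {}
        for col, ds in f["channels"].items():
            v = ds[()]
            if v.dtype.kind == "S":
                v = v.astype(str)
            cols[col] = v
        rec = Recording(signal=sig, fs=float(f.attrs["fs"]),
                        channels=pd.DataFrame(cols),
                        line_freq=float(f.attrs["line_freq"]))
    return rec


def write_trials(path, trials: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_audio(outdir, trials: pd.DataFrame, traces,
                fs_audio: float = 8192.0) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tid, x in zip(trials["trial_id"], traces):
        pcm = np.clip(np.asarray(x) * 32767, -32768, 32767).astype(np.int16)
        scipy.io.wavfile.write(outdir / f"trial_{tid:04d}.wav",
                               int(fs_audio), pcm)


def read_audio(path):
    fs, x = scipy.io.wavfile.read(path)
    return float(fs), x.astype(np.float64) / 32767.0


def write_json(path, obj) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict("records")
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default,
                               allow_nan=True))
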