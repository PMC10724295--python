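"""Portable HDF5 containers for recordings and epochs, plus TSV helpers."""

from __future__ import annotations

import io as _io

import h5py
import numpy as np
import pandas as pd

from .preprocess import EpochsArray
from .simulate import RawRecording


def _frame_to_group(g: h5py.Group, frame: pd.DataFrame) -> None:
    buf = _io.StringIO()
    frame.to_csv(buf, sep="\t", index=False)
    g.attrs["table_tsv"] = buf.getvalue()


def _frame_from_group(g: h5py.Group) -> pd.DataFrame:
    return pd.read_csv(_io.StringIO(g.attrs["table_tsv"]), sep="\t")


def save_recording(path, rec: RawRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip")
        f.attrs["srate"] = rec.srate
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["channel_names"] = list(rec.channel_names)
        _frame_to_group(f, rec.events)


def load_recording(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        return RawRecording(
            data=f["data"][()],
            srate=float(f.attrs["srate"]),
            channel_names=tuple(str(c) for c in f.attrs["channel_names"]),
            events=_frame_from_group(f),
            subject_id=str(f.attrs["subject_id"]),
        )


def save_epochs(path, ep: EpochsArray) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ep.data, compression="gzip")
        f.create_dataset("retained_mask", data=ep.retained_mask)
        f.attrs["srate"] = ep.srate
        f.attrs["window_ms"] = list(ep.window_ms)
        f.attrs["subject_id"] = ep.subject_id
        f.attrs["channel_names"] = list(ep.channel_names)
        _frame_to_group(f, ep.meta)


def load_epochs(path) -> EpochsArray:
    with h5py.File(path, "r") as f:
        return EpochsArray(
            data=f["data"][()],
            srate=float(f.attrs["srate"]),
            window_ms=tuple(float(v) for v in f.attrs["window_ms"]),
            channel_names=tuple(str(c) for c in f.attrs["channel_names"]),
            meta=_frame_from_group(f),
            retained_mask=f["retained_mask"][()].astype(bool),
            subject_id=str(f.attrs["subject_id"]),
        )


def events_to_tsv(path, rec: RawRecording) -> None:
    rec.events.to_csv(path, sep="\t", index=False)
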