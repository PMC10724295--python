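"""Deterministic preprocessing: filter, re-reference, epoch, reject.

Mirrors a conventional ERP chain: a 0.1-40 Hz second-order (12 dB/oct)
Butterworth band-pass applied forward-backward (zero phase), average
re-reference plus mean-signal detrend, epoching from -300 to 700 ms around
stimulus onset with baseline correction over the first 100 ms of the epoch,
and ±100 μV amplitude-criterion epoch rejection.

Artifact-specific steps that only make sense on real recordings (wavelet
ICA, line-noise removal, bad-channel interpolation) are not re-implemented;
``extract_epochs`` accepts a ``raw_hook`` callable so such a stage can be
slotted in front when working with real data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .simulate import RawRecording


class PreprocessError(ValueError):
    pass


@dataclass
class EpochsArray:
    """Trials x channels x time tensor with trial metadata.

    ``retained_mask`` marks epochs that survived amplitude rejection; all
    analyses downstream operate on retained epochs only.
    """

    data: np.ndarray  # (n_trials, n_channels, n_times), μV
    srate: float
    window_ms: tuple[float, float]
    channel_names: tuple[str, ...]
    meta: pd.DataFrame
    retained_mask: np.ndarray
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        n, c, t = self.data.shape
        if len(self.meta) != n:
            raise PreprocessError("meta length must equal number of epochs")
        if len(self.channel_names) != c:
            raise PreprocessError("channel_names length must match data")
        if len(self.retained_mask) != n:
            raise PreprocessError("retained_mask length must match data")

    @property
    def times_ms(self) -> np.ndarray:
        n_t = self.data.shape[2]
        return self.window_ms[0] + np.arange(n_t) * 1000.0 / self.srate

    def sample_of(self, t_ms: float) -> int:
        return int(round((t_ms - self.window_ms[0]) / 1000.0 * self.srate))

    def select(
        self,
        role: str | None = None,
        category: str | None = None,
        block: str | None = None,
        include_targets: bool = False,
        retained_only: bool = True,
    ) -> "EpochsArray":
        """Subset epochs by trial metadata (and drop rejected epochs)."""
        m = np.ones(len(self.meta), dtype=bool)
        if role is not None:
            m &= np.asarray(self.meta["role"] == role)
        if category is not None:
            m &= np.asarray(self.meta["category"] == category)
        if block is not None:
            m &= np.asarray(self.meta["block"] == block)
        if not include_targets:
            m &= ~np.asarray(self.meta["is_target"], dtype=bool)
        if retained_only:
            m &= self.retained_mask
        return EpochsArray(
            data=self.data[m],
            srate=self.srate,
            window_ms=self.window_ms,
            channel_names=self.channel_names,
            meta=self.meta.loc[m].reset_index(drop=True),
            retained_mask=self.retained_mask[m].copy(),
            subject_id=self.subject_id,
        )


def bandpass_filter(
    rec: RawRecording, low: float = 0.1, high: float = 40.0
) -> RawRecording:
    """Zero-phase second-order Butterworth band-pass (12 dB/oct roll-off)."""
    if not (0 < low < high):
        raise PreprocessError("need 0 < low < high")
    if rec.srate <= 2 * high:
        raise PreprocessError("sampling rate must exceed twice the high cutoff")
    sos = butter(2, [low, high], btype="bandpass", fs=rec.srate, output="sos")
    # float32 filtering halves the memory traffic on long recordings; the
    # result is upcast back so downstream arithmetic stays in double.
    out = sosfiltfilt(
        sos.astype(np.float32), rec.data.astype(np.float32, copy=False), axis=-1
    )
    out = out.astype(np.float64, copy=False)
    return RawRecording(
        data=out,
        srate=rec.srate,
        channel_names=rec.channel_names,
        events=rec.events,
        subject_id=rec.subject_id,
    )


def rereference_average_and_detrend(rec: RawRecording) -> RawRecording:
    """Average reference (per-sample channel mean 0), then mean detrend
    (per-channel time mean 0)."""
    if rec.data.shape[0] < 2:
        raise PreprocessError("average reference needs at least 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    out = out - out.mean(axis=1, keepdims=True)
    return RawRecording(
        data=out,
        srate=rec.srate,
        channel_names=rec.channel_names,
        events=rec.events,
        subject_id=rec.subject_id,
    )


def extract_epochs(
    rec: RawRecording,
    window_ms: tuple[float, float] = (-300.0, 700.0),
    baseline_ms: tuple[float, float] = (-300.0, -200.0),
    raw_hook=None,
) -> EpochsArray:
    """Cut epochs around every event and baseline-correct them.

    The window is sample-aligned as ``[onset + window_ms[0], onset +
    window_ms[1])`` — at 1000 Hz an event at sample 5000 with the default
    window yields samples 4700..5699.  The baseline interval (default: the
    first 100 ms of the epoch, i.e. [-300, -200) ms) is averaged per epoch
    and channel and subtracted.  ``raw_hook``, if given, is applied to the
    recording first (entry point for artifact-removal stages).
    """
    if raw_hook is not None:
        rec = raw_hook(rec)
    sr = rec.srate
    lo = int(round(window_ms[0] / 1000.0 * sr))
    hi = int(round(window_ms[1] / 1000.0 * sr))
    b_lo = int(round((baseline_ms[0] - window_ms[0]) / 1000.0 * sr))
    b_hi = int(round((baseline_ms[1] - window_ms[0]) / 1000.0 * sr))
    if not (0 <= b_lo < b_hi <= hi - lo):
        raise PreprocessError("baseline interval must lie within the window")
    n_t = hi - lo
    samples = np.asarray(rec.events["sample"], dtype=int)
    n_samples = rec.data.shape[1]
    epochs = np.empty((len(samples), rec.data.shape[0], n_t))
    for i, s in enumerate(samples):
        if s + lo < 0 or s + hi > n_samples:
            raise PreprocessError(
                f"trial {i} (sample {s}) lacks full window support"
            )
        epochs[i] = rec.data[:, s + lo : s + hi]
    base = epochs[:, :, b_lo:b_hi].mean(axis=2, keepdims=True)
    epochs -= base
    return EpochsArray(
        data=epochs,
        srate=sr,
        window_ms=window_ms,
        channel_names=rec.channel_names,
        meta=rec.events.reset_index(drop=True),
        retained_mask=np.ones(len(samples), dtype=bool),
        subject_id=rec.subject_id,
    )


def reject_amplitude(ep: EpochsArray, threshold: float = 100.0) -> EpochsArray:
    """Flag epochs whose absolute amplitude exceeds ``threshold`` μV."""
    peak = np.maximum(
        ep.data.max(axis=(1, 2)), -ep.data.min(axis=(1, 2))
    )
    keep = ep.retained_mask & (peak <= threshold)
    return replace(ep, retained_mask=keep)


def retained_counts(ep: EpochsArray) -> pd.DataFrame:
    """Retained-epoch counts per (block, role, category) — rejection log."""
    m = ep.meta.assign(retained=ep.retained_mask)
    return (
        m.groupby(["block", "role", "category"], as_index=False)["retained"]
        .sum()
    )


def preprocess_recording(
    rec: RawRecording,
    low: float = 0.1,
    high: float = 40.0,
    window_ms: tuple[float, float] = (-300.0, 700.0),
    baseline_ms: tuple[float, float] = (-300.0, -200.0),
    threshold: float = 100.0,
    raw_hook=None,
) -> EpochsArray:
    """The full deterministic chain: filter → re-reference → epoch → reject."""
    rec = bandpass_filter(rec, low, high)
    rec = rereference_average_and_detrend(rec)
    ep = extract_epochs(rec, window_ms, baseline_ms, raw_hook=raw_hook)
    return reject_amplitude(ep, threshold)
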