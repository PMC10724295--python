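"""Synthetic multichannel EEG with known representational structure.

Each subject is simulated as a continuous 61-channel recording at 1000 Hz
containing one event per trial of the supplied sequences.  The signal is a
sum of

* a common evoked waveform shared by every stimulus (a posterior-weighted
  P1/N1/P2 complex),
* per-effect contributions: a seeded random unit-norm spatial pattern times
  a half-cosine temporal envelope over the effect's latency window, scaled
  by the effect amplitude and by a per-character feature (binary consistency
  membership, or standardised log frequency),
* an optional deviance response ("vmmn" effect): a negative deflection at
  the six posterior occipital-temporal ROI channels, added to deviant-role
  trials only,
* additive noise, a seeded mixture of white and one-pole-filtered ("pink")
  noise.

Because the injected effects mirror the model representational dissimilarity
structures used downstream, every analysis stage has a recoverable ground
truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    CharacterTable,
    TrialSequence,
    generate_session,
    make_default_character_table,
)

EPOCH_WINDOW_MS = (-300.0, 700.0)
SRATE = 1000.0

ROI_LEFT = ("P7", "PO7", "O1")
ROI_RIGHT = ("P8", "PO8", "O2")

#: 61 scalp labels on the 10-10 system — a 64-channel cap minus the two
#: mastoids and the EOG channel, as typically mounted for visual ERP work.
SCALP_61 = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

DIMENSIONS = ("orthographic", "phonological", "semantic", "frequency", "vmmn")
_DIM_TO_CATEGORY = {
    "orthographic": "IOr",
    "phonological": "IPh",
    "semantic": "ISe",
}


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Montage:
    """61 scalp channels with unit-sphere positions."""

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (61, 3), unit norm

    def __post_init__(self) -> None:
        if len(self.channel_names) != 61:
            raise SimulationError("montage must have 61 channels")
        if len(set(self.channel_names)) != 61:
            raise SimulationError("montage channel names must be unique")
        for ch in ROI_LEFT + ROI_RIGHT:
            if ch not in self.channel_names:
                raise SimulationError(f"ROI channel {ch} missing from montage")
        if self.positions.shape != (61, 3):
            raise SimulationError("positions must be (61, 3)")

    def index_of(self, names) -> np.ndarray:
        lut = {ch: i for i, ch in enumerate(self.channel_names)}
        return np.array([lut[n] for n in names])


_DEFAULT_MONTAGE: Montage | None = None


def default_montage() -> Montage:
    """The default 61-channel 10-10 montage, positions taken from MNE."""
    global _DEFAULT_MONTAGE
    if _DEFAULT_MONTAGE is None:
        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            std = mne.channels.make_standard_montage("standard_1005")
        pos_map = std.get_positions()["ch_pos"]
        pos = np.array([pos_map[ch] for ch in SCALP_61])
        pos = pos - pos.mean(axis=0)
        pos /= np.linalg.norm(pos, axis=1, keepdims=True)
        _DEFAULT_MONTAGE = Montage(channel_names=SCALP_61, positions=pos)
    return _DEFAULT_MONTAGE


# ---------------------------------------------------------------------------
# effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effect injected into the simulation.

    ``amplitude`` (μV) applies in every block; ``oddball_boost`` is added on
    top in oddball blocks, letting consistency representations be stronger
    (or present only) under high-precision prediction.  For consistency and
    frequency dimensions the spatial pattern is a unit-norm random vector
    from ``pattern_seed``; the ``vmmn`` dimension instead adds a negative
    per-channel deflection of ``amplitude`` μV at the six ROI channels, on
    deviant trials only.
    """

    dimension: str
    window_ms: tuple[float, float]
    amplitude: float
    pattern_seed: int = 0
    roi_restricted: bool = False
    oddball_boost: float = 0.0

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise SimulationError(f"unknown dimension {self.dimension!r}")
        lo, hi = self.window_ms
        if not (EPOCH_WINDOW_MS[0] <= lo < hi <= EPOCH_WINDOW_MS[1]):
            raise SimulationError(
                f"effect window {self.window_ms} outside epoch support {EPOCH_WINDOW_MS}"
            )
        if self.amplitude < 0 or self.oddball_boost < 0:
            raise SimulationError("amplitudes must be >= 0")


def default_effects(
    consistency_amplitude: float = 6.0,
    frequency_amplitude: float = 6.0,
    vmmn_amplitude: float = 2.0,
) -> list[EffectSpec]:
    """Default ground truth mirroring the qualitative target pattern.

    Consistency (sub-lexical) representations are injected in the oddball
    condition only (amplitude 0 plus an oddball boost) over 150-500 ms;
    the lexical frequency code is present in both conditions over an
    underlying 140-240 ms window (whose detectable footprint after the
    half-cosine taper is roughly 150-220 ms); deviants carry a -2 μV
    posterior deviance response over 150-300 ms.  Amplitudes are calibrated
    so group-level partial correlations land in the weak-effect regime
    (subject-mean rho of roughly 0.1-0.3) typical of time-resolved RSA.
    """
    return [
        EffectSpec("orthographic", (150.0, 500.0), 0.0,
                   pattern_seed=101, oddball_boost=consistency_amplitude),
        EffectSpec("phonological", (150.0, 500.0), 0.0,
                   pattern_seed=102, oddball_boost=consistency_amplitude),
        EffectSpec("semantic", (150.0, 500.0), 0.0,
                   pattern_seed=103, oddball_boost=consistency_amplitude),
        EffectSpec("frequency", (140.0, 240.0), frequency_amplitude,
                   pattern_seed=104),
        EffectSpec("vmmn", (150.0, 300.0), vmmn_amplitude,
                   pattern_seed=105, roi_restricted=True),
    ]


def character_feature(
    dimension: str, character_id: str, table: CharacterTable
) -> float:
    """Per-character scalar driving an effect's trial-to-trial variation.

    Consistency dimensions are binary (1 = the character is inconsistent on
    that dimension); frequency is the standardised log10 corpus frequency
    over the 12-character inventory.
    """
    if dimension == "vmmn":
        raise SimulationError("vmmn effects are role-driven, not feature-driven")
    if dimension not in DIMENSIONS:
        raise SimulationError(f"unknown dimension {dimension!r}")
    if dimension == "frequency":
        logf = np.log10(np.asarray(table.frame["frequency"], dtype=float))
        z = (logf - logf.mean()) / logf.std()
        idx = table.character_ids.index(character_id)  # raises if unknown
        return float(z[idx])
    cat = table.category_of(character_id)
    return 1.0 if cat == _DIM_TO_CATEGORY[dimension] else 0.0


# ---------------------------------------------------------------------------
# recording container
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """Continuous multichannel EEG (μV) with a per-trial event table.

    ``events`` has one row per trial with columns ``sample`` (onset sample,
    strictly increasing), ``block``, ``index``, ``character_id``,
    ``category``, ``role``, ``is_target``.
    """

    data: np.ndarray  # (channels, samples)
    srate: float
    channel_names: tuple[str, ...]
    events: pd.DataFrame
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise SimulationError("data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise SimulationError("data contains non-finite values")
        s = np.asarray(self.events["sample"])
        if len(s) and np.any(np.diff(s) <= 0):
            raise SimulationError("event samples must be strictly increasing")


# ---------------------------------------------------------------------------
# waveform pieces
# ---------------------------------------------------------------------------

def _common_evoked(montage: Montage, n_samples_post: int = 700) -> np.ndarray:
    """Deterministic P1/N1/P2 complex, posterior-weighted; (61, n) μV."""
    t = np.arange(n_samples_post) / SRATE * 1000.0  # ms after onset
    wave = (
        3.0 * np.exp(-0.5 * ((t - 120.0) / 25.0) ** 2)
        - 4.0 * np.exp(-0.5 * ((t - 170.0) / 30.0) ** 2)
        + 2.5 * np.exp(-0.5 * ((t - 240.0) / 45.0) ** 2)
    )
    # weight channels toward posterior sites (negative y in MNE head coords)
    w = np.clip(-montage.positions[:, 1], 0.0, None) + 0.3
    w /= w.max()
    return np.outer(w, wave)


def _half_cosine(window_ms: tuple[float, float]) -> tuple[np.ndarray, int]:
    """Envelope samples and onset offset (samples after stimulus onset)."""
    lo, hi = window_ms
    n = int(round((hi - lo) / 1000.0 * SRATE))
    x = (np.arange(n) + 0.5) / n
    return np.sin(np.pi * x), int(round(lo / 1000.0 * SRATE))


def _pattern(seed: int, roi_idx: np.ndarray) -> np.ndarray:
    """Seeded unit-norm spatial pattern, zero at the ROI channels and zero-sum.

    Keeping representational patterns out of the six vMMN ROI channels (and
    zero-mean, so average referencing leaves them untouched) makes the
    deviance ground truth separable from the representational ground truth;
    the RSA machinery is indifferent to which channels carry the pattern.
    """
    v = np.random.default_rng(seed).standard_normal(61)
    v[roi_idx] = 0.0
    rest = np.setdiff1d(np.arange(61), roi_idx)
    v[rest] -= v[rest].mean()
    return v / np.linalg.norm(v)


def _noise(
    rng: np.random.Generator,
    shape: tuple[int, int],
    noise_sd: float,
    pink_fraction: float,
    a: float = 0.98,
) -> np.ndarray:
    """White + one-pole ("pink") noise mixture, variance-weighted.

    The AR(1) component is scaled by its asymptotic standard deviation
    1/sqrt(1 - a^2), so each component has unit variance before mixing.
    Generated and returned in float32 (μV): continuous recordings are the
    memory bottleneck of cohort simulation and single precision is far below
    the noise floor.
    """
    from scipy.signal import lfilter

    w = rng.standard_normal(shape, dtype=np.float32)
    if pink_fraction > 0:
        p = lfilter(
            np.array([1.0], dtype=np.float32),
            np.array([1.0, -a], dtype=np.float32),
            rng.standard_normal(shape, dtype=np.float32), axis=-1,
        ).astype(np.float32)
        p *= np.float32(np.sqrt(1.0 - a * a))
        w *= np.float32(np.sqrt(1.0 - pink_fraction))
        w += np.float32(np.sqrt(pink_fraction)) * p
    w *= np.float32(noise_sd)
    return w


# ---------------------------------------------------------------------------
# subject and cohort simulation
# ---------------------------------------------------------------------------

def simulate_subject(
    seq_list: list[TrialSequence],
    table: CharacterTable,
    montage: Montage | None = None,
    effects: list[EffectSpec] | None = None,
    noise_sd: float = 8.0,
    pink_fraction: float = 0.5,
    seed: int = 0,
    subject_id: str = "S00",
    inter_block_gap_s: float = 2.0,
    edge_pad_s: float = 1.0,
) -> RawRecording:
    """Render one subject's continuous recording from trial sequences.

    Blocks are concatenated with a silent gap; every trial contributes the
    common evoked waveform plus all applicable effects.  Noise is a
    ``pink_fraction``-weighted mixture (by variance) of white and one-pole
    pink noise with total standard deviation ``noise_sd`` μV.  Deterministic
    given ``seed``.
    """
    if montage is None:
        montage = default_montage()
    if effects is None:
        effects = default_effects()
    rng = np.random.default_rng(seed)

    pad = int(round(edge_pad_s * SRATE))
    gap = int(round(inter_block_gap_s * SRATE))
    post = int(round(EPOCH_WINDOW_MS[1] / 1000.0 * SRATE))

    # global onset samples
    rows = []
    offset = pad
    for seq in seq_list:
        onset_samples = (
            np.round(np.array([t.onset_ms for t in seq.trials]) / 1000.0 * SRATE)
            .astype(int) + offset
        )
        for t, s in zip(seq.trials, onset_samples):
            rows.append(
                {
                    "sample": int(s),
                    "block": t.block,
                    "index": t.index,
                    "character_id": t.character_id,
                    "category": t.category,
                    "role": t.role,
                    "is_target": t.is_target,
                }
            )
        offset = int(onset_samples[-1]) + post + gap
    events = pd.DataFrame(rows)
    n_samples = int(events["sample"].iloc[-1]) + post + pad

    roi_idx = montage.index_of(ROI_LEFT + ROI_RIGHT)
    if noise_sd > 0:
        data = _noise(rng, (61, n_samples), noise_sd, pink_fraction)
    else:
        data = np.zeros((61, n_samples), dtype=np.float32)

    evoked = _common_evoked(montage, post)

    # precompute per-effect pieces
    pieces = []
    for eff in effects:
        env, off = _half_cosine(eff.window_ms)
        if eff.dimension == "vmmn":
            pat = np.zeros(61)
            pat[roi_idx] = -1.0  # negative deflection, per-channel μV
            feats = None
        else:
            pat = _pattern(eff.pattern_seed, roi_idx)
            feats = {
                cid: character_feature(eff.dimension, cid, table)
                for cid in table.character_ids
            }
        pieces.append((eff, pat, env, off, feats))

    for row in events.itertuples(index=False):
        s = row.sample
        data[:, s : s + post] += evoked
        in_oddball = row.block.startswith("oddball_")
        for eff, pat, env, off, feats in pieces:
            amp = eff.amplitude + (eff.oddball_boost if in_oddball else 0.0)
            if amp == 0:
                continue
            if eff.dimension == "vmmn":
                if row.role != "deviant":
                    continue
                scale = amp
            else:
                scale = amp * feats[row.character_id]
                if scale == 0:
                    continue
            sl = slice(s + off, s + off + len(env))
            data[:, sl] += np.outer(pat, scale * env)

    return RawRecording(
        data=data,
        srate=SRATE,
        channel_names=montage.channel_names,
        events=events,
        subject_id=subject_id,
    )


@dataclass(frozen=True)
class SubjectRecording:
    subject_id: str
    recording: RawRecording
    sequences: list[TrialSequence]


def iter_cohort(
    n_subjects: int = 45,
    table: CharacterTable | None = None,
    montage: Montage | None = None,
    effects: list[EffectSpec] | None = None,
    between_subject_sd: float = 0.0,
    n_trials_oddball: int = 420,
    n_trials_equal: int = 480,
    p_deviant: float = 0.25,
    p_target: float = 0.1,
    noise_sd: float = 8.0,
    pink_fraction: float = 0.5,
    seed: int = 0,
):
    """Lazily simulate a cohort, one fresh session design per subject.

    Yields :class:`SubjectRecording` one at a time so full-size cohorts can
    be processed in bounded memory (a continuous study-scale recording is
    hundreds of MB).  Per-subject effect amplitudes are drawn
    Normal(amplitude, between_subject_sd) truncated at zero (likewise for
    the oddball boost); per-subject seeds are derived from the master seed,
    so the cohort is reproducible element-wise.
    """
    if n_subjects < 1:
        raise SimulationError("n_subjects must be >= 1")
    if table is None:
        table = make_default_character_table(seed)
    if effects is None:
        effects = default_effects()
    master = np.random.default_rng(seed)
    for i in range(n_subjects):
        sub_seed = int(master.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        seqs = generate_session(
            table,
            n_trials_oddball=n_trials_oddball,
            n_trials_equal=n_trials_equal,
            p_deviant=p_deviant,
            p_target=p_target,
            seed=int(sub_rng.integers(0, 2**31 - 1)),
        )
        sub_effects = []
        for eff in effects:
            amp = eff.amplitude
            boost = eff.oddball_boost
            if between_subject_sd > 0:
                if amp > 0:
                    amp = max(0.0, float(sub_rng.normal(amp, between_subject_sd)))
                if boost > 0:
                    boost = max(0.0, float(sub_rng.normal(boost, between_subject_sd)))
            sub_effects.append(
                EffectSpec(
                    eff.dimension, eff.window_ms, amp,
                    pattern_seed=eff.pattern_seed,
                    roi_restricted=eff.roi_restricted,
                    oddball_boost=boost,
                )
            )
        sid = f"S{i:02d}"
        rec = simulate_subject(
            seqs, table, montage, sub_effects,
            noise_sd=noise_sd, pink_fraction=pink_fraction,
            seed=int(sub_rng.integers(0, 2**31 - 1)), subject_id=sid,
        )
        yield SubjectRecording(subject_id=sid, recording=rec, sequences=seqs)


def simulate_cohort(*args, **kwargs) -> list[SubjectRecording]:
    """Eager variant of :func:`iter_cohort`; holds every recording in memory,
    so prefer the iterator for study-scale cohorts."""
    return list(iter_cohort(*args, **kwargs))
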