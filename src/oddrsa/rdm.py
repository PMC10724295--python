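"""Representational dissimilarity matrices: neural time courses and models.

Neural RDMs are 9x9 (one row per inconsistent character), computed at each
point of a -100..600 ms grid with 10 ms resolution.  The feature vector at
time t concatenates all scalp channels over an 11-sample window (t ± 5
samples at 1000 Hz): with 61 channels that is 671 features.  Dissimilarity
between two characters is the mean of 1 - Pearson correlation over all
cross-character trial pairs — individual trials, no averaging and no
cross-validated distance.

Model RDMs come in four families: binary consistency predictors
(orthographic / phonological / semantic: 1 for a between-category pair,
0 within), a radical-control RDM (0 iff the pair shares a phonetic-radical
set), a frequency RDM (absolute log10 corpus-frequency difference) and
rating RDMs (absolute difference of mean 1-7 consistency ratings).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CharacterTable
from .preprocess import EpochsArray

DEFAULT_TIMES_MS = np.arange(-100, 601, 10)
HALF_WINDOW = 5  # samples on each side of the centre time point

_DIM_TO_CATEGORY = {
    "orthographic": "IOr",
    "phonological": "IPh",
    "semantic": "ISe",
}
_DIM_TO_RATING = {
    "orthographic": "rating_orth",
    "phonological": "rating_phon",
    "semantic": "rating_sem",
}


class RDMError(ValueError):
    pass


@dataclass(frozen=True)
class RDM:
    """A labelled symmetric dissimilarity matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str = "neural"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise RDMError("values must be square and match labels")
        if not np.allclose(self.values, self.values.T):
            raise RDMError("RDM must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise RDMError("RDM diagonal must be zero")

    def reorder(self, labels) -> "RDM":
        idx = [self.labels.index(l) for l in labels]
        return RDM(tuple(labels), self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, kind: str = "neural") -> "RDM":
        f = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(f.index), f.to_numpy(dtype=float), kind)


@dataclass(frozen=True)
class RDMStack:
    """Time-indexed neural RDMs for one subject and condition."""

    times_ms: np.ndarray
    values: np.ndarray  # (n_times, n, n)
    labels: tuple[str, ...]
    subject_id: str = "S00"
    condition: str = "oddball"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_ms) <= 0):
            raise RDMError("time grid must be strictly increasing")
        if self.values.shape[0] != len(self.times_ms):
            raise RDMError("one RDM per time point required")

    def rdm_at(self, t_ms: float) -> RDM:
        i = int(np.argmin(np.abs(self.times_ms - t_ms)))
        return RDM(self.labels, self.values[i], "neural")

    def vectors(self) -> np.ndarray:
        """(n_times, n_pairs) lower-triangle vectors."""
        n = len(self.labels)
        r, c = np.tril_indices(n, -1)
        return self.values[:, r, c]


# ---------------------------------------------------------------------------
# neural RDMs
# ---------------------------------------------------------------------------

def spatiotemporal_features(
    ep: EpochsArray, t_ms: float, half_window: int = HALF_WINDOW
) -> np.ndarray:
    """Trials x features matrix at time t.

    Features concatenate each channel's samples over t ± half_window
    (channel-major order), so 61 channels give 61 x 11 = 671 features.
    """
    c = ep.sample_of(t_ms)
    lo, hi = c - half_window, c + half_window + 1
    if lo < 0 or hi > ep.data.shape[2]:
        raise RDMError(
            f"feature window at {t_ms} ms truncated by the epoch edge"
        )
    block = ep.data[:, :, lo:hi]  # (trials, channels, 2h+1)
    return block.reshape(block.shape[0], -1)


def _pairwise_distance(features: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between every pair of trial vectors."""
    z = features - features.mean(axis=1, keepdims=True)
    sd = np.linalg.norm(z, axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z /= sd
    return 1.0 - z @ z.T


def neural_rdm_timecourse(
    ep: EpochsArray,
    condition: str,
    table: CharacterTable,
    times_ms: np.ndarray = DEFAULT_TIMES_MS,
    include_targets: bool = False,
    half_window: int = HALF_WINDOW,
) -> RDMStack:
    """Time-resolved 9x9 neural RDM over the inconsistent characters.

    ``condition='oddball'`` pools deviant-role trials across the three
    oddball blocks; ``condition='equal_probability'`` uses the equiprobable
    trials of the nine inconsistent characters.  Entry (i, j) is the mean
    over all cross-character trial pairs of 1 - Pearson correlation between
    spatiotemporal feature vectors; the diagonal is zero.
    """
    if condition == "oddball":
        sel = ep.select(role="deviant", include_targets=include_targets)
    elif condition == "equal_probability":
        sel = ep.select(role="equiprobable", include_targets=include_targets)
        keep = np.asarray(sel.meta["category"] != "CC")
        sel = EpochsArray(
            data=sel.data[keep], srate=sel.srate, window_ms=sel.window_ms,
            channel_names=sel.channel_names,
            meta=sel.meta.loc[keep].reset_index(drop=True),
            retained_mask=sel.retained_mask[keep], subject_id=sel.subject_id,
        )
    else:
        raise RDMError(f"unknown condition {condition!r}")

    labels = tuple(table.inconsistent_ids)
    char = np.asarray(sel.meta["character_id"])
    counts = {l: int((char == l).sum()) for l in labels}
    poor = [l for l, c in counts.items() if c < 2]
    if poor:
        raise RDMError(f"characters with fewer than 2 retained trials: {poor}")

    # group indicator for block averaging of the trial-pair distance matrix
    G = np.stack([(char == l).astype(float) for l in labels])  # (9, n)
    n_per = G.sum(axis=1)
    denom = np.outer(n_per, n_per)

    out = np.zeros((len(times_ms), len(labels), len(labels)))
    for ti, t in enumerate(times_ms):
        F = spatiotemporal_features(sel, float(t), half_window)
        D = _pairwise_distance(F)
        S = G @ D @ G.T
        M = S / denom
        np.fill_diagonal(M, 0.0)
        out[ti] = 0.5 * (M + M.T)  # exact symmetry despite float noise
    return RDMStack(
        times_ms=np.asarray(times_ms, dtype=float),
        values=out,
        labels=labels,
        subject_id=sel.subject_id,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# model RDMs
# ---------------------------------------------------------------------------

def predictor_rdm(dimension: str, table: CharacterTable) -> RDM:
    """Binary consistency predictor: 1 for between-category pairs.

    A pair scores 1 iff exactly one of the two characters is inconsistent
    on the given dimension (e.g. an IOr-IPh pair for the orthographic
    predictor), 0 for within-category pairs.
    """
    if dimension not in _DIM_TO_CATEGORY:
        raise RDMError(f"unknown predictor dimension {dimension!r}")
    labels = tuple(table.inconsistent_ids)
    inc = np.array(
        [table.category_of(l) == _DIM_TO_CATEGORY[dimension] for l in labels],
        dtype=float,
    )
    vals = np.abs(inc[:, None] - inc[None, :])
    return RDM(labels, vals, kind="predictor")


def radical_control_rdm(table: CharacterTable) -> RDM:
    """0 iff the pair shares a phonetic-radical set, else 1."""
    labels = tuple(table.inconsistent_ids)
    rad = np.array(
        [
            int(table.frame.loc[table.frame["character_id"] == l, "radical_set"].iloc[0])
            for l in labels
        ]
    )
    vals = (rad[:, None] != rad[None, :]).astype(float)
    return RDM(labels, vals, kind="radical_control")


def frequency_rdm(table: CharacterTable) -> RDM:
    """Absolute log10 corpus-frequency difference (scale-invariant)."""
    labels = tuple(table.inconsistent_ids)
    f = np.array([table.frequency_of(l) for l in labels])
    if np.any(f <= 0):
        raise RDMError("frequencies must be positive")
    lf = np.log10(f)
    vals = np.abs(lf[:, None] - lf[None, :])
    return RDM(labels, vals, kind="frequency")


def rating_rdm(dimension: str, table: CharacterTable) -> RDM:
    """Pairwise distance of 1-7 consistency ratings on one dimension."""
    if dimension not in _DIM_TO_RATING:
        raise RDMError(f"unknown rating dimension {dimension!r}")
    col = _DIM_TO_RATING[dimension]
    if col not in table.frame.columns or table.frame[col].isna().any():
        raise RDMError(f"ratings {col!r} missing from the character table")
    labels = tuple(table.inconsistent_ids)
    s = np.array(
        [
            float(table.frame.loc[table.frame["character_id"] == l, col].iloc[0])
            for l in labels
        ]
    )
    vals = np.abs(s[:, None] - s[None, :])
    return RDM(labels, vals, kind="rating")


def model_rdms(table: CharacterTable, ratings: bool = False) -> dict[str, RDM]:
    """The standard model set keyed by name.

    With ``ratings=False``: the three binary predictors plus frequency and
    the radical control.  With ``ratings=True`` the consistency models are
    rating-based instead.
    """
    if ratings:
        models = {
            dim: rating_rdm(dim, table)
            for dim in ("orthographic", "phonological", "semantic")
        }
    else:
        models = {
            dim: predictor_rdm(dim, table)
            for dim in ("orthographic", "phonological", "semantic")
        }
    models["frequency"] = frequency_rdm(table)
    models["radical_control"] = radical_control_rdm(table)
    return models


# ---------------------------------------------------------------------------
# vectorisation
# ---------------------------------------------------------------------------

def vectorize_lower_triangle(rdm: RDM | np.ndarray) -> np.ndarray:
    """Strictly-lower triangle in row-major order ((1,0), (2,0), (2,1), ...)."""
    m = rdm.values if isinstance(rdm, RDM) else np.asarray(rdm)
    r, c = np.tril_indices(m.shape[0], -1)
    return m[r, c]


def symmetrize_from_lower(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize_lower_triangle` (zero diagonal)."""
    m = np.zeros((n, n))
    r, c = np.tril_indices(n, -1)
    m[r, c] = vec
    return m + m.T
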