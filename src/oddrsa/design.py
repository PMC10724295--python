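"""Stimulus inventories and trial sequences for oddball / equal-probability blocks.

The experimental design uses 12 Chinese phonogram-like stimuli: 3 consistent
characters (CC) and 9 inconsistent ones, split into three categories of three —
orthographically inconsistent (IOr), phonologically inconsistent (IPh) and
semantically inconsistent (ISe).  Characters are organised in three radical
sets (groups sharing a phonetic radical); each category contains one character
from each set.

A session comprises one equal-probability block (every character equally
likely, p = 0.25 per category) followed by three oddball blocks, one per
inconsistent category.  In an oddball block the three CC characters are the
frequent standards (p = 0.75) and the three characters of one inconsistent
category are the rare deviants (p = 0.25).  Deviants never occur twice in a
row, and a rare colour-change target (p = 0.1) may only follow a non-target
standard trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CATEGORIES = ("CC", "IOr", "IPh", "ISe")
INCONSISTENT_CATEGORIES = ("IOr", "IPh", "ISe")
RADICAL_SETS = (1, 2, 3)

ROLE_STANDARD = "standard"
ROLE_DEVIANT = "deviant"
ROLE_EQUIPROBABLE = "equiprobable"

BLOCK_EQUAL = "equal_probability"
ODDBALL_BLOCKS = ("oddball_IOr", "oddball_IPh", "oddball_ISe")

#: stimulus-on duration and inter-stimulus-interval jitter, in ms
STIMULUS_MS = 200.0
ISI_RANGE_MS = (500.0, 600.0)


class DesignError(ValueError):
    """Raised when a stimulus table or sequence request is infeasible."""


# ---------------------------------------------------------------------------
# character table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CharacterTable:
    """The 12-stimulus inventory.

    Wraps a DataFrame with columns ``character_id``, ``category``,
    ``radical_set``, ``frequency`` (occurrences per million) and optional
    ``rating_orth``, ``rating_phon``, ``rating_sem`` (1-7 consistency
    ratings).  Exactly three characters per category; within each category
    the radical sets are a permutation of {1, 2, 3}.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        required = {"character_id", "category", "radical_set", "frequency"}
        missing = required - set(f.columns)
        if missing:
            raise DesignError(f"character table missing columns: {sorted(missing)}")
        if len(f) != 12:
            raise DesignError(f"character table must have 12 rows, got {len(f)}")
        if f["character_id"].duplicated().any():
            raise DesignError("duplicate character ids")
        counts = f["category"].value_counts()
        for cat in CATEGORIES:
            if counts.get(cat, 0) != 3:
                raise DesignError(f"category {cat!r} must have 3 characters")
        for cat in CATEGORIES:
            sets = sorted(f.loc[f["category"] == cat, "radical_set"])
            if sets != [1, 2, 3]:
                raise DesignError(
                    f"radical sets within {cat!r} must be a permutation of (1,2,3)"
                )
        if (f["frequency"] <= 0).any():
            raise DesignError("frequencies must be positive")
        for col in ("rating_orth", "rating_phon", "rating_sem"):
            if col in f.columns and f[col].notna().any():
                vals = f[col].dropna()
                if ((vals < 1) | (vals > 7)).any():
                    raise DesignError(f"{col} must lie in [1, 7]")

    @property
    def character_ids(self) -> list[str]:
        return list(self.frame["character_id"])

    @property
    def inconsistent_ids(self) -> list[str]:
        mask = self.frame["category"] != "CC"
        return list(self.frame.loc[mask, "character_id"])

    def ids_of(self, category: str) -> list[str]:
        return list(
            self.frame.loc[self.frame["category"] == category, "character_id"]
        )

    def category_of(self, character_id: str) -> str:
        row = self.frame.loc[self.frame["character_id"] == character_id]
        if row.empty:
            raise DesignError(f"unknown character {character_id!r}")
        return str(row["category"].iloc[0])

    def frequency_of(self, character_id: str) -> float:
        row = self.frame.loc[self.frame["character_id"] == character_id]
        if row.empty:
            raise DesignError(f"unknown character {character_id!r}")
        return float(row["frequency"].iloc[0])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CharacterTable":
        return cls(pd.read_csv(path, sep="\t"))


def make_default_character_table(
    seed: int,
    freq_range: tuple[float, float] = (1.0, 300.0),
) -> CharacterTable:
    """Build a synthetic 12-character inventory.

    Character ids encode category and radical set (e.g. ``IPh_r2``).
    Corpus frequencies are drawn log-uniformly from ``freq_range``
    (occurrences per million).  Consistency ratings on the 1-7 scale are
    high (~6) on every dimension a character is consistent on and low (~2)
    on the dimension its category is inconsistent on, with seeded jitter.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = freq_range
    if not (0 < lo < hi):
        raise DesignError("freq_range must satisfy 0 < lo < hi")
    rows = []
    for cat in CATEGORIES:
        for rad in RADICAL_SETS:
            freq = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            ratings = {}
            for dim, col in (
                ("IOr", "rating_orth"),
                ("IPh", "rating_phon"),
                ("ISe", "rating_sem"),
            ):
                base = 2.0 if cat == dim else 6.0
                ratings[col] = float(np.clip(base + rng.normal(0, 0.5), 1.0, 7.0))
            rows.append(
                {
                    "character_id": f"{cat}_r{rad}",
                    "category": cat,
                    "radical_set": rad,
                    "frequency": freq,
                    **ratings,
                }
            )
    return CharacterTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# trials and sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    index: int
    character_id: str
    category: str
    role: str
    is_target: bool
    block: str
    onset_ms: float


@dataclass(frozen=True)
class TrialSequence:
    """An ordered block of trials with stimulus onsets.

    Onsets accumulate a 200 ms stimulus followed by a uniform 500-600 ms
    blank, both seeded, so a sequence fully determines a presentation
    timeline.
    """

    block: str
    trials: tuple[Trial, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def roles(self) -> list[str]:
        return [t.role for t in self.trials]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "character_id": [t.character_id for t in self.trials],
                "category": [t.category for t in self.trials],
                "role": [t.role for t in self.trials],
                "is_target": [t.is_target for t in self.trials],
                "block": [t.block for t in self.trials],
                "onset_ms": [t.onset_ms for t in self.trials],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, seed: int = -1) -> "TrialSequence":
        f = pd.read_csv(path, sep="\t")
        trials = tuple(
            Trial(
                index=int(r["index"]),
                character_id=str(r["character_id"]),
                category=str(r["category"]),
                role=str(r["role"]),
                is_target=bool(r["is_target"]),
                block=str(r["block"]),
                onset_ms=float(r["onset_ms"]),
            )
            for _, r in f.iterrows()
        )
        block = trials[0].block if trials else ""
        return cls(block=block, trials=trials, seed=seed)


def _onsets(n: int, rng: np.random.Generator, start_ms: float = 0.0) -> np.ndarray:
    isi = rng.uniform(*ISI_RANGE_MS, size=n)
    on = np.empty(n)
    t = start_ms
    for i in range(n):
        on[i] = t
        t += STIMULUS_MS + isi[i]
    return on


def _nonadjacent_positions(
    n: int, k: int, rng: np.random.Generator, start: int = 0
) -> np.ndarray:
    """Uniformly sample k mutually non-adjacent positions from start..n-1.

    Uses the standard bijection: k non-adjacent choices out of m slots
    correspond to k unordered choices out of m - k + 1.
    """
    m = n - start
    if k > (m + 1) // 2:
        raise DesignError(
            f"cannot place {k} non-adjacent items in {m} slots"
        )
    base = np.sort(rng.choice(m - k + 1, size=k, replace=False))
    return base + np.arange(k) + start


def _balanced_assignment(
    ids: list[str], n: int, rng: np.random.Generator
) -> list[str]:
    """n items over ids, counts as equal as possible, order randomised.

    The multiset of assigned ids is seed-invariant (equal split first,
    deterministic remainder), only the order depends on the rng.
    """
    per, rem = divmod(n, len(ids))
    pool = [cid for cid in ids for _ in range(per)] + list(ids[:rem])
    return list(rng.permutation(pool))


def _assign_targets(
    roles: list[str],
    n_targets: int,
    rng: np.random.Generator,
    eligible_roles: set[str],
    max_retries: int = 200,
) -> np.ndarray:
    """Pick target positions whose predecessor is an eligible non-target.

    A target at i requires roles[i-1] in eligible_roles and i-1 not itself
    a target; targets themselves must sit on eligible roles (standards in
    oddball blocks, anything in the equal-probability block).  Rejection
    sampling over shuffled eligible positions with a retry cap.
    """
    n = len(roles)
    eligible = [
        i
        for i in range(1, n)
        if roles[i] in eligible_roles and roles[i - 1] in eligible_roles
    ]
    if n_targets == 0:
        return np.zeros(n, dtype=bool)
    for _ in range(max_retries):
        order = rng.permutation(len(eligible))
        chosen: set[int] = set()
        for j in order:
            i = eligible[j]
            if (i - 1) in chosen or (i + 1) in chosen:
                continue
            chosen.add(i)
            if len(chosen) == n_targets:
                mask = np.zeros(n, dtype=bool)
                mask[list(chosen)] = True
                return mask
    raise DesignError(
        f"could not place {n_targets} targets under the predecessor rule"
    )


def generate_oddball_sequence(
    table: CharacterTable,
    deviant_category: str,
    n_trials: int = 420,
    p_deviant: float = 0.25,
    p_target: float = 0.1,
    seed: int = 0,
) -> TrialSequence:
    """One oddball block: frequent CC standards, rare same-category deviants.

    Counts are enforced exactly (e.g. 315 standards / 105 deviants at the
    defaults, deviants split equally over the category's three characters);
    deviant positions are drawn uniformly over all non-adjacent placements.
    Colour-change targets (``round(p_target * n_trials)`` of them) are
    placed on standard trials immediately preceded by a non-target standard.
    """
    if deviant_category not in INCONSISTENT_CATEGORIES:
        raise DesignError(f"deviant_category must be one of {INCONSISTENT_CATEGORIES}")
    n_dev_f = n_trials * p_deviant
    n_dev = int(round(n_dev_f))
    if abs(n_dev_f - n_dev) > 1e-9:
        raise DesignError("n_trials * p_deviant must be an integer")
    if n_dev % 3 != 0:
        raise DesignError("deviant count must be divisible by 3")
    if n_dev > (n_trials + 1) // 2:
        raise DesignError(
            f"{n_dev} deviants in {n_trials} trials cannot avoid adjacency"
        )
    rng = np.random.default_rng(seed)
    n_std = n_trials - n_dev

    roles = np.array([ROLE_STANDARD] * n_trials, dtype=object)
    dev_pos = _nonadjacent_positions(n_trials, n_dev, rng)
    roles[dev_pos] = ROLE_DEVIANT

    dev_ids = _balanced_assignment(table.ids_of(deviant_category), n_dev, rng)
    std_ids = _balanced_assignment(table.ids_of("CC"), n_std, rng)
    chars = np.empty(n_trials, dtype=object)
    chars[dev_pos] = dev_ids
    chars[roles == ROLE_STANDARD] = std_ids

    n_targets = int(round(p_target * n_trials))
    targets = _assign_targets(list(roles), n_targets, rng, {ROLE_STANDARD})

    onsets = _onsets(n_trials, rng)
    block = f"oddball_{deviant_category}"
    trials = tuple(
        Trial(
            index=i,
            character_id=str(chars[i]),
            category=table.category_of(str(chars[i])),
            role=str(roles[i]),
            is_target=bool(targets[i]),
            block=block,
            onset_ms=float(onsets[i]),
        )
        for i in range(n_trials)
    )
    return TrialSequence(block=block, trials=trials, seed=seed)


def generate_equal_probability_sequence(
    table: CharacterTable,
    n_trials: int = 480,
    p_target: float = 0.1,
    seed: int = 0,
) -> TrialSequence:
    """The equal-probability block: all 12 characters, fully randomised.

    Exactly ``n_trials / 12`` presentations per character (so each category
    has probability 0.25).  Targets may fall on any trial whose predecessor
    is a non-target trial.
    """
    if n_trials % 12 != 0:
        raise DesignError("n_trials must be divisible by 12")
    rng = np.random.default_rng(seed)
    chars = _balanced_assignment(table.character_ids, n_trials, rng)
    n_targets = int(round(p_target * n_trials))
    targets = _assign_targets(
        [ROLE_EQUIPROBABLE] * n_trials, n_targets, rng, {ROLE_EQUIPROBABLE}
    )
    onsets = _onsets(n_trials, rng)
    trials = tuple(
        Trial(
            index=i,
            character_id=chars[i],
            category=table.category_of(chars[i]),
            role=ROLE_EQUIPROBABLE,
            is_target=bool(targets[i]),
            block=BLOCK_EQUAL,
            onset_ms=float(onsets[i]),
        )
        for i in range(n_trials)
    )
    return TrialSequence(block=BLOCK_EQUAL, trials=trials, seed=seed)


def generate_session(
    table: CharacterTable,
    n_trials_oddball: int = 420,
    n_trials_equal: int = 480,
    p_deviant: float = 0.25,
    p_target: float = 0.1,
    seed: int = 0,
) -> list[TrialSequence]:
    """Full session: equal-probability block first, oddball order shuffled."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    seqs = [
        generate_equal_probability_sequence(
            table, n_trials=n_trials_equal, p_target=p_target, seed=int(seeds[0])
        )
    ]
    order = rng.permutation(len(INCONSISTENT_CATEGORIES))
    for k, idx in enumerate(order):
        seqs.append(
            generate_oddball_sequence(
                table,
                INCONSISTENT_CATEGORIES[idx],
                n_trials=n_trials_oddball,
                p_deviant=p_deviant,
                p_target=p_target,
                seed=int(seeds[k + 1]),
            )
        )
    return seqs


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_sequence(
    seq: TrialSequence,
    p_deviant: float = 0.25,
    p_target: float = 0.1,
) -> list[str]:
    """Check every design invariant; return human-readable violations.

    An empty list means the sequence is valid.
    """
    v: list[str] = []
    n = len(seq)
    roles = seq.roles
    is_odd = seq.block.startswith("oddball_")

    if is_odd:
        n_dev = sum(r == ROLE_DEVIANT for r in roles)
        n_std = sum(r == ROLE_STANDARD for r in roles)
        want_dev = int(round(n * p_deviant))
        if n_dev != want_dev:
            v.append(f"expected {want_dev} deviants, found {n_dev}")
        if n_std + n_dev != n:
            v.append("oddball block contains non-standard/deviant roles")
        dev_cat = seq.block.split("_", 1)[1]
        dev_chars: dict[str, int] = {}
        for t in seq.trials:
            if t.role == ROLE_DEVIANT:
                if t.category != dev_cat:
                    v.append(
                        f"trial {t.index}: deviant category {t.category} != block {dev_cat}"
                    )
                dev_chars[t.character_id] = dev_chars.get(t.character_id, 0) + 1
            elif t.role == ROLE_STANDARD:
                if t.category != "CC":
                    v.append(f"trial {t.index}: standard is not a CC character")
            else:
                v.append(f"trial {t.index}: role {t.role} invalid in oddball block")
        if dev_chars and len(set(dev_chars.values())) > 1:
            v.append(f"deviant presentations not split equally: {dev_chars}")
        for i in range(1, n):
            if roles[i] == ROLE_DEVIANT and roles[i - 1] == ROLE_DEVIANT:
                v.append(f"adjacent deviants at trials {i - 1},{i}")
    else:
        counts: dict[str, int] = {}
        for t in seq.trials:
            if t.role != ROLE_EQUIPROBABLE:
                v.append(f"trial {t.index}: role {t.role} invalid in equal block")
            counts[t.character_id] = counts.get(t.character_id, 0) + 1
        if len(counts) != 12:
            v.append(f"expected 12 distinct characters, found {len(counts)}")
        if len(set(counts.values())) > 1:
            v.append(f"unequal character counts: {counts}")

    n_targets = sum(t.is_target for t in seq.trials)
    want_targets = int(round(p_target * n))
    if n_targets != want_targets:
        v.append(f"expected {want_targets} targets, found {n_targets}")
    for i, t in enumerate(seq.trials):
        if not t.is_target:
            continue
        if i == 0:
            v.append("target at trial 0 has no preceding trial")
            continue
        prev = seq.trials[i - 1]
        if prev.is_target:
            v.append(f"target at trial {i} preceded by a target")
        if is_odd and prev.role != ROLE_STANDARD:
            v.append(f"target at trial {i} not preceded by a standard")
        if is_odd and t.role != ROLE_STANDARD:
            v.append(f"target at trial {i} is not a standard trial")

    onsets = [t.onset_ms for t in seq.trials]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        v.append("onsets not strictly increasing")
    return v
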