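"""Scoring of the colour-change detection task.

Participants ignore character identity and press a button whenever a
character turns red.  A press within 700 ms of a colour change counts as a
hit; any other press is a false alarm.  The false-alarm denominator is the
number of non-target trials (every non-target trial offers a press
opportunity); both denominators are reported alongside the rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import TrialSequence


class BehaviorError(ValueError):
    pass


def score_responses(
    log: pd.DataFrame, hit_window_ms: float = 700.0
) -> dict[str, float]:
    """Hit rate, false-alarm rate and mean hit latency from a response log.

    ``log`` needs columns ``is_target`` (bool) and ``response_time_ms``
    (press latency from stimulus/colour-change onset; NaN when no press).
    """
    for col in ("is_target", "response_time_ms"):
        if col not in log.columns:
            raise BehaviorError(f"response log missing column {col!r}")
    rt = np.asarray(log["response_time_ms"], dtype=float)
    if np.any(rt[~np.isnan(rt)] <= 0):
        raise BehaviorError("response times must be positive")
    is_target = np.asarray(log["is_target"], dtype=bool)
    n_targets = int(is_target.sum())
    if n_targets == 0:
        raise BehaviorError("response log contains no target trials")
    pressed = ~np.isnan(rt)
    hits = is_target & pressed & (rt < hit_window_ms)
    false_alarms = pressed & ~hits
    n_nontargets = int((~is_target).sum())
    return {
        "hit_rate": float(hits.sum() / n_targets),
        "false_alarm_rate": float(false_alarms.sum() / max(n_nontargets, 1)),
        "mean_latency_ms": float(rt[hits].mean()) if hits.any() else float("nan"),
        "n_targets": n_targets,
        "n_nontargets": n_nontargets,
    }


def simulate_response_log(
    seq: TrialSequence,
    hit_prob: float = 0.99,
    fa_prob: float = 0.005,
    latency_mean_ms: float = 390.0,
    latency_sd_ms: float = 35.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic button-press log for one block.

    Targets are answered with probability ``hit_prob`` at a truncated-normal
    latency; non-targets attract a stray press with probability ``fa_prob``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in seq.trials:
        rt = np.nan
        if t.is_target:
            if rng.random() < hit_prob:
                rt = max(50.0, float(rng.normal(latency_mean_ms, latency_sd_ms)))
        elif rng.random() < fa_prob:
            rt = max(50.0, float(rng.normal(latency_mean_ms, latency_sd_ms)))
        rows.append(
            {"index": t.index, "is_target": t.is_target, "response_time_ms": rt}
        )
    return pd.DataFrame(rows)
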