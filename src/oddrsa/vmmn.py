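"""Visual mismatch negativity with the equal-probability control.

The differential waveform for an inconsistent category is the deviant ERP
minus the equiprobable ERP over the *same three characters*, averaged over
a left (P7, PO7, O1) or right (P8, PO8, O2) posterior occipital-temporal
ROI and cropped to 0-600 ms.  Because deviant and equiprobable stimuli are
physically identical and equally probable within their blocks, a residual
negativity is a "genuine" deviance response free of refractoriness
confounds; the classical deviant-minus-standard contrast is also available
for comparison.

Group inference is a two-tailed cluster-mass sign-permutation test: clusters
are runs of two or more neighbouring time points whose one-sample t values
exceed the pointwise two-tailed threshold (per-tail p = 0.025) with a common
sign, scored by the signed sum of t values; the null is the per-permutation
maximum absolute mass.  Each cluster is reported with a Cohen's d computed
from the subject means over the cluster's rectangular time extent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import EpochsArray
from .rsa import Cluster, ClusterResult, RSAError, _one_sample_t, _perm_t
from .simulate import ROI_LEFT, ROI_RIGHT

ROI_CHANNELS = {"left": ROI_LEFT, "right": ROI_RIGHT}
ANALYSIS_WINDOW_MS = (0.0, 600.0)


class VMMNError(ValueError):
    pass


def erp(
    ep: EpochsArray,
    role: str | None = None,
    category: str | None = None,
    block: str | None = None,
    include_targets: bool = False,
) -> np.ndarray:
    """Channels x time mean waveform over the retained epochs of a selection."""
    sel = ep.select(
        role=role, category=category, block=block, include_targets=include_targets
    )
    if sel.data.shape[0] == 0:
        raise VMMNError(
            f"no retained epochs match role={role!r} category={category!r}"
        )
    return sel.data.mean(axis=0)


@dataclass(frozen=True)
class DifferentialWaveform:
    subject_id: str
    deviant_category: str
    roi: str
    times_ms: np.ndarray
    values: np.ndarray  # μV, deviant minus control
    contrast: str = "deviant_minus_equiprobable"

    def __post_init__(self) -> None:
        if len(self.times_ms) != len(self.values):
            raise VMMNError("times and values must align")
        if not np.all(np.isfinite(self.values)):
            raise VMMNError("waveform contains non-finite values")


def differential_waveform(
    ep: EpochsArray,
    deviant_category: str | None,
    roi: str,
    contrast: str = "deviant_minus_equiprobable",
    window_ms: tuple[float, float] = ANALYSIS_WINDOW_MS,
) -> DifferentialWaveform:
    """ROI-averaged deviant-minus-control waveform for one subject.

    The control is the equiprobable ERP of the same characters (default) or
    the standard ERP from the category's own oddball block
    (``contrast='deviant_minus_standard'``).  ``deviant_category=None``
    pools the deviants of all three inconsistent categories against the
    equiprobable ERP of all nine inconsistent characters.  The sign
    convention is deviant minus control, so a deviance response appears as
    a negativity.
    """
    if roi not in ROI_CHANNELS:
        raise VMMNError(f"roi must be one of {sorted(ROI_CHANNELS)}")
    missing = [c for c in ROI_CHANNELS[roi] if c not in ep.channel_names]
    if missing:
        raise VMMNError(f"ROI channels missing from epochs: {missing}")
    dev = erp(ep, role="deviant", category=deviant_category)
    if contrast == "deviant_minus_equiprobable":
        if deviant_category is None:
            sel = ep.select(role="equiprobable")
            keep = np.asarray(sel.meta["category"] != "CC")
            if not keep.any():
                raise VMMNError("no inconsistent equiprobable epochs")
            ctl = sel.data[keep].mean(axis=0)
        else:
            ctl = erp(ep, role="equiprobable", category=deviant_category)
    elif contrast == "deviant_minus_standard":
        if deviant_category is None:
            ctl = erp(ep, role="standard")
        else:
            ctl = erp(ep, role="standard", block=f"oddball_{deviant_category}")
    else:
        raise VMMNError(f"unknown contrast {contrast!r}")
    idx = [ep.channel_names.index(c) for c in ROI_CHANNELS[roi]]
    diff = (dev - ctl)[idx].mean(axis=0)
    times = ep.times_ms
    keep = (times >= window_ms[0]) & (times <= window_ms[1])
    return DifferentialWaveform(
        subject_id=ep.subject_id,
        deviant_category=deviant_category or "all",
        roi=roi,
        times_ms=times[keep],
        values=diff[keep],
        contrast=contrast,
    )


def _masses_and_runs(
    t: np.ndarray, t_crit: float, min_run: int
) -> list[tuple[int, int, float]]:
    """Same-sign supra-threshold runs of length >= min_run with their mass."""
    out = []
    for sign in (1.0, -1.0):
        mask = sign * t > t_crit
        start = None
        for i in range(len(mask) + 1):
            inside = i < len(mask) and mask[i]
            if inside and start is None:
                start = i
            elif not inside and start is not None:
                if i - start >= min_run:
                    out.append((start, i - 1, float(t[start:i].sum())))
                start = None
    out.sort(key=lambda c: c[0])
    return out


def _null_max_mass(
    t_perm: np.ndarray, t_crit: float, min_run: int
) -> np.ndarray:
    """Per-permutation maximum absolute cluster mass, vectorised over rows."""
    n_perm, T = t_perm.shape
    best = np.zeros(n_perm)
    for sign in (1.0, -1.0):
        B = sign * t_perm > t_crit
        cur_mass = np.zeros(n_perm)
        cur_len = np.zeros(n_perm, dtype=np.int64)
        for j in range(T):
            b = B[:, j]
            cur_mass = np.where(b, cur_mass + t_perm[:, j], 0.0)
            cur_len = np.where(b, cur_len + 1, 0)
            ok = cur_len >= min_run
            best = np.where(ok, np.maximum(best, np.abs(cur_mass)), best)
    return best


def cluster_mass_permutation_test(
    diffs: np.ndarray,
    times_ms: np.ndarray | None = None,
    n_perm: int = 10000,
    cluster_threshold_p: float = 0.025,
    corrected_alpha: float = 0.05,
    min_run: int = 2,
    seed: int | None = None,
) -> ClusterResult:
    """Two-tailed cluster-mass sign-permutation test on subject waveforms.

    ``diffs`` is subjects x times (e.g. stacked differential waveforms).
    The cluster-forming threshold is the t quantile for a per-tail p of
    ``cluster_threshold_p``; clusters need >= ``min_run`` neighbouring
    points of common sign; the statistic is the signed sum of t values and
    the permutation null uses the maximum absolute mass.  Each cluster's
    effect size is Cohen's d of the subject-mean amplitude over the
    cluster's time window.
    """
    X = np.asarray(diffs, dtype=float)
    if X.ndim != 2:
        raise VMMNError("diffs must be subjects x times")
    n, T = X.shape
    if n < 2:
        raise VMMNError("need at least 2 subjects")
    if not np.all(np.isfinite(X)):
        raise VMMNError("diffs contain non-finite values")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value resolution")
    if times_ms is None:
        times_ms = np.arange(T, dtype=float)
    t_crit = float(stats.t.ppf(1.0 - cluster_threshold_p, df=n - 1))

    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    t_perm = _perm_t(X, signs)
    null_max = _null_max_mass(t_perm, t_crit, min_run)

    t_obs = _one_sample_t(X)
    clusters = []
    for start, stop, mass in _masses_and_runs(t_obs, t_crit, min_run):
        p = (1 + int((null_max >= abs(mass)).sum())) / (n_perm + 1)
        window_means = X[:, start : stop + 1].mean(axis=1)
        sd = window_means.std(ddof=1)
        d = float(window_means.mean() / sd) if sd > 0 else float("nan")
        clusters.append(
            Cluster(
                window_ms=(float(times_ms[start]), float(times_ms[stop])),
                start=start,
                stop=stop,
                stat=mass,
                p_value=p,
                significant=p < corrected_alpha,
                effect_size=d,
            )
        )
    return ClusterResult(
        clusters=tuple(clusters),
        n_perm=n_perm,
        seed=seed,
        threshold=t_crit,
        corrected_alpha=corrected_alpha,
        statistic="mass",
    )
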