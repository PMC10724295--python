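"""Partial Spearman RSA time courses and sign-permutation cluster inference.

For each subject, condition and model RDM the analysis computes a time
course of partial Spearman correlations between the lower-triangle vectors
of the neural RDM and the model RDM, partialling out control models: when
testing a sub-lexical (consistency) model the lexical frequency model is
controlled, and vice versa.  Group inference is a one-sided sign-permutation
test with maximum-cluster-size correction: each permutation flips whole
subject time courses, the cluster-forming threshold is the pointwise 95th
percentile of the permutation t distribution, and cluster p-values come
from the permutation distribution of maximum cluster size (with the
observed statistic included in the null — the add-one rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .rdm import RDM, RDMStack, vectorize_lower_triangle


class RSAError(ValueError):
    pass


# ---------------------------------------------------------------------------
# partial Spearman correlation
# ---------------------------------------------------------------------------

def partial_spearman(
    x: np.ndarray, y: np.ndarray, controls: list[np.ndarray] | None = None
) -> float:
    """Rank-based partial correlation of x and y given control vectors.

    All vectors are rank-transformed (average ranks for ties); the ranks of
    x and y are each regressed on the control ranks (with intercept) and the
    Pearson correlation of the residuals is returned.  With no controls this
    is the ordinary Spearman rho.  A constant x or y yields NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    controls = controls or []
    n = len(x)
    if len(y) != n or any(len(c) != n for c in controls):
        raise RSAError("all vectors must have the same length")
    if n < 4:
        raise RSAError("need at least 4 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    if controls:
        Z = np.column_stack([np.ones(n)] + [stats.rankdata(c) for c in controls])
        rx = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
        ry = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
        # a predictor fully explained by its controls carries no residual
        # variance: the partial correlation is zero by convention
        if np.allclose(rx, 0) or np.allclose(ry, 0):
            return 0.0
    else:
        rx = rx - rx.mean()
        ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


DEFAULT_CONTROL_SCHEME = {
    "orthographic": ("frequency",),
    "phonological": ("frequency",),
    "semantic": ("frequency",),
    "frequency": ("orthographic", "phonological", "semantic"),
    "radical_control": (),
}


def default_controls(model_name: str) -> tuple[str, ...]:
    """Control models partialled out when testing ``model_name``.

    Sub-lexical consistency models are controlled for lexical frequency and
    vice versa; the radical-control model is run as a standalone screen.
    An "all others" scheme can be passed explicitly to
    :func:`rsa_timecourse` instead.
    """
    return DEFAULT_CONTROL_SCHEME.get(model_name, ())


# ---------------------------------------------------------------------------
# time courses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RSATimecourse:
    subject_id: str
    condition: str
    model_name: str
    times_ms: np.ndarray
    partial_rho: np.ndarray
    controls: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.times_ms) != len(self.partial_rho):
            raise RSAError("times and values must align")


def rsa_timecourse(
    stack: RDMStack,
    model: RDM,
    control_models: list[RDM] | None = None,
    model_name: str | None = None,
    control_names: tuple[str, ...] = (),
) -> RSATimecourse:
    """Per-time-point partial Spearman between a neural stack and a model."""
    model = model.reorder(list(stack.labels)) if model.labels != stack.labels else model
    controls = []
    for cm in control_models or []:
        cm = cm.reorder(list(stack.labels)) if cm.labels != stack.labels else cm
        controls.append(vectorize_lower_triangle(cm))
    mv = vectorize_lower_triangle(model)
    neural = stack.vectors()
    rho = np.array([partial_spearman(nv, mv, controls) for nv in neural])
    return RSATimecourse(
        subject_id=stack.subject_id,
        condition=stack.condition,
        model_name=model_name or model.kind,
        times_ms=np.asarray(stack.times_ms, dtype=float),
        partial_rho=rho,
        controls=control_names,
    )


def condition_difference(
    tc_odd: RSATimecourse, tc_eq: RSATimecourse
) -> RSATimecourse:
    """Oddball-minus-equal-probability representation-strength difference."""
    if tc_odd.subject_id != tc_eq.subject_id or tc_odd.model_name != tc_eq.model_name:
        raise RSAError("time courses must share subject and model")
    if not np.array_equal(tc_odd.times_ms, tc_eq.times_ms):
        raise RSAError("time grids differ")
    return RSATimecourse(
        subject_id=tc_odd.subject_id,
        condition="oddball_minus_equal",
        model_name=tc_odd.model_name,
        times_ms=tc_odd.times_ms,
        partial_rho=tc_odd.partial_rho - tc_eq.partial_rho,
        controls=tc_odd.controls,
    )


# ---------------------------------------------------------------------------
# group inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cluster:
    window_ms: tuple[float, float]
    start: int  # inclusive time index
    stop: int  # inclusive time index
    stat: float  # size for RSA, signed mass for vMMN
    p_value: float
    significant: bool
    effect_size: float | None = None


@dataclass(frozen=True)
class ClusterResult:
    clusters: tuple[Cluster, ...]
    n_perm: int
    seed: int | None
    threshold: np.ndarray | float
    corrected_alpha: float
    statistic: str = "size"

    @property
    def significant_clusters(self) -> tuple[Cluster, ...]:
        return tuple(c for c in self.clusters if c.significant)


def _one_sample_t(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    m = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def _perm_t(X: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t statistics for all sign-flip permutations, vectorised.

    Sign flips leave each subject's squared values unchanged, so the
    permutation variance follows from the permuted mean alone.
    """
    n, _ = X.shape
    sumsq = (X**2).sum(axis=0)
    M = signs @ X / n
    var = (sumsq / n - M**2) * n / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = M / np.sqrt(var / n)
    return np.where(np.isfinite(t), t, 0.0)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (start, stop) inclusive index pairs."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask) - 1))
    return out


def _max_run_lengths(B: np.ndarray) -> np.ndarray:
    """Per-row maximum run length of True in a boolean matrix."""
    n_rows, n_cols = B.shape
    cur = np.zeros(n_rows, dtype=np.int64)
    best = np.zeros(n_rows, dtype=np.int64)
    for j in range(n_cols):
        cur = np.where(B[:, j], cur + 1, 0)
        best = np.maximum(best, cur)
    return best


def sign_permutation_cluster_test(
    timecourses: np.ndarray,
    times_ms: np.ndarray | None = None,
    n_perm: int = 10000,
    cluster_alpha: float = 0.05,
    corrected_alpha: float = 0.05,
    seed: int | None = None,
) -> ClusterResult:
    """One-sided maximum-cluster-size sign-permutation test.

    ``timecourses`` is subjects x times.  Each permutation flips every
    subject's whole time course by an independent random sign; the
    cluster-forming threshold at each time point is the (1 - cluster_alpha)
    quantile of that point's permutation t distribution; observed clusters
    are maximal supra-threshold runs scored by their size; the null is the
    per-permutation maximum cluster size.  p-values use the add-one rule, so
    p >= 1/(n_perm + 1) and results are reproducible bit-exactly given seed.
    """
    X = np.asarray(timecourses, dtype=float)
    if X.ndim != 2:
        raise RSAError("timecourses must be subjects x times")
    n, T = X.shape
    if n < 2:
        raise RSAError("need at least 2 subjects")
    if not np.all(np.isfinite(X)):
        raise RSAError("timecourses contain non-finite values")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value resolution")
    if times_ms is None:
        times_ms = np.arange(T, dtype=float)
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1

    t_perm = _perm_t(X, signs)
    threshold = np.quantile(t_perm, 1.0 - cluster_alpha, axis=0)
    t_obs = _one_sample_t(X)

    null_max = _max_run_lengths(t_perm > threshold[None, :])
    clusters = []
    for start, stop in _runs(t_obs > threshold):
        size = stop - start + 1
        p = (1 + int((null_max >= size).sum())) / (n_perm + 1)
        clusters.append(
            Cluster(
                window_ms=(float(times_ms[start]), float(times_ms[stop])),
                start=start,
                stop=stop,
                stat=float(size),
                p_value=p,
                significant=p < corrected_alpha,
            )
        )
    return ClusterResult(
        clusters=tuple(clusters),
        n_perm=n_perm,
        seed=seed,
        threshold=threshold,
        corrected_alpha=corrected_alpha,
        statistic="size",
    )
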