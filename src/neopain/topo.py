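"""Reference-independent topographic statistics and randomization tests.

Implements the momentary map descriptors used throughout the analysis —
global field power (GFP) and the dissimilarity index (DISS) — and the two
timepoint-wise randomization tests built on them:

* the topographic ANOVA (TANOVA): is the *shape* of the scalp field
  different between two groups at each latency? Observed statistic is the
  DISS between the two group-average maps; the null permutes subjects
  across groups.
* the topographic consistency test (TCT): do subjects within one group
  share a common topography at each latency? Observed statistic is the GFP
  of the grand average; the null shuffles channels within each subject,
  destroying across-subject spatial consistency while keeping every
  subject's amplitude distribution.

Both tests control multiple comparisons with a run-length rule: only
periods continuously significant for at least 5% of the tested window
survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "gfp",
    "diss",
    "spatial_correlation",
    "significant_runs",
    "RandomizationResult",
    "tanova",
    "tct",
]

#: Fraction of the tested window a run must span to survive filtering.
RUN_LENGTH_FRACTION = 0.05


def gfp(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Global field power: population SD of the potentials across channels.

    Reference-independent — adding a constant to every channel leaves it
    unchanged — and homogeneous: ``gfp(c*v) == c*gfp(v)`` for c > 0.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[axis] < 2:
        raise ValueError("GFP requires at least 2 channels")
    return values.std(axis=axis)


def _avg_ref(v: np.ndarray) -> np.ndarray:
    return v - v.mean(axis=-1, keepdims=True)


def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation between two maps after average-referencing."""
    u = _avg_ref(np.asarray(u, dtype=float))
    v = _avg_ref(np.asarray(v, dtype=float))
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("spatial correlation undefined for flat maps")
    return float(u @ v / (nu * nv))


def diss(u: np.ndarray, v: np.ndarray) -> float:
    """Dissimilarity index between two average-referenced maps.

    Root-mean-square difference of the GFP-normalized maps::

        DISS = sqrt( mean_i (u_i/GFP(u) - v_i/GFP(v))^2 )

    Ranges from 0 (identical shape) to 2 (polarity-reversed); invariant to
    positive rescaling of either map, and tied to the spatial correlation r
    by DISS² = 2(1 − r).
    """
    u = _avg_ref(np.asarray(u, dtype=float))
    v = _avg_ref(np.asarray(v, dtype=float))
    gu, gv = gfp(u), gfp(v)
    if gu == 0 or gv == 0:
        raise ValueError("DISS undefined for zero-GFP maps")
    return float(np.sqrt(np.mean((u / gu - v / gv) ** 2)))


def significant_runs(
    significant: np.ndarray, times_ms: np.ndarray, min_run_ms: float
) -> list[tuple[float, float]]:
    """Contiguous True runs spanning at least ``min_run_ms``.

    Returns half-open ``[start, end)`` intervals in ms; ``end`` is the time
    one sample step past the last significant sample. The filter only ever
    removes significance, never creates it.
    """
    significant = np.asarray(significant, dtype=bool)
    if significant.size != times_ms.size:
        raise ValueError("mask and time axis disagree")
    step = float(times_ms[1] - times_ms[0]) if times_ms.size > 1 else 0.0
    runs: list[tuple[float, float]] = []
    idx = np.flatnonzero(np.diff(np.r_[0, significant.astype(np.int8), 0]))
    for lo, hi in zip(idx[::2], idx[1::2]):
        length_ms = (hi - lo) * step
        if length_ms >= min_run_ms:
            runs.append((float(times_ms[lo]), float(times_ms[lo]) + length_ms))
    return runs


@dataclass
class RandomizationResult:
    """Outcome of a timepoint-wise randomization test."""

    times_ms: np.ndarray
    statistic: np.ndarray  # observed statistic per timepoint
    p: np.ndarray  # right-tailed permutation p per timepoint
    alpha: float
    min_run_ms: float
    segments: list[tuple[float, float]]  # surviving [start, end) ms
    n_iter: int
    null_percentile: np.ndarray | None = None  # 95th pct of null per timepoint
    meta: dict = field(default_factory=dict)

    @property
    def raw_significant(self) -> np.ndarray:
        """Per-timepoint significance before the run-length filter."""
        return self.p <= self.alpha

    def in_segment(self, t_ms: np.ndarray | float) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        out = np.zeros(t.shape, dtype=bool)
        for lo, hi in self.segments:
            out |= (t >= lo) & (t < hi)
        return out


def _perm_p(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Right-tailed p with the +1 correction; null shape (n_iter, n_t)."""
    exceed = (null >= observed[None, :]).sum(axis=0)
    return (1.0 + exceed) / (1.0 + null.shape[0])


def tanova(
    group_a,
    group_b,
    window_ms: tuple[float, float] | None = None,
    n_iter: int = 5000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    run_length_fraction: float = RUN_LENGTH_FRACTION,
) -> RandomizationResult:
    """Topographic ANOVA between two groups of epochs.

    At every timepoint the observed statistic is the DISS between the two
    group-average maps; the null redraws group membership (subject-label
    permutation preserving group sizes, sampled with replacement and
    including the identity). Timepoints where the observed DISS exceeds the
    (1−alpha) quantile of the null are significant; only runs at least
    ``run_length_fraction`` of the tested window long are kept.

    Timepoints where either group average is flat (zero GFP) get p = 1:
    the DISS is undefined there and is conservatively nonsignificant.
    """
    if group_a.montage != group_b.montage or group_a.fs_hz != group_b.fs_hz:
        raise ValueError("groups must share montage and sampling rate")
    if group_a.n_subjects < 2 or group_b.n_subjects < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)

    sl = group_a.window_slice(window_ms) if window_ms else slice(None)
    times = group_a.times_ms[sl]
    a = group_a.data[:, :, sl]
    b = group_b.data[:, :, sl]
    na, nb = a.shape[0], b.shape[0]
    pooled = np.concatenate([a, b], axis=0)  # (n, C, T)
    n, n_ch, n_t = pooled.shape

    def _diss_series(mean_a: np.ndarray, mean_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-timepoint DISS of two channels×time averages; flags flat maps."""
        ma = mean_a - mean_a.mean(axis=0, keepdims=True)
        mb = mean_b - mean_b.mean(axis=0, keepdims=True)
        ga, gb = ma.std(axis=0), mb.std(axis=0)
        flat = (ga == 0) | (gb == 0)
        ga = np.where(flat, 1.0, ga)
        gb = np.where(flat, 1.0, gb)
        d = np.sqrt(np.mean((ma / ga - mb / gb) ** 2, axis=0))
        return np.where(flat, 0.0, d), flat

    observed, flat = _diss_series(a.mean(axis=0), b.mean(axis=0))

    null = np.empty((n_iter, n_t))
    for i in range(n_iter):
        perm = rng.permutation(n)
        pa = pooled[perm[:na]].mean(axis=0)
        pb = pooled[perm[na:]].mean(axis=0)
        null[i], _ = _diss_series(pa, pb)

    p = _perm_p(observed, null)
    p[flat] = 1.0
    min_run_ms = run_length_fraction * (times[-1] - times[0] + 1000.0 / group_a.fs_hz)
    segs = significant_runs(p <= alpha, times, min_run_ms)
    return RandomizationResult(
        times_ms=times, statistic=observed, p=p, alpha=alpha,
        min_run_ms=float(min_run_ms), segments=segs, n_iter=n_iter,
        null_percentile=np.quantile(null, 1 - alpha, axis=0),
        meta={"test": "tanova", "n_a": na, "n_b": nb},
    )


def tct(
    group,
    window_ms: tuple[float, float] = (-200.0, 1000.0),
    n_iter: int = 5000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    run_length_fraction: float = RUN_LENGTH_FRACTION,
) -> RandomizationResult:
    """Topographic consistency test within one group.

    Observed statistic: GFP of the grand-average map at every timepoint.
    Null: each subject's channels are shuffled by an independent random
    permutation (drawn per subject per iteration, shared across the
    timepoints of that iteration), the shuffled subjects are averaged and
    the GFP of that average recomputed. Consistency at a timepoint means
    the observed GFP exceeds the (1−alpha) null quantile; the 5% run-length
    rule is applied over the tested window.
    """
    if group.n_subjects < 3:
        raise ValueError("TCT needs at least 3 subjects")
    if group.n_channels < 2:
        raise ValueError("TCT needs at least 2 channels")
    rng = np.random.default_rng(seed)

    sl = group.window_slice(window_ms)
    times = group.times_ms[sl]
    x = group.data[:, :, sl]  # (S, C, T)
    n_sub, n_ch, n_t = x.shape

    observed = x.mean(axis=0).std(axis=0)

    null = np.empty((n_iter, n_t))
    rows = np.arange(n_sub)[:, None]
    for i in range(n_iter):
        perms = np.argsort(rng.random((n_sub, n_ch)), axis=1)
        shuffled = x[rows, perms, :]
        null[i] = shuffled.mean(axis=0).std(axis=0)

    p = _perm_p(observed, null)
    min_run_ms = run_length_fraction * (times[-1] - times[0] + 1000.0 / group.fs_hz)
    segs = significant_runs(p <= alpha, times, min_run_ms)
    return RandomizationResult(
        times_ms=times, statistic=observed, p=p, alpha=alpha,
        min_run_ms=float(min_run_ms), segments=segs, n_iter=n_iter,
        null_percentile=np.quantile(null, 1 - alpha, axis=0),
        meta={"test": "tct", "n_subjects": n_sub},
    )
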