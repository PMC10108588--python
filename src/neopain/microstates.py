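"""ERP microstate identification, selection, back-fitting and events.

A microstate is a quasi-stable scalp topography dominating the evoked
response for a contiguous period. The workflow implemented here:

1. pool grand-average maps at topographically consistent timepoints (TCT)
   from all groups, GFP-normalized;
2. cluster them with an atomize-and-agglomerate hierarchical scheme
   (AAHC): start from singleton clusters and repeatedly dissolve the
   cluster contributing least explained variance, reassigning its members
   to the remaining templates;
3. choose the number of states k by split-half cross-validation over
   subjects (train half defines templates, held-out half scores explained
   variance; k stops growing when the marginal gain falls below a
   threshold);
4. back-fit the final templates to each group average: c_m(t) is the
   squared (positive-part, in the polarity-sensitive ERP convention)
   spatial correlation between the average map at t and template m;
5. declare a template active where c_m(t) beats the 95th percentile of a
   null built from baseline topographies, in runs of at least 5% of the
   postlance window; contiguous runs become events with onset, duration
   and power (∫ GFP·c dt, µV·ms), merging runs separated by less than the
   template's mean run duration pooled across occurrences and groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet
from .topo import RandomizationResult, significant_runs

__all__ = [
    "MicrostateSet",
    "ActivationSeries",
    "MicrostateEvent",
    "PooledMaps",
    "pool_consistent_maps",
    "baseline_map_pool",
    "cluster_microstates",
    "select_k",
    "fit_microstates",
    "explained_variance",
    "activation_significance",
    "extract_events",
    "extract_events_groups",
    "total_field_power",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MicrostateSet:
    """k template topographies (average-referenced, unit GFP)."""

    templates: np.ndarray  # (k, n_channels)
    ids: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        if self.templates.ndim != 2 or self.templates.shape[0] < 1:
            raise ValueError("templates must be (k, n_channels), k >= 1")
        if len(self.ids) != self.templates.shape[0]:
            raise ValueError("one id per template required")
        if np.abs(self.templates.mean(axis=1)).max() > 1e-9:
            raise ValueError("templates must be average-referenced")
        if np.abs(self.templates.std(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("templates must have unit GFP")
        k = self.templates.shape[0]
        if k > 1:
            u = self.templates / np.linalg.norm(self.templates, axis=1,
                                                keepdims=True)
            c = u @ u.T
            np.fill_diagonal(c, 0.0)
            if np.abs(c).max() >= 1.0 - 1e-12:
                raise ValueError("templates must be pairwise non-identical")

    @property
    def k(self) -> int:
        return self.templates.shape[0]


@dataclass
class ActivationSeries:
    """Back-fitting result for one group average."""

    times_ms: np.ndarray
    gfp: np.ndarray  # (T,) GFP of the group average, µV
    c: np.ndarray  # (k, T) explained-variance fraction per template
    template_ids: tuple[str, ...]
    polarity_sensitive: bool = True
    valid: np.ndarray | None = None  # False where GFP = 0 (c undefined)
    data_maps_unit: np.ndarray | None = None  # (T, C) unit-norm average maps
    masks: np.ndarray | None = None  # (k, T) significance masks
    thresholds: np.ndarray | None = None  # (T,) null 95th percentile
    p_raw: np.ndarray | None = None  # (k, T) per-timepoint null-exceedance p

    @property
    def dt_ms(self) -> float:
        return float(self.times_ms[1] - self.times_ms[0])


@dataclass
class MicrostateEvent:
    template_id: str
    occurrence: int
    onset_ms: float
    duration_ms: float
    power_uVms: float
    group: str | None = None


@dataclass
class PooledMaps:
    """Consistent-timepoint maps from all groups, plus per-subject data."""

    maps: np.ndarray  # (N, C) GFP-normalized grand-average maps
    gfp: np.ndarray  # (N,) GFP of each grand-average map, µV
    group_of: np.ndarray  # (N,) group label per map
    time_of: np.ndarray  # (N,) latency ms per map
    #: group -> (subjects, channels, n_consistent) raw per-subject data
    subject_data: dict[str, np.ndarray]
    #: group -> consistent latencies (ms)
    consistent_times: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def _normalize_maps(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-reference and scale maps (N, C) to unit GFP; returns GFPs."""
    m = maps - maps.mean(axis=1, keepdims=True)
    g = m.std(axis=1)
    keep = g > 0
    return np.where(keep[:, None], m / np.where(g == 0, 1, g)[:, None], m), g


def pool_consistent_maps(
    groups: dict[str, EpochSet],
    tct_results: dict[str, RandomizationResult],
) -> PooledMaps:
    """Grand-average maps at TCT-consistent timepoints, from every group.

    Consistency means membership in a run-length-filtered TCT segment.
    Raises if no group has any consistent timepoint.
    """
    maps, gfps, tags, times = [], [], [], []
    subject_data, cons_times = {}, {}
    for g, es in groups.items():
        res = tct_results[g]
        sl = es.window_slice((res.times_ms[0], res.times_ms[-1] + 1e-6))
        mask = res.in_segment(res.times_ms)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            subject_data[g] = np.empty((es.n_subjects, es.n_channels, 0))
            cons_times[g] = np.empty(0)
            continue
        data = es.data[:, :, sl][:, :, idx]  # (S, C, n_cons)
        avg = data.mean(axis=0).T  # (n_cons, C)
        norm, g_amp = _normalize_maps(avg)
        maps.append(norm)
        gfps.append(g_amp)
        tags.append(np.full(idx.size, g, dtype=object))
        times.append(res.times_ms[idx])
        subject_data[g] = data
        cons_times[g] = res.times_ms[idx]
    if not maps:
        raise ValueError("no consistent timepoints in any group")
    return PooledMaps(
        maps=np.concatenate(maps),
        gfp=np.concatenate(gfps),
        group_of=np.concatenate(tags),
        time_of=np.concatenate(times),
        subject_data=subject_data,
        consistent_times=cons_times,
    )


def baseline_map_pool(
    groups: dict[str, EpochSet] | EpochSet,
    window_ms: tuple[float, float] = (-500.0, 0.0),
) -> np.ndarray:
    """All per-subject, per-timepoint baseline maps, shape (P, C).

    The prestimulus topographies of every subject form the random-map pool
    for the activation null.
    """
    if isinstance(groups, EpochSet):
        groups = {"all": groups}
    pool = []
    for es in groups.values():
        sl = es.window_slice(window_ms)
        x = es.data[:, :, sl]  # (S, C, T)
        pool.append(np.moveaxis(x, 1, 2).reshape(-1, es.n_channels))
    return np.concatenate(pool)


# ---------------------------------------------------------------------------
# AAHC clustering
# ---------------------------------------------------------------------------

def _unit(maps: np.ndarray) -> np.ndarray:
    m = maps - maps.mean(axis=1, keepdims=True)
    n = np.linalg.norm(m, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return m / n


def _cluster_template(members: np.ndarray, polarity_sensitive: bool) -> np.ndarray:
    """Orientation-consistent mean of member maps, unit L2 norm."""
    if polarity_sensitive or members.shape[0] == 1:
        t = members.mean(axis=0)
    else:
        # first principal orientation: top right-singular vector
        _, _, vt = np.linalg.svd(members, full_matrices=False)
        t = vt[0]
        # orient with the majority of members
        if np.sign(members @ t).sum() < 0:
            t = -t
    n = np.linalg.norm(t)
    if n == 0:  # perfectly cancelling members; fall back to first member
        t = members[0]
        n = np.linalg.norm(t)
    return t / n


def _aahc(
    maps: np.ndarray,
    k_min: int,
    polarity_sensitive: bool = True,
    record: set[int] | None = None,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Atomize-and-agglomerate down to ``k_min`` clusters.

    Returns {k: (templates (k, C) unit-norm, labels (N,))} for every k in
    ``record`` (plus k_min). Deterministic: ties resolved by lowest index.
    """
    x = _unit(np.asarray(maps, dtype=float))  # (N, C)
    n = x.shape[0]
    record = set(record or ()) | {k_min}

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    tmpl: dict[int, np.ndarray] = {i: x[i] for i in range(n)}
    # contribution of each cluster to the explained variance
    contrib: dict[int, float] = {i: 1.0 for i in range(n)}

    def _corr(vecs: np.ndarray, t: np.ndarray) -> np.ndarray:
        return vecs @ t

    def _update(cid: int) -> None:
        mem = x[members[cid]]
        tmpl[cid] = _cluster_template(mem, polarity_sensitive)
        c = _corr(mem, tmpl[cid])
        contrib[cid] = float((c**2).sum())

    snapshots: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def _snapshot(k: int) -> None:
        cids = sorted(members)
        lab = np.empty(n, dtype=int)
        for j, cid in enumerate(cids):
            lab[members[cid]] = j
        snapshots[k] = (np.array([tmpl[c] for c in cids]), lab)

    if n in record:
        _snapshot(n)
    while len(members) > k_min:
        worst = min(sorted(members), key=lambda c: (contrib[c], c))
        orphan_idx = members.pop(worst)
        tmpl.pop(worst)
        contrib.pop(worst)
        cids = sorted(members)
        t_mat = np.array([tmpl[c] for c in cids])  # (k, C)
        corr = x[orphan_idx] @ t_mat.T  # (n_orphans, k)
        score = corr if polarity_sensitive else np.abs(corr)
        best = np.argmax(score, axis=1)
        touched = set()
        for i, b in zip(orphan_idx, best):
            members[cids[b]].append(i)
            touched.add(cids[b])
        for cid in touched:
            _update(cid)
        if len(members) in record:
            _snapshot(len(members))
    return snapshots


def cluster_microstates(
    maps: np.ndarray,
    k: int,
    polarity_sensitive: bool = True,
    ids: tuple[str, ...] | None = None,
    provenance: dict | None = None,
) -> MicrostateSet:
    """AAHC clustering of GFP-normalized maps into ``k`` templates.

    Distance is 1 − spatial correlation (polarity-sensitive by default,
    the ERP convention). Templates are ordered by the mean latency rank of
    their members so state labels follow the evoked sequence. The
    procedure is fully deterministic for a given map set.
    """
    maps = np.asarray(maps, dtype=float)
    if k > maps.shape[0]:
        raise ValueError("k exceeds the number of maps")
    templates, labels = _aahc(maps, k, polarity_sensitive)[k]
    order = np.argsort([np.nonzero(labels == j)[0].mean() for j in range(k)])
    templates = templates[order]
    t = templates - templates.mean(axis=1, keepdims=True)
    t /= t.std(axis=1, keepdims=True)
    ids = ids or tuple(f"MS{i + 1}" for i in range(k))
    prov = {"method": "aahc", "polarity_sensitive": polarity_sensitive,
            "n_maps": maps.shape[0], **(provenance or {})}
    return MicrostateSet(templates=t, ids=ids, provenance=prov)


# ---------------------------------------------------------------------------
# k selection by split-half cross-validation
# ---------------------------------------------------------------------------

def _holdout_ev(test_maps: np.ndarray, test_gfp: np.ndarray,
                templates: np.ndarray, polarity_sensitive: bool) -> float:
    """Σ_t (GFP_t · best corr)² / Σ_t GFP_t² on held-out maps."""
    u = _unit(test_maps)
    corr = u @ templates.T
    best = corr.max(axis=1) if polarity_sensitive else np.abs(corr).max(axis=1)
    best = np.clip(best, 0.0, None)
    denom = (test_gfp**2).sum()
    return float(((test_gfp * best) ** 2).sum() / denom) if denom > 0 else 0.0


def select_k(
    pooled: PooledMaps,
    k_range: tuple[int, int] = (2, 12),
    n_iter: int = 100,
    split: float = 0.5,
    seed: int | np.random.Generator | None = None,
    gain_threshold: float = 0.01,
    polarity_sensitive: bool = True,
) -> tuple[int, dict]:
    """Choose the number of microstates by subject-level split-half CV.

    Each iteration draws a random ``split`` fraction of subjects (within
    every group) to form training grand averages at the consistent
    timepoints, clusters them for every k in ``k_range`` (one AAHC descent
    yields the whole curve), and scores the explained variance on the
    held-out subjects' grand averages.

    Because the best-of-k correlation grows with k even on structureless
    maps (an order-statistics effect), each iteration also scores the same
    templates against channel-shuffled copies of the held-out maps; this
    chance curve is subtracted before applying the elbow rule. k* is the
    largest k whose marginal chance-corrected CV gain over k−1 still
    reaches ``gain_threshold`` (default one percentage point); a
    structureless cohort therefore yields k_min.

    Returns (k*, curve) where curve maps "k", "mean_ev" (raw),
    "mean_ev_corrected" and the per-iteration arrays.
    """
    k_lo, k_hi = k_range
    n_sub = {g: d.shape[0] for g, d in pooled.subject_data.items()}
    if min(n_sub.values()) < 4:
        raise ValueError("split-half CV needs at least 4 subjects per group")
    rng = np.random.default_rng(seed)
    ks = np.arange(k_lo, k_hi + 1)

    ev = np.full((n_iter, ks.size), np.nan)
    ev_chance = np.full((n_iter, ks.size), np.nan)
    for it in range(n_iter):
        train_maps, train_g, test_maps, test_g = [], [], [], []
        for g, data in pooled.subject_data.items():
            if data.shape[2] == 0:
                continue
            s = data.shape[0]
            perm = rng.permutation(s)
            n_train = max(2, int(round(split * s)))
            tr, te = perm[:n_train], perm[n_train:]
            if te.size == 0:
                tr, te = perm[:-1], perm[-1:]
            for sel, buf_m, buf_g in ((tr, train_maps, train_g),
                                      (te, test_maps, test_g)):
                avg = data[sel].mean(axis=0).T  # (n_cons, C)
                norm, gamp = _normalize_maps(avg)
                buf_m.append(norm)
                buf_g.append(gamp)
        xtr = np.concatenate(train_maps)
        xte = np.concatenate(test_maps)
        gte = np.concatenate(test_g)
        if xtr.shape[0] < k_hi:
            raise ValueError("k_range exceeds available training maps")
        snaps = _aahc(xtr, k_lo, polarity_sensitive, record=set(ks.tolist()))
        # channel-shuffled copies of the held-out maps estimate the
        # chance level of the best-of-k correlation
        shuf = np.array([m[rng.permutation(m.size)] for m in xte])
        for j, k in enumerate(ks):
            templates = snaps[k][0]
            ev[it, j] = _holdout_ev(xte, gte, templates, polarity_sensitive)
            ev_chance[it, j] = _holdout_ev(shuf, gte, templates,
                                           polarity_sensitive)

    mean_ev = ev.mean(axis=0)
    corrected = mean_ev - ev_chance.mean(axis=0)
    gains = np.diff(corrected)
    below = np.flatnonzero(gains < gain_threshold)
    if below.size == 0:
        k_star = int(ks[-1])
    else:
        k_star = int(ks[below[0]])  # last k before the first sub-threshold gain
    curve = {"k": ks, "mean_ev": mean_ev, "mean_ev_corrected": corrected,
             "ev": ev, "ev_chance": ev_chance,
             "gain_threshold": gain_threshold}
    return k_star, curve


# ---------------------------------------------------------------------------
# back-fitting and significance
# ---------------------------------------------------------------------------

def fit_microstates(
    average: np.ndarray | EpochSet,
    mset: MicrostateSet,
    times_ms: np.ndarray | None = None,
    polarity_sensitive: bool = True,
) -> ActivationSeries:
    """Project a group-average (channels × time) onto the templates.

    c_m(t) is the squared spatial correlation between the average map at t
    and template m; in the polarity-sensitive convention only positively
    oriented matches count (negative correlations explain nothing).
    Zero-GFP timepoints are masked as invalid.
    """
    if isinstance(average, EpochSet):
        times_ms = average.times_ms
        average = average.grand_average()
    if times_ms is None:
        raise ValueError("times_ms required with a bare array")
    avg = np.asarray(average, dtype=float)  # (C, T)
    if avg.shape[0] != mset.templates.shape[1]:
        raise ValueError("montage mismatch between average and templates")
    maps = avg.T - avg.T.mean(axis=1, keepdims=True)
    g = maps.std(axis=1)
    valid = g > 0
    u = maps / np.where(valid, np.linalg.norm(maps, axis=1),
                        1.0)[:, None]
    t_unit = mset.templates / np.linalg.norm(mset.templates, axis=1,
                                             keepdims=True)
    corr = u @ t_unit.T  # (T, k)
    if polarity_sensitive:
        c = np.clip(corr, 0.0, None) ** 2
    else:
        c = corr**2
    c[~valid] = np.nan
    return ActivationSeries(
        times_ms=np.asarray(times_ms, dtype=float), gfp=g, c=c.T,
        template_ids=mset.ids, polarity_sensitive=polarity_sensitive,
        valid=valid, data_maps_unit=u,
    )


def explained_variance(
    series: ActivationSeries, window_ms: tuple[float, float] | None = None
) -> float:
    """GFP²-weighted fraction of the signal explained by the best template.

    Σ_t GFP_t² · max_m c_m(t) / Σ_t GFP_t², over ``window_ms`` (whole
    series if omitted). Reported in the analysis as "% of the cortical
    signal" after multiplying by 100.
    """
    t = series.times_ms
    sel = np.ones(t.size, dtype=bool)
    if window_ms is not None:
        sel = (t >= window_ms[0]) & (t < window_ms[1])
    sel &= series.valid if series.valid is not None else True
    if not sel.any():
        return 0.0
    best = np.nanmax(series.c[:, sel], axis=0)
    w = series.gfp[sel] ** 2
    return float((w * best).sum() / w.sum())


def activation_significance(
    series: ActivationSeries,
    baseline_pool: np.ndarray,
    alpha: float = 0.05,
    window_ms: tuple[float, float] = (0.0, 1000.0),
    min_run_ms: float | None = None,
    n_iter: int = 5000,
    seed: int | np.random.Generator | None = None,
) -> ActivationSeries:
    """Mask timepoints where a template beats the baseline-topography null.

    The null at each timepoint is the set of c-values obtained by fitting
    ``n_iter`` random baseline topographies (drawn with replacement from
    the pool of every subject's prestimulus maps) to the group-average map
    at that timepoint. A template is active where its observed c exceeds
    the (1−alpha) null quantile continuously for at least ``min_run_ms``
    (default 5% of the tested window). Returns a copy of the series with
    ``masks`` and ``thresholds`` attached.
    """
    pool = np.asarray(baseline_pool, dtype=float)
    if pool.size == 0:
        raise ValueError("empty baseline pool")
    rng = np.random.default_rng(seed)
    t = series.times_ms
    sel = (t >= window_ms[0]) & (t < window_ms[1])
    duration = window_ms[1] - window_ms[0]
    if min_run_ms is None:
        min_run_ms = 0.05 * duration
    if min_run_ms > duration:
        warnings.warn("min_run_ms exceeds the tested window; no runs possible")

    if series.data_maps_unit is None:
        raise ValueError("series must come from fit_microstates")

    draws = pool[rng.integers(0, pool.shape[0], size=n_iter)]
    du = _unit(draws)  # (n_iter, C)
    corr_null = du @ series.data_maps_unit[sel].T  # (n_iter, T_sel)
    if series.polarity_sensitive:
        c_null = np.clip(corr_null, 0.0, None) ** 2
    else:
        c_null = corr_null**2
    thr_sel = np.quantile(c_null, 1.0 - alpha, axis=0, method="higher")

    thresholds = np.full(t.size, np.nan)
    thresholds[sel] = thr_sel
    k = series.c.shape[0]
    masks = np.zeros((k, t.size), dtype=bool)
    valid = series.valid if series.valid is not None else np.ones(t.size, bool)
    # +1-corrected exceedance p per template and timepoint
    c_obs = np.nan_to_num(series.c[:, sel])  # (k, T_sel)
    exceed = (c_null[None, :, :] >= c_obs[:, None, :]).sum(axis=1)
    p_sel = (1.0 + exceed) / (1.0 + n_iter)
    p_raw = np.full((k, t.size), np.nan)
    p_raw[:, sel] = p_sel
    raw = np.zeros((k, t.size), dtype=bool)
    raw[:, sel] = p_sel <= alpha
    raw &= valid[None, :]
    for m in range(k):
        for lo, hi in significant_runs(raw[m] & sel, t, min_run_ms):
            masks[m, (t >= lo) & (t < hi)] = True

    out = ActivationSeries(
        times_ms=t, gfp=series.gfp, c=series.c,
        template_ids=series.template_ids,
        polarity_sensitive=series.polarity_sensitive, valid=series.valid,
        data_maps_unit=series.data_maps_unit, masks=masks,
        thresholds=thresholds, p_raw=p_raw,
    )
    return out


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def _runs_of(mask: np.ndarray, times: np.ndarray) -> list[tuple[int, int]]:
    """Sample-index [start, stop) runs of a boolean mask."""
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(np.int8), 0]))
    return [(int(a), int(b)) for a, b in zip(idx[::2], idx[1::2])]


def _mean_run_durations(
    groups: dict[str, ActivationSeries]
) -> dict[str, float]:
    """Per-template mean raw-run duration pooled over occurrences/groups."""
    durs: dict[str, list[float]] = {}
    for series in groups.values():
        dt = series.dt_ms
        for m, tid in enumerate(series.template_ids):
            for a, b in _runs_of(series.masks[m], series.times_ms):
                durs.setdefault(tid, []).append((b - a) * dt)
    return {tid: float(np.mean(v)) for tid, v in durs.items() if v}


def extract_events(
    series: ActivationSeries,
    group: str | None = None,
    mean_durations: dict[str, float] | None = None,
) -> list[MicrostateEvent]:
    """Turn significance-mask runs into events with onset/duration/power.

    Two runs of the same template merge into one event when their gap does
    not exceed that template's mean run duration (pooled across
    occurrences and, when supplied via ``mean_durations``, across groups).
    Onset is the first active sample's latency (may be negative), duration
    the merged run length, power ∫ GFP(t)·c_m(t) dt in µV·ms. The
    procedure is deterministic given masks and series.
    """
    if series.masks is None:
        raise ValueError("run activation_significance first")
    if mean_durations is None:
        mean_durations = _mean_run_durations({"": series})
    dt = series.dt_ms
    t = series.times_ms
    events: list[MicrostateEvent] = []
    for m, tid in enumerate(series.template_ids):
        runs = _runs_of(series.masks[m], t)
        if not runs:
            continue
        gap_max = mean_durations.get(tid, 0.0)
        merged = [list(runs[0])]
        for a, b in runs[1:]:
            if (a - merged[-1][1]) * dt <= gap_max:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for occ, (a, b) in enumerate(merged):
            c = np.nan_to_num(series.c[m, a:b])
            power = float((series.gfp[a:b] * c).sum() * dt)
            events.append(MicrostateEvent(
                template_id=tid, occurrence=occ, onset_ms=float(t[a]),
                duration_ms=float((b - a) * dt), power_uVms=power,
                group=group,
            ))
    return events


def extract_events_groups(
    groups: dict[str, ActivationSeries]
) -> dict[str, list[MicrostateEvent]]:
    """Events per group with the merge rule pooled across all groups."""
    mean_dur = _mean_run_durations(groups)
    return {g: extract_events(s, group=g, mean_durations=mean_dur)
            for g, s in groups.items()}


def total_field_power(
    average: np.ndarray | EpochSet,
    times_ms: np.ndarray | None = None,
    window_ms: tuple[float, float] = (0.0, 1000.0),
) -> float:
    """Mean GFP (µV) of a group average over the postlance window."""
    if isinstance(average, EpochSet):
        times_ms = average.times_ms
        average = average.grand_average()
    if times_ms is None:
        raise ValueError("times_ms required with a bare array")
    avg = np.asarray(average, dtype=float)
    sel = (times_ms >= window_ms[0]) & (times_ms < window_ms[1])
    if not sel.any():
        raise ValueError("empty window")
    return float(avg[:, sel].std(axis=0).mean())
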