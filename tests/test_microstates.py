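"""Microstate clustering, model selection, back-fitting and events."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from neopain.containers import EpochSet
from neopain.microstates import (
    ActivationSeries,
    MicrostateSet,
    _aahc,
    activation_significance,
    baseline_map_pool,
    cluster_microstates,
    explained_variance,
    extract_events,
    extract_events_groups,
    fit_microstates,
    pool_consistent_maps,
    select_k,
    total_field_power,
)
from neopain.synthetic import make_templates
from neopain.topo import RandomizationResult, tct


def matched_correlations(recovered, truth):
    """Best one-to-one |correlation| matching via the Hungarian algorithm."""
    r = recovered / np.linalg.norm(recovered, axis=1, keepdims=True)
    t = truth / np.linalg.norm(truth, axis=1, keepdims=True)
    c = np.abs(r @ t.T)
    rows, cols = linear_sum_assignment(-c)
    return c[rows, cols]


class TestClustering:
    def test_planted_cluster_recovery(self, rng):
        truth = np.array(list(make_templates(18, 3, seed=21).values()))
        labels = rng.integers(0, 3, 300)
        maps = truth[labels] + 0.2 * rng.standard_normal((300, 18))
        mset = cluster_microstates(maps, 3)
        assert (matched_correlations(mset.templates, truth) > 0.95).all()

    def test_k_equals_n_maps(self, rng):
        maps = rng.standard_normal((5, 18))
        mset = cluster_microstates(maps, 5)
        norm = maps - maps.mean(axis=1, keepdims=True)
        norm /= norm.std(axis=1, keepdims=True)
        assert (matched_correlations(mset.templates, norm) > 0.999).all()

    def test_deterministic(self, rng):
        maps = rng.standard_normal((60, 18))
        a = cluster_microstates(maps, 4)
        b = cluster_microstates(maps.copy(), 4)
        assert np.array_equal(a.templates, b.templates)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_microstates(rng.standard_normal((3, 8)), 4)

    def test_training_ev_nondecreasing_in_k(self, rng):
        truth = np.array(list(make_templates(12, 4, seed=5).values()))
        maps = truth[rng.integers(0, 4, 200)] + 0.5 * rng.standard_normal((200, 12))
        snaps = _aahc(maps, 2, polarity_sensitive=True,
                      record=set(range(2, 9)))
        u = maps - maps.mean(axis=1, keepdims=True)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        evs = []
        for k in range(2, 9):
            tm = snaps[k][0]
            evs.append((np.clip(u @ tm.T, 0, None).max(axis=1) ** 2).mean())
        assert all(b >= a - 1e-9 for a, b in zip(evs, evs[1:]))

    def test_template_invariants_enforced(self):
        with pytest.raises(ValueError):
            MicrostateSet(templates=np.ones((1, 8)), ids=("a",))


class TestPoolingAndSelection:
    def test_pooled_count_under_full_consistency(self, rng):
        n_ch = 8
        tmpl = make_templates(n_ch, 1, seed=9, smooth=False)["M1"]
        data = 5.0 * np.tile(tmpl[None, :, None], (10, 1, 40))
        data += 0.1 * rng.standard_normal(data.shape)
        data -= data.mean(axis=1, keepdims=True)
        groups = {g: EpochSet(data=data.copy(), fs_hz=100.0, tmin_ms=-100.0,
                              montage=tuple(f"c{i}" for i in range(n_ch)))
                  for g in ("A", "B")}
        res = {g: tct(es, window_ms=(-100.0, 300.0), n_iter=200, seed=i)
               for i, (g, es) in enumerate(groups.items())}
        pooled = pool_consistent_maps(groups, res)
        n_t = groups["A"].window_slice((-100.0, 300.0)).stop
        assert pooled.maps.shape[0] == 2 * n_t  # timepoints x groups

    def test_empty_consistency_rejected(self, rng):
        n_ch = 6
        es = EpochSet(data=rng.standard_normal((8, n_ch, 30)), fs_hz=100.0,
                      tmin_ms=-100.0,
                      montage=tuple(f"c{i}" for i in range(n_ch)))
        empty = RandomizationResult(
            times_ms=es.times_ms, statistic=np.zeros(30),
            p=np.ones(30), alpha=0.05, min_run_ms=15.0, segments=[],
            n_iter=10)
        with pytest.raises(ValueError, match="consistent"):
            pool_consistent_maps({"A": es}, {"A": empty})

    def test_select_k_recovers_planted_count(self, shifted_cohort):
        groups, _, _ = shifted_cohort
        res = {g: tct(es, n_iter=400, seed=30 + i)
               for i, (g, es) in enumerate(groups.items())}
        pooled = pool_consistent_maps(groups, res)
        k_star, curve = select_k(pooled, k_range=(2, 8), n_iter=25, seed=31)
        assert k_star == 4
        # reproducible given the seed
        k_again, _ = select_k(pooled, k_range=(2, 8), n_iter=25, seed=31)
        assert k_again == k_star

    def test_select_k_flat_curve_yields_k_min(self, rng):
        n_ch = 8
        # pure noise: no k explains held-out structure
        data = rng.standard_normal((12, n_ch, 60))
        data -= data.mean(axis=1, keepdims=True)
        es = EpochSet(data=data, fs_hz=100.0, tmin_ms=-100.0,
                      montage=tuple(f"c{i}" for i in range(n_ch)))
        full = RandomizationResult(
            times_ms=es.times_ms, statistic=np.zeros(60), p=np.zeros(60),
            alpha=0.05, min_run_ms=0.0,
            segments=[(es.times_ms[0], es.times_ms[-1] + 10.0)], n_iter=10)
        pooled = pool_consistent_maps({"A": es}, {"A": full})
        k_star, curve = select_k(pooled, k_range=(2, 6), n_iter=10, seed=1)
        assert k_star == 2


class TestFitting:
    def test_pure_template_fully_explained(self):
        tmpl = make_templates(12, 2, seed=2)
        mset = cluster_microstates(np.array(list(tmpl.values())), 2)
        avg = np.tile(mset.templates[0][:, None], (1, 20)) * 3.0
        series = fit_microstates(avg, mset, times_ms=np.arange(20) * 10.0)
        assert np.allclose(series.c[0], 1.0)
        assert explained_variance(series) == pytest.approx(1.0)

    def test_orthogonal_average_explains_nothing(self):
        tmpl = make_templates(12, 3, seed=2)
        mats = np.array(list(tmpl.values()))
        mset = cluster_microstates(mats[:2], 2)
        avg = np.tile(mats[2][:, None], (1, 20))
        series = fit_microstates(avg, mset, times_ms=np.arange(20) * 10.0)
        assert explained_variance(series) == pytest.approx(0.0, abs=1e-12)

    def test_c_bounded_and_zero_gfp_masked(self, rng):
        tmpl = make_templates(12, 2, seed=3)
        mset = cluster_microstates(np.array(list(tmpl.values())), 2)
        avg = rng.standard_normal((12, 30))
        avg[:, 5] = 0.0
        series = fit_microstates(avg, mset, times_ms=np.arange(30) * 10.0)
        finite = np.isfinite(series.c)
        assert ((series.c[finite] >= 0) & (series.c[finite] <= 1)).all()
        assert not series.valid[5] and np.isnan(series.c[:, 5]).all()

    def test_polarity_insensitive_mode(self):
        tmpl = make_templates(12, 1, seed=4)
        mset = cluster_microstates(np.array(list(tmpl.values())), 1)
        avg = -np.tile(mset.templates[0][:, None], (1, 10))
        t = np.arange(10) * 10.0
        sens = fit_microstates(avg, mset, times_ms=t, polarity_sensitive=True)
        insens = fit_microstates(avg, mset, times_ms=t, polarity_sensitive=False)
        assert np.allclose(sens.c, 0.0)
        assert np.allclose(insens.c, 1.0)

    def test_scripted_activations_peak_in_intervals(self, shifted_cohort):
        groups, truth, _ = shifted_cohort
        tmat = np.array([truth.templates[k] for k in sorted(truth.templates)])
        mset = MicrostateSet(templates=tmat, ids=tuple(sorted(truth.templates)))
        series = fit_microstates(groups["A"], mset)
        for tid, onset, dur, _ in truth.scripts["A"].entries:
            m = mset.ids.index(tid)
            peak_t = series.times_ms[np.nanargmax(series.c[m])]
            assert onset - 20 <= peak_t <= onset + dur + 20


class TestActivationAndEvents:
    def _series(self, masks, gfp=None, dt=10.0, c=None):
        k, n_t = masks.shape
        times = np.arange(n_t) * dt
        gfp = np.ones(n_t) if gfp is None else gfp
        c = np.ones((k, n_t)) if c is None else c
        return ActivationSeries(
            times_ms=times, gfp=gfp, c=c,
            template_ids=tuple(f"M{i + 1}" for i in range(k)),
            masks=masks)

    def test_single_run_event_geometry(self):
        masks = np.zeros((1, 100), bool)
        masks[0, 10:30] = True  # [100, 300) ms
        events = extract_events(self._series(masks))
        assert len(events) == 1
        e = events[0]
        assert e.onset_ms == 100.0 and e.duration_ms == 200.0
        # power = sum(gfp * c) * dt = 20 * 10
        assert e.power_uVms == pytest.approx(200.0)

    def test_separated_runs_stay_distinct(self):
        masks = np.zeros((1, 100), bool)
        masks[0, 10:20] = True  # 100 ms run
        masks[0, 60:70] = True  # gap 400 ms > mean duration 100 ms
        events = extract_events(self._series(masks))
        assert [e.occurrence for e in events] == [0, 1]

    def test_close_runs_merge(self):
        masks = np.zeros((1, 100), bool)
        masks[0, 10:20] = True  # 100 ms
        masks[0, 25:45] = True  # 200 ms; gap 50 <= mean 150
        events = extract_events(self._series(masks))
        assert len(events) == 1
        assert events[0].onset_ms == 100.0
        assert events[0].duration_ms == 350.0

    def test_group_pooled_merge_rule(self):
        masks_a = np.zeros((1, 100), bool)
        masks_a[0, 10:20] = True
        masks_b = np.zeros((1, 100), bool)
        masks_b[0, 10:40] = True  # longer runs in B raise the pooled mean
        groups = {"A": self._series(masks_a), "B": self._series(masks_b)}
        events = extract_events_groups(groups)
        assert {e.group for evs in events.values() for e in evs} == {"A", "B"}

    def test_null_activation_mostly_filtered(self, rng):
        # template never present: ~5% raw exceedance, killed by run filter
        tmpl = make_templates(12, 2, seed=6)
        mset = cluster_microstates(np.array(list(tmpl.values())), 2)
        other = make_templates(12, 6, seed=77)
        rates, runs = [], 0
        for sim in range(20):
            avg = rng.standard_normal((12, 100))
            pool = rng.standard_normal((400, 12))
            series = fit_microstates(avg, mset,
                                     times_ms=np.arange(100) * 10.0)
            out = activation_significance(series, pool, n_iter=200,
                                          window_ms=(0.0, 1000.0),
                                          seed=rng)
            tested = ~np.isnan(out.p_raw[0])
            rates.append((out.p_raw[:, tested] <= 0.05).mean())
            runs += out.masks.any()
        assert abs(np.mean(rates) - 0.05) < 0.03
        assert runs <= 6  # run filter kills almost all null activations

    def test_min_run_longer_than_window_warns(self, rng):
        tmpl = make_templates(12, 1, seed=8)
        mset = cluster_microstates(np.array(list(tmpl.values())), 1)
        avg = rng.standard_normal((12, 20))
        series = fit_microstates(avg, mset, times_ms=np.arange(20) * 10.0)
        with pytest.warns(UserWarning, match="min_run"):
            out = activation_significance(series, rng.standard_normal((50, 12)),
                                          n_iter=50, window_ms=(0.0, 200.0),
                                          min_run_ms=500.0, seed=1)
        assert not out.masks.any()

    def test_empty_baseline_pool_rejected(self, rng):
        tmpl = make_templates(12, 1, seed=8)
        mset = cluster_microstates(np.array(list(tmpl.values())), 1)
        avg = rng.standard_normal((12, 20))
        series = fit_microstates(avg, mset, times_ms=np.arange(20) * 10.0)
        with pytest.raises(ValueError):
            activation_significance(series, np.empty((0, 12)), n_iter=10)


class TestTotalFieldPower:
    def test_zero_average(self):
        avg = np.zeros((8, 50))
        assert total_field_power(avg, np.arange(50) * 10.0, (0.0, 500.0)) == 0.0

    def test_constant_gfp_construction(self):
        tmpl = make_templates(8, 1, seed=3, smooth=False)["M1"]
        avg = 3.7 * np.tile(tmpl[:, None], (1, 50))
        val = total_field_power(avg, np.arange(50) * 10.0, (0.0, 500.0))
        assert val == pytest.approx(3.7)

    def test_matches_brute_force_mean_of_sds(self, rng):
        avg = rng.standard_normal((8, 60))
        times = np.arange(60) * 10.0
        sel = (times >= 100.0) & (times < 400.0)
        expect = np.mean([np.std(avg[:, i]) for i in np.nonzero(sel)[0]])
        assert total_field_power(avg, times, (100.0, 400.0)) == pytest.approx(expect)

    def test_baseline_pool_shape(self, small_cohort):
        groups, _ = small_cohort
        pool = baseline_map_pool(groups, (-500.0, 0.0))
        es = groups["A"]
        n_baseline = es.window_slice((-500.0, 0.0)).stop
        assert pool.shape == (2 * es.n_subjects * n_baseline, es.n_channels)
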