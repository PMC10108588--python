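"""The synthetic-data generators: determinism, calibration, ground truth."""

import numpy as np
import pytest

from neopain.facial import ACTIONS, score_constellation
from neopain.synthetic import (
    FacialSimSpec,
    MicrostateScript,
    SyntheticCohortSpec,
    four_state_script,
    generate_erp_cohort,
    generate_facial_cohort,
    make_templates,
)
from neopain.topo import spatial_correlation


class TestTemplates:
    def test_average_referenced_unit_gfp_orthogonal(self):
        tmpl = make_templates(18, 4, seed=3)
        mats = np.array(list(tmpl.values()))
        assert np.abs(mats.mean(axis=1)).max() < 1e-9
        assert np.abs(mats.std(axis=1) - 1.0).max() < 1e-9
        gram = mats @ mats.T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-9

    def test_script_validation(self):
        tmpl = make_templates(8, 2, seed=1, smooth=False)
        with pytest.raises(ValueError, match="duration"):
            MicrostateScript(entries=[("M1", 0.0, -5.0, 1.0)], templates=tmpl)
        with pytest.raises(ValueError, match="unknown template"):
            MicrostateScript(entries=[("zz", 0.0, 10.0, 1.0)], templates=tmpl)

    def test_event_outside_epoch_rejected(self):
        tmpl = make_templates(8, 1, seed=1, smooth=False)
        script = MicrostateScript(entries=[("M1", 900.0, 200.0, 1.0)],
                                  templates=tmpl, jitter_sd_ms=0.0)
        with pytest.raises(ValueError, match="exits the epoch"):
            SyntheticCohortSpec(n_subjects_per_group=2, n_channels=8,
                                group_scripts={"A": script, "B": script})


class TestErpCohort:
    def test_seeded_determinism(self):
        tmpl = make_templates(18, 4, seed=1)
        spec = lambda: SyntheticCohortSpec(
            n_subjects_per_group=3,
            group_scripts={"A": four_state_script(tmpl),
                           "B": four_state_script(tmpl)},
            seed=99)
        g1, _ = generate_erp_cohort(spec())
        g2, _ = generate_erp_cohort(spec())
        assert np.array_equal(g1["A"].data, g2["A"].data)
        assert np.array_equal(g1["B"].data, g2["B"].data)

    def test_average_reference_preserved(self, small_cohort):
        groups, _ = small_cohort
        for es in groups.values():
            assert np.abs(es.data.mean(axis=1)).max() < 1e-9

    def test_noise_free_topography_matches_template(self):
        tmpl = make_templates(18, 1, seed=4)
        script = MicrostateScript(
            entries=[("M1", 100.0, 200.0, 5.0)], templates=tmpl,
            jitter_sd_ms=0.0, snr=np.inf)
        spec = SyntheticCohortSpec(n_subjects_per_group=3,
                                   group_scripts={"A": script, "B": script},
                                   seed=0)
        groups, _ = generate_erp_cohort(spec)
        avg = groups["A"].grand_average()
        mid = groups["A"].time_index(200.0)
        assert spatial_correlation(avg[:, mid], tmpl["M1"]) == pytest.approx(1.0)

    def test_zero_amplitude_gives_unit_noise(self):
        tmpl = make_templates(18, 1, seed=4)
        script = MicrostateScript(entries=[("M1", 100.0, 200.0, 0.0)],
                                  templates=tmpl, jitter_sd_ms=0.0, snr=5.0)
        spec = SyntheticCohortSpec(n_subjects_per_group=5,
                                   group_scripts={"A": script, "B": script},
                                   seed=6)
        groups, _ = generate_erp_cohort(spec)
        rms = np.sqrt(np.mean(groups["A"].data**2, axis=(1, 2)))
        assert np.allclose(rms, 1.0, rtol=0.05)

    def test_snr_calibration(self):
        # realized epoch-wise SNR within 10% of requested
        tmpl = make_templates(18, 2, seed=8)
        ids = list(tmpl)
        for snr in (2.0, 5.0, 10.0):
            script = MicrostateScript(
                entries=[(ids[0], 100.0, 300.0, 4.0),
                         (ids[1], 500.0, 300.0, 4.0)],
                templates=tmpl, jitter_sd_ms=0.0, snr=snr)
            spec = SyntheticCohortSpec(n_subjects_per_group=20,
                                       group_scripts={"A": script, "B": script},
                                       seed=11)
            groups, _ = generate_erp_cohort(spec)
            noisefree = MicrostateScript(
                entries=script.entries, templates=tmpl,
                jitter_sd_ms=0.0, snr=np.inf)
            clean, _ = generate_erp_cohort(SyntheticCohortSpec(
                n_subjects_per_group=20,
                group_scripts={"A": noisefree, "B": noisefree}, seed=11))
            sig_rms = np.sqrt(np.mean(clean["A"].data**2))
            noise = groups["A"].data - clean["A"].data
            noise_rms = np.sqrt(np.mean(noise**2))
            assert sig_rms / noise_rms == pytest.approx(snr, rel=0.10)

    def test_winner_take_all_matches_script(self):
        # two orthogonal templates in disjoint intervals, snr 10, n = 20
        tmpl = make_templates(18, 2, seed=13)
        ids = list(tmpl)
        script = MicrostateScript(
            entries=[(ids[0], 100.0, 300.0, 4.0), (ids[1], 500.0, 300.0, 4.0)],
            templates=tmpl, jitter_sd_ms=0.0, snr=10.0)
        spec = SyntheticCohortSpec(n_subjects_per_group=20,
                                   group_scripts={"A": script, "B": script},
                                   seed=17)
        groups, _ = generate_erp_cohort(spec)
        es = groups["A"]
        tmat = np.array([tmpl[i] for i in ids])
        hits = 0
        for s in range(es.n_subjects):
            ok = True
            for j, (tid, onset, dur, _) in enumerate(script.entries):
                mid = es.time_index(onset + dur / 2)
                v = es.data[s, :, mid]
                corr = tmat @ v / (np.linalg.norm(tmat, axis=1) * np.linalg.norm(v))
                ok &= int(np.argmax(np.abs(corr))) == j
            hits += ok
        assert hits / es.n_subjects >= 0.95

    def test_ground_truth_records_realized_onsets(self, shifted_cohort):
        groups, truth, shift_id = shifted_cohort
        for g, per_subject in truth.events.items():
            assert len(per_subject) == groups[g].n_subjects
            scripted = {tid: onset for tid, onset, _, _ in
                        [(e[0], e[1], e[2], e[3]) for e in
                         truth.scripts[g].entries]}
            for events in per_subject:
                for tid, onset, dur, amp in events:
                    assert abs(onset - scripted[tid]) < 60.0  # truncated jitter


class TestFacialCohort:
    def test_all_present_scores_70(self):
        spec = FacialSimSpec(n_subjects_per_group=4,
                             p_action={"hi": 1.0, "lo": 1.0},
                             baseline_p=1.0, obstruction_rate=0.0, seed=1)
        records, _ = generate_facial_cohort(spec)
        for rec in records:
            assert score_constellation(rec, "NFCS-7").total == 70

    def test_all_absent_scores_zero(self):
        spec = FacialSimSpec(n_subjects_per_group=4,
                             p_action={"hi": 0.0, "lo": 0.0},
                             baseline_p=0.0, obstruction_rate=0.0, seed=2)
        records, _ = generate_facial_cohort(spec)
        for rec in records:
            assert score_constellation(rec, "NFCS-7").total == 0

    def test_binomial_expectation_of_totals(self):
        spec = FacialSimSpec(n_subjects_per_group=50,
                             p_action={"hi": 0.8, "lo": 0.1},
                             obstruction_rate=0.0, seed=3)
        records, truth = generate_facial_cohort(spec)
        for gname, p in (("hi", 0.8), ("lo", 0.1)):
            totals = [score_constellation(r, "NFCS-7").total
                      for r in records
                      if r.group == gname and r.epoch == "reactivity"]
            mean_expect = 70 * p
            se = np.sqrt(70 * p * (1 - p) / len(totals))
            assert abs(np.mean(totals) - mean_expect) < 3 * se

    def test_obstruction_produces_reason_coded_missing(self):
        spec = FacialSimSpec(n_subjects_per_group=30, obstruction_rate=2.0,
                             seed=4)
        records, _ = generate_facial_cohort(spec)
        n_missing = sum(r.n_missing for r in records)
        assert n_missing > 0
        for rec in records:
            miss = np.isnan(rec.values)
            assert all(rec.reasons[i, j] == "obstruction"
                       for i, j in zip(*np.nonzero(miss)))

    def test_determinism(self):
        spec = lambda: FacialSimSpec(n_subjects_per_group=5, seed=42)
        r1, t1 = generate_facial_cohort(spec())
        r2, t2 = generate_facial_cohort(spec())
        for a, b in zip(r1, r2):
            assert np.array_equal(a.values, b.values, equal_nan=True)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            FacialSimSpec(n_subjects_per_group=2, p_action={"a": 1.2, "b": 0.1})
        with pytest.raises(ValueError):
            FacialSimSpec(n_subjects_per_group=2, obstruction_mean_len_s=0.5)
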