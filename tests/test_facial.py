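"""NFCS scoring, the missing-data cascade, and the comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neopain.facial import (
    ACTIONS,
    CLINICAL_THRESHOLD,
    FacialCodingRecord,
    classify_clinical,
    compare_constellations,
    handle_missing,
    icc_two_way,
    scale_to_30,
    score_constellation,
    score_record,
)


def record(values, epoch="reactivity", **kw):
    return FacialCodingRecord(subject_id="s1", epoch=epoch,
                              values=np.asarray(values, float), **kw)


def full(v):
    return np.full((7, 10), float(v))


class TestScoring:
    def test_all_present_maxima(self):
        rec = record(full(1))
        assert score_constellation(rec, "NFCS-7").total == 70
        assert score_constellation(rec, "NFCS-3").total == 30
        assert score_constellation(rec, "NFCS-P-3").total == 30

    def test_all_absent_scores_zero(self):
        rec = record(full(0))
        for c in ("NFCS-7", "NFCS-3", "NFCS-P-3"):
            assert score_constellation(rec, c).total == 0

    def test_partial_matrix_sums_selected_actions(self):
        vals = full(0)
        vals[ACTIONS.index("brow bulge"), :4] = 1
        vals[ACTIONS.index("eye squeeze"), :2] = 1
        rec = record(vals)
        assert score_constellation(rec, "NFCS-P-3").total == 6
        # eye squeeze is the only overlap with NFCS-3
        assert score_constellation(rec, "NFCS-3").total == 2

    def test_unresolved_missing_directs_to_handler(self):
        vals = full(1)
        vals[0, 3] = np.nan
        with pytest.raises(ValueError, match="handle_missing"):
            score_constellation(record(vals), "NFCS-P-3")


class TestMissingDataCascade:
    def test_fully_observed_unchanged(self):
        rec = record(full(1), cry_constant=True, body_constant=True)
        out, flags = handle_missing(rec)
        assert np.array_equal(out.values, rec.values)
        assert not (flags.constancy_used or flags.prorated or flags.excluded)

    def test_constancy_fills_closest_preceding(self):
        vals = full(0)
        row = ACTIONS.index("brow bulge")
        vals[row] = [1, 1, np.nan, np.nan, 1, 1, 1, 1, 1, 1]
        rec = record(vals, cry_constant=True, body_constant=True)
        out, flags = handle_missing(rec)
        assert flags.constancy_used and not flags.forward_fill_fallback
        assert np.array_equal(out.values[row], np.ones(10))
        assert score_constellation(out, "NFCS-P-3", flags).total == 10

    def test_constancy_never_changes_observed_cells(self):
        vals = full(0)
        vals[0] = [0, 1, np.nan, 1, 0, 1, 0, 1, 0, 1]
        rec = record(vals, cry_constant=True, body_constant=True)
        out, _ = handle_missing(rec)
        observed = ~np.isnan(vals)
        assert np.array_equal(out.values[observed], vals[observed])

    def test_leading_gap_uses_following_value_with_flag(self):
        vals = full(0)
        vals[0] = [np.nan, np.nan, 1, 1, 1, 1, 1, 1, 1, 1]
        rec = record(vals, cry_constant=True, body_constant=True)
        out, flags = handle_missing(rec)
        assert flags.forward_fill_fallback
        assert np.array_equal(out.values[0], np.ones(10))

    def test_constancy_needs_60pct_and_constant_distress(self):
        vals = full(1)
        vals[0, :5] = np.nan  # 50% codable -> constancy ineligible
        rec = record(vals, cry_constant=True, body_constant=True)
        _, flags = handle_missing(rec)
        assert ACTIONS[0] not in flags.constancy_actions
        # cry not constant blocks constancy even at 90% codable
        vals2 = full(1)
        vals2[0, 0] = np.nan
        rec2 = record(vals2, cry_constant=False, body_constant=True)
        _, flags2 = handle_missing(rec2)
        assert not flags2.constancy_used

    def test_coder_override_blocks_constancy(self):
        vals = full(1)
        vals[0, 0] = np.nan
        rec = record(vals, cry_constant=True, body_constant=True,
                     coder_override=True)
        _, flags = handle_missing(rec)
        assert not flags.constancy_used

    def test_proration_worked_example(self):
        # NFCS-P-3: 30 cells, 21 observed summing to 14 -> 14 * 30/21 = 20
        vals = full(0)
        p3 = [ACTIONS.index(a) for a in
              ("brow bulge", "eye squeeze", "nasolabial furrow")]
        vals[p3[0], :5] = np.nan  # 50% codable, constancy inapplicable
        vals[p3[1], :2] = np.nan
        vals[p3[2], :2] = np.nan
        observed = [(r, c) for r in p3 for c in range(10)
                    if not np.isnan(vals[r, c])]
        assert len(observed) == 21
        for r, c in observed[:14]:
            vals[r, c] = 1
        rec = record(vals, cry_constant=False, body_constant=True)
        out, flags = handle_missing(rec, "NFCS-P-3")
        assert flags.prorated and not flags.excluded
        score = score_constellation(out, "NFCS-P-3", flags)
        assert score.total == pytest.approx(20.0)

    def test_proration_is_identity_when_complete(self):
        rec = record(full(1))
        assert score_record(rec, "NFCS-P-3").total == 30

    def test_exclusion_below_60pct(self):
        vals = full(1)
        p3 = [ACTIONS.index(a) for a in
              ("brow bulge", "eye squeeze", "nasolabial furrow")]
        for r in p3:
            vals[r, :5] = np.nan  # 50% observed overall
        rec = record(vals, cry_constant=False, body_constant=False)
        out, flags = handle_missing(rec, "NFCS-P-3")
        assert flags.excluded
        score = score_constellation(out, "NFCS-P-3", flags)
        assert np.isnan(score.total)

    def test_prorated_total_bounded_by_max(self):
        # all observed cells present: proration lands exactly on the maximum
        vals = full(1)
        p3 = [ACTIONS.index(a) for a in
              ("brow bulge", "eye squeeze", "nasolabial furrow")]
        vals[p3[0], :4] = np.nan
        rec = record(vals, cry_constant=False, body_constant=True)
        out, flags = handle_missing(rec, "NFCS-P-3")
        score = score_constellation(out, "NFCS-P-3", flags)
        assert score.total == 30  # 26 * 30/26; binary cells can never exceed max


class TestClinicalGrouping:
    def test_threshold_boundary(self):
        assert classify_clinical(9.0).label == "NFCS-clinical"
        assert classify_clinical(8.99).label == "NFCS-subclinical"
        assert classify_clinical(30.0).label == "NFCS-clinical"
        assert classify_clinical(0.0).label == "NFCS-subclinical"

    def test_monotone_in_total(self, rng):
        totals = np.sort(rng.uniform(0, 30, 50))
        labels = [classify_clinical(t).label for t in totals]
        first_clin = next((i for i, l in enumerate(labels)
                           if l == "NFCS-clinical"), len(labels))
        assert all(l == "NFCS-subclinical" for l in labels[:first_clin])
        assert all(l == "NFCS-clinical" for l in labels[first_clin:])

    def test_baseline_epoch_rejected(self):
        rec = record(full(1), epoch="baseline")
        score = score_constellation(rec, "NFCS-P-3")
        with pytest.raises(ValueError):
            classify_clinical(score)

    def test_scale_to_30(self):
        assert scale_to_30(70.0) == 30.0
        assert scale_to_30(0.0) == 0.0
        assert scale_to_30(21.0) == pytest.approx(9.0)
        with pytest.raises(ValueError):
            scale_to_30(71.0)

    def test_nfcs7_score_auto_scaled(self):
        rec = record(full(1))
        score = score_constellation(rec, "NFCS-7")
        assert classify_clinical(score).label == "NFCS-clinical"
        assert CLINICAL_THRESHOLD == 9.0


class TestCompareConstellations:
    def test_identical_columns_friedman_null(self, rng):
        col = rng.integers(0, 30, 12).astype(float)
        df = pd.DataFrame({"NFCS-7": col, "NFCS-3": col, "NFCS-P-3": col})
        rep = compare_constellations(df)
        assert rep["friedman"]["chi2"] == 0.0
        assert rep["friedman"]["p"] == 1.0

    def test_uniform_shift_gives_extreme_wilcoxon(self, rng):
        a = rng.integers(0, 20, 15).astype(float)
        df = pd.DataFrame({"A": a, "B": a + 1.0})
        rep = compare_constellations(df)
        z = rep["wilcoxon"][("A", "B")]["z"]
        # all 15 differences are exactly -1: W+ = 0 (the most extreme
        # value) and all |d| tied, so the tie-corrected variance applies
        n = 15
        mu = n * (n + 1) / 4
        var = n * (n + 1) * (2 * n + 1) / 24 - (n**3 - n) / 48
        z_min = (0 - mu + 0.5) / np.sqrt(var)
        assert z == pytest.approx(z_min)
        assert rep["wilcoxon"][("A", "B")]["p"] < 0.001

    def test_mannwhitney_type_one_error(self, rng):
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            x = rng.standard_normal(12)
            y = rng.standard_normal(12)
            p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
            rejections += p < 0.05
        rate = rejections / n_sim
        assert abs(rate - 0.05) < 2 * np.sqrt(0.05 * 0.95 / n_sim) + 0.01

    def test_group_comparison_reports_u(self, rng):
        df = pd.DataFrame({"A": rng.uniform(0, 30, 20),
                           "B": rng.uniform(0, 30, 20)})
        groups = pd.Series(["x"] * 10 + ["y"] * 10)
        rep = compare_constellations(df, groups)
        assert set(rep["mannwhitney"]["tests"]) == {"A", "B"}


class TestIcc:
    def test_identical_raters_give_one(self, rng):
        col = rng.uniform(0, 30, 20)
        assert icc_two_way(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_independent_raters_near_zero(self, rng):
        a = rng.uniform(0, 30, 500)
        b = rng.permutation(a)
        assert abs(icc_two_way(np.column_stack([a, b]))) < 0.15

    def test_matches_mean_squares_oracle(self, rng):
        x = rng.uniform(0, 10, (9, 3))
        n, k = x.shape
        # brute-force two-way ANOVA mean squares
        grand = x.mean()
        msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = ((x - x.mean(1, keepdims=True) - x.mean(0) + grand) ** 2).sum() / (
            (n - 1) * (k - 1))
        expect = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_two_way(x) == pytest.approx(expect, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.uniform(0, 10, (12, 3))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 3),
            "rater": np.tile(np.arange(3), 12),
            "score": x.ravel(),
        })
        res = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
        icc2 = float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_two_way(x) == pytest.approx(icc2, abs=1e-9)

    def test_zero_variance_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert icc_two_way(np.ones((5, 3))) == 0.0
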