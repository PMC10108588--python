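"""Neonatal Facial Coding System (NFCS) scoring with structured missingness.

Facial actions are coded second by second as 0 (absent) or 1 (present) over
two 10-second epochs (baseline before, reactivity after the heel lance).
Three constellations of the seven coded actions are scored:

* NFCS-7  — all seven actions, epoch maximum 70;
* NFCS-3  — eye squeeze, vertical stretch mouth, horizontal stretch mouth
  (epoch maximum 30);
* NFCS-P-3 — brow bulge, eye squeeze, nasolabial furrow (the facial items
  of the Premature Infant Pain Profile-Revised; epoch maximum 30).

Missing cells (face obstructed by movement or equipment) are handled by a
fixed cascade — facial symmetry (resolved by the coder, passed through as
a flag), a constancy rule (fill from the closest preceding observation when
cry and body movement stayed constant and ≥60% of the action's seconds are
codable), proration (scale the observed sum when ≥60% of the
constellation's cells are observed), and finally exclusion.

Reactivity NFCS-P-3 totals at or above 9/30 define the clinically
significant facial-activity group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ACTIONS",
    "CONSTELLATIONS",
    "FacialCodingRecord",
    "NFCSScore",
    "ClinicalGroup",
    "MissingFlags",
    "handle_missing",
    "score_constellation",
    "score_record",
    "scale_to_30",
    "classify_clinical",
    "compare_constellations",
    "icc_two_way",
]

ACTIONS: tuple[str, ...] = (
    "brow bulge",
    "eye squeeze",
    "nasolabial furrow",
    "open lips",
    "vertical stretch mouth",
    "horizontal stretch mouth",
    "taut tongue",
)

CONSTELLATIONS: dict[str, tuple[str, ...]] = {
    "NFCS-7": ACTIONS,
    "NFCS-3": ("eye squeeze", "vertical stretch mouth", "horizontal stretch mouth"),
    "NFCS-P-3": ("brow bulge", "eye squeeze", "nasolabial furrow"),
}

EPOCH_SECONDS = 10
#: Minimum codable fraction for the constancy and proration rules.
MIN_CODABLE_FRACTION = 0.6
#: Reactivity NFCS-P-3 clinical threshold (out of 30).
CLINICAL_THRESHOLD = 9.0


@dataclass
class FacialCodingRecord:
    """One subject × epoch coding matrix: 7 actions × 10 seconds.

    ``values`` holds 0/1 codes with NaN for missing cells; ``reasons``
    carries a missingness reason code per missing cell (same shape, object
    dtype, None where observed).
    """

    subject_id: str
    epoch: str  # "baseline" | "reactivity"
    values: np.ndarray
    reasons: np.ndarray | None = None
    cry_constant: bool | None = None
    body_constant: bool | None = None
    coder_override: bool = False  # coder believes activity did NOT stay constant
    symmetry_used: bool = False
    group: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(ACTIONS), EPOCH_SECONDS):
            raise ValueError(f"matrix must be {len(ACTIONS)}x{EPOCH_SECONDS}")
        observed = self.values[~np.isnan(self.values)]
        if not np.isin(observed, (0.0, 1.0)).all():
            raise ValueError("cells must be 0, 1 or missing")
        if self.epoch not in ("baseline", "reactivity"):
            raise ValueError("epoch must be 'baseline' or 'reactivity'")
        if self.reasons is None:
            self.reasons = np.full(self.values.shape, None, dtype=object)

    def action_row(self, action: str) -> np.ndarray:
        return self.values[ACTIONS.index(action)]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass
class MissingFlags:
    symmetry_used: bool = False
    constancy_used: bool = False
    constancy_actions: list[str] = field(default_factory=list)
    forward_fill_fallback: bool = False  # gap opened the epoch; nearest following used
    prorated: bool = False
    capped: bool = False
    excluded: bool = False


@dataclass
class NFCSScore:
    constellation: str
    epoch: str
    total: float
    max_score: int
    flags: MissingFlags = field(default_factory=MissingFlags)
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if not self.flags.excluded and not (0.0 <= self.total <= self.max_score):
            raise ValueError("total outside [0, max]")


@dataclass
class ClinicalGroup:
    label: str  # "NFCS-clinical" | "NFCS-subclinical"
    threshold: float = CLINICAL_THRESHOLD


def _fill_constant_row(row: np.ndarray) -> tuple[np.ndarray, bool]:
    """Fill NaNs with the closest preceding value (following if none before).

    Returns the filled row and whether the fallback (closest following)
    was needed because a gap opened the epoch.
    """
    out = row.copy()
    fallback = False
    last = np.nan
    for i in range(out.size):
        if np.isnan(out[i]):
            out[i] = last
        else:
            last = out[i]
    # leading gap: no preceding value existed
    if np.isnan(out[0:1]).any() or np.isnan(out).any():
        nxt = np.nan
        for i in range(out.size - 1, -1, -1):
            if np.isnan(out[i]):
                out[i] = nxt
                fallback = True
            else:
                nxt = out[i]
    return out, fallback


def handle_missing(
    record: FacialCodingRecord,
    constellation: str = "NFCS-P-3",
    min_fraction: float = MIN_CODABLE_FRACTION,
) -> tuple[FacialCodingRecord, MissingFlags]:
    """Apply the missing-data cascade; exclusion is a state, not an error.

    Order: symmetry (already resolved upstream by the coder; flag passed
    through) → per-action constancy fill → constellation-level proration
    eligibility → exclusion. Proration itself is performed at scoring time
    (it yields a total, not filled cells); this function decides and flags
    which path applies. Observed cells are never changed.
    """
    flags = MissingFlags(symmetry_used=record.symmetry_used)
    values = record.values.copy()

    constancy_ok = (
        record.cry_constant is True
        and record.body_constant is True
        and not record.coder_override
    )
    if constancy_ok:
        for ai, action in enumerate(ACTIONS):
            row = values[ai]
            n_obs = int((~np.isnan(row)).sum())
            if n_obs < row.size and n_obs / row.size >= min_fraction:
                filled, fb = _fill_constant_row(row)
                values[ai] = filled
                flags.constancy_used = True
                flags.constancy_actions.append(action)
                flags.forward_fill_fallback |= fb

    rows = [ACTIONS.index(a) for a in CONSTELLATIONS[constellation]]
    sub = values[rows]
    n_missing = int(np.isnan(sub).sum())
    if n_missing:
        observed_fraction = 1.0 - n_missing / sub.size
        if observed_fraction >= min_fraction:
            flags.prorated = True
        else:
            flags.excluded = True

    return replace(record, values=values), flags


def score_constellation(
    record: FacialCodingRecord,
    constellation: str,
    flags: MissingFlags | None = None,
) -> NFCSScore:
    """Sum the binary cells of the constellation's actions over 10 seconds.

    Requires a complete matrix for those actions unless *flags* marks the
    record as prorated (total = observed_sum × total_cells/observed_cells,
    capped at the maximum) or excluded (total = NaN).
    """
    if constellation not in CONSTELLATIONS:
        raise KeyError(f"unknown constellation {constellation!r}")
    rows = [ACTIONS.index(a) for a in CONSTELLATIONS[constellation]]
    sub = record.values[rows]
    max_score = sub.size  # 70 or 30
    flags = flags or MissingFlags()

    n_missing = int(np.isnan(sub).sum())
    if n_missing == 0:
        total = float(np.nansum(sub))
    elif flags.prorated:
        observed = sub[~np.isnan(sub)]
        total = float(observed.sum() * sub.size / observed.size)
        if total > max_score:
            total = float(max_score)
            flags.capped = True
    elif flags.excluded:
        total = float("nan")
    else:
        raise ValueError(
            f"{n_missing} unresolved missing cells for {constellation}; "
            "run handle_missing first"
        )
    return NFCSScore(
        constellation=constellation, epoch=record.epoch, total=total,
        max_score=max_score, flags=flags, subject_id=record.subject_id,
    )


def score_record(record: FacialCodingRecord, constellation: str) -> NFCSScore:
    """Missing-data cascade followed by scoring, in one call."""
    filled, flags = handle_missing(record, constellation)
    return score_constellation(filled, constellation, flags)


def scale_to_30(total_0_to_70: float) -> float:
    """Linearly rescale an NFCS-7 total (0–70) onto the 0–30 range."""
    if not 0.0 <= total_0_to_70 <= 70.0:
        raise ValueError("NFCS-7 total must lie in [0, 70]")
    return total_0_to_70 * 30.0 / 70.0


def classify_clinical(
    score: NFCSScore | float, threshold: float = CLINICAL_THRESHOLD
) -> ClinicalGroup:
    """Clinical-significance split on the reactivity total (0–30 scale).

    Totals ≥ threshold (default 9/30) are clinically significant
    pain-related facial activity; the grouping is defined on poststimulus
    scores only, so a baseline score raises.
    """
    if isinstance(score, NFCSScore):
        if score.epoch != "reactivity":
            raise ValueError("clinical grouping is defined on reactivity scores")
        total = score.total
        if score.max_score != 30:
            total = scale_to_30(total)
    else:
        total = float(score)
    label = "NFCS-clinical" if total >= threshold else "NFCS-subclinical"
    return ClinicalGroup(label=label, threshold=threshold)


# ---------------------------------------------------------------------------
# constellation-comparison statistics
# ---------------------------------------------------------------------------

def _wilcoxon_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Signed-rank Z (normal approximation, continuity-corrected) and p.

    Exact p below n=10 pairs (after dropping zero differences), normal
    approximation with tie-corrected variance otherwise.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    method = "exact" if n < 10 else "approx"
    res = stats.wilcoxon(d, method=method, correction=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
    cc = 0.5 * np.sign(w_plus - mu) if w_plus != mu else 0.0
    z = (w_plus - mu - cc) / np.sqrt(var) if var > 0 else 0.0
    return float(z), float(res.pvalue)


def _friedman_two(x: np.ndarray) -> dict:
    """Tie-corrected Friedman χ² for exactly two paired columns."""
    n, k = x.shape
    ranks = stats.rankdata(x, axis=1)
    col_sums = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * (col_sums**2).sum() - 3.0 * n * (k + 1)
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    c = 1.0 - ties / (n * (k**3 - k))
    chi2 = q / c if c > 0 else 0.0
    return {"chi2": float(chi2), "df": k - 1,
            "p": float(stats.chi2.sf(chi2, k - 1))}


def compare_constellations(
    scores: pd.DataFrame, groups: pd.Series | None = None
) -> dict:
    """Nonparametric comparison of constellation totals.

    Parameters
    ----------
    scores
        Subjects × constellations table of totals on a common scale
        (NFCS-7 pre-scaled to 0–30 by the caller where intended).
    groups
        Optional per-subject cohort labels (exactly two levels) for
        between-cohort Mann–Whitney U tests per constellation.

    Returns a dict with the Friedman χ²/df/p across constellations,
    pairwise Wilcoxon signed-rank Z and p, and (if *groups* is given)
    per-constellation Mann–Whitney U and p between the two cohorts.
    """
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 constellations")
    if scores.shape[0] < 3:
        raise ValueError("Friedman test needs at least 3 subjects")
    cols = [scores[c].to_numpy(dtype=float) for c in scores.columns]

    if all(np.array_equal(cols[0], c) for c in cols[1:]):
        friedman = {"chi2": 0.0, "df": scores.shape[1] - 1, "p": 1.0}
    elif scores.shape[1] >= 3:
        f = stats.friedmanchisquare(*cols)
        friedman = {"chi2": float(f.statistic), "df": scores.shape[1] - 1,
                    "p": float(f.pvalue)}
    else:
        friedman = _friedman_two(np.column_stack(cols))

    pairwise = {}
    for a, b in combinations(scores.columns, 2):
        z, p = _wilcoxon_z(scores[a].to_numpy(), scores[b].to_numpy())
        pairwise[(a, b)] = {"z": z, "p": p}

    report = {"friedman": friedman, "wilcoxon": pairwise}

    if groups is not None:
        levels = pd.unique(groups)
        if len(levels) != 2:
            raise ValueError("Mann-Whitney comparison needs exactly 2 cohorts")
        mw = {}
        for c in scores.columns:
            x = scores.loc[groups == levels[0], c].to_numpy(dtype=float)
            y = scores.loc[groups == levels[1], c].to_numpy(dtype=float)
            method = "exact" if (len(x) < 10 and len(y) < 10) else "asymptotic"
            r = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            mw[c] = {"u": float(r.statistic), "p": float(r.pvalue)}
        report["mannwhitney"] = {"groups": tuple(levels), "tests": mw}

    return report


def icc_two_way(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is subjects × raters, complete. Computed from the two-way
    ANOVA mean squares::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    With zero between-subject variance the coefficient is undefined; the
    defined limit 0 is returned with a warning.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be subjects x raters with >=2 of each")
    if np.isnan(x).any():
        raise ValueError("ratings must be complete")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or np.isclose(msr, 0) and np.isclose(denom, 0):
        warnings.warn("zero between-subject variance; ICC undefined, returning 0")
        return 0.0
    return float((msr - mse) / denom)
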