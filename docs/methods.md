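# Methods

This note documents the models and procedures implemented in `neopain`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. What the synthetic cohorts emulate

The package is exercised on ground-truthed synthetic data standing in
for stimulus-locked neonatal recordings: 18 scalp electrodes on the
10/20 system (visual O1/O2, auditory T7/T8, association
F7/F3/F4/F8/P7/P8/TP9/TP10, somatosensory C3/Cz/C4/CP3/CPz/CP4; Fz was
the acquisition reference and does not re-enter the montage after
common-average re-referencing, though the montage is configurable),
epochs from 500 ms before to 1000 ms after the stimulus trigger.

**EEG generator.** Each subject's epoch is

    x(t) = Σ_e a_e · u_{m(e)} · w(t; o_e + δ, d_e)  +  n(t)

where `u_m` are average-referenced, unit-GFP, mutually orthogonal
template maps (random spatially smoothed vectors, Gram–Schmidt within
the zero-sum subspace), `w` is a boxcar over `[o, o+d)` with half-cosine
edges (ramp 20 ms), δ is per-subject Gaussian onset jitter truncated so
events stay inside the epoch, and `n` is per-channel 1/f^α noise
(α = 1) mixed across electrodes by a Gaussian kernel over unit-sphere
electrode distances (width 0.6 chord units) and scaled so that the
epoch-wise SNR — signal RMS over noise RMS across all channels and
samples — equals the requested value. Everything is average-referenced;
`snr = inf` gives noise-free epochs, zero-amplitude scripts get unit-RMS
noise.

*Canonical 4-state script.* Onsets 40/260/480/740 ms, durations
150/150/170/200 ms, amplitude 4 µV per state (grand-average GFP in the
few-µV range typical of neonatal ERPs), default SNR 5, jitter SD 6 ms.
Two timing properties are deliberate identifiability choices for the
planted ground truth: inter-state gaps of at least 70 ms keep states
disjoint under latency shifts up to 60 ms, and the jitter SD is small
because correlation-based activation detection follows the earliest and
latest subjects — a measured event widens by roughly the realized jitter
*range* (≈3.7·SD at n = 20), and at SD 10 ms that widening alone would
exceed the recovery tolerances regardless of noise level. The trigger in
the emulated protocol is accelerometer-locked, so small jitter is also
physically plausible; the consistency-test window nevertheless starts at
−200 ms to absorb trigger uncertainty, as in the clinical protocol.

**Facial generator.** 7 actions × 10 s binary matrices per epoch
(baseline and reactivity), per-second Bernoulli presence with per-group
probabilities (defaults 0.8 vs 0.1 — two groups at the extremes of the
0–30 range, reproducing the strongly bimodal clinical distribution of
poststimulus totals; baseline presence 0.02). Obstruction bouts arrive
Poisson (rate 0.5/epoch) with geometric lengths (mean 2 s, capped at the
epoch); obstructed seconds become missing cells with reason code
`obstruction`, and cry/body-movement constancy holds with probability
0.8 during obstructed epochs.

What the generators do **not** emulate: volume conduction and realistic
neonatal head geometry, artifacts (ECG, movement), non-stationary or
state-dependent noise, coder disagreement, and any correlation between a
subject's facial score and their EEG beyond group membership. Passing
tests therefore show the *statistical machinery* behaves as specified
under its own assumptions, not that those assumptions hold in clinical
recordings.

## 2. NFCS scoring and missing data

Constellations: NFCS-7 (all actions, epoch max 70), NFCS-3 (eye squeeze,
vertical stretch mouth, horizontal stretch mouth) and NFCS-P-3 (brow
bulge, eye squeeze, nasolabial furrow), both max 30. NFCS-7 totals are
rescaled by 30/70 when compared on the 0–30 scale, per subject before
averaging. The clinical threshold is 9/30 on the reactivity NFCS-P-3
total (≥ 9 → clinically significant); the grouping is defined on
poststimulus scores only and a baseline score raises.

Missing cells are resolved in a fixed cascade, mirroring the order in
which the rules are applied clinically:

1. **Symmetry** — judged by the coder upstream; carried as a flag.
2. **Constancy**, per action: if ≥60% of that action's 10 s is codable
   *and* cry and body movement stayed constant *and* the coder did not
   override, missing cells are filled with the closest preceding
   observed value (closest following, flagged, if a gap opens the
   epoch). Observed cells are never changed.
3. **Proration**, per constellation: if missing cells remain but ≥60% of
   the constellation's 30 (or 70) cells are observed, the total is
   `observed_sum × total_cells / observed_cells` (a guard caps at the
   maximum, though binary cells cannot exceed it).
4. **Exclusion** otherwise — a state, not an exception.

The 60% and 9/30 thresholds are configuration values with these
defaults. Constellation comparisons use Friedman (scipy for ≥3 paired
columns; a tie-corrected rank implementation for the 2-column case that
scipy rejects), pairwise Wilcoxon signed-rank (exact p below 10 nonzero
pairs, tie-corrected continuity-corrected normal Z otherwise) and
Mann–Whitney U between cohorts. Interrater reliability is ICC(2,1) —
two-way random effects, absolute agreement, single rater — computed from
the ANOVA mean squares, with 0 returned (with a warning) in the
degenerate zero-variance limit; pingouin serves as an independent
cross-check in the tests, not as the implementation.

## 3. Signal conditioning

Zero-phase ("bidirectional", i.e. forward–backward `filtfilt`)
second-order Butterworth band-pass 1–30 Hz followed by a second-order
band-stop 48–52 Hz; the effective magnitude response is fourth-order.
Filters apply to continuous data before epoching — a 1 Hz high-pass
applied to an already-epoched 1.5 s window distorts slow quasi-stable
states, which is why the analysis drivers demonstrate the filters on a
continuous trace and run the (already band-limited) synthetic epochs
through re-referencing only. Epochs are half-open `[start, end)` windows
with `round((end−start)·fs/1000)` samples and t = 0 at the trigger;
onsets may legitimately be negative. Common-average re-referencing is
idempotent and makes every map sum to zero (tolerance 10⁻⁶ µV).
Channels that could not be recorded or cleaned are reconstructed by
spherical-spline interpolation (order m = 4, Legendre series truncated
at 7 terms, ridge 10⁻⁸ for conditioning) on idealized unit-sphere 10/20
coordinates, capped at 4 bad channels per subject — the cap reflects the
worst case observed clinically. Component-based denoising is a no-op
hook: the pipeline accepts pre-cleaned data, because component selection
is a manual, recording-specific judgement.

## 4. Randomization statistics

All permutation p-values use the add-one estimator
`p = (1 + #{null ≥ observed}) / (1 + B)` with permutations sampled with
replacement (the identity included in the null's support), which keeps
them valid at any B. Significance masks are filtered by the run-length
rule — only periods continuously significant for at least 5% of the
tested window survive (75 ms for −500…1000 ms, 60 ms for −200…1000 ms,
50 ms for 0…1000 ms). The filter can only remove significance, never
create it; the trade-off is insensitivity to genuinely brief effects
(the analysis drivers show a 60 ms planted latency shift that the
TANOVA cannot report precisely because each discrepancy window it
creates is shorter than the 75 ms floor).

**TANOVA.** Observed statistic: DISS between the two group-average maps
at each timepoint, i.e. computed on group averages rather than averaged
over per-subject DISS values, and on GFP-normalized maps (a config
toggle disables normalization). Null: subject labels permuted across
groups, preserving sizes. Timepoints where either group average is flat
get p = 1 (DISS undefined; conservatively nonsignificant).

**TCT.** Observed statistic: GFP of the grand average. Null: each
subject's channels shuffled by an independent permutation, drawn per
subject per iteration and shared across that iteration's timepoints —
the per-timepoint test is identical to drawing fresh permutations per
timepoint, and sharing makes the nulls temporally coherent and the
computation one gather per iteration.

**Activation gating.** Back-fitting uses
cₘ(t) = max(r(map(t), uₘ), 0)² in the polarity-sensitive ERP convention
(anticorrelated orientations explain nothing; a polarity-insensitive
toggle squares the raw correlation). The null at each timepoint is the
c-value of baseline topographies — drawn with replacement from the pool
of every subject's prestimulus maps, one shared draw per test — against
the group-average map at that timepoint; within one two-group
comparison both groups face the same draw, so identical averages yield
identical masks. Zero-GFP timepoints are masked invalid.

**Events.** Contiguous supra-threshold runs (after the run-length rule
over the postlance window) are candidate events; two runs of one
template merge when their gap does not exceed that template's mean run
duration pooled across occurrences and groups (a single-pass rule using
the pre-merge mean). Onset is the first active sample, duration the run
length, power ∫ GFP(t)·cₘ(t) dt in µV·ms. Extraction is deterministic
given masks and series.

## 5. Microstate identification and model selection

Pooled maps are the grand-average topographies at TCT-consistent
latencies from all groups, GFP-normalized. Clustering is an
atomize-and-agglomerate hierarchy (AAHC): every map starts as its own
cluster; the cluster contributing least summed squared correlation to
its template is dissolved and its members reassigned to their
best-matching remaining template (signed correlation when
polarity-sensitive); affected templates are recomputed as the
orientation-consistent member mean (first principal orientation in the
polarity-insensitive mode). Ties resolve to the lowest index, making
the procedure deterministic. One descent records the template set at
every k in the search range. Final templates are renormalized to unit
GFP and ordered by their members' mean latency so labels follow the
evoked sequence.

k is selected by subject-level split-half cross-validation (default 100
iterations, 50/50 split within each group): train-half grand averages
are clustered, and the held-out explained variance
`Σ_t (GFP_t · max_m r_t,m)² / Σ_t GFP_t²` is evaluated on the test-half
grand averages. Because the best-of-k correlation grows with k even on
structureless maps (an order-statistics effect of roughly 1–2
percentage points per added template at 18 channels), each iteration
also scores the same templates against channel-shuffled copies of the
held-out maps, and this chance curve is subtracted before the elbow
rule. k* is the largest k whose marginal chance-corrected gain still
reaches one percentage point (configurable); a structureless cohort
therefore yields the smallest k in the range. The raw (uncorrected)
curve is reported alongside, since its plateau value is the "% of
signal explained" quantity of interest.

## 6. Group comparison

Observed differences: both group averages are back-fitted with the
shared template set, gated with one shared baseline-null draw, events
extracted with the pooled merge rule and matched across groups by
template and comparable latency (interval overlap, else nearest onsets
within 300 ms, greedy per template; unmatched events are reported as
incomparable rather than tested). Tested parameters: onset, duration
and power per matched pair, plus total field power (mean GFP over the
postlance second). Two-tailed p uses the add-one estimator on
|difference|; the significance threshold is p < 0.025.

The null re-forms the two groups at random from the pooled original
subjects (sizes preserved), refits, re-extracts and re-matches; a pair
absent in an iteration contributes nothing to that pair's null (the
usable count is reported). Under exchangeable subjects this
re-randomization is calibrated by construction, and because it retains
the shared evoked structure its null spread reflects parameter
estimation noise — which is what gives the test power against, e.g., a
60 ms latency shift. A common-phase spectral surrogate generator
(`surrogate="phase"`: one random phase sequence applied to every
channel, preserving per-channel amplitude spectra and the instantaneous
cross-channel structure while destroying stimulus locking) is
implemented behind the same interface; it tests the broader null of *no
stimulus-locked structure at all* and is deliberately conservative for
latency parameters, because its null onsets are spread over the whole
analysis window. It is provided for sensitivity analyses, not as the
default.

Demographic statistics are pooled-variance two-sample t (Welch
available) computed from printed summary rows, and uncorrected Pearson
χ² for 2×2 count tables.

## 7. Numerical conventions and degenerate inputs

- Time in ms, half-open windows, t = 0 at the trigger; µV throughout;
  power in µV·ms (an occasionally seen "ms²" labelling of this quantity
  is treated as a units typo, not a different quantity).
- Average-reference tolerance 10⁻⁶ µV on containers, 10⁻⁹ on templates.
- Flat maps: GFP 0 is legal; DISS with a flat input raises in the
  scalar API and is assigned p = 1 inside TANOVA; back-fitting masks
  zero-GFP timepoints.
- Stage seeds derive from one master seed through a SeedSequence mixed
  with a CRC32 of the stage name — independent streams, stable under
  adding stages, always below 2³¹.
- Tie-breaks: AAHC dissolution and reassignment prefer the lowest
  index; rank ties use average ranks with tie-corrected variances.

## 8. Problem sizes

Defaults embed the study-scale constants (5000 randomization
iterations, 100 CV iterations, 18 channels, 2 kHz supported). The test
suite and analysis drivers run the same code at desk scale as the
package's own verification conditions: 500 Hz (drivers 250 Hz), 12–20
subjects per group, nulls of 200–2000 iterations, and calibration
studies of 50 simulations × 200 iterations per test. The pipeline-level
recovery conditions are a 4-state script at SNR 5, n = 20 per group,
500 Hz.

## 9. Known limitations

- The AAHC variant is one reasonable member of that family; other
  implementations differ in the dissolution criterion and template
  update, and template sets need not coincide on real, noisy data.
- Event boundaries from correlation-based gating are ensemble
  boundaries: they track the earliest/latest subjects, so durations are
  biased upward by the jitter range. The synthetic scripts are designed
  so this bias stays small relative to state length; on real data with
  larger latency variability, reported durations should be read
  accordingly.
- The baseline-topography null is evaluated against group-average maps
  (the fitted object), not per-subject maps; this follows the fitting
  target but is a sensitivity-analysis candidate.
- The reassignment null tests group exchangeability; it cannot separate
  *which* parameter differs when several covary (a latency shift also
  perturbs neighbouring-state overlap on real data).
- EDF is read (via mne) but not written; the canonical on-disk format
  is a delimited dump + JSON sidecar, chosen to keep every artifact
  plain text.
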