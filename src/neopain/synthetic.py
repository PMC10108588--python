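"""Ground-truthed synthetic cohorts: scripted ERP microstates and NFCS tables.

The EEG generator emulates stimulus-locked neonatal epochs: each subject's
epoch is a scripted sequence of quasi-stable scalp topographies (unit-GFP,
average-referenced templates switched on for fixed intervals with
half-cosine onset/offset ramps and per-subject onset jitter) embedded in
spatially smoothed 1/f noise calibrated to a requested epoch-wise SNR.

The facial generator emulates second-by-second binary NFCS coding with
obstruction-driven missingness: per-action Bernoulli presence, Poisson
obstruction bouts with geometric lengths, and cry/body constancy flags.
Choosing well-separated per-action probabilities for the two groups
reproduces the bimodal total-score distribution seen clinically (most
subjects at the extremes of the 0–30 range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet
from .facial import ACTIONS, EPOCH_SECONDS, FacialCodingRecord
from .montage import DEFAULT_MONTAGE, adjacency_weights

__all__ = [
    "MicrostateScript",
    "SyntheticCohortSpec",
    "FacialSimSpec",
    "GroundTruth",
    "make_templates",
    "four_state_script",
    "generate_erp_cohort",
    "generate_facial_cohort",
]


# ---------------------------------------------------------------------------
# EEG cohort
# ---------------------------------------------------------------------------

@dataclass
class MicrostateScript:
    """Scripted sequence of template activations for one group.

    entries: (template_id, onset_ms, duration_ms, amplitude_uV), sorted by
    onset. Templates are average-referenced unit-GFP channel vectors.
    """

    entries: list[tuple[str, float, float, float]]
    templates: dict[str, np.ndarray]
    jitter_sd_ms: float = 10.0
    snr: float = 5.0

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e[1])
        for tid, onset, dur, amp in self.entries:
            if tid not in self.templates:
                raise ValueError(f"entry references unknown template {tid!r}")
            if dur <= 0:
                raise ValueError("durations must be positive")
            if amp < 0:
                raise ValueError("amplitudes must be nonnegative")
        if self.jitter_sd_ms < 0 or not self.snr > 0:
            raise ValueError("jitter_sd_ms >= 0 and snr > 0 required")
        for tid, v in self.templates.items():
            v = np.asarray(v, dtype=float)
            if abs(v.mean()) > 1e-9:
                raise ValueError(f"template {tid!r} not average-referenced")
            if abs(v.std() - 1.0) > 1e-9:
                raise ValueError(f"template {tid!r} does not have unit GFP")
            self.templates[tid] = v

    @property
    def n_channels(self) -> int:
        return next(iter(self.templates.values())).size


@dataclass
class SyntheticCohortSpec:
    """Study conditions for one two-group synthetic EEG cohort."""

    n_subjects_per_group: int
    group_scripts: dict[str, MicrostateScript]
    n_channels: int = 18
    fs_hz: float = 500.0
    epoch_window_ms: tuple[float, float] = (-500.0, 1000.0)
    pink_exponent: float = 1.0
    spatial_smoothing_width: float = 0.6
    ramp_ms: float = 20.0
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if len(self.group_scripts) != 2:
            raise ValueError("exactly 2 group scripts required")
        if self.n_channels < 4:
            raise ValueError("need at least 4 channels")
        lo, hi = self.epoch_window_ms
        if not (lo < 0.0 <= hi):
            raise ValueError("epoch window must contain the stimulus (t=0)")
        if len(self.montage) != self.n_channels:
            # generic labels when the study montage does not apply
            self.montage = tuple(f"ch{i:02d}" for i in range(self.n_channels))
        for name, script in self.group_scripts.items():
            if script.n_channels != self.n_channels:
                raise ValueError(f"script {name!r} channel count mismatch")
            for tid, onset, dur, _ in script.entries:
                if onset < lo or onset + dur > hi:
                    raise ValueError(
                        f"event {tid!r} [{onset}, {onset + dur}) ms exits the epoch"
                    )


@dataclass
class GroundTruth:
    """Realized per-subject scripts and the shared template dictionary."""

    templates: dict[str, np.ndarray]
    #: group -> list (per subject) of realized (template_id, onset, duration, amplitude)
    events: dict[str, list[list[tuple[str, float, float, float]]]]
    scripts: dict[str, MicrostateScript] | None = None
    meta: dict = field(default_factory=dict)


def make_templates(
    n_channels: int,
    k: int,
    seed: int | np.random.Generator = 0,
    montage: tuple[str, ...] | None = None,
    smooth: bool = True,
) -> dict[str, np.ndarray]:
    """k mutually orthogonal, average-referenced, unit-GFP template maps.

    Random vectors are spatially smoothed over the electrode adjacency (so
    the maps look like scalp fields rather than salt-and-pepper noise),
    projected onto the zero-mean subspace, orthonormalized and scaled to
    unit GFP (RMS 1).
    """
    if k > n_channels - 1:
        raise ValueError("at most n_channels-1 orthogonal zero-mean maps exist")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((k, n_channels))
    if smooth and montage is not None and len(montage) == n_channels:
        raw = raw @ adjacency_weights(tuple(montage)).T
    raw -= raw.mean(axis=1, keepdims=True)
    # Gram-Schmidt within the zero-mean subspace
    out = []
    for v in raw:
        for u in out:
            v = v - (v @ u) / (u @ u) * u
        if np.linalg.norm(v) < 1e-12:
            raise RuntimeError("degenerate template draw")
        out.append(v)
    templates = {}
    for i, v in enumerate(out):
        v = v - v.mean()
        templates[f"M{i + 1}"] = v / v.std()
    return templates


def four_state_script(
    templates: dict[str, np.ndarray] | None = None,
    n_channels: int = 18,
    montage: tuple[str, ...] = DEFAULT_MONTAGE,
    seed: int = 0,
    onset_shift_ms: dict[str, float] | None = None,
    amplitude_uV: float = 4.0,
    jitter_sd_ms: float = 6.0,
    snr: float = 5.0,
) -> MicrostateScript:
    """The study's canonical 4-state poststimulus script.

    Four sequential, non-overlapping activations in the first second after
    the stimulus (onsets 40/260/480/740 ms, durations 150/150/170/200 ms),
    echoing the serial engagement of pain-related networks. Inter-state
    gaps of ≥70 ms keep the states disjoint even under latency shifts up
    to 60 ms, and state durations of ≥150 ms keep the additive run
    widening of null-gated activation (on the order of the ramp width
    plus the onset jitter) small relative to each state's length — both
    are identifiability choices for the planted ground truth. Amplitude
    4 µV per state puts grand-average GFP in the few-µV range typical of
    neonatal ERPs. Onset jitter (default SD 6 ms) reflects a small,
    accelerometer-locked trigger uncertainty; because correlation-based
    activation detection follows the earliest and latest subjects, the
    expected jitter *range* across 20 subjects (≈3.7 SD) is what widens a
    measured event, and 6 ms keeps that widening within the ground
    truth's recovery tolerances. ``onset_shift_ms`` shifts named states
    to build group differences with known ground truth.
    """
    if templates is None:
        templates = make_templates(n_channels, 4, seed=seed, montage=montage)
    ids = list(templates)
    base = [
        (ids[0], 40.0, 150.0),
        (ids[1], 260.0, 150.0),
        (ids[2], 480.0, 170.0),
        (ids[3], 740.0, 200.0),
    ]
    shift = onset_shift_ms or {}
    entries = [
        (tid, onset + shift.get(tid, 0.0), dur, amplitude_uV)
        for tid, onset, dur in base
    ]
    return MicrostateScript(entries=entries, templates=dict(templates),
                            jitter_sd_ms=jitter_sd_ms, snr=snr)


def _envelope(times_ms: np.ndarray, onset: float, duration: float,
              ramp_ms: float) -> np.ndarray:
    """Boxcar over [onset, onset+duration) with half-cosine edges inside."""
    ramp = min(ramp_ms, duration / 2.0)
    t = times_ms
    env = np.zeros_like(t)
    inside = (t >= onset) & (t < onset + duration)
    env[inside] = 1.0
    if ramp > 0:
        rise = inside & (t < onset + ramp)
        env[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - onset) / ramp))
        fall = inside & (t >= onset + duration - ramp)
        env[fall] = 0.5 * (1 - np.cos(np.pi * (onset + duration - t[fall]) / ramp))
    return env


def _pink_noise(rng: np.random.Generator, n_channels: int, n_times: int,
                exponent: float) -> np.ndarray:
    """Per-channel 1/f^exponent Gaussian noise, unit variance per channel."""
    freqs = np.fft.rfftfreq(n_times, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * scale
    x = np.fft.irfft(spec, n=n_times, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_erp_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[dict[str, EpochSet], GroundTruth]:
    """Simulate one epoch per subject for two groups, with ground truth.

    Per subject: signal = Σ entries amplitude × template × ramped boxcar
    (onset jittered by a truncated Gaussian so events stay inside the
    epoch), plus spatially smoothed pink noise scaled so the epoch-wise
    SNR (signal RMS / noise RMS over all channels and samples) equals the
    script's ``snr``. Everything is average-referenced; ``snr=inf`` gives
    noise-free epochs; zero-amplitude scripts get unit-RMS noise.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.epoch_window_ms
    n_times = int(round((hi - lo) * spec.fs_hz / 1000.0))
    times = lo + np.arange(n_times) * 1000.0 / spec.fs_hz
    try:
        mix = adjacency_weights(tuple(spec.montage))
    except ValueError:  # no idealized positions (generic labels): no mixing
        mix = np.eye(spec.n_channels)

    groups: dict[str, EpochSet] = {}
    truth_events: dict[str, list] = {}
    all_templates: dict[str, np.ndarray] = {}
    for gname, script in spec.group_scripts.items():
        all_templates.update(script.templates)
        data = np.empty((spec.n_subjects_per_group, spec.n_channels, n_times))
        realized: list[list[tuple[str, float, float, float]]] = []
        for s in range(spec.n_subjects_per_group):
            sig = np.zeros((spec.n_channels, n_times))
            events = []
            for tid, onset, dur, amp in script.entries:
                if script.jitter_sd_ms > 0:
                    j_lo, j_hi = lo - onset, hi - (onset + dur)
                    jit = float(np.clip(rng.normal(0.0, script.jitter_sd_ms),
                                        j_lo, j_hi))
                else:
                    jit = 0.0
                o = onset + jit
                sig += amp * np.outer(script.templates[tid],
                                      _envelope(times, o, dur, spec.ramp_ms))
                events.append((tid, o, dur, amp))
            noise = mix @ _pink_noise(rng, spec.n_channels, n_times,
                                      spec.pink_exponent)
            noise -= noise.mean(axis=0, keepdims=True)
            sig_rms = np.sqrt(np.mean(sig**2))
            noise_rms = np.sqrt(np.mean(noise**2))
            if np.isinf(script.snr):
                noise[:] = 0.0
            elif sig_rms > 0:
                noise *= sig_rms / (script.snr * noise_rms)
            else:
                noise /= noise_rms
            epoch = sig + noise
            epoch -= epoch.mean(axis=0, keepdims=True)
            data[s] = epoch
            realized.append(events)
        groups[gname] = EpochSet(data=data, fs_hz=spec.fs_hz, tmin_ms=lo,
                                 montage=tuple(spec.montage),
                                 reference="common_average")
        truth_events[gname] = realized

    truth = GroundTruth(templates=all_templates, events=truth_events,
                        scripts=dict(spec.group_scripts),
                        meta={"seed": spec.seed, "fs_hz": spec.fs_hz,
                              "window_ms": spec.epoch_window_ms})
    return groups, truth


# ---------------------------------------------------------------------------
# facial-coding cohort
# ---------------------------------------------------------------------------

@dataclass
class FacialSimSpec:
    """Study conditions for a synthetic facial-coding cohort.

    ``p_action`` maps group label → per-second presence probability during
    reactivity, either a scalar or one probability per action. Defaults
    (0.8 vs 0.1) put the two groups at the extremes of the score range,
    reproducing the bimodal clinical distribution. Obstruction bouts
    arrive as a Poisson count per epoch with geometric lengths.
    """

    n_subjects_per_group: int
    p_action: dict[str, float | np.ndarray] = None  # type: ignore[assignment]
    baseline_p: float = 0.02
    obstruction_rate: float = 0.5  # mean bouts per epoch
    obstruction_mean_len_s: float = 2.0  # geometric mean bout length, >= 1
    p_constancy: float = 0.8  # P(cry & body movement constant during bouts)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_action is None:
            self.p_action = {"high": 0.8, "low": 0.1}
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least 1 subject per group")
        for g, p in self.p_action.items():
            p = np.broadcast_to(np.asarray(p, dtype=float), (len(ACTIONS),)).copy()
            if ((p < 0) | (p > 1)).any():
                raise ValueError(f"probabilities for group {g!r} outside [0,1]")
            self.p_action[g] = p
        if not 0 <= self.baseline_p <= 1 or not 0 <= self.p_constancy <= 1:
            raise ValueError("probabilities must lie in [0,1]")
        if self.obstruction_rate < 0 or self.obstruction_mean_len_s < 1:
            raise ValueError("obstruction bouts must have rate >= 0, length >= 1 s")


def generate_facial_cohort(
    spec: FacialSimSpec,
) -> tuple[list[FacialCodingRecord], dict]:
    """Simulate baseline + reactivity coding records with obstruction.

    Returns the records (two per subject) and a ground truth dict with the
    complete pre-obstruction matrices and true totals per constellation.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[FacialCodingRecord] = []
    truth: dict = {"true_values": {}, "true_totals": {}, "group": {}}

    for gname, p in spec.p_action.items():
        for s in range(spec.n_subjects_per_group):
            sid = f"{gname}-{s:03d}"
            truth["group"][sid] = gname
            for epoch, probs in (("baseline", np.full(len(ACTIONS), spec.baseline_p)),
                                 ("reactivity", p)):
                full = (rng.random((len(ACTIONS), EPOCH_SECONDS))
                        < probs[:, None]).astype(float)
                values = full.copy()
                reasons = np.full(values.shape, None, dtype=object)
                n_bouts = rng.poisson(spec.obstruction_rate)
                obstructed = np.zeros(EPOCH_SECONDS, dtype=bool)
                for _ in range(n_bouts):
                    length = min(int(rng.geometric(1.0 / spec.obstruction_mean_len_s)),
                                 EPOCH_SECONDS)
                    start = int(rng.integers(0, EPOCH_SECONDS - length + 1))
                    obstructed[start:start + length] = True
                if obstructed.any():
                    values[:, obstructed] = np.nan
                    reasons[:, obstructed] = "obstruction"
                constant = bool(rng.random() < spec.p_constancy)
                rec = FacialCodingRecord(
                    subject_id=sid, epoch=epoch, values=values, reasons=reasons,
                    cry_constant=constant if obstructed.any() else True,
                    body_constant=constant if obstructed.any() else True,
                    group=gname,
                )
                records.append(rec)
                truth["true_values"][(sid, epoch)] = full
                truth["true_totals"][(sid, epoch)] = {
                    name: float(full[[ACTIONS.index(a) for a in acts]].sum())
                    for name, acts in
                    (("NFCS-7", ACTIONS),
                     ("NFCS-3", ("eye squeeze", "vertical stretch mouth",
                                 "horizontal stretch mouth")),
                     ("NFCS-P-3", ("brow bulge", "eye squeeze",
                                   "nasolabial furrow")))
                }
    return records, truth
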