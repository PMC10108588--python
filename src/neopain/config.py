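"""Structured run configuration with study-constant defaults.

Every tunable of the pipeline lives here with its clinical-study default:
band-pass 1–30 Hz, notch 48–52 Hz, epoch −500…1000 ms, TCT window
−200…1000 ms, 5000 randomization iterations, 100 cross-validation
iterations, 5% run-length rule, clinical threshold 9/30, α = 0.05
(right-tailed randomizations) and 0.025 (two-tailed parameter
comparisons). Configs round-trip losslessly through YAML; unknown keys
are rejected with the path to the offending field. Stage seeds are
derived from the single master seed by a documented splitting rule.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["RunConfig", "validate_config", "stage_seed"]

_STAGES = ("simulate_eeg", "simulate_facial", "preprocess", "tct", "tanova",
           "microstates", "compare")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31.

    Mixes the master seed with a CRC32 of the stage name through a
    SeedSequence, so stages are statistically independent and adding a
    stage never perturbs the others.
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the study constants."""

    seed: int  # master seed, mandatory
    out_dir: str = "results/pipeline"
    cohorts: tuple[str, ...] = ("preterm", "term")
    group_labels: tuple[str, str] = ("subclinical", "clinical")

    # synthetic cohort
    n_subjects_per_group: int = 16
    n_channels: int = 18
    fs_hz: float = 500.0
    epoch_window_ms: tuple[float, float] = (-500.0, 1000.0)
    snr: float = 5.0
    jitter_sd_ms: float = 10.0
    onset_shift_ms: float = 60.0  # clinical-group shift of one scripted state
    facial_p_high: float = 0.8
    facial_p_low: float = 0.1

    # preprocessing
    bandpass_hz: tuple[float, float] = (1.0, 30.0)
    notch_hz: tuple[float, float] = (48.0, 52.0)
    apply_filters: bool = False  # synthetic epochs are already band-limited

    # randomization statistics
    tanova_window_ms: tuple[float, float] = (-500.0, 1000.0)
    tct_window_ms: tuple[float, float] = (-200.0, 1000.0)
    postlance_window_ms: tuple[float, float] = (0.0, 1000.0)
    n_iter_randomization: int = 5000
    n_iter_surrogate: int = 5000
    n_iter_activation: int = 5000
    alpha: float = 0.05
    alpha_two_tailed: float = 0.025
    run_length_fraction: float = 0.05

    # microstates
    k_range: tuple[int, int] = (2, 12)
    cv_iterations: int = 100
    cv_split: float = 0.5
    cv_gain_threshold: float = 0.01
    polarity_sensitive: bool = True

    # facial coding
    clinical_threshold: float = 9.0
    min_codable_fraction: float = 0.6

    version: str = "1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed: every stochastic stage needs an explicit seed")
        checks = {
            "epoch_window_ms": self.epoch_window_ms,
            "tanova_window_ms": self.tanova_window_ms,
            "tct_window_ms": self.tct_window_ms,
            "postlance_window_ms": self.postlance_window_ms,
        }
        for name, (lo, hi) in checks.items():
            if hi <= lo:
                raise ValueError(f"{name}: window end must exceed start")
        for name in ("n_iter_randomization", "n_iter_surrogate",
                     "n_iter_activation", "cv_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name}: iteration count must be positive")
        if not 0 < self.cv_split < 1:
            raise ValueError("cv_split: must lie in (0, 1)")
        if self.k_range[0] < 1 or self.k_range[1] < self.k_range[0]:
            raise ValueError("k_range: need 1 <= k_min <= k_max")
        if not 0 < self.alpha < 1 or not 0 < self.alpha_two_tailed < 1:
            raise ValueError("alpha: significance levels must lie in (0, 1)")

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.seed, stage)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return yaml.safe_dump(d, sort_keys=True)


_TUPLE_FIELDS = {f.name for f in dataclasses.fields(RunConfig)
                 if "tuple" in str(f.type)}


def validate_config(raw: str | dict | None) -> RunConfig:
    """Parse YAML text (or a dict) into a validated RunConfig.

    Unknown keys are rejected; type and range errors carry the field
    name. An empty input is invalid only because ``seed`` is mandatory —
    pass ``{"seed": ...}`` to obtain the full default set.
    """
    if isinstance(raw, str):
        data = yaml.safe_load(raw) or {}
    else:
        data = dict(raw or {})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in data:
        raise ValueError("seed: missing (every run must be explicitly seeded)")
    kwargs = {}
    for key, value in data.items():
        if key in _TUPLE_FIELDS:
            if not isinstance(value, (list, tuple)):
                raise ValueError(f"{key}: expected a 2-element sequence")
            value = tuple(value)
        kwargs[key] = value
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ValueError(f"config type error: {exc}") from exc
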