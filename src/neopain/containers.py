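"""In-memory containers for stimulus-locked epoched EEG.

The analysis works on one fixed-length epoch per subject, time-locked to a
noxious stimulus at t = 0 ms (release of the heel lance). ``EpochSet`` is
the shared substrate of every topographic statistic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import DEFAULT_MONTAGE

#: µV tolerance for the common-average (zero channel-mean) invariant.
AVG_REF_TOL = 1e-6


@dataclass
class EpochSet:
    """Subjects × channels × time stimulus-locked epochs in µV.

    Parameters
    ----------
    data
        Array of shape ``(n_subjects, n_channels, n_times)``.
    fs_hz
        Sampling rate in Hz.
    tmin_ms
        Time of the first sample, in ms relative to the stimulus trigger.
    montage
        Ordered channel names (10/20 labels).
    reference
        ``"original"`` or ``"common_average"``.
    interpolated
        Per-subject list of channel names replaced by interpolation.
    """

    data: np.ndarray
    fs_hz: float
    tmin_ms: float
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    reference: str = "original"
    interpolated: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (subjects, channels, time)")
        if self.data.shape[1] != len(self.montage):
            raise ValueError(
                f"{self.data.shape[1]} channels but {len(self.montage)} montage labels"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite samples in epoch data")
        if not self.interpolated:
            self.interpolated = [[] for _ in range(self.n_subjects)]
        if self.reference == "common_average":
            worst = np.abs(self.data.mean(axis=1)).max() if self.data.size else 0.0
            if worst > AVG_REF_TOL:
                raise ValueError(
                    f"common_average declared but channel means reach {worst:.2g} µV"
                )

    # -- shape accessors ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Strictly increasing time axis in ms, uniform step 1000/fs_hz."""
        return self.tmin_ms + np.arange(self.n_times) * 1000.0 / self.fs_hz

    # -- helpers -----------------------------------------------------------
    def time_index(self, t_ms: float) -> int:
        """Index of the sample closest to *t_ms*."""
        return int(np.argmin(np.abs(self.times_ms - t_ms)))

    def window_slice(self, window_ms: tuple[float, float]) -> slice:
        """Half-open sample slice covering ``[start, end)`` ms."""
        start, end = window_ms
        if end <= start:
            raise ValueError("window end must exceed start")
        t = self.times_ms
        lo = int(np.searchsorted(t, start - 1e-9))
        hi = int(np.searchsorted(t, end - 1e-9))
        if lo == hi:
            raise ValueError(f"window {window_ms} contains no samples")
        return slice(lo, hi)

    def grand_average(self) -> np.ndarray:
        """Channels × time mean across subjects."""
        return self.data.mean(axis=0)

    def copy_with(self, **kw) -> "EpochSet":
        return replace(self, **kw)
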