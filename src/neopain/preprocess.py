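"""Deterministic EEG conditioning: filtering, re-referencing, epoching,
and spherical-spline channel interpolation.

The conditioning chain mirrors standard neonatal ERP practice: a
second-order zero-phase (forward-backward) Butterworth band-pass at
1-30 Hz, a matching band-stop notch at 48-52 Hz for mains interference,
re-referencing to the common average, and extraction of stimulus-locked
epochs from 500 ms before to 1000 ms after the trigger. Channels that were
not recorded or could not be denoised are reconstructed with a
Perrin-style spherical-spline interpolation from the remaining good
channels. Independent-component denoising is intentionally a no-op hook:
the pipeline accepts pre-cleaned data.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre
from scipy import signal

from .containers import EpochSet
from .montage import electrode_positions

__all__ = [
    "bandpass_notch",
    "rereference_common_average",
    "epoch",
    "interpolate_channels",
    "ica_hook",
]


def bandpass_notch(
    data: np.ndarray,
    fs_hz: float,
    band: tuple[float, float] = (1.0, 30.0),
    notch: tuple[float, float] | None = (48.0, 52.0),
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass then band-stop along the last axis.

    "Bidirectional" second-order filtering is realized as forward-backward
    application (filtfilt) of a 2nd-order design, i.e. an effective
    4th-order magnitude response with zero phase shift. Output length
    equals input length.
    """
    data = np.asarray(data, dtype=float)
    if not np.isfinite(data).all():
        raise ValueError("non-finite samples")
    nyq = fs_hz / 2.0
    if band[1] >= nyq or (notch and notch[1] >= nyq):
        raise ValueError("filter edge at or above Nyquist frequency")
    sos = signal.butter(order, band, btype="bandpass", fs=fs_hz, output="sos")
    out = signal.sosfiltfilt(sos, data, axis=-1)
    if notch is not None:
        sos_n = signal.butter(order, notch, btype="bandstop", fs=fs_hz,
                              output="sos")
        out = signal.sosfiltfilt(sos_n, out, axis=-1)
    return out


def rereference_common_average(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous channel mean; idempotent."""
    if epochs.n_channels < 2:
        raise ValueError("common average needs at least 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy_with(data=data, reference="common_average")


def epoch(
    continuous: np.ndarray,
    fs_hz: float,
    triggers: np.ndarray | list[int] | int,
    window_ms: tuple[float, float] = (-500.0, 1000.0),
    montage: tuple[str, ...] | None = None,
) -> EpochSet:
    """Slice stimulus-locked epochs out of continuous data.

    ``continuous`` is channels × time (one recording shared by all
    triggers) or subjects × channels × time with one trigger per subject.
    The window is half-open ``[start, end)`` ms around each trigger sample;
    the sample count is ``round((end-start)*fs/1000)``.
    """
    continuous = np.asarray(continuous, dtype=float)
    trig = np.atleast_1d(np.asarray(triggers, dtype=int))
    lo, hi = window_ms
    if hi <= lo:
        raise ValueError("window end must exceed start")
    n_samp = int(round((hi - lo) * fs_hz / 1000.0))
    off = int(round(lo * fs_hz / 1000.0))

    if continuous.ndim == 2:
        recs = [continuous] * trig.size
    elif continuous.ndim == 3:
        if continuous.shape[0] != trig.size:
            raise ValueError("one trigger per subject required")
        recs = list(continuous)
    else:
        raise ValueError("continuous data must be 2-D or 3-D")

    out = np.empty((trig.size, recs[0].shape[0], n_samp))
    for i, (rec, t) in enumerate(zip(recs, trig)):
        start = t + off
        stop = start + n_samp
        if start < 0 or stop > rec.shape[-1]:
            raise ValueError(
                f"trigger {t} too close to the recording edge for {window_ms}"
            )
        out[i] = rec[:, start:stop]
    if montage is None:
        montage = tuple(f"ch{i:02d}" for i in range(out.shape[1]))
    return EpochSet(data=out, fs_hz=fs_hz, tmin_ms=lo, montage=tuple(montage))


def ica_hook(epochs: EpochSet) -> EpochSet:
    """Placeholder for component-based denoising; returns input unchanged.

    Component selection is a manual, recording-specific step; the pipeline
    expects data that have already been cleaned.
    """
    return epochs


# ---------------------------------------------------------------------------
# spherical-spline interpolation
# ---------------------------------------------------------------------------

def _g_matrix(cosang: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    """Perrin g(cosθ) = (1/4π) Σ_n (2n+1) / (n(n+1))^m  P_n(cosθ)."""
    n = np.arange(1, n_terms + 1)
    coeffs = np.zeros(n_terms + 1)
    coeffs[1:] = (2 * n + 1) / (n * (n + 1.0)) ** m
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coeffs) / (4 * np.pi)


def spherical_spline(
    good_pos: np.ndarray,
    bad_pos: np.ndarray,
    good_values: np.ndarray,
    m: int = 4,
    n_terms: int = 7,
    reg: float = 1e-8,
) -> np.ndarray:
    """Interpolate potentials at ``bad_pos`` from ``good_pos`` values.

    Spherical-spline interpolation on the unit sphere (order ``m``,
    Legendre series truncated at ``n_terms``); ``good_values`` may carry
    trailing axes (e.g. time). Exactly reproduces constant maps via the
    constraint term.
    """
    gg = _g_matrix(good_pos @ good_pos.T, m, n_terms)
    gb = _g_matrix(bad_pos @ good_pos.T, m, n_terms)
    n = good_pos.shape[0]
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = gg + reg * np.eye(n)
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    vals = np.asarray(good_values, dtype=float)
    flat = vals.reshape(n, -1)
    rhs = np.vstack([flat, np.zeros((1, flat.shape[1]))])
    sol = np.linalg.solve(a, rhs)
    c, c0 = sol[:n], sol[n]
    out = gb @ c + c0
    return out.reshape((bad_pos.shape[0],) + vals.shape[1:])


def interpolate_channels(
    epochs: EpochSet,
    bad_channels: dict[int, list[str]] | list[str],
    positions: np.ndarray | None = None,
    max_bad: int = 4,
    m: int = 4,
    n_terms: int = 7,
) -> EpochSet:
    """Replace bad channels with spherical-spline estimates per subject.

    ``bad_channels`` is either one list applied to every subject or a
    mapping subject index → channel names. At most ``max_bad`` channels may
    be interpolated per subject (the clinically observed range); good
    channels are untouched.
    """
    if positions is None:
        positions = electrode_positions(tuple(epochs.montage))
    if positions.shape[0] != epochs.n_channels:
        raise ValueError("positions required for every montage channel")

    if isinstance(bad_channels, dict):
        per_subject = {int(k): list(v) for k, v in bad_channels.items()}
    else:
        per_subject = {s: list(bad_channels) for s in range(epochs.n_subjects)}

    data = epochs.data.copy()
    interpolated = [list(x) for x in epochs.interpolated]
    any_interp = False
    for s, bads in per_subject.items():
        if not bads:
            continue
        any_interp = True
        if len(bads) > max_bad:
            raise ValueError(f"{len(bads)} bad channels exceeds cap {max_bad}")
        unknown = [b for b in bads if b not in epochs.montage]
        if unknown:
            raise ValueError(f"bad channels not in montage: {unknown}")
        bad_idx = [epochs.montage.index(b) for b in bads]
        good_idx = [i for i in range(epochs.n_channels) if i not in bad_idx]
        data[s, bad_idx] = spherical_spline(
            positions[good_idx], positions[bad_idx], data[s, good_idx],
            m=m, n_terms=n_terms,
        )
        interpolated[s] = sorted(set(interpolated[s]) | set(bads))
    # interpolation perturbs the exact zero channel-mean; caller re-references
    ref = "original" if any_interp else epochs.reference
    return epochs.copy_with(data=data, interpolated=interpolated, reference=ref)
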