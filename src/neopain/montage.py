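"""Electrode montage used throughout: an 18-channel neonatal 10/20 layout.

The recording layout covers primary visual (O1, O2), primary auditory
(T7, T8), association (F7, F3, F4, F8, P7, P8, TP9, TP10) and somatosensory
(C3, Cz, C4, CP3, CPz, CP4) scalp areas, referenced at Fz during acquisition.
Positions are idealized spherical 10/20 coordinates taken from mne's
standard montage, centred and projected onto the unit sphere; they are a
geometric fixture, not digitized coordinates.
"""

from __future__ import annotations

import functools
import warnings

import numpy as np

#: Default 18-channel scalp montage (common-average analyses; Fz was the
#: acquisition reference and does not re-enter the montage by default).
DEFAULT_MONTAGE: tuple[str, ...] = (
    "F7", "F3", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP3", "CPz", "CP4", "TP10",
    "P7", "P8", "O1", "O2",
)


@functools.lru_cache(maxsize=8)
def electrode_positions(montage: tuple[str, ...] = DEFAULT_MONTAGE) -> np.ndarray:
    """Unit-sphere 3D positions, shape (n_channels, 3), ordered like *montage*.

    Uses mne's idealized ``standard_1020`` montage as the coordinate source,
    recentres the requested subset, and normalizes each electrode to the
    unit sphere (spherical-spline interpolation assumes a spherical head).
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1020")
    ch_pos = std.get_positions()["ch_pos"]
    missing = [ch for ch in montage if ch not in ch_pos]
    if missing:
        raise ValueError(f"no idealized position for channels: {missing}")
    pos = np.asarray([ch_pos[ch] for ch in montage], dtype=float)
    pos = pos - pos.mean(axis=0)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return pos


def adjacency_weights(montage: tuple[str, ...] = DEFAULT_MONTAGE,
                      width: float = 0.6) -> np.ndarray:
    """Row-normalized spatial smoothing kernel over electrode distances.

    Gaussian in chord distance on the unit sphere; ``width`` is the kernel
    scale in chord-distance units. Used to give simulated noise an EEG-like
    spatial correlation structure.
    """
    pos = electrode_positions(tuple(montage))
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    w = np.exp(-0.5 * (d / width) ** 2)
    return w / w.sum(axis=1, keepdims=True)
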