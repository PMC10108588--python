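"""Plain-text interchange formats.

Epoched EEG travels as a delimited numeric dump (rows = subject × channel,
columns = samples) with a JSON sidecar carrying sampling rate, montage,
window and reference state. EDF/EDF+ recordings are read through mne when
supplied. Facial coding tables are wide CSVs (one row per action per
subject-epoch, cells ``0``/``1``/``NA:<reason>``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochSet
from .facial import ACTIONS, EPOCH_SECONDS, FacialCodingRecord

__all__ = [
    "save_epochs",
    "load_epochs",
    "read_edf",
    "write_facial_records",
    "read_facial_records",
    "events_to_frame",
    "randomization_to_frame",
]


def save_epochs(epochs: EpochSet, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (data) and ``<prefix>.json`` (sidecar)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    flat = epochs.data.reshape(-1, epochs.n_times)
    data_path = prefix.with_suffix(".tsv")
    np.savetxt(data_path, flat, fmt="%.8g", delimiter="\t")
    sidecar = {
        "fs_hz": epochs.fs_hz,
        "tmin_ms": epochs.tmin_ms,
        "montage": list(epochs.montage),
        "n_subjects": epochs.n_subjects,
        "n_channels": epochs.n_channels,
        "n_times": epochs.n_times,
        "reference": epochs.reference,
        "interpolated": epochs.interpolated,
        "units": "uV",
    }
    meta_path = prefix.with_suffix(".json")
    meta_path.write_text(json.dumps(sidecar, indent=1))
    return data_path, meta_path


def load_epochs(prefix: str | Path) -> EpochSet:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    flat = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    data = flat.reshape(meta["n_subjects"], meta["n_channels"], meta["n_times"])
    return EpochSet(
        data=data, fs_hz=meta["fs_hz"], tmin_ms=meta["tmin_ms"],
        montage=tuple(meta["montage"]), reference=meta["reference"],
        interpolated=[list(x) for x in meta["interpolated"]],
    )


def read_edf(path: str | Path, montage: tuple[str, ...]) -> tuple[np.ndarray, float]:
    """Continuous channels × time (µV) and sampling rate from an EDF file.

    Channel labels must include every montage channel; channels are
    returned in montage order.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    missing = [ch for ch in montage if ch not in raw.ch_names]
    if missing:
        raise ValueError(f"EDF lacks montage channels: {missing}")
    raw.pick(list(montage))
    raw.reorder_channels(list(montage))
    return raw.get_data() * 1e6, float(raw.info["sfreq"])


# ---------------------------------------------------------------------------
# facial coding tables
# ---------------------------------------------------------------------------

def _cell(v: float, reason: str | None) -> str:
    if np.isnan(v):
        return f"NA:{reason or 'unspecified'}"
    return str(int(v))


def write_facial_records(
    records: list[FacialCodingRecord], path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for ai, action in enumerate(ACTIONS):
            row = {
                "subject": rec.subject_id,
                "group": rec.group or "",
                "epoch": rec.epoch,
                "action": action,
                "cry_constant": rec.cry_constant,
                "body_constant": rec.body_constant,
                "coder_override": rec.coder_override,
                "symmetry_used": rec.symmetry_used,
            }
            for s in range(EPOCH_SECONDS):
                row[f"t{s + 1}"] = _cell(rec.values[ai, s], rec.reasons[ai, s])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_facial_records(path: str | Path) -> list[FacialCodingRecord]:
    df = pd.read_csv(Path(path), dtype={f"t{s + 1}": str for s in range(EPOCH_SECONDS)})
    records = []
    for (subject, epoch), sub in df.groupby(["subject", "epoch"], sort=False):
        sub = sub.set_index("action").reindex(list(ACTIONS))
        if sub["subject"].isna().any():
            raise ValueError(f"incomplete action set for {subject}/{epoch}")
        values = np.empty((len(ACTIONS), EPOCH_SECONDS))
        reasons = np.full(values.shape, None, dtype=object)
        for ai, action in enumerate(ACTIONS):
            for s in range(EPOCH_SECONDS):
                cell = str(sub.loc[action, f"t{s + 1}"]).strip()
                if cell.startswith("NA"):
                    values[ai, s] = np.nan
                    reasons[ai, s] = cell.split(":", 1)[1] if ":" in cell else None
                else:
                    values[ai, s] = float(cell)
        first = sub.iloc[0]

        def _tri(v):
            return None if pd.isna(v) else bool(v)

        records.append(FacialCodingRecord(
            subject_id=str(subject), epoch=str(epoch), values=values,
            reasons=reasons, cry_constant=_tri(first["cry_constant"]),
            body_constant=_tri(first["body_constant"]),
            coder_override=bool(first["coder_override"]),
            symmetry_used=bool(first["symmetry_used"]),
            group=str(first["group"]) if first["group"] else None,
        ))
    return records


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame([
        {"template": e.template_id, "occurrence": e.occurrence,
         "onset_ms": e.onset_ms, "duration_ms": e.duration_ms,
         "power_uVms": e.power_uVms, "group": e.group}
        for e in events
    ])


def randomization_to_frame(result) -> pd.DataFrame:
    sig = result.in_segment(result.times_ms)
    return pd.DataFrame({
        "time_ms": result.times_ms,
        "statistic": result.statistic,
        "p": result.p,
        "significant": sig,
    })
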