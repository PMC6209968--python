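"""Record readers and writers.

Native format: a two-column CSV per record (``time_s, abp_mmHg, ppg_au``)
with a JSON sidecar of metadata (sampling rate, gain subgroup, synthetic
ground truth).  A WFDB reader is provided for users holding real waveform
files; it is optional and imported lazily so the package never requires a
download.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import WaveformRecord

__all__ = ["write_record", "read_record", "read_wfdb_record"]

_COLUMNS = ("time_s", "abp_mmHg", "ppg_au")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def write_record(record: WaveformRecord, directory: str | Path) -> Path:
    """Write ``<subject_id>.csv`` plus ``<subject_id>.json``; returns CSV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = np.arange(record.n_samples) / record.fs
    df = pd.DataFrame(
        {"time_s": t, "abp_mmHg": record.abp, "ppg_au": record.ppg}
    )
    csv_path = directory / f"{record.subject_id}.csv"
    df.to_csv(csv_path, index=False, float_format="%.6f")
    meta = {
        "subject_id": record.subject_id,
        "fs": record.fs,
        "gain_subgroup": record.gain_subgroup,
        "units": {"abp": "mmHg", "ppg": "a.u."},
        "truth": _jsonable(record.truth) if record.truth is not None else None,
    }
    with open(directory / f"{record.subject_id}.json", "w") as fh:
        json.dump(meta, fh)
    return csv_path


def read_record(path: str | Path) -> WaveformRecord:
    """Read a native CSV+JSON record pair back into a WaveformRecord."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"record file not found: {path}")
    df = pd.read_csv(path)
    for col in _COLUMNS[1:]:
        if col not in df.columns:
            raise ValueError(f"record {path.name} is missing column {col!r}")
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    if meta.get("units", {}).get("abp") not in (None, "mmHg"):
        raise ValueError(f"unexpected ABP units in {sidecar.name}")
    truth = meta.get("truth")
    if truth is not None:
        for key in ("beat_peaks", "beat_feet"):
            if key in truth:
                truth[key] = np.asarray(truth[key], dtype=np.intp)
    return WaveformRecord(
        subject_id=meta.get("subject_id", path.stem),
        fs=float(meta["fs"]),
        abp=df["abp_mmHg"].to_numpy(),
        ppg=df["ppg_au"].to_numpy(),
        gain_subgroup=meta.get("gain_subgroup", ""),
        truth=truth,
    )


def read_wfdb_record(
    record_path: str | Path, abp_channel: str = "ABP", ppg_channel: str = "PLETH"
) -> WaveformRecord:
    """Read a WFDB record holding simultaneous ABP and PPG channels.

    Requires the optional ``wfdb`` package.
    """
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package"
        ) from exc
    rec = wfdb.rdrecord(str(record_path))  # pragma: no cover
    names = list(rec.sig_name)  # pragma: no cover
    for ch in (abp_channel, ppg_channel):  # pragma: no cover
        if ch not in names:
            raise ValueError(f"channel {ch!r} not present in {record_path}")
    abp = rec.p_signal[:, names.index(abp_channel)]  # pragma: no cover
    ppg = rec.p_signal[:, names.index(ppg_channel)]  # pragma: no cover
    return WaveformRecord(  # pragma: no cover
        subject_id=Path(record_path).stem,
        fs=float(rec.fs),
        abp=abp,
        ppg=ppg,
    )
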