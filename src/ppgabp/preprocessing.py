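"""Filtering, beat detection, 10-beat epoch segmentation and quality screening.

Records are band-pass filtered (0.5-15 Hz, zero-phase Butterworth), z-scored,
and cut into consecutive non-overlapping epochs of ten heartbeats bounded by
pulse feet.  An automated quality screen replaces manual artifact review:
epochs with channel beat-count mismatch, irregular rhythm, amplitude
outliers, clipping, or flatline runs are dropped.  Alignment for the
in-phase analysis shifts the PPG by a single integer lag so that mean
systolic-peak positions coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import signal

from .synthetic import WaveformRecord

__all__ = [
    "Epoch",
    "bandpass_filter",
    "normalize",
    "detect_systolic_peaks",
    "segment_epochs",
    "quality_screen",
    "align_epoch",
    "classify_by_sbp",
    "preprocess_record",
]

#: minimum spacing between systolic peaks (seconds); caps rate at ~180 bpm
REFRACTORY_S = 0.33


def bandpass_filter(
    x: np.ndarray, fs: float, low: float = 0.5, high: float = 15.0
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass; removes DC, keeps length."""
    if fs <= 2.0 * high:
        raise ValueError(f"sampling rate {fs} Hz too low for band edge {high} Hz")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def normalize(x: np.ndarray) -> np.ndarray:
    """Z-score: zero mean, unit standard deviation."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("cannot normalize a constant (zero-variance) signal")
    return (x - x.mean()) / sd


def detect_systolic_peaks(x: np.ndarray, fs: float) -> np.ndarray:
    """Indices of systolic maxima in a filtered pulse waveform.

    A refractory period of ``REFRACTORY_S`` suppresses dicrotic waves; a
    prominence threshold relative to the robust signal span rejects small
    secondary oscillations.
    """
    x = np.asarray(x, dtype=float)
    span = np.percentile(x, 95) - np.percentile(x, 5)
    if span <= 0:
        warnings.warn("no peaks found: flat signal", stacklevel=2)
        return np.array([], dtype=np.intp)
    peaks, _ = signal.find_peaks(
        x, distance=max(int(round(REFRACTORY_S * fs)), 1), prominence=0.45 * span
    )
    if peaks.size == 0:
        warnings.warn("no peaks found", stacklevel=2)
    return peaks.astype(np.intp)


@dataclass
class Epoch:
    """An aligned pair of ten-beat ABP/PPG segments.

    Beat indices are relative to the epoch start; ``alignment_shift`` is the
    integer lag applied to the PPG channel by :func:`align_epoch` (0 before).
    """

    subject_id: str
    index: int
    abp: np.ndarray
    ppg: np.ndarray
    beat_indices_abp: np.ndarray
    beat_indices_ppg: np.ndarray
    fs: float
    quality_ok: bool = True
    alignment_shift: int = 0
    start: int = 0  # sample offset within the parent record

    def __post_init__(self) -> None:
        if self.abp.shape != self.ppg.shape:
            raise ValueError("abp and ppg must have equal length")
        for idx in (self.beat_indices_abp, self.beat_indices_ppg):
            if idx.size and (
                np.any(np.diff(idx) <= 0)
                or idx[0] < 0
                or idx[-1] >= self.abp.size
            ):
                raise ValueError("beat indices must be strictly increasing, in range")

    @property
    def n_samples(self) -> int:
        return self.abp.size


def _preceding_trough(x: np.ndarray, peak: int, window: int) -> int:
    lo = max(0, peak - window)
    if lo == peak:
        return peak
    return lo + int(np.argmin(x[lo:peak]))


def segment_epochs(
    abp: np.ndarray,
    ppg: np.ndarray,
    fs: float,
    abp_peaks: np.ndarray,
    ppg_peaks: np.ndarray,
    subject_id: str = "",
    beats_per_epoch: int = 10,
) -> list[Epoch]:
    """Cut both channels into consecutive windows of ten ABP beats.

    Windows run from the trough preceding the first beat to the trough
    preceding the 11th beat (half-open, so epochs partition the covered
    span); a trailing partial window is discarded.
    """
    abp = np.asarray(abp, dtype=float)
    ppg = np.asarray(ppg, dtype=float)
    abp_peaks = np.asarray(abp_peaks, dtype=np.intp)
    ppg_peaks = np.asarray(ppg_peaks, dtype=np.intp)
    if abp_peaks.size < beats_per_epoch:
        warnings.warn(
            f"only {abp_peaks.size} beats detected; need {beats_per_epoch}",
            stacklevel=2,
        )
        return []
    median_ibi = int(np.median(np.diff(abp_peaks))) if abp_peaks.size > 1 else int(fs)
    n_epochs = abp_peaks.size // beats_per_epoch
    epochs: list[Epoch] = []
    for e in range(n_epochs):
        first = abp_peaks[e * beats_per_epoch]
        start = _preceding_trough(abp, int(first), median_ibi)
        nxt = (e + 1) * beats_per_epoch
        if nxt < abp_peaks.size:
            end = _preceding_trough(abp, int(abp_peaks[nxt]), median_ibi)
        else:
            # last full epoch: extend to the trough after the 10th beat
            last = int(abp_peaks[nxt - 1])
            hi = min(abp.size, last + median_ibi)
            end = last + int(np.argmin(abp[last:hi])) if hi > last else abp.size
        if end <= start:
            continue
        beats = abp_peaks[e * beats_per_epoch : nxt]
        p_beats = ppg_peaks[(ppg_peaks >= start) & (ppg_peaks < end)]
        epochs.append(
            Epoch(
                subject_id=subject_id,
                index=e,
                abp=abp[start:end].copy(),
                ppg=ppg[start:end].copy(),
                beat_indices_abp=(beats - start).astype(np.intp),
                beat_indices_ppg=(p_beats - start).astype(np.intp),
                fs=fs,
                start=start,
            )
        )
    return epochs


def _clipped_fraction(x: np.ndarray) -> float:
    """Fraction of samples in runs of identical consecutive values near extremes."""
    d = np.diff(x)
    flat = d == 0.0
    if not np.any(flat):
        return 0.0
    span = x.max() - x.min()
    if span == 0:
        return 1.0
    near_edge = (x[1:] <= x.min() + 0.02 * span) | (x[1:] >= x.max() - 0.02 * span)
    return float(np.count_nonzero(flat & near_edge)) / x.size


def _longest_flat_run(x: np.ndarray) -> int:
    d = np.diff(x) == 0.0
    if not np.any(d):
        return 1
    # lengths of runs of True in d, +1 for sample count
    changes = np.flatnonzero(np.diff(d.astype(np.int8)))
    bounds = np.concatenate([[-1], changes, [d.size - 1]])
    best = 0
    for a, b in zip(bounds[:-1], bounds[1:]):
        if d[b]:
            best = max(best, b - a)
    return best + 1


def quality_screen(
    epoch: Epoch,
    ibi_cv_max: float = 0.25,
    amplitude_outlier_sd: float = 4.0,
    clip_fraction_max: float = 0.01,
    flatline_max_s: float = 0.1,
) -> bool:
    """Automated artifact screen; True when the epoch looks usable."""
    if epoch.beat_indices_abp.size != epoch.beat_indices_ppg.size:
        return False
    ibi = np.diff(epoch.beat_indices_abp)
    if ibi.size and ibi.mean() > 0 and ibi.std() / ibi.mean() > ibi_cv_max:
        return False
    for x, beats in (
        (epoch.abp, epoch.beat_indices_abp),
        (epoch.ppg, epoch.beat_indices_ppg),
    ):
        amps = []
        for i, pk in enumerate(beats):
            lo = beats[i - 1] if i > 0 else max(0, pk - int(epoch.fs))
            if lo >= pk:
                continue
            amps.append(x[pk] - x[lo:pk].min())
        amps = np.asarray(amps)
        if amps.size >= 4:
            med = np.median(amps)
            mad = np.median(np.abs(amps - med)) * 1.4826
            floor = 0.05 * abs(med) + 1e-12
            z = np.abs(amps - med) / max(mad, floor)
            if np.any(z > amplitude_outlier_sd):
                return False
        if _clipped_fraction(x) > clip_fraction_max:
            return False
        if _longest_flat_run(x) > flatline_max_s * epoch.fs:
            return False
    return True


def align_epoch(epoch: Epoch) -> Epoch:
    """Shift PPG so mean systolic-peak positions coincide with ABP's.

    Returns a new epoch with both channels trimmed to equal length and the
    applied lag stored in ``alignment_shift``.  If the required shift would
    exceed half the epoch, the epoch is flagged ``quality_ok=False`` instead.
    """
    if epoch.beat_indices_ppg.size == 0 or epoch.beat_indices_abp.size == 0:
        return replace(epoch, quality_ok=False)
    lag = int(
        round(
            float(np.mean(epoch.beat_indices_ppg))
            - float(np.mean(epoch.beat_indices_abp))
        )
    )
    n = epoch.n_samples
    if abs(lag) > n // 2:
        return replace(epoch, quality_ok=False)
    if lag >= 0:
        abp = epoch.abp[: n - lag]
        ppg = epoch.ppg[lag:]
        a_beats = epoch.beat_indices_abp
        p_beats = epoch.beat_indices_ppg - lag
    else:
        abp = epoch.abp[-lag:]
        ppg = epoch.ppg[: n + lag]
        a_beats = epoch.beat_indices_abp + lag
        p_beats = epoch.beat_indices_ppg
    m = min(abp.size, ppg.size)
    keep_a = a_beats[(a_beats >= 0) & (a_beats < m)]
    keep_p = p_beats[(p_beats >= 0) & (p_beats < m)]
    return Epoch(
        subject_id=epoch.subject_id,
        index=epoch.index,
        abp=abp[:m].copy(),
        ppg=ppg[:m].copy(),
        beat_indices_abp=keep_a.astype(np.intp),
        beat_indices_ppg=keep_p.astype(np.intp),
        fs=epoch.fs,
        quality_ok=epoch.quality_ok,
        alignment_shift=lag,
        start=epoch.start,
    )


def classify_by_sbp(record: WaveformRecord) -> str:
    """Group label from the raw ABP: mean per-beat systolic maximum (mmHg).

    NT below 120, PHT in [120, 140), HT at or above 140.
    """
    filtered = bandpass_filter(record.abp, record.fs)
    peaks = detect_systolic_peaks(filtered, record.fs)
    if peaks.size == 0:
        raise ValueError(f"no beats detected for subject {record.subject_id!r}")
    half = max(int(round(0.12 * record.fs)), 1)
    maxima = [
        record.abp[max(0, p - half) : min(record.abp.size, p + half + 1)].max()
        for p in peaks
    ]
    sbp = float(np.mean(maxima))
    if sbp < 120.0:
        return "NT"
    if sbp < 140.0:
        return "PHT"
    return "HT"


def preprocess_record(
    record: WaveformRecord,
    beats_per_epoch: int = 10,
    low: float = 0.5,
    high: float = 15.0,
) -> tuple[list[Epoch], dict]:
    """Filter, normalize, detect beats, segment and screen one record.

    Returns the epochs (with ``quality_ok`` set by the screen) and a small
    info dict with the SBP-derived group label and processing counts.
    """
    abp_f = normalize(bandpass_filter(record.abp, record.fs, low, high))
    ppg_f = normalize(bandpass_filter(record.ppg, record.fs, low, high))
    abp_peaks = detect_systolic_peaks(abp_f, record.fs)
    ppg_peaks = detect_systolic_peaks(ppg_f, record.fs)
    epochs = segment_epochs(
        abp_f,
        ppg_f,
        record.fs,
        abp_peaks,
        ppg_peaks,
        subject_id=record.subject_id,
        beats_per_epoch=beats_per_epoch,
    )
    for ep in epochs:
        ep.quality_ok = quality_screen(ep)
    info = {
        "group": classify_by_sbp(record),
        "n_beats": int(abp_peaks.size),
        "n_epochs": len(epochs),
        "n_quality_ok": sum(ep.quality_ok for ep in epochs),
        "abp_peaks": abp_peaks,
        "ppg_peaks": ppg_peaks,
    }
    return epochs, info
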