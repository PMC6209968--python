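"""Time-domain similarity: pulse-amplitude scatter and in-phase morphology.

Two questions are addressed here.  First, whether per-beat PPG amplitudes
track per-beat arterial pulse pressures (they do not when the PPG channel
carries an arbitrary device gain — the amplitude analysis is therefore run
separately within each electronic-gain subgroup).  Second, whether the
*shapes* of the two waveforms agree: after aligning systolic peaks, the
Pearson correlation of the sample vectors measures morphology similarity,
averaged over epochs per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .preprocessing import Epoch

__all__ = [
    "AmplitudePair",
    "pearson_r",
    "epoch_morphology_r",
    "subject_average_r",
    "beat_amplitudes",
    "amplitude_correlation",
]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient.

    Computed from the raw-sum form
    r = (n Σxy − Σx Σy) / sqrt[(n Σx² − (Σx)²)(n Σy² − (Σy)²)]
    after centering for numerical stability.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(np.dot(xc, xc))
    syy = float(np.dot(yc, yc))
    if sxx <= 0.0 or syy <= 0.0:
        raise ValueError("correlation undefined for constant input")
    r = float(np.dot(xc, yc)) / np.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0))


def epoch_morphology_r(epoch: Epoch) -> float:
    """Pearson r between the (aligned) ABP and PPG sample vectors."""
    return pearson_r(epoch.abp, epoch.ppg)


def subject_average_r(epoch_r_values: Sequence[float]) -> float:
    """Arithmetic mean of per-epoch correlations for one subject."""
    vals = np.asarray(list(epoch_r_values), dtype=float)
    if vals.size == 0:
        raise ValueError("subject has no usable epochs")
    return float(vals.mean())


def beat_amplitudes(x: np.ndarray, beat_indices: np.ndarray) -> np.ndarray:
    """Per-beat pulse amplitude: systolic peak minus the preceding foot.

    The foot is the minimum between the previous beat's peak and the current
    one.  A first beat without searchable history is skipped.
    """
    x = np.asarray(x, dtype=float)
    beats = np.asarray(beat_indices, dtype=np.intp)
    if beats.size == 0:
        return np.array([])
    ibi = int(np.median(np.diff(beats))) if beats.size > 1 else beats[0]
    amps = []
    for i, pk in enumerate(beats):
        lo = int(beats[i - 1]) if i > 0 else int(pk) - ibi
        if lo < 0 or lo >= pk:
            continue  # no preceding foot available
        amps.append(x[pk] - x[lo:pk].min())
    return np.asarray(amps, dtype=float)


@dataclass(frozen=True)
class AmplitudePair:
    """One beat's ABP amplitude (mmHg) and PPG amplitude (a.u.)."""

    abp_amp: float
    ppg_amp: float
    gain_subgroup: str = ""

    def __post_init__(self) -> None:
        if self.abp_amp < 0 or self.ppg_amp < 0:
            raise ValueError("amplitudes must be non-negative")


def amplitude_correlation(
    pairs: Iterable[AmplitudePair],
    by_gain_subgroup: bool = True,
    reject_threshold: float = 0.3,
    min_pairs: int = 10,
) -> dict:
    """ABP-vs-PPG amplitude correlation, per electronic-gain subgroup.

    Returns ``{"r": {subgroup: r}, "n": {subgroup: count}, "rejected": bool}``
    where ``rejected`` is the verdict that amplitudes are *not* correlated
    (every subgroup |r| below ``reject_threshold``).  Subgroups with fewer
    than ``min_pairs`` beats are skipped with a warning.
    """
    pairs = list(pairs)
    if by_gain_subgroup:
        keys = sorted({p.gain_subgroup for p in pairs})
        grouped = {k: [p for p in pairs if p.gain_subgroup == k] for k in keys}
    else:
        grouped = {"all": pairs}
    rs: dict[str, float] = {}
    ns: dict[str, int] = {}
    for key, members in grouped.items():
        if len(members) < min_pairs:
            warnings.warn(
                f"subgroup {key!r} has only {len(members)} pairs; skipped",
                stacklevel=2,
            )
            continue
        a = np.array([p.abp_amp for p in members])
        b = np.array([p.ppg_amp for p in members])
        rs[key] = pearson_r(a, b)
        ns[key] = len(members)
    rejected = bool(rs) and all(abs(r) < reject_threshold for r in rs.values())
    return {"r": rs, "n": ns, "rejected": rejected}
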