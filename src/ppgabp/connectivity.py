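"""Spectral synchrony and causality measures from a fitted VAR.

Six measures are derived per frequency from the decomposition
(A(f), H(f), S(f)):

* COH   — coherence, |S_xy| / sqrt(S_xx S_yy)
* pCOH  — partial coherence from P(f) = S(f)^-1; identical in magnitude to
          COH in the bivariate case
* PDC   — partial directed coherence, |A_ij| column-normalized
* DTF   — directed transfer function, |H_ij| row-normalized
* ffDTF — full-frequency DTF, the DTF numerator over a row denominator
          summed over the whole frequency grid
* dDTF  — direct DTF, ffDTF multiplied elementwise by pCOH

Directionality convention used throughout: element (i, j) quantifies the
influence of channel j on channel i (j drives i).  Channel 0 is ABP and
channel 1 is PPG, so "ABP -> PPG" is element (1, 0).

Each measure is summarized per epoch as its maximum over the 1-10 Hz band
and averaged over epochs per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .mvar import SpectralDecomposition

__all__ = [
    "ConnectivityProfile",
    "SubjectSummary",
    "coherence",
    "partial_coherence",
    "pdc",
    "dtf",
    "ffdtf",
    "ddtf",
    "connectivity_profile",
    "band_max",
    "summarize_subject",
    "DIRECTED_MEASURES",
    "MEASURE_KEYS",
]

#: index pairs of the two causal directions, (sink, source)
ABP_TO_PPG = (1, 0)
PPG_TO_ABP = (0, 1)

DIRECTED_MEASURES = ("PDC", "DTF", "ffDTF", "dDTF")
MEASURE_KEYS = (
    "COH",
    "pCOH",
    "PDC_abp_to_ppg",
    "PDC_ppg_to_abp",
    "DTF_abp_to_ppg",
    "DTF_ppg_to_abp",
    "ffDTF_abp_to_ppg",
    "ffDTF_ppg_to_abp",
    "dDTF_abp_to_ppg",
    "dDTF_ppg_to_abp",
)


def coherence(S_f: np.ndarray) -> np.ndarray:
    """|S_xy(f)| / sqrt(S_xx(f) S_yy(f)) per frequency."""
    sxx = np.real(S_f[:, 0, 0])
    syy = np.real(S_f[:, 1, 1])
    bad = (sxx <= 0) | (syy <= 0)
    if np.any(bad):
        raise ValueError(
            f"zero auto-spectrum at frequency index {int(np.argmax(bad))}"
        )
    return np.abs(S_f[:, 0, 1]) / np.sqrt(sxx * syy)


def partial_coherence(S_f: np.ndarray) -> np.ndarray:
    """|P_xy(f)| / sqrt(P_xx(f) P_yy(f)) with P(f) = S(f)^-1."""
    det = S_f[:, 0, 0] * S_f[:, 1, 1] - S_f[:, 0, 1] * S_f[:, 1, 0]
    if np.any(np.abs(det) < 1e-300):
        raise np.linalg.LinAlgError("singular spectral matrix")
    P = np.linalg.inv(S_f)
    pxx = np.abs(P[:, 0, 0])
    pyy = np.abs(P[:, 1, 1])
    return np.abs(P[:, 0, 1]) / np.sqrt(pxx * pyy)


def pdc(A_f: np.ndarray) -> np.ndarray:
    """Partial directed coherence: |A_ij(f)| normalized by its column."""
    mag = np.abs(A_f)
    col = np.sqrt(np.sum(mag**2, axis=1, keepdims=True))  # (nf, 1, 2)
    if np.any(col == 0):
        raise ValueError("zero column in A(f)")
    return mag / col


def dtf(H_f: np.ndarray) -> np.ndarray:
    """Directed transfer function: |H_ij(f)| normalized by its row."""
    mag = np.abs(H_f)
    row = np.sqrt(np.sum(mag**2, axis=2, keepdims=True))  # (nf, 2, 1)
    if np.any(row == 0):
        raise ValueError("zero row in H(f)")
    return mag / row


def ffdtf(H_f: np.ndarray) -> np.ndarray:
    """Full-frequency DTF: row denominator summed over the whole grid."""
    mag = np.abs(H_f)
    denom = np.sqrt(np.sum(mag**2, axis=(0, 2)))  # (2,)
    if np.any(denom == 0):
        raise ValueError("degenerate all-zero transfer matrix")
    return mag / denom[None, :, None]


def ddtf(ffdtf_f: np.ndarray, pcoh_f: np.ndarray) -> np.ndarray:
    """Direct DTF: ffDTF scaled by partial coherence.

    The single cross-channel pCOH value multiplies both off-diagonal
    (directed) elements; diagonal elements are unchanged.
    """
    if ffdtf_f.shape[0] != pcoh_f.shape[0]:
        raise ValueError(
            f"frequency grid mismatch: {ffdtf_f.shape[0]} vs {pcoh_f.shape[0]}"
        )
    out = ffdtf_f.copy()
    out[:, 0, 1] *= pcoh_f
    out[:, 1, 0] *= pcoh_f
    return out


@dataclass
class ConnectivityProfile:
    """All six measures on a common frequency grid for one epoch."""

    freqs: np.ndarray
    coh: np.ndarray  # (nf,)
    pcoh: np.ndarray  # (nf,)
    pdc: np.ndarray  # (nf, 2, 2)
    dtf: np.ndarray  # (nf, 2, 2)
    ffdtf: np.ndarray  # (nf, 2, 2)
    ddtf: np.ndarray  # (nf, 2, 2)


def connectivity_profile(decomp: SpectralDecomposition) -> ConnectivityProfile:
    """Evaluate every measure from one spectral decomposition."""
    coh = coherence(decomp.S_f)
    pcoh = partial_coherence(decomp.S_f)
    ff = ffdtf(decomp.H_f)
    return ConnectivityProfile(
        freqs=decomp.freqs,
        coh=coh,
        pcoh=pcoh,
        pdc=pdc(decomp.A_f),
        dtf=dtf(decomp.H_f),
        ffdtf=ff,
        ddtf=ddtf(ff, pcoh),
    )


def band_max(
    values: np.ndarray, freqs: np.ndarray, band: tuple[float, float] = (1.0, 10.0)
):
    """Maximum over grid frequencies within [band[0], band[1]] Hz.

    ``values`` may be (nf,) or (nf, 2, 2); the maximum is taken along the
    frequency axis.
    """
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if not np.any(mask):
        raise ValueError(f"band [{lo}, {hi}] Hz outside the frequency grid")
    return np.max(values[mask], axis=0)


@dataclass
class SubjectSummary:
    """Per-subject epoch-averaged morphology r and band-max synchrony values."""

    subject_id: str
    group: str
    mean_r: float
    band_max: dict[str, float]
    n_epochs_used: int
    mean_profiles: Optional[dict[str, np.ndarray]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_epochs_used < 1:
            raise ValueError("subject summary requires at least one epoch")


def _epoch_band_values(
    profile: ConnectivityProfile, band: tuple[float, float]
) -> dict[str, float]:
    vals = {
        "COH": float(band_max(profile.coh, profile.freqs, band)),
        "pCOH": float(band_max(profile.pcoh, profile.freqs, band)),
    }
    for name, arr in zip(
        DIRECTED_MEASURES, (profile.pdc, profile.dtf, profile.ffdtf, profile.ddtf)
    ):
        m = band_max(arr, profile.freqs, band)
        vals[f"{name}_abp_to_ppg"] = float(m[ABP_TO_PPG])
        vals[f"{name}_ppg_to_abp"] = float(m[PPG_TO_ABP])
    return vals


def summarize_subject(
    profiles: Sequence[ConnectivityProfile],
    group: str,
    subject_id: str,
    epoch_r: Optional[Sequence[float]] = None,
    band: tuple[float, float] = (1.0, 10.0),
    keep_profiles: bool = False,
) -> SubjectSummary:
    """Average per-epoch band maxima (and morphology r) for one subject.

    With ``keep_profiles`` the epoch-mean frequency profiles of COH and the
    ABP->PPG directed measures are retained for frequency-resolved testing.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError(f"subject {subject_id!r} has no usable epochs")
    per_epoch = [_epoch_band_values(p, band) for p in profiles]
    band_means = {
        key: float(np.mean([d[key] for d in per_epoch])) for key in MEASURE_KEYS
    }
    mean_r = float(np.mean(epoch_r)) if epoch_r is not None and len(epoch_r) else np.nan
    mean_profiles = None
    if keep_profiles:
        i, j = ABP_TO_PPG
        mean_profiles = {
            "freqs": profiles[0].freqs,
            "COH": np.mean([p.coh for p in profiles], axis=0),
            "PDC_abp_to_ppg": np.mean([p.pdc[:, i, j] for p in profiles], axis=0),
            "DTF_abp_to_ppg": np.mean([p.dtf[:, i, j] for p in profiles], axis=0),
        }
    return SubjectSummary(
        subject_id=subject_id,
        group=group,
        mean_r=mean_r,
        band_max=band_means,
        n_epochs_used=len(profiles),
        mean_profiles=mean_profiles,
    )
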