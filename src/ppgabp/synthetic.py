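"""Synthetic coupled ABP/PPG waveform generation.

Two kinds of generators live here:

* exact bivariate vector-autoregressive (VAR) processes with known
  coefficients, used as ground truth for the spectral estimator, and
* physiologically shaped arterial pulse trains with a derived
  photoplethysmogram channel, assembled into cohorts with normotensive
  (NT), prehypertensive (PHT) and hypertensive (HT) group structure.

The PPG channel is modelled as a delayed, low-pass-filtered copy of the
arterial pressure wave with an independent per-record amplitude scale and
additive white noise.  The delay (pulse transit time) and the noise level
are group dependent: higher pressure means a shorter transit delay and a
cleaner, more strongly coupled PPG.  The per-record PPG amplitude is drawn
independently of systolic pressure, emulating device-side automatic gain,
so that pulse amplitudes in the two channels are uncorrelated across
records by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

GROUPS = ("NT", "PHT", "HT")

__all__ = [
    "GROUPS",
    "VARSpec",
    "CohortSpec",
    "WaveformRecord",
    "companion_matrix",
    "simulate_var",
    "generate_pulse_train",
    "derive_ppg_from_abp",
    "generate_cohort",
]


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Companion form of a VAR(p) coefficient stack of shape (p, d, d)."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, d, _ = coeffs.shape
    top = np.concatenate(list(coeffs), axis=1)  # (d, d*p)
    if p == 1:
        return top
    lower = np.eye(d * (p - 1), d * p)
    return np.vstack([top, lower])


@dataclass(frozen=True)
class VARSpec:
    """A stationary bivariate VAR(p) process specification.

    ``coeffs`` are in regression form: x(t) = sum_k coeffs[k-1] @ x(t-k) + e(t)
    with innovations e(t) ~ N(0, noise_cov).
    """

    order: int
    coeffs: np.ndarray  # (p, 2, 2)
    noise_cov: np.ndarray  # (2, 2)
    fs: float = 125.0

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coeffs, dtype=float)
        if coeffs.shape != (self.order, 2, 2):
            raise ValueError(
                f"coeffs must have shape ({self.order}, 2, 2), got {coeffs.shape}"
            )
        object.__setattr__(self, "coeffs", coeffs)
        cov = np.asarray(self.noise_cov, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T, atol=1e-12):
            raise ValueError("noise_cov must be a symmetric 2x2 matrix")
        if np.min(np.linalg.eigvalsh(cov)) <= 0:
            raise ValueError("noise_cov must be positive definite")
        object.__setattr__(self, "noise_cov", cov)
        if self.order < 1:
            raise ValueError("order must be a positive integer")
        rho = self.spectral_radius
        if rho >= 1.0:
            raise ValueError(
                f"non-stationary VAR specification: companion spectral radius "
                f"{rho:.4f} >= 1"
            )

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(self.coeffs)))))


def simulate_var(
    spec: VARSpec, n: int, seed: int, burn_in: Optional[int] = None
) -> np.ndarray:
    """Simulate ``n`` samples of the bivariate process; returns shape (n, 2).

    A burn-in of at least ``10 * p`` samples (default ``max(10 p, 200)``) is
    generated from zero initial conditions and discarded so the returned
    segment is effectively stationary.
    """
    p = spec.order
    if n <= 100 * p:
        raise ValueError(f"n must exceed 100*p = {100 * p}")
    if burn_in is None:
        burn_in = max(10 * p, 200)
    elif burn_in < 10 * p:
        raise ValueError("burn_in must be at least 10*p")
    rng = np.random.default_rng(seed)
    total = n + burn_in
    chol = np.linalg.cholesky(spec.noise_cov)
    innov = rng.standard_normal((total, 2)) @ chol.T
    x = np.zeros((total, 2))
    coeffs = spec.coeffs
    for t in range(total):
        acc = innov[t].copy()
        kmax = min(p, t)
        for k in range(1, kmax + 1):
            acc += coeffs[k - 1] @ x[t - k]
        x[t] = acc
    return x[burn_in:]


# ---------------------------------------------------------------------------
# Arterial pulse waveform
# ---------------------------------------------------------------------------

# Beat template: two smooth lobes, a dominant systolic upstroke peaking early
# in the cycle and a smaller, wider dicrotic wave.  Positions/widths are
# fractions of the beat period.
_SYS_POS, _SYS_WIDTH = 0.18, 0.055
_DICROTIC_POS, _DICROTIC_WIDTH, _DICROTIC_AMP = 0.45, 0.09, 0.38


def _beat_template(n_samples: int) -> np.ndarray:
    u = np.arange(n_samples) / n_samples
    w = np.exp(-0.5 * ((u - _SYS_POS) / _SYS_WIDTH) ** 2)
    w += _DICROTIC_AMP * np.exp(-0.5 * ((u - _DICROTIC_POS) / _DICROTIC_WIDTH) ** 2)
    w -= w.min()
    return w / w.max()


def generate_pulse_train(
    heart_rate_bpm: float,
    sbp_mmHg: float,
    dbp_mmHg: float,
    fs: float = 125.0,
    duration_s: float = 120.0,
    jitter: float = 0.0,
    amplitude_jitter_mmHg: float = 0.0,
    seed: int = 0,
    return_beats: bool = False,
):
    """Concatenated per-beat arterial pressure templates.

    Beat periods get multiplicative Gaussian jitter (fractional SD ``jitter``)
    and peak amplitudes additive jitter (SD ``amplitude_jitter_mmHg``).  Each
    beat spans diastolic ``dbp_mmHg`` to systolic ``sbp_mmHg``.

    Returns the waveform, or ``(waveform, peak_indices, foot_indices)`` when
    ``return_beats`` is true (ground-truth systolic peaks and beat onsets).
    """
    if not 30.0 <= heart_rate_bpm <= 200.0:
        raise ValueError("heart_rate_bpm must lie in [30, 200]")
    if dbp_mmHg >= sbp_mmHg:
        raise ValueError("dbp must be below sbp")
    base_period = 60.0 / heart_rate_bpm
    if duration_s < base_period:
        raise ValueError("duration too short to contain a single beat")
    rng = np.random.default_rng(seed)
    n_total = int(round(duration_s * fs))
    segments = []
    peaks: list[int] = []
    feet: list[int] = []
    start = 0
    while start < n_total:
        period = base_period * (1.0 + jitter * rng.standard_normal())
        period = float(np.clip(period, 0.3, 2.0))
        m = max(int(round(period * fs)), 8)
        template = _beat_template(m)
        amp = (sbp_mmHg - dbp_mmHg) + amplitude_jitter_mmHg * rng.standard_normal()
        amp = max(amp, 1.0)
        seg = dbp_mmHg + amp * template
        feet.append(start)
        peaks.append(start + int(np.argmax(seg)))
        segments.append(seg)
        start += m
    x = np.concatenate(segments)[:n_total]
    peak_idx = np.array([i for i in peaks if i < n_total], dtype=np.intp)
    foot_idx = np.array([i for i in feet if i < n_total], dtype=np.intp)
    if return_beats:
        return x, peak_idx, foot_idx
    return x


def derive_ppg_from_abp(
    abp: np.ndarray,
    fs: float,
    delay_ms: float = 200.0,
    smooth_cutoff_hz: float = 10.0,
    gain: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Derive a PPG-like channel: delay, low-pass smoothing, gain, noise.

    The output is mean-removed.  The low-pass stage is a zero-phase
    first-order Butterworth, so the only systematic lag between the channels
    is the transit delay itself.
    """
    if delay_ms < 0:
        raise ValueError("delay_ms must be non-negative")
    if gain <= 0:
        raise ValueError("gain must be positive")
    if smooth_cutoff_hz >= fs / 2:
        raise ValueError("smooth_cutoff_hz must be below the Nyquist frequency")
    abp = np.asarray(abp, dtype=float)
    d = int(round(delay_ms / 1000.0 * fs))
    if d > 0:
        delayed = np.concatenate([np.full(d, abp[0]), abp[:-d]])
    else:
        delayed = abp
    b, a = signal.butter(1, smooth_cutoff_hz / (fs / 2.0), btype="low")
    smoothed = signal.filtfilt(b, a, delayed)
    y = gain * smoothed
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sd * rng.standard_normal(y.shape)
    return y - y.mean()


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

# AHA systolic-pressure bands defining the three groups.
SBP_BANDS = {"NT": (0.0, 120.0), "PHT": (120.0, 140.0), "HT": (140.0, np.inf)}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic NT/PHT/HT cohort.

    Defaults mirror the study population: 43/40/37 subjects, 120 s records
    at 125 Hz, and pulse transit delays that shorten with rising pressure.
    """

    n_per_group: tuple[int, int, int] = (43, 40, 37)
    duration_s: float = 120.0
    fs: float = 125.0
    heart_rate_bpm: tuple[float, float] = (80.0, 8.0)  # subject-level mean, SD
    beat_jitter: float = 0.02  # within-record fractional period jitter
    amp_jitter_mmHg: float = 1.0
    sbp_range_mmHg: tuple[tuple[float, float], ...] = (
        (95.0, 115.0),
        (122.0, 137.0),
        (142.0, 175.0),
    )
    transit_delay_ms: tuple[float, float, float] = (250.0, 200.0, 150.0)
    delay_jitter_ms: float = 12.0
    ppg_gain_subgroups: tuple[tuple[float, float], tuple[float, float]] = (
        (0.6, 0.75),
        (2.2, 3.0),
    )
    ppg_noise_frac: tuple[float, float, float] = (0.30, 0.20, 0.12)
    abp_noise_mmHg: float = 0.5
    smooth_cutoff_hz: float = 10.0
    proportional_gain: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 3 or any(n < 0 for n in self.n_per_group):
            raise ValueError("n_per_group must be three non-negative integers")
        for grp, (lo, hi) in zip(GROUPS, self.sbp_range_mmHg):
            blo, bhi = SBP_BANDS[grp]
            if not (blo <= lo < hi <= min(bhi, 300.0)):
                raise ValueError(
                    f"sbp_range for {grp} must lie inside its AHA band "
                    f"[{blo}, {bhi}) mmHg"
                )
        d = self.transit_delay_ms
        if not (d[0] > d[1] > d[2] > 0):
            raise ValueError(
                "transit delays must decrease strictly from NT to HT"
            )
        if self.smooth_cutoff_hz >= self.fs / 2:
            raise ValueError("smooth_cutoff_hz must be below Nyquist")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")


@dataclass
class WaveformRecord:
    """One subject's simultaneous ABP (mmHg) and PPG (a.u.) waveforms."""

    subject_id: str
    fs: float
    abp: np.ndarray
    ppg: np.ndarray
    gain_subgroup: str = ""
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.abp = np.asarray(self.abp, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        if self.abp.shape != self.ppg.shape or self.abp.ndim != 1:
            raise ValueError("abp and ppg must be 1-D vectors of equal length")
        if self.truth is not None:
            if self.abp.min() < 20.0 or self.abp.max() > 300.0:
                raise ValueError("synthetic ABP outside physiologic 20-300 mmHg")

    @property
    def n_samples(self) -> int:
        return self.abp.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _pulse_amplitude(x: np.ndarray) -> float:
    """Robust pulse amplitude: central 2-98 percentile span."""
    lo, hi = np.percentile(x, [2.0, 98.0])
    return float(hi - lo)


def generate_cohort(spec: CohortSpec) -> list[WaveformRecord]:
    """Generate a full synthetic cohort; deterministic in ``spec.seed``."""
    ss = np.random.SeedSequence(spec.seed)
    n_total = sum(spec.n_per_group)
    children = ss.spawn(n_total + 1)
    master = np.random.default_rng(children[0])
    records: list[WaveformRecord] = []
    idx = 0
    for g, (group, n_g) in enumerate(zip(GROUPS, spec.n_per_group)):
        lo_sbp, hi_sbp = spec.sbp_range_mmHg[g]
        for i in range(n_g):
            rng = np.random.default_rng(children[idx + 1])
            idx += 1
            hr = float(
                np.clip(
                    spec.heart_rate_bpm[0]
                    + spec.heart_rate_bpm[1] * rng.standard_normal(),
                    50.0,
                    120.0,
                )
            )
            sbp = float(rng.uniform(lo_sbp, hi_sbp))
            pulse_pressure = 30.0 + 0.35 * (sbp - 90.0)
            dbp = sbp - pulse_pressure
            delay = float(
                max(
                    spec.transit_delay_ms[g]
                    + spec.delay_jitter_ms * rng.standard_normal(),
                    40.0,
                )
            )
            seeds = rng.integers(0, 2**31 - 1, size=4)
            abp, peak_idx, foot_idx = generate_pulse_train(
                hr,
                sbp,
                dbp,
                fs=spec.fs,
                duration_s=spec.duration_s,
                jitter=spec.beat_jitter,
                amplitude_jitter_mmHg=spec.amp_jitter_mmHg,
                seed=int(seeds[0]),
                return_beats=True,
            )
            clean = derive_ppg_from_abp(
                abp,
                spec.fs,
                delay_ms=delay,
                smooth_cutoff_hz=spec.smooth_cutoff_hz,
                gain=1.0,
                noise_sd=0.0,
            )
            sub = int(master.integers(0, 2))
            gain_subgroup = ("low", "high")[sub]
            if spec.proportional_gain is not None:
                scale = spec.proportional_gain
                target_amp = scale * _pulse_amplitude(clean)
            else:
                g_lo, g_hi = spec.ppg_gain_subgroups[sub]
                target_amp = float(rng.uniform(g_lo, g_hi))
                scale = target_amp / _pulse_amplitude(clean)
            ppg = scale * clean
            noise_sd = spec.ppg_noise_frac[g] * float(np.std(ppg))
            noise_rng = np.random.default_rng(int(seeds[1]))
            if noise_sd > 0:
                ppg = ppg + noise_sd * noise_rng.standard_normal(ppg.shape)
            ppg = ppg - ppg.mean()
            if spec.abp_noise_mmHg > 0:
                abp_rng = np.random.default_rng(int(seeds[2]))
                abp = abp + spec.abp_noise_mmHg * abp_rng.standard_normal(abp.shape)
            abp = np.clip(abp, 20.0, 300.0)
            records.append(
                WaveformRecord(
                    subject_id=f"{group}{i:03d}",
                    fs=spec.fs,
                    abp=abp,
                    ppg=ppg,
                    gain_subgroup=gain_subgroup,
                    truth={
                        "group": group,
                        "sbp_mmHg": sbp,
                        "dbp_mmHg": dbp,
                        "heart_rate_bpm": hr,
                        "delay_ms": delay,
                        "ppg_pulse_amplitude": target_amp,
                        "ppg_noise_sd": noise_sd,
                        "beat_peaks": peak_idx,
                        "beat_feet": foot_idx,
                    },
                )
            )
    if not records:
        warnings.warn("empty cohort requested", stacklevel=2)
    return records
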