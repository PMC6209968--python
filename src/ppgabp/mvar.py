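"""Bivariate autoregressive modelling and its frequency-domain decomposition.

Each ten-beat epoch is modelled as a bivariate VAR(p),

    x(t) = sum_{k=1..p} Phi(k) x(t-k) + e(t),   e(t) ~ (0, Sigma),

fitted by multivariate least squares without intercept (channels are
zero-mean after normalization).  The model order is chosen per group by
the Schwarz-Bayes criterion, minimized per epoch and combined by the mode,
so a single p serves every epoch of a group.  The frequency-domain form

    A(f) = I - sum_k Phi(k) e^{-i 2 pi f k / fs},
    H(f) = A(f)^{-1},   S(f) = H(f) Sigma H(f)*

feeds the synchrony and causality measures downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .synthetic import companion_matrix

__all__ = [
    "VARModel",
    "SpectralDecomposition",
    "fit_var",
    "select_order",
    "spectral_decompose",
]


@dataclass
class VARModel:
    """Fitted bivariate VAR.

    ``coeffs`` holds the regression-form lag matrices Phi(k) of shape
    (p, 2, 2); the sign-flipped matrices A(k) = -Phi(k) of the moving-
    equation convention (A(0) = I, sum_k A(k) x(t-k) = e(t)) are available
    as :attr:`a_matrices`.
    """

    order: int
    coeffs: np.ndarray
    noise_cov: np.ndarray
    n_samples: int
    criterion_value: Optional[float] = None
    stable: bool = True

    @property
    def a_matrices(self) -> np.ndarray:
        """Lag matrices with A(0)=I convention: A(k) = -Phi(k), k >= 1."""
        return -self.coeffs

    def __post_init__(self) -> None:
        cov = np.asarray(self.noise_cov, dtype=float)
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("noise_cov must be symmetric")
        if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
            raise ValueError("noise_cov must be positive semidefinite")


def _lagged(data: np.ndarray, p: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Response and lag-regressor matrices using the last ``n - window`` rows."""
    n = data.shape[0]
    y = data[window:]
    z = np.empty((n - window, 2 * p))
    for k in range(1, p + 1):
        z[:, 2 * (k - 1) : 2 * k] = data[window - k : n - k]
    return y, z


def fit_var(x: np.ndarray, y: np.ndarray, order: int) -> VARModel:
    """Multivariate OLS fit of a bivariate VAR(p) (no intercept).

    The residual covariance uses divisor (n - p) - 2p: effective samples
    minus parameters per equation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("channels must be equal-length 1-D vectors")
    p = int(order)
    n = x.size
    if p < 1:
        raise ValueError("order must be >= 1")
    if n <= 10 * p:
        raise ValueError(f"insufficient data: need more than {10 * p} samples, got {n}")
    data = np.column_stack([x, y])
    resp, z = _lagged(data, p, p)
    b, _, rank, _ = np.linalg.lstsq(z, resp, rcond=None)
    if rank < 2 * p:
        raise np.linalg.LinAlgError(
            f"rank-deficient lag regressor matrix (rank {rank} < {2 * p})"
        )
    resid = resp - z @ b
    dof = (n - p) - 2 * p
    if dof <= 0:
        raise ValueError("insufficient data for residual covariance")
    sigma = resid.T @ resid / dof
    coeffs = np.stack([b[2 * k : 2 * k + 2].T for k in range(p)])
    radius = float(np.max(np.abs(np.linalg.eigvals(companion_matrix(coeffs)))))
    return VARModel(
        order=p,
        coeffs=coeffs,
        noise_cov=sigma,
        n_samples=n,
        stable=radius < 1.0,
    )


def _bic_curve(data: np.ndarray, p_max: int, penalty_scale: float = 1.0) -> np.ndarray:
    """Schwarz criterion ln det(Sigma_p) + scale * (ln n / n) * 4p for p=1..p_max.

    All orders are evaluated on the common sample t = p_max .. n-1 so the
    criteria are comparable; the Gram matrix is formed once and nested
    sub-systems solved per order.
    """
    n = data.shape[0]
    n_eff = n - p_max
    if n_eff <= 2 * p_max + 2:
        raise ValueError("epoch too short for the requested p_max")
    resp, z = _lagged(data, p_max, p_max)
    m = np.concatenate([z, resp], axis=1)
    gram = m.T @ m
    g_yy = gram[-2:, -2:]
    bics = np.empty(p_max)
    for p in range(1, p_max + 1):
        g_zz = gram[: 2 * p, : 2 * p]
        g_zy = gram[: 2 * p, -2:]
        try:
            b = np.linalg.solve(g_zz, g_zy)
        except np.linalg.LinAlgError:
            bics[p - 1] = np.inf
            continue
        rss = g_yy - g_zy.T @ b
        rss = (rss + rss.T) / 2.0
        sign, logdet = np.linalg.slogdet(rss / n_eff)
        if sign <= 0:
            bics[p - 1] = np.inf
            continue
        bics[p - 1] = logdet + penalty_scale * (np.log(n_eff) / n_eff) * 4 * p
    return bics


def select_order(
    epochs: Iterable[tuple[np.ndarray, np.ndarray]],
    p_max: int,
    penalty_scale: float = 1.0,
) -> int:
    """Group model order: mode of per-epoch Bayesian-criterion optima.

    ``epochs`` yields (abp, ppg) channel pairs (zero-mean).  Ties in the
    mode resolve to the smaller order.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    optima = []
    for x, y in epochs:
        data = np.column_stack(
            [np.asarray(x, dtype=float), np.asarray(y, dtype=float)]
        )
        bics = _bic_curve(data, p_max, penalty_scale)
        optima.append(int(np.argmin(bics)) + 1)
    if not optima:
        raise ValueError("no epochs supplied")
    counts = np.bincount(optima, minlength=p_max + 1)
    return int(np.argmax(counts))  # argmax takes the smallest index on ties


@dataclass
class SpectralDecomposition:
    """Frequency grid with A(f), H(f) = A(f)^-1 and S(f) = H Sigma H*."""

    freqs: np.ndarray  # (nf,)
    A_f: np.ndarray  # (nf, 2, 2) complex
    H_f: np.ndarray  # (nf, 2, 2) complex
    S_f: np.ndarray  # (nf, 2, 2) complex
    fs: float


def spectral_decompose(
    model: VARModel, fs: float, freq_resolution: float = 0.1
) -> SpectralDecomposition:
    """Evaluate A(f), H(f), S(f) on a grid from 0 to fs/2."""
    if not model.stable:
        raise ValueError("spectral decomposition requires a stable model")
    freqs = np.arange(0.0, fs / 2.0 + freq_resolution / 2.0, freq_resolution)
    k = np.arange(1, model.order + 1)
    phase = np.exp(-1j * 2.0 * np.pi * np.outer(freqs, k) / fs)  # (nf, p)
    a_f = np.eye(2)[None, :, :] - np.einsum("fk,kij->fij", phase, model.coeffs)
    det = a_f[:, 0, 0] * a_f[:, 1, 1] - a_f[:, 0, 1] * a_f[:, 1, 0]
    bad = np.abs(det) < 1e-12
    if np.any(bad):
        f_bad = freqs[np.argmax(bad)]
        raise np.linalg.LinAlgError(f"A(f) numerically singular at f = {f_bad:.3f} Hz")
    h_f = np.empty_like(a_f)
    h_f[:, 0, 0] = a_f[:, 1, 1] / det
    h_f[:, 1, 1] = a_f[:, 0, 0] / det
    h_f[:, 0, 1] = -a_f[:, 0, 1] / det
    h_f[:, 1, 0] = -a_f[:, 1, 0] / det
    sigma = np.asarray(model.noise_cov, dtype=float)
    s_f = np.einsum("fij,jk,flk->fil", h_f, sigma, np.conj(h_f))
    return SpectralDecomposition(freqs=freqs, A_f=a_f, H_f=h_f, S_f=s_f, fs=fs)
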