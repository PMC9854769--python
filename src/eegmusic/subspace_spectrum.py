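"""Subspace (MUSIC/Pisarenko) spectral estimation and the Welch baseline.

The parametric chain models a windowed EEG channel ``y(n)`` as ``p`` sinusoidal
components in additive white noise.  Its biased sample autocorrelation lags
``g(k) = (1/N) sum_n y(n) y(n+k)`` form a symmetric positive-semidefinite
Toeplitz matrix ``R`` of order ``L``, whose eigendecomposition splits into a
signal subspace (the ``d`` leading eigenvectors) and a noise subspace (the
remaining ``L - d``).  The MUSIC pseudospectrum probes candidate angular
frequencies with the steering vector ``s(w) = [1, e^{jw}, ..., e^{j(L-1)w}]``:

    P_MUSIC(w) = 1 / sum_{k>d} |s(w)^H v_k|^2

Peaks mark frequencies whose steering vectors are (nearly) orthogonal to the
noise subspace.  Pseudospectrum values are not calibrated power densities;
given the peak frequencies, per-component powers are recovered from the
Pisarenko harmonic system ``cos(k w_i) P_i = g(k)``, ``k = 1..p``.

How many eigen-dimensions the signal occupies is a modeling choice exposed as
``p_mode``:

* ``real_sinusoids`` — ``d = 2p``; a real tone spans two complex-exponential
  dimensions, the correct choice for validation on real signals (default).
* ``complex_dims`` — ``d = p``; the literal "one dimension per band" reading
  (p = 3 for alpha/beta/gamma).
* ``noise_threshold`` — ``d`` = number of eigenvalues above a cut; no prior
  component count needed.

The noise-variance estimate is the mean of the noise-subspace eigenvalues.
:func:`welch_psd` provides the non-parametric baseline (averaged modified
periodograms) against which the parametric chain is compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.signal

from .errors import ConfigError, DataError, NumericalError

__all__ = [
    "DEFAULT_GRID",
    "default_grid",
    "SubspaceConfig",
    "AutocorrMatrix",
    "EigenSplit",
    "PseudoSpectrum",
    "PisarenkoSolution",
    "estimate_autocorrelation",
    "eigen_split",
    "music_pseudospectrum",
    "music_spectra_batch",
    "pisarenko_powers",
    "welch_psd",
]

_P_MODES = ("real_sinusoids", "complex_dims", "noise_threshold")


def default_grid(n_bins: int = 124, f_lo: float = 8.0, f_hi: float = 40.0) -> np.ndarray:
    """Uniform frequency grid over the alpha-to-gamma band (124 bins)."""
    return np.linspace(f_lo, f_hi, n_bins)


DEFAULT_GRID: np.ndarray = default_grid()


@dataclass
class SubspaceConfig:
    """Correlation order, signal-subspace dimension and how to count it."""

    L: int = 20
    p: int = 3
    p_mode: str = "real_sinusoids"
    threshold: float | None = None
    squared_magnitude: bool = True  # False: literal unsquared |s^H v| estimator

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ConfigError(f"correlation order L must be >= 2, got {self.L}")
        if self.p_mode not in _P_MODES:
            raise ConfigError(f"p_mode must be one of {_P_MODES}, got {self.p_mode!r}")
        if self.p_mode == "noise_threshold":
            if self.threshold is None or self.threshold <= 0:
                raise ConfigError("noise_threshold mode needs a positive threshold")
        elif not 0 <= self.p < self.L:
            raise ConfigError(f"need 0 <= p < L, got p={self.p}, L={self.L}")

    def signal_dim(self, eigenvalues: np.ndarray | None = None) -> int:
        """Signal-subspace dimension ``d`` under the configured counting mode."""
        if self.p_mode == "complex_dims":
            return self.p
        if self.p_mode == "real_sinusoids":
            return 2 * self.p
        if eigenvalues is None:
            raise ConfigError("noise_threshold mode needs eigenvalues to count d")
        return int(np.sum(eigenvalues > self.threshold))


@dataclass
class AutocorrMatrix:
    """Biased autocorrelation lags g(0..L-1) and their Toeplitz matrix."""

    lags: np.ndarray  # microvolts^2
    n_samples: int

    @property
    def L(self) -> int:
        return len(self.lags)

    @property
    def matrix(self) -> np.ndarray:
        return scipy.linalg.toeplitz(self.lags)


def estimate_autocorrelation(x: np.ndarray, L: int) -> AutocorrMatrix:
    """Biased sample autocorrelation, g(k) = (1/N) sum x(n) x(n+k).

    The biased normalization (divide by N, not N-k) makes the Toeplitz
    matrix positive semidefinite, which the eigen-split relies on.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n < 4 * L:
        raise DataError(f"need at least 4L={4 * L} samples for L={L}, got {n}")
    lags = np.array([np.dot(x[: n - k], x[k:]) for k in range(L)]) / n
    return AutocorrMatrix(lags=lags, n_samples=n)


@dataclass
class EigenSplit:
    """Sorted eigendecomposition of R partitioned at signal dimension d."""

    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns, orthonormal, aligned with eigenvalues
    d: int  # signal-subspace dimension
    noise_variance: float  # mean of the L-d trailing eigenvalues

    @property
    def L(self) -> int:
        return len(self.eigenvalues)

    @property
    def noise_vectors(self) -> np.ndarray:
        """Columns spanning the noise subspace (L x (L-d))."""
        return self.eigenvectors[:, self.d:]


def eigen_split(R: AutocorrMatrix | np.ndarray, cfg: SubspaceConfig) -> EigenSplit:
    """Full symmetric eigendecomposition split into signal/noise subspaces."""
    mat = R.matrix if isinstance(R, AutocorrMatrix) else np.asarray(R, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise DataError(f"expected a square matrix, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-8 * max(1.0, np.abs(mat).max())):
        raise DataError("autocorrelation matrix is not symmetric")
    vals, vecs = np.linalg.eigh(mat)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    d = cfg.signal_dim(vals)
    L = len(vals)
    if d >= L:
        raise ConfigError(
            f"signal dimension d={d} leaves no noise subspace (L={L}); "
            "the pseudospectrum is undefined")
    sigma2 = float(np.mean(vals[d:]))
    return EigenSplit(eigenvalues=vals, eigenvectors=vecs, d=d,
                      noise_variance=max(sigma2, 0.0))


@dataclass
class PseudoSpectrum:
    """MUSIC estimator values on a frequency grid, with located peaks."""

    freqs: np.ndarray  # Hz
    values: np.ndarray
    peaks: list[tuple[float, float]]  # (frequency Hz, value), ranked by value

    def top_frequencies(self, k: int) -> np.ndarray:
        return np.array([f for f, _ in self.peaks[:k]])


def _find_peaks(freqs: np.ndarray, values: np.ndarray) -> list[tuple[float, float]]:
    """Strict local maxima, ranked by descending value."""
    if len(values) < 3:
        return []
    mid = values[1:-1]
    mask = (mid > values[:-2]) & (mid > values[2:])
    idx = np.flatnonzero(mask) + 1
    order = idx[np.argsort(values[idx])[::-1]]
    return [(float(freqs[i]), float(values[i])) for i in order]


def music_pseudospectrum(
    split: EigenSplit,
    fs: float,
    freqs: np.ndarray | None = None,
    squared: bool = True,
) -> PseudoSpectrum:
    """Evaluate P_MUSIC on a grid of physical frequencies (Hz).

    ``squared=True`` (default) uses the standard squared-magnitude projection
    onto the noise subspace; ``squared=False`` keeps the unsquared form.
    Peak positions are identical either way.
    """
    if split.d >= split.L:
        raise ConfigError("empty noise subspace")
    freqs = DEFAULT_GRID if freqs is None else np.asarray(freqs, dtype=float)
    if np.any(np.diff(freqs) <= 0) or freqs[0] < 0 or freqs[-1] > fs / 2:
        raise ConfigError("frequency grid must be strictly increasing within [0, fs/2]")
    omega = 2 * np.pi * freqs / fs
    steering = np.exp(1j * np.outer(omega, np.arange(split.L)))  # (F, L)
    proj = steering.conj() @ split.noise_vectors  # (F, L-d)
    mags = np.abs(proj)
    denom = (mags ** 2 if squared else mags).sum(axis=1)
    values = 1.0 / np.maximum(denom, np.finfo(float).tiny)
    return PseudoSpectrum(freqs=freqs, values=values,
                          peaks=_find_peaks(freqs, values))


def music_spectra_batch(
    windows: np.ndarray,
    fs: float,
    cfg: SubspaceConfig,
    freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized pseudospectra for a batch of signal windows.

    ``windows`` has shape (B, w); returns (B, F).  Equivalent to running
    ``estimate_autocorrelation -> eigen_split -> music_pseudospectrum`` per
    row, but with stacked Toeplitz assembly and a batched ``eigh``, which is
    what makes MUSIC feature extraction fast on long multichannel trials.
    Only the fixed-dimension modes batch; ``noise_threshold`` falls back to
    the per-window path.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 2:
        raise DataError(f"expected (batch, window) array, got shape {windows.shape}")
    b, w = windows.shape
    L = cfg.L
    if w < 4 * L:
        raise DataError(f"window of {w} samples too short for L={L} (need 4L)")
    freqs = DEFAULT_GRID if freqs is None else np.asarray(freqs, dtype=float)

    if cfg.p_mode == "noise_threshold":
        out = np.empty((b, len(freqs)))
        for i in range(b):
            split = eigen_split(estimate_autocorrelation(windows[i], L), cfg)
            out[i] = music_pseudospectrum(split, fs, freqs,
                                          squared=cfg.squared_magnitude).values
        return out

    lags = np.empty((b, L))
    for k in range(L):
        lags[:, k] = np.einsum("ij,ij->i", windows[:, : w - k], windows[:, k:]) / w
    ii, jj = np.indices((L, L))
    mats = lags[:, np.abs(ii - jj)]  # (B, L, L) Toeplitz stack
    vals, vecs = np.linalg.eigh(mats)  # ascending
    d = cfg.signal_dim()
    if d >= L:
        raise ConfigError(f"signal dimension d={d} leaves no noise subspace (L={L})")
    omega = 2 * np.pi * freqs / fs
    steering = np.exp(-1j * np.outer(omega, np.arange(L)))  # s(w)^H rows
    n_noise = L - d

    def _proj_power(sub: np.ndarray) -> np.ndarray:
        # sub: (B, L, m) eigenvector block; returns sum_k |s^H v_k|^2 as (B, F)
        m = sub.shape[2]
        flat = sub.transpose(1, 0, 2).reshape(L, b * m)
        proj = steering @ flat  # one complex gemm
        p = np.abs(proj) ** 2
        return p.reshape(len(freqs), b, m).sum(axis=2).T

    if cfg.squared_magnitude and d < n_noise:
        # |s|^2 = L, so the noise-subspace power is L minus the
        # signal-subspace power — projecting onto the smaller block is cheaper
        signal = vecs[:, :, n_noise:]  # ascending order: trailing = signal
        denom = L - _proj_power(signal)
    elif cfg.squared_magnitude:
        denom = _proj_power(vecs[:, :, :n_noise])
    else:
        noise = vecs[:, :, :n_noise]
        flat = noise.transpose(1, 0, 2).reshape(L, b * n_noise)
        mags = np.abs(steering @ flat)
        denom = mags.reshape(len(freqs), b, n_noise).sum(axis=2).T
    return 1.0 / np.maximum(denom, np.finfo(float).tiny)


@dataclass
class PisarenkoSolution:
    """Per-component sinusoid powers recovered from autocorrelation lags."""

    omegas: np.ndarray  # rad/sample
    powers: np.ndarray  # microvolts^2 (A_i^2 / 2 for amplitude A_i)
    residual: float  # norm of A @ P - g(1..p)
    condition_number: float


def pisarenko_powers(
    omegas: np.ndarray,
    lags: np.ndarray | AutocorrMatrix,
    cond_cap: float = 1e12,
) -> PisarenkoSolution:
    """Solve the p x p harmonic system cos(k w_i) P_i = g(k), k = 1..p."""
    if isinstance(lags, AutocorrMatrix):
        lags = lags.lags
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    lags = np.asarray(lags, dtype=float).ravel()
    p = len(omegas)
    if p < 1:
        raise DataError("need at least one frequency")
    if np.any(omegas <= 0) or np.any(omegas >= np.pi):
        raise DataError("frequencies must lie strictly inside (0, pi) rad/sample")
    if len(np.unique(omegas)) != p:
        raise DataError("frequencies must be distinct")
    if len(lags) < p + 1:
        raise DataError(f"need lags g(0..{p}), got only {len(lags)}")
    k = np.arange(1, p + 1)
    system = np.cos(np.outer(k, omegas))  # (p, p)
    cond = float(np.linalg.cond(system))
    if not np.isfinite(cond) or cond > cond_cap:
        raise NumericalError(
            f"Pisarenko system ill-conditioned (cond={cond:.3g} > {cond_cap:.3g}); "
            "frequencies too close or too near the band edges")
    rhs = lags[1: p + 1]
    powers = np.linalg.solve(system, rhs)
    residual = float(np.linalg.norm(system @ powers - rhs))
    return PisarenkoSolution(omegas=omegas, powers=powers,
                             residual=residual, condition_number=cond)


def welch_psd(
    x: np.ndarray,
    fs: float,
    segment_length: int = 1024,
    overlap_fraction: float = 0.5,
    window: str = "hamming",
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density (averaged modified periodograms).

    Density-normalized: the integral over [0, fs/2] approximates the signal
    variance (Parseval, up to window-loss correction).  Returns
    ``(freqs, psd)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not 0 <= overlap_fraction < 1:
        raise ConfigError(f"overlap fraction must be in [0, 1), got {overlap_fraction}")
    if segment_length > len(x):
        raise DataError(
            f"segment length {segment_length} exceeds signal length {len(x)}")
    return scipy.signal.welch(
        x, fs=fs, window=window, nperseg=segment_length,
        noverlap=int(segment_length * overlap_fraction), detrend=False,
    )
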