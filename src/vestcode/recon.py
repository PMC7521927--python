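"""Optimal linear (Wiener) stimulus reconstruction and coding fraction.

The stimulus estimate is S_rec(t) = Σ_i (K_i ⊛ R_i)(t), where R_i are
mean-subtracted binarized spike trains and the acausal kernels K_i minimize
the mean-squared reconstruction error.  In the frequency domain, for one
neuron

    K~(f) = P_RS*(f) / P_RR(f)

and for a pair the 2×2 cross-spectral matrix [P_RiRj] is inverted against
the cross-spectra with the stimulus.  Kernels are truncated to a ±window
(default 300 ms), cosine-tapered over their last 10%, and restricted to
0–30 Hz (zero response outside).

Reconstruction quality is the coding fraction CF = 1 − RMSE/σ_S: 1 for a
perfect reconstruction, 0 when no better than predicting the stimulus mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, windows

from .containers import Trace
from .spectral import SpectralSettings, _as_sequence, _engine_csd, _resolve_segments

__all__ = [
    "ReconSettings",
    "Kernel",
    "ReconstructionResult",
    "optimal_kernel_single",
    "optimal_kernel_pair",
    "reconstruct",
    "coding_fraction",
    "reconstruct_and_score",
]


class ReconSettings(SpectralSettings):
    """Wiener-decoder settings: spectral estimator plus kernel shaping."""

    def __init__(self, window_s: float = 2.048, overlap: float = 0.5,
                 n_tapers: int = 5, nw: float = 3.0,
                 kernel_halfwidth_s: float = 0.3, taper_frac: float = 0.1,
                 max_freq: float = 30.0, cond_threshold: float = 1e8,
                 ridge: float = 1e-6):
        super().__init__(window_s, overlap, n_tapers, nw)
        self.kernel_halfwidth_s = float(kernel_halfwidth_s)
        self.taper_frac = float(taper_frac)
        self.max_freq = float(max_freq)
        self.cond_threshold = float(cond_threshold)
        self.ridge = float(ridge)


@dataclass
class Kernel:
    """Acausal time-domain decoding filter on lags ``-L..L`` samples."""

    lags: np.ndarray  # seconds, symmetric around 0
    values: np.ndarray
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.size != self.values.size or self.lags.size % 2 != 1:
            raise ValueError("kernel must have an odd number of lags")


@dataclass
class ReconstructionResult:
    kernels: list
    reconstructed: Trace
    valid: np.ndarray
    mse: float
    cf: float
    n_valid: int
    flags: dict = field(default_factory=dict)


def _freq_kernels_to_time(freqs, K, nperseg, fs, settings: ReconSettings):
    """Inverse-transform a frequency-domain kernel to a tapered ±window."""
    K = np.array(K, dtype=complex)
    K[freqs > settings.max_freq] = 0.0
    # undo the one-sided doubling baked into the engine's density estimates:
    # ratios of same-scaled estimates are unaffected, so K is already the
    # per-frequency transfer and inverts directly.
    h = np.fft.irfft(K, n=nperseg)
    L = min(int(round(settings.kernel_halfwidth_s * fs)), nperseg // 2 - 1)
    vals = np.concatenate([h[-L:], h[:L + 1]])
    taper = windows.tukey(2 * L + 1, alpha=2 * settings.taper_frac)
    lags = np.arange(-L, L + 1) / fs
    return Kernel(lags, vals * taper, fs)


def _prep(R, fs_hint):
    vals, fs, kind = _as_sequence(R)
    fs = fs or fs_hint or 1000.0
    if kind == "spikes":
        vals = vals / fs  # work in counts per bin; kernel units: stimulus/spike
    return vals, fs


def optimal_kernel_single(R, S: Trace, segments=None,
                          settings: ReconSettings | None = None) -> Kernel:
    """Wiener kernel for one spike train: K~ = P_RS* / P_RR."""
    settings = settings or ReconSettings()
    x, fs = _prep(R, S.sample_rate)
    if np.count_nonzero(x) == 0:
        raise ValueError("degenerate (empty) spike train")
    if x.size != S.n_samples:
        raise ValueError("spike train and stimulus must be aligned")
    freqs, pxs, _ = _engine_csd(x, S.values, fs, settings, segments)
    _, pxx, _ = _engine_csd(x, x, fs, settings, segments)
    K = np.zeros_like(pxs)
    ok = pxx.real > 0
    K[ok] = pxs[ok] / pxx.real[ok]
    return _freq_kernels_to_time(freqs, K, settings.nperseg(fs), fs, settings)


def optimal_kernel_pair(R1, R2, S: Trace, segments=None,
                        settings: ReconSettings | None = None):
    """Wiener kernels for a neuron pair via a per-frequency 2×2 solve.

    When the cross-spectral matrix is ill-conditioned a small ridge
    (``ridge``·mean diagonal) is added and flagged; identical inputs fall
    back to the single-neuron kernel with a warning.

    Returns ``(K1, K2, flags)``.
    """
    settings = settings or ReconSettings()
    x1, fs = _prep(R1, S.sample_rate)
    x2, _ = _prep(R2, S.sample_rate)
    flags = {"regularized_bins": 0, "singular_fallback": False}
    if np.array_equal(x1, x2):
        warnings.warn("identical spike trains: pair decoder is singular, "
                      "falling back to a single-neuron kernel")
        flags["singular_fallback"] = True
        k1 = optimal_kernel_single(R1, S, segments=segments, settings=settings)
        zero = Kernel(k1.lags, np.zeros_like(k1.values), fs)
        return k1, zero, flags
    freqs, p11, _ = _engine_csd(x1, x1, fs, settings, segments)
    _, p22, _ = _engine_csd(x2, x2, fs, settings, segments)
    _, p12, _ = _engine_csd(x1, x2, fs, settings, segments)
    _, p1s, _ = _engine_csd(x1, S.values, fs, settings, segments)
    _, p2s, _ = _engine_csd(x2, S.values, fs, settings, segments)
    K1 = np.zeros_like(p1s)
    K2 = np.zeros_like(p2s)
    for i in range(freqs.size):
        M = np.array([[p11[i].real, p12[i]], [np.conj(p12[i]), p22[i].real]],
                     dtype=complex)
        if not np.all(np.isfinite(M)) or M[0, 0] <= 0 or M[1, 1] <= 0:
            continue
        cond = np.linalg.cond(M)
        if cond > settings.cond_threshold:
            M += settings.ridge * np.mean([M[0, 0].real, M[1, 1].real]) * np.eye(2)
            flags["regularized_bins"] += 1
        sol = np.linalg.solve(M, np.array([p1s[i], p2s[i]]))
        K1[i], K2[i] = sol
    nperseg = settings.nperseg(fs)
    return (_freq_kernels_to_time(freqs, K1, nperseg, fs, settings),
            _freq_kernels_to_time(freqs, K2, nperseg, fs, settings),
            flags)


def reconstruct(trains, kernels, n_samples: int | None = None,
                segments=None, fs: float | None = None):
    """Convolve mean-subtracted spike trains with their kernels.

    Convolution is carried out per contiguous segment (never across a
    concatenation seam); samples within half a kernel width of any seam are
    marked invalid for scoring.  Returns ``(trace, valid_mask)``.
    """
    if not isinstance(trains, (list, tuple)):
        trains = [trains]
    if isinstance(kernels, Kernel):
        kernels = [kernels]
    if len(trains) != len(kernels):
        raise ValueError("one kernel per spike train required")
    seqs = []
    for t in trains:
        x, fs_t = _prep(t, fs)
        fs = fs or fs_t
        seqs.append(x)
    n = n_samples or seqs[0].size
    segs = _resolve_segments(n, segments)
    out = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    for x, k in zip(seqs, kernels):
        xc = x - x.mean()
        half = (k.values.size - 1) // 2
        for a, b in segs:
            out[a:b] += fftconvolve(xc[a:b], k.values, mode="same")
    half = max((k.values.size - 1) // 2 for k in kernels)
    for a, b in segs:
        lo, hi = a + half, b - half
        if hi > lo:
            valid[lo:hi] = True
    return Trace(out, fs or 1000.0, units="deg/s"), valid


def coding_fraction(S: Trace, reconstructed: Trace, valid=None,
                    min_valid_s: float = 10.0):
    """CF = 1 − sqrt(⟨(S − S_rec)²⟩)/σ_S over the valid samples.

    Returns ``(cf, n_valid)``.  A constant stimulus (σ = 0) is an error, as
    is fewer than ``min_valid_s`` seconds of valid data.
    """
    if S.n_samples != reconstructed.n_samples:
        raise ValueError("stimulus and reconstruction must be aligned")
    valid = np.ones(S.n_samples, bool) if valid is None else np.asarray(valid, bool)
    n_valid = int(valid.sum())
    if n_valid < min_valid_s * S.sample_rate:
        raise ValueError(f"need at least {min_valid_s} s of valid samples")
    sigma = np.std(S.values[valid])
    if sigma == 0:
        raise ValueError("stimulus has zero variance; CF undefined")
    mse = float(np.mean((S.values[valid] - reconstructed.values[valid]) ** 2))
    return 1.0 - np.sqrt(mse) / sigma, n_valid


def reconstruct_and_score(trains, S: Trace, segments=None,
                          settings: ReconSettings | None = None,
                          min_valid_s: float = 10.0) -> ReconstructionResult:
    """Fit kernels, reconstruct, and score in one call (1 or 2 neurons)."""
    settings = settings or ReconSettings()
    if not isinstance(trains, (list, tuple)):
        trains = [trains]
    flags = {}
    if len(trains) == 1:
        kernels = [optimal_kernel_single(trains[0], S, segments, settings)]
    elif len(trains) == 2:
        k1, k2, flags = optimal_kernel_pair(trains[0], trains[1], S,
                                            segments, settings)
        kernels = [k1, k2]
    else:
        raise ValueError("reconstruction supports 1 or 2 spike trains")
    rec, valid = reconstruct(list(trains), kernels, n_samples=S.n_samples,
                             segments=segments, fs=S.sample_rate)
    cf, n_valid = coding_fraction(S, rec, valid, min_valid_s=min_valid_s)
    mse = float(np.mean((S.values[valid] - rec.values[valid]) ** 2))
    return ReconstructionResult(kernels=kernels, reconstructed=rec,
                                valid=valid, mse=mse, cf=cf,
                                n_valid=n_valid, flags=flags)
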