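"""Temporal-whitening index, coherence-based mutual information, and coding
optimality.

The whitening index (WI) quantifies how frequency-independent a response
power spectrum is over the 0–20 Hz band of naturalistic head motion:

    WI = ∫_band P(f) df / (bandwidth · max_band P)

with the in-band maximum taken after 3-point median smoothing so a single
noisy estimator bin cannot set the white reference level.  WI = 1 for a
perfectly flat ("white") spectrum and shrinks as the spectrum becomes
peaked; it is invariant to overall spectral scaling.

Mutual information uses the Gaussian-channel coherence lower bound
MI = −∫_band log2(1 − C(f)) df (bits/s).  Optimality divides MI by the
water-filling Gaussian-channel capacity given the neuron's noise spectrum
and a total signal-power budget equal to the measured stimulus-driven
response power — "the mutual information divided by its maximum possible
value for a given level of variability".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .containers import SpectralEstimate, Trace
from .spectral import SpectralSettings, coherence_spectrum, power_spectrum

__all__ = [
    "WhiteningResult",
    "InformationResult",
    "whitening_index",
    "stimulus_whitening_index",
    "coherence",
    "mutual_information_rate",
    "water_filling_capacity",
    "optimality",
]

DEFAULT_BAND = (0.0, 20.0)


@dataclass
class WhiteningResult:
    wi: float
    band: tuple
    reference_max: float
    band_integral: float


@dataclass
class InformationResult:
    freqs: np.ndarray
    coherence: np.ndarray
    mi_rate: float
    mi_max: float = float("nan")
    optimality: float = float("nan")


def whitening_index(spec: SpectralEstimate, band=DEFAULT_BAND) -> WhiteningResult:
    """Band integral over bandwidth times the (median-smoothed) band maximum."""
    sub = spec.band(*band)
    if sub.freqs.size < 3:
        raise ValueError("spectrum does not cover the requested band")
    if np.all(sub.power == 0):
        raise ValueError("all-zero spectrum has no whitening index")
    smoothed = median_filter(sub.power, size=3, mode="nearest")
    ref = float(smoothed.max())
    integral = float(np.trapezoid(sub.power, sub.freqs))
    bandwidth = band[1] - band[0]
    wi = integral / (bandwidth * ref)
    return WhiteningResult(wi=min(wi, 1.0), band=tuple(band),
                           reference_max=ref, band_integral=integral)


def stimulus_whitening_index(stimulus: Trace, band=DEFAULT_BAND,
                             settings: SpectralSettings | None = None,
                             segments=None) -> WhiteningResult:
    """Whitening index of the head-velocity stimulus itself, computed with
    the same spectral method as for neural responses."""
    est = power_spectrum(stimulus, segments=segments,
                         settings=settings or SpectralSettings())
    return whitening_index(est, band=band)


def coherence(response, stimulus, segments=None,
              settings: SpectralSettings | None = None,
              fs: float | None = None):
    """Stimulus–response magnitude-squared coherence on the estimator grid.

    Thin wrapper over the spectral engine; returns ``(freqs, C)`` with C in
    [0, 1] and NaN where either auto-spectrum vanishes.
    """
    return coherence_spectrum(response, stimulus, segments=segments,
                              settings=settings, fs=fs)


def mutual_information_rate(freqs: np.ndarray, c: np.ndarray,
                            band=DEFAULT_BAND, cap: float = 1 - 1e-9) -> float:
    """Coherence lower bound on the mutual information rate (bits/s).

    MI = −∫_band log2(1 − C(f)) df, trapezoidal on the estimator grid.
    Coherence of exactly 1 would be infinite; values are capped just below 1
    (the cap is recorded implicitly by the clipping).
    """
    freqs = np.asarray(freqs, dtype=float)
    c = np.asarray(c, dtype=float)
    sel = (freqs >= band[0]) & (freqs <= band[1]) & np.isfinite(c)
    if np.sum(sel) < 2:
        raise ValueError("coherence does not cover the requested band")
    cc = np.clip(c[sel], 0.0, cap)
    integrand = -np.log2(1.0 - cc)
    return float(np.trapezoid(integrand, freqs[sel]))


def water_filling_capacity(freqs: np.ndarray, noise: np.ndarray,
                           budget: float, flat_allocation: bool = False):
    """Gaussian-channel capacity over a band for a total signal-power budget.

    Water filling picks the signal allocation S(f) = max(0, μ − N(f)) with
    the water level μ chosen so ∫ S df = budget, and

        C_max = ∫ log2(1 + S(f)/N(f)) df   (bits/s).

    With ``flat_allocation=True`` the budget is instead spread uniformly —
    the simpler bound exposed for sensitivity analysis.  Returns
    ``(capacity, allocation)``.
    """
    freqs = np.asarray(freqs, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if freqs.size < 2:
        raise ValueError("need at least two frequency bins")
    if np.any(noise <= 0):
        raise ValueError("noise spectrum must be positive on the band")
    if budget <= 0:
        raise ValueError("signal power budget must be positive")
    bandwidth = freqs[-1] - freqs[0]
    if flat_allocation:
        alloc = np.full_like(noise, budget / bandwidth)
    else:
        lo, hi = float(noise.min()), float(noise.max()) + budget / bandwidth
        for _ in range(200):
            mu = 0.5 * (lo + hi)
            alloc = np.maximum(mu - noise, 0.0)
            if np.trapezoid(alloc, freqs) > budget:
                hi = mu
            else:
                lo = mu
        alloc = np.maximum(0.5 * (lo + hi) - noise, 0.0)
    capacity = float(np.trapezoid(np.log2(1.0 + alloc / noise), freqs))
    return capacity, alloc


def optimality(mi_rate: float, noise: SpectralEstimate, budget: float,
               band=DEFAULT_BAND, flat_allocation: bool = False) -> InformationResult:
    """Coding optimality: MI over the water-filling capacity bound.

    ``noise`` is the neuron's variability spectrum (resting-discharge or
    trial-residual); ``budget`` the measured stimulus-driven response power
    on the band.  The result is clipped to [0, 1].
    """
    sub = noise.band(*band)
    keep = sub.power > 0
    if np.sum(keep) < 2:
        raise ValueError("noise spectrum must be positive on the band")
    mi_max, _ = water_filling_capacity(sub.freqs[keep], sub.power[keep],
                                       budget, flat_allocation=flat_allocation)
    opt = float(np.clip(mi_rate / mi_max, 0.0, 1.0)) if mi_max > 0 else np.nan
    return InformationResult(freqs=sub.freqs, coherence=np.array([]),
                             mi_rate=mi_rate, mi_max=mi_max, optimality=opt)
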