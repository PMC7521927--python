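"""Shared in-memory containers for signals and spectral estimates.

Time conventions used throughout the package: signals are uniformly sampled
(default 1 kHz), sample ``t`` covers the half-open interval
``[t/fs, (t+1)/fs)``, and all spectra are reported on a one-sided frequency
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trace:
    """A uniformly sampled signal (head velocity, eye velocity, eye position).

    Parameters
    ----------
    values:
        Sample values, shape ``(n,)``. Units are whatever the caller uses
        (deg/s for velocities, deg for positions, sp/s for rate traces).
    sample_rate:
        Sampling rate in Hz (default 1000).
    units:
        Free-form unit label carried through I/O.
    """

    values: np.ndarray
    sample_rate: float = 1000.0
    units: str = "deg/s"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("Trace values must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def sd(self) -> float:
        return float(np.std(self.values))


@dataclass
class SpectralEstimate:
    """One-sided power spectral estimate with estimator metadata.

    ``scaling`` records the normalization: ``"density"`` is the standard
    one-sided density (integral over frequency recovers the variance) used
    for traces; ``"rate"`` is the point-process convention (two-sided density
    reported on the one-sided grid, so a Poisson train is flat at its rate
    lambda in sp^2/s) used for spike trains.
    """

    freqs: np.ndarray
    power: np.ndarray
    n_windows: int = 0
    n_tapers: int = 0
    resolution: float = 0.0
    scaling: str = "density"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    def band(self, fmin: float, fmax: float) -> "SpectralEstimate":
        """Restrict the estimate to frequencies in ``[fmin, fmax]``."""
        sel = (self.freqs >= fmin) & (self.freqs <= fmax)
        return SpectralEstimate(
            self.freqs[sel], self.power[sel], self.n_windows,
            self.n_tapers, self.resolution, self.scaling, dict(self.meta),
        )

    def band_mean(self, fmin: float, fmax: float) -> float:
        sub = self.band(fmin, fmax)
        if sub.freqs.size == 0:
            raise ValueError("no frequency bins inside the requested band")
        return float(np.mean(sub.power))

    def band_integral(self, fmin: float, fmax: float) -> float:
        sub = self.band(fmin, fmax)
        if sub.freqs.size < 2:
            raise ValueError("need at least two bins to integrate a band")
        return float(np.trapezoid(sub.power, sub.freqs))


@dataclass
class CrossSpectrum:
    """One-sided complex cross-spectrum between two signals."""

    freqs: np.ndarray
    values: np.ndarray
    n_windows: int = 0
    n_tapers: int = 0
    resolution: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.freqs.shape != self.values.shape:
            raise ValueError("freqs and values must have the same shape")


@dataclass
class ConfidenceBand:
    """Per-frequency percentile band over surrogate spectra."""

    freqs: np.ndarray
    low: np.ndarray
    high: np.ndarray
    level: float = 95.0
    n_surrogates: int = 1000

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.low = np.asarray(self.low, dtype=float)
        self.high = np.asarray(self.high, dtype=float)
        if np.any(self.low > self.high):
            raise ValueError("lower band edge exceeds upper band edge")
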