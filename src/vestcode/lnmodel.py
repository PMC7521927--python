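"""Linear–nonlinear (LN) cascade encoding model.

The linear stage is the transfer function H(f) = P_SR(f)/P_SS(f) between
head velocity S(t) and the binarized response R(t); its magnitude G(f) is
the response tuning curve, and |H(1 Hz)| summarizes sensitivity.  The static
nonlinearity is fit by plotting the observed firing rate against the linear
prediction (H ⊛ S)(t), binned.  The predicted response power spectrum adds
the resting-discharge spectrum to the spectrum of the predicted rate:

    P_RR,predicted(f) = P0(f) + P_FR,predicted(f)

which rests on the observation that trial-to-trial variability during
stimulation has the same spectrum as the resting discharge.

Note on symbols: the field literature uses G both for the tuning gain and
for the static nonlinearity; here ``G`` is always the tuning magnitude and
``nonlinearity`` the static map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .containers import SpectralEstimate, Trace
from .spectral import SpectralSettings, _as_sequence, _engine_csd, power_spectrum
from .spikes import SpikeTrain, binarize
from .synth import generate_renewal_spiketrain
from .coding import whitening_index, DEFAULT_BAND

__all__ = [
    "TransferFunctionEstimate",
    "Nonlinearity",
    "LNModel",
    "estimate_transfer",
    "fit_nonlinearity",
    "smoothed_rate",
    "fit_ln_model",
    "predict_firing_rate",
    "predict_response_spectrum",
    "whitening_vs_cv_curve",
]


@dataclass
class TransferFunctionEstimate:
    """Linear stage H(f) with tuning magnitude G = |H| and 1 Hz sensitivity."""

    freqs: np.ndarray
    H: np.ndarray
    valid: np.ndarray  # bins where the stimulus had usable power

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.H = np.asarray(self.H, dtype=complex)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def G(self) -> np.ndarray:
        return np.abs(self.H)

    @property
    def sensitivity_1hz(self) -> float:
        sel = self.valid
        return float(np.interp(1.0, self.freqs[sel], self.G[sel]))

    def interpolate(self, freqs: np.ndarray) -> np.ndarray:
        """Complex H on an arbitrary grid; zero outside the valid band."""
        sel = self.valid
        fv = self.freqs[sel]
        re = np.interp(freqs, fv, self.H[sel].real, left=0.0, right=0.0)
        im = np.interp(freqs, fv, self.H[sel].imag, left=0.0, right=0.0)
        out = re + 1j * im
        out[(freqs < fv.min()) | (freqs > fv.max())] = 0.0
        return out


@dataclass
class Nonlinearity:
    """Binned static map from linear drive (sp/s) to firing rate (sp/s).

    Piecewise-linear between bin centers; extrapolation clamps to the end
    bins; outputs are non-negative by construction.
    """

    drive_centers: np.ndarray
    rate_values: np.ndarray

    def __post_init__(self) -> None:
        self.drive_centers = np.asarray(self.drive_centers, dtype=float)
        self.rate_values = np.maximum(np.asarray(self.rate_values, dtype=float), 0.0)

    def __call__(self, drive: np.ndarray) -> np.ndarray:
        return np.interp(drive, self.drive_centers, self.rate_values)


@dataclass
class LNModel:
    linear: TransferFunctionEstimate
    nonlinearity: Nonlinearity
    p0: SpectralEstimate
    base_rate: float = 0.0
    settings: dict = field(default_factory=dict)


def _response_sequence(R, fs_hint=None):
    vals, fs, kind = _as_sequence(R)
    return vals, fs or fs_hint or 1000.0


def estimate_transfer(S: Trace, R, segments=None,
                      settings: SpectralSettings | None = None,
                      power_floor: float = 1e-6) -> TransferFunctionEstimate:
    """H(f) = P_SR(f)/P_SS(f) on the estimator grid.

    ``R`` may be a spike train (binarized to sp/s) or a rate trace.  Bins
    where the stimulus power falls below ``power_floor`` of its maximum are
    marked invalid (the ratio is unreliable there); an entirely powerless
    stimulus is an error.
    """
    settings = settings or SpectralSettings()
    rv, fs = _response_sequence(R, S.sample_rate)
    if rv.size != S.n_samples:
        raise ValueError("stimulus and response must be aligned")
    freqs, psr, _ = _engine_csd(S.values, rv, fs, settings, segments)
    _, pss, _ = _engine_csd(S.values, S.values, fs, settings, segments)
    pss = pss.real
    if pss.max() <= 0:
        raise ValueError("stimulus has no in-band power")
    valid = pss >= power_floor * pss.max()
    if not np.any(valid):
        raise ValueError("stimulus has no in-band power")
    H = np.zeros_like(psr)
    H[valid] = psr[valid] / pss[valid]
    return TransferFunctionEstimate(freqs, H, valid)


def smoothed_rate(train: SpikeTrain, sigma_ms: float = 25.0) -> Trace:
    """Firing-rate trace: 1 kHz binarization smoothed with a Gaussian kernel
    (SD ``sigma_ms``, ~100 ms wide).  Used only for nonlinearity fitting —
    spectra are always computed on unsmoothed sequences."""
    fs = train.sample_rate
    x = binarize(train) * fs
    return Trace(gaussian_filter1d(x, sigma=sigma_ms * fs / 1000.0), fs,
                 units="sp/s")


def fit_nonlinearity(linear_drive: Trace, firing_rate: Trace,
                     n_bins: int = 20, min_count: int = 10) -> Nonlinearity:
    """Binned mean firing rate as a function of the linear prediction.

    Bins are uniform over the observed drive range; bins with fewer than
    ``min_count`` samples are merged into their neighbours.  A constant
    drive yields a flat map at the mean rate.
    """
    if n_bins < 5:
        raise ValueError("need at least 5 bins")
    d = linear_drive.values
    r = firing_rate.values
    if d.size != r.size:
        raise ValueError("drive and rate traces must be aligned")
    lo, hi = d.min(), d.max()
    if hi - lo <= 1e-12 * max(abs(hi), 1.0):
        m = float(r.mean())
        return Nonlinearity(np.array([lo - 1.0, lo + 1.0]), np.array([m, m]))
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums_r = np.bincount(idx, weights=r, minlength=n_bins)
    sums_d = np.bincount(idx, weights=d, minlength=n_bins)
    keep = counts >= min_count
    if keep.sum() < 2:
        keep = counts > 0
    centers = sums_d[keep] / counts[keep]
    rates = sums_r[keep] / counts[keep]
    order = np.argsort(centers)
    return Nonlinearity(centers[order], rates[order])


def _linear_prediction(model_linear: TransferFunctionEstimate, S: Trace) -> Trace:
    n = S.n_samples
    f = np.fft.rfftfreq(n, d=1.0 / S.sample_rate)
    H = model_linear.interpolate(f)
    drive = np.fft.irfft(np.fft.rfft(S.values) * H, n=n)
    return Trace(drive, S.sample_rate, units="sp/s")


def fit_ln_model(stimulus: Trace, response: SpikeTrain,
                 resting: SpikeTrain, segments=None,
                 settings: SpectralSettings | None = None,
                 n_bins: int = 20) -> LNModel:
    """Fit the full cascade: linear stage, static nonlinearity, and the
    resting-discharge spectrum P0 used for spectrum prediction."""
    settings = settings or SpectralSettings()
    tfe = estimate_transfer(stimulus, response, segments=segments,
                            settings=settings)
    drive = _linear_prediction(tfe, stimulus)
    rate = smoothed_rate(response)
    # smooth the drive with the same kernel as the rate: binning smoothed
    # rate against raw drive would attenuate the fitted map (regression
    # dilution) because the smoother removes drive power above ~6 Hz
    sigma = rate.sample_rate * 25.0 / 1000.0
    drive_s = Trace(gaussian_filter1d(drive.values, sigma=sigma),
                    drive.sample_rate, units=drive.units)
    nl = fit_nonlinearity(drive_s, rate, n_bins=n_bins)
    p0 = power_spectrum(resting, settings=settings)
    return LNModel(linear=tfe, nonlinearity=nl, p0=p0,
                   base_rate=resting.rate, settings=settings.as_dict())


def predict_firing_rate(model: LNModel, S: Trace) -> Trace:
    """FR_predicted(t) = nonlinearity((H ⊛ S)(t)), non-negative."""
    drive = _linear_prediction(model.linear, S)
    return Trace(model.nonlinearity(drive.values), S.sample_rate, units="sp/s")


def predict_response_spectrum(model: LNModel, S: Trace,
                              settings: SpectralSettings | None = None,
                              segments=None) -> SpectralEstimate:
    """P_RR,predicted(f) = P0(f) + P_FR,predicted(f) on the estimator grid."""
    settings = settings or SpectralSettings()
    fr = predict_firing_rate(model, S)
    pfr = power_spectrum(fr, segments=segments, settings=settings,
                         scaling="rate")
    p0 = model.p0
    if p0.freqs.shape != pfr.freqs.shape or not np.allclose(p0.freqs, pfr.freqs):
        p0_power = np.interp(pfr.freqs, p0.freqs, p0.power)
    else:
        p0_power = p0.power
    return SpectralEstimate(
        pfr.freqs, pfr.power + p0_power, n_windows=pfr.n_windows,
        n_tapers=pfr.n_tapers, resolution=pfr.resolution, scaling="rate",
        meta={"components": "P0 + P_FR_predicted"},
    )


def whitening_vs_cv_curve(model: LNModel, cv_grid, stimulus: Trace,
                          resting_duration: float = 100.0, seed: int = 0,
                          band=DEFAULT_BAND,
                          settings: SpectralSettings | None = None):
    """Predicted whitening index as resting variability is swept.

    The linear and nonlinear stages stay fixed; for each CV on the grid a
    matched gamma renewal resting discharge (same base rate) is generated
    and its spectrum replaces P0 in the prediction.  Returns a list of
    ``(cv, predicted_wi)`` pairs.
    """
    settings = settings or SpectralSettings()
    fr = predict_firing_rate(model, stimulus)
    pfr = power_spectrum(fr, settings=settings, scaling="rate")
    out = []
    for i, cv in enumerate(cv_grid):
        train = generate_renewal_spiketrain(model.base_rate, cv,
                                            resting_duration,
                                            seed=seed * 1000 + i)
        p0 = power_spectrum(train, settings=settings)
        total = SpectralEstimate(pfr.freqs, pfr.power + p0.power,
                                 scaling="rate")
        out.append((float(cv), whitening_index(total, band=band).wi))
    return out
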