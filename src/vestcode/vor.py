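"""Vestibulo-ocular reflex (VOR) pathway transfer-function model.

Head velocity drives a four-stage linear cascade — semicircular-canal
afferents, vestibular-nucleus (VN) neurons with velocity storage, the neural
integrator (NI), and the oculomotor plant — whose output is compensatory eye
velocity.  In the frequency domain (s = 2πif):

    T_aff(s)   = s·Tc·(1 + s·T1) / ((1 + s·T2)(1 + s·Tc))
    T_VN(s)    = −g_VOR·(T_VOR/Tc)·(1 + s·Tc) / (1 + s·T_VOR)
    T_NI(s)    = (s·Te1 + 1) / s
    T_Plant(s) = s·e^(−sτ) / ((s·Te1 + 1)(s·Te2 + 1))

The canal time constant Tc cancels in T_aff·T_VN (velocity storage replaces
it with T_VOR), and T_NI·T_Plant collapses to a delayed first-order low-pass
e^(−sτ)/(1 + s·Te2); both identities are unit-tested.  With g_VOR = 1 the
full cascade has gain ≈ 1 and phase ≈ 180° across the 0–20 Hz band of
naturalistic head motion: eye velocity ≈ −head velocity.

The model is used two ways: forward (head → eye, :func:`simulate_vor`) and
as a downstream decoder applied to recorded or synthetic VOR-neuron spike
trains (:func:`predict_eye_from_spikes`), whose output spectrum is compared
to the actual eye-velocity spectrum with a matching index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .containers import SpectralEstimate, Trace
from .spectral import SpectralSettings, power_spectrum
from .spikes import SegmentMask, SpikeTrain, binarize

__all__ = [
    "VORParams",
    "MatchingResult",
    "stage_response",
    "total_response",
    "simulate_vor",
    "predict_eye_from_spikes",
    "matching_index",
    "vor_gain",
]


@dataclass
class VORParams:
    """Cascade constants (seconds, except the dimensionless reflex gain).

    Defaults are the standard literature values: T1 = 0.0175, T2 = 0.0027
    (afferent lead/lag), Tc = 5.7 (canal torsion pendulum), T_VOR = 16
    (velocity-storage time constant), Te1 = 1 and Te2 = 0.016 (neural
    integrator and plant), tau = 0.008 (conduction delay), g_VOR = 1.
    """

    T1: float = 0.0175
    T2: float = 0.0027
    Tc: float = 5.7
    T_VOR: float = 16.0
    Te1: float = 1.0
    Te2: float = 0.016
    tau: float = 0.008
    g_VOR: float = 1.0

    def __post_init__(self) -> None:
        for name in ("T1", "T2", "Tc", "T_VOR", "Te1", "Te2", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"time constant {name} must be positive")


@dataclass
class MatchingResult:
    mi: float
    predicted_spectrum: SpectralEstimate
    actual_spectrum: SpectralEstimate
    log_rms: float
    log_sd_actual: float


_STAGES = ("afferents", "vn", "ni", "plant")


def stage_response(params: VORParams, f, stage: str):
    """Complex gain of one cascade stage at frequency ``f`` (Hz).

    The NI stage has a pole at f = 0; its DC response is returned as
    ``inf`` and excluded from band integrals downstream.
    """
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    f = np.asarray(f, dtype=float)
    s = 2j * np.pi * f
    p = params
    if stage == "afferents":
        return s * p.Tc * (1 + s * p.T1) / ((1 + s * p.T2) * (1 + s * p.Tc))
    if stage == "vn":
        return -p.g_VOR * (p.T_VOR / p.Tc) * (1 + s * p.Tc) / (1 + s * p.T_VOR)
    if stage == "ni":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(s == 0, np.inf + 0j, (s * p.Te1 + 1) / np.where(s == 0, 1, s))
        return out
    # plant
    return s * np.exp(-s * p.tau) / ((s * p.Te1 + 1) * (s * p.Te2 + 1))


def ni_plant_response(params: VORParams, f):
    """T_NI·T_Plant in simplified form: e^(−sτ)/(1 + s·Te2).

    The integrator pole cancels exactly against the plant zero, so the
    composite motor stage is a plain delayed first-order low-pass, finite
    at f = 0.  Equality with the stagewise product is unit-tested.
    """
    s = 2j * np.pi * np.asarray(f, dtype=float)
    return np.exp(-s * params.tau) / (s * params.Te2 + 1)


def total_response(params: VORParams, f):
    """Head-velocity → eye-velocity transfer of the full cascade.

    Evaluated in simplified form (the NI pole cancels against the plant
    zero), so it is finite everywhere, with T(0) = 0.
    """
    f = np.asarray(f, dtype=float)
    s = 2j * np.pi * f
    p = params
    sensory = s * p.T_VOR * (1 + s * p.T1) / ((1 + s * p.T2) * (1 + s * p.T_VOR))
    motor = np.exp(-s * p.tau) / (s * p.Te2 + 1)
    return -p.g_VOR * sensory * motor


def _apply_filter(x: np.ndarray, fs: float, response) -> np.ndarray:
    """Multiply the rfft of ``x`` by ``response(f)`` and invert to a real trace."""
    n = x.size
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    h = np.asarray(response(f), dtype=complex)
    h[~np.isfinite(h)] = 0.0
    return np.fft.irfft(np.fft.rfft(x) * h, n=n)


def simulate_vor(head: Trace, params: VORParams | None = None) -> Trace:
    """Slow-phase eye velocity evoked by a head-velocity trace."""
    params = params or VORParams()
    ev = _apply_filter(head.values, head.sample_rate,
                       lambda f: total_response(params, f))
    return Trace(ev, head.sample_rate, units="deg/s")


def neural_drive(head: Trace, params: VORParams | None = None) -> Trace:
    """Modelled VOR-neuron rate modulation T_aff·T_VN ∘ head (sp/s per unit gain).

    This is the sensory half of the cascade — what a model-consistent VOR
    neuron's firing-rate modulation looks like for a given head movement.
    """
    params = params or VORParams()

    def resp(f):
        return stage_response(params, f, "afferents") * stage_response(params, f, "vn")

    return Trace(_apply_filter(head.values, head.sample_rate, resp),
                 head.sample_rate, units="sp/s")


def predict_eye_from_spikes(r_vor: SpikeTrain, params: VORParams | None = None,
                            rate_gain: float = 1.0,
                            settings: SpectralSettings | None = None,
                            segments=None):
    """Decode a VOR-neuron spike train into predicted eye velocity.

    The binarized train (sp/s) is mean-subtracted — the NI 1/s pole would
    otherwise integrate the mean rate without bound — divided by
    ``rate_gain`` (the neuron's (sp/s)/(deg/s) scale, so that a
    model-consistent rate modulation reproduces :func:`simulate_vor`'s
    output), then filtered by T_NI·T_Plant.

    Returns ``(eye_velocity, spectrum)``.
    """
    params = params or VORParams()
    if r_vor.n_spikes == 0:
        raise ValueError("empty spike train")
    if rate_gain <= 0:
        raise ValueError("rate_gain must be positive")
    x = binarize(r_vor) * r_vor.sample_rate
    x = (x - x.mean()) / rate_gain
    ev = _apply_filter(x, r_vor.sample_rate,
                       lambda f: ni_plant_response(params, f))
    trace = Trace(ev, r_vor.sample_rate, units="deg/s")
    est = power_spectrum(trace, segments=segments,
                         settings=settings or SpectralSettings())
    return trace, est


def matching_index(predicted: SpectralEstimate, actual: SpectralEstimate,
                   band=(0.0, 20.0)) -> MatchingResult:
    """Agreement between predicted and actual eye-velocity spectra.

    mi = max(0, 1 − RMS_f(log P_pred − log P_act) / SD_f(log P_act)) over the
    scored band (natural log); 1 iff the spectra are identical on the band,
    0 for gross disagreement.  Zero-power bins are floored at 1e−12 of the
    in-band maximum; mi is invariant to common rescaling of both spectra.
    """
    if predicted.freqs.shape != actual.freqs.shape or \
            not np.allclose(predicted.freqs, actual.freqs):
        raise ValueError("spectra must share a frequency grid")
    sel = (predicted.freqs >= band[0]) & (predicted.freqs <= band[1]) & \
        (predicted.freqs > 0)
    if np.sum(sel) < 3:
        raise ValueError("too few bins inside the scored band")
    p, a = predicted.power[sel], actual.power[sel]
    floor = 1e-12 * max(p.max(), a.max())
    lp, la = np.log(np.maximum(p, floor)), np.log(np.maximum(a, floor))
    rms = float(np.sqrt(np.mean((lp - la) ** 2)))
    sd = float(np.std(la))
    mi = 1.0 if rms == 0 else max(0.0, 1.0 - rms / sd) if sd > 0 else 0.0
    return MatchingResult(mi, predicted, actual, log_rms=rms, log_sd_actual=sd)


def vor_gain(head: Trace, eye: Trace, exclude: SegmentMask | None = None):
    """VOR gain: minus the slope of the eye-vs-head OLS regression.

    Samples inside ``exclude`` (saccades / quick phases) are dropped before
    fitting.  Returns ``(gain, diagnostics)`` with the regression R²,
    intercept and retained-sample count.
    """
    if head.n_samples != eye.n_samples:
        raise ValueError("head and eye traces must be aligned")
    keep = np.ones(head.n_samples, dtype=bool)
    if exclude is not None:
        fs = head.sample_rate
        for a, b in exclude.intervals:
            i0, i1 = int(round(a * fs)), int(round(b * fs))
            keep[max(0, i0):min(head.n_samples, i1)] = False
    if keep.sum() < head.sample_rate:  # < 1 s of data
        raise ValueError("fewer than 1 s of retained samples")
    res = sps.linregress(head.values[keep], eye.values[keep])
    return -res.slope, {
        "r_squared": res.rvalue ** 2,
        "intercept": res.intercept,
        "n_samples": int(keep.sum()),
    }
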