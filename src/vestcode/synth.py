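"""Synthetic cohort generator: naturalistic stimuli, renewal resting
discharges, LN-cascade responses, repeated trials and model eye movements.

The generator stands in for the macaque recordings the pipeline was designed
around.  Its study conditions are:

* head-velocity stimuli with a Gaussian amplitude distribution, symmetric
  about zero, with power confined to the 0–20 Hz band of naturalistic head
  motion (white Gaussian noise → causal first-order shaping knee →
  zero-phase 20 Hz cutoff → rescale);
* resting discharges as gamma-interval renewal processes, with the ISI CV
  set through the gamma shape k = 1/CV² (so low-frequency spectral power is
  λ·CV², the renewal-theory limit);
* stimulus-driven responses via a linear–nonlinear cascade whose spikes are
  drawn by time-rescaling the same gamma renewal process, so resting-segment
  variability matches the target CV;
* compensatory eye movements from the VOR cascade model, with optional
  Poisson-timed quick phases (40–80 ms half-sine transients).

All randomness flows from one integer seed through named substreams
(:func:`substream`), so every module can be tested independently and
identical specs give bit-identical outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as ssig

from .containers import Trace
from .spikes import SegmentMask, SpikeTrain
from .vor import VORParams, neural_drive, simulate_vor

__all__ = [
    "StimulusSpec",
    "NeuronSpec",
    "substream",
    "generate_naturalistic_stimulus",
    "generate_renewal_spiketrain",
    "generate_ln_response",
    "generate_trials",
    "generate_eye_movement",
]


def substream(seed: int, *keys) -> np.random.Generator:
    """Named random substream derived from one master seed.

    Each key is hashed into the seed sequence, so streams for different
    purposes ("stimulus", ("trial", 3), ...) are independent yet fully
    reproducible from the master seed.
    """
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        h = hashlib.sha256(repr(k).encode()).digest()
        ints.append(int.from_bytes(h[:4], "little"))
    return np.random.default_rng(ints)


@dataclass
class StimulusSpec:
    """Parameters of the naturalistic head-velocity stimulus.

    ``corner_freq`` is the first-order shaping knee (most natural head-motion
    power sits below a few Hz); ``max_freq`` the hard band limit;
    ``target_sd`` the overall intensity in deg/s.
    """

    duration: float
    sample_rate: float = 1000.0
    corner_freq: float = 2.0
    max_freq: float = 20.0
    target_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 < self.corner_freq < self.max_freq <= self.sample_rate / 2:
            raise ValueError("require 0 < corner_freq < max_freq <= Nyquist")
        if self.target_sd <= 0:
            raise ValueError("target_sd must be positive")


@dataclass
class NeuronSpec:
    """Parameters of one synthetic central vestibular neuron.

    ``sensitivity`` scales the linear stage in (sp/s)/(deg/s);
    ``kernel_shape`` selects the linear filter: "identity", "lowpass"
    (first-order at ``kernel_corner`` Hz), "bandpass" (``kernel_corner`` is a
    (low, high) pair) or "vor" (the afferent+VN sensory cascade of the VOR
    model, giving a model-consistent VOR neuron).  ``nonlinearity`` is
    "identity" or ("rectifier", threshold, slope) applied to the drive;
    firing rates are always floored at zero.  ``class_label`` (PVP/EH/VO) is
    carried as metadata only.
    """

    base_rate: float
    target_cv: float
    sensitivity: float = 0.5
    kernel_shape: str = "identity"
    kernel_corner: object = 16.0
    nonlinearity: object = "identity"
    seed: int = 0
    class_label: str = "VO"
    vor_params: VORParams = field(default_factory=VORParams)

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if not 0 < self.target_cv <= 1.5:
            raise ValueError("target_cv must be in (0, 1.5]")
        if self.sensitivity < 0:
            raise ValueError("sensitivity must be non-negative")
        if self.kernel_shape not in ("identity", "lowpass", "bandpass", "vor"):
            raise ValueError(f"unknown kernel_shape {self.kernel_shape!r}")


def generate_naturalistic_stimulus(spec: StimulusSpec) -> Trace:
    """Gaussian, zero-mean, band-limited head-velocity stimulus.

    White Gaussian noise is low-pass shaped by a causal first-order filter
    with knee at ``corner_freq``, hard-limited to ``max_freq`` by a
    zero-phase spectral cutoff, then demeaned and rescaled to ``target_sd``.
    Linear filtering of Gaussian noise keeps the marginal exactly Gaussian
    and symmetric.
    """
    n = int(round(spec.duration * spec.sample_rate))
    if n < 2 * spec.sample_rate:
        raise ValueError("stimulus too short: need at least 2 s for "
                         "spectral estimates over the 0-20 Hz band")
    rng = substream(spec.seed, "stimulus")
    x = rng.standard_normal(n)
    b, a = ssig.butter(1, spec.corner_freq / (spec.sample_rate / 2), "low")
    x = ssig.lfilter(b, a, x)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, d=1.0 / spec.sample_rate)
    X[f > spec.max_freq] = 0.0
    x = np.fft.irfft(X, n=n)
    x -= x.mean()
    x *= spec.target_sd / np.std(x)
    return Trace(x, spec.sample_rate, units="deg/s")


def _gamma_isi_stream(rng, k: float, mean_interval: float, total: float):
    """Cumulative gamma interval times covering at least ``total``."""
    expected = total / mean_interval
    m = int(expected + 10 * np.sqrt(expected / k + 1) + 50)
    t = np.cumsum(rng.gamma(shape=k, scale=mean_interval / k, size=m))
    while t.size and t[-1] < total:
        extra = np.cumsum(rng.gamma(shape=k, scale=mean_interval / k, size=m)) + t[-1]
        t = np.concatenate([t, extra])
    return t


def generate_renewal_spiketrain(rate: float, cv: float, duration: float,
                                seed: int = 0,
                                sample_rate: float = 1000.0) -> SpikeTrain:
    """Gamma-interval renewal spike train with target rate and ISI CV.

    The gamma shape is k = 1/CV², mean interval 1/rate; CV = 1 recovers a
    Poisson process.
    """
    if rate <= 0 or duration <= 0:
        raise ValueError("rate and duration must be positive")
    if cv <= 0:
        raise ValueError("cv must be positive")
    rng = substream(seed, "renewal")
    k = 1.0 / cv**2
    t = _gamma_isi_stream(rng, k, 1.0 / rate, duration)
    times = t[t < duration]
    return SpikeTrain(times, duration=duration, sample_rate=sample_rate)


def _linear_drive(stimulus: Trace, spec: NeuronSpec) -> np.ndarray:
    fs = stimulus.sample_rate
    s = stimulus.values
    if spec.kernel_shape == "identity":
        out = s
    elif spec.kernel_shape == "lowpass":
        b, a = ssig.butter(1, float(spec.kernel_corner) / (fs / 2), "low")
        out = ssig.lfilter(b, a, s)
    elif spec.kernel_shape == "bandpass":
        lo, hi = spec.kernel_corner
        b, a = ssig.butter(1, [lo / (fs / 2), hi / (fs / 2)], "band")
        out = ssig.lfilter(b, a, s)
    else:  # "vor": model-consistent VOR neuron sensory drive
        drv = neural_drive(stimulus, spec.vor_params).values
        scale = abs(spec.vor_params.g_VOR) or 1.0
        out = drv / scale
    return spec.sensitivity * out


def _apply_nonlinearity(drive: np.ndarray, spec: NeuronSpec) -> np.ndarray:
    nl = spec.nonlinearity
    if nl == "identity" or nl is None:
        out = drive
    else:
        name = nl[0]
        if name != "rectifier":
            raise ValueError(f"unknown nonlinearity {nl!r}")
        _, threshold, slope = nl
        out = slope * np.maximum(drive - threshold, 0.0)
    return np.maximum(spec.base_rate + out, 0.0)


def firing_rate_profile(stimulus: Trace, spec: NeuronSpec) -> Trace:
    """Deterministic instantaneous-rate profile of the LN cascade (sp/s)."""
    rate = _apply_nonlinearity(_linear_drive(stimulus, spec), spec)
    return Trace(rate, stimulus.sample_rate, units="sp/s")


def _time_rescaled_train(rate: np.ndarray, fs: float, cv: float,
                         rng: np.random.Generator) -> SpikeTrain:
    """Draw spikes from a rate profile by time-rescaling a gamma renewal
    process, so that resting (constant-rate) segments keep the target CV."""
    dt = 1.0 / fs
    lam = np.cumsum(rate) * dt
    lam_total = lam[-1]
    grid_t = (np.arange(rate.size) + 1) * dt
    k = 1.0 / cv**2
    marks = _gamma_isi_stream(rng, k, 1.0, lam_total)
    marks = marks[marks < lam_total]
    # monotone guard: flat stretches of lam (silenced epochs) are fine for
    # np.interp as long as lam is non-decreasing
    times = np.interp(marks, np.concatenate([[0.0], lam]),
                      np.concatenate([[0.0], grid_t]))
    times = times[(times >= 0) & (times < rate.size * dt)]
    keep = np.concatenate([[True], np.diff(times) > 0])
    return SpikeTrain(times[keep], duration=rate.size * dt, sample_rate=fs)


def generate_ln_response(stimulus: Trace, spec: NeuronSpec,
                         pause_mask: SegmentMask | None = None,
                         seed: int | None = None) -> SpikeTrain:
    """Stimulus-driven spike train from the LN cascade.

    The instantaneous rate is ``nonlinearity(kernel ⊛ stimulus) + base_rate``
    floored at zero; spikes are drawn by time-rescaling a gamma renewal
    process with the neuron's target CV, mirroring the observation that the
    trial-to-trial variability spectrum matches the resting-discharge
    spectrum.  ``pause_mask`` silences the neuron during the marked epochs
    (vestibular quick phases).
    """
    if stimulus.sample_rate != 1000.0:
        raise ValueError("stimulus must be sampled at 1 kHz")
    rate = firing_rate_profile(stimulus, spec).values.copy()
    if pause_mask is not None:
        fs = stimulus.sample_rate
        for a, b in pause_mask.intervals:
            rate[int(round(a * fs)):int(round(b * fs))] = 0.0
    rng = substream(spec.seed if seed is None else seed, "ln_response")
    return _time_rescaled_train(rate, stimulus.sample_rate, spec.target_cv, rng)


def generate_trials(stimulus: Trace, spec: NeuronSpec, n_trials: int,
                    seed: int = 0) -> list:
    """Repeated presentations: shared deterministic LN drive, independent
    spiking-noise realizations per trial."""
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    trains = []
    for i in range(n_trials):
        trial_seed = int(substream(seed, ("trial", i)).integers(0, 2**31 - 1))
        trains.append(generate_ln_response(stimulus, spec, seed=trial_seed))
    for a, b in zip(trains, trains[1:]):
        if a.n_spikes == b.n_spikes and np.array_equal(a.times, b.times):
            raise RuntimeError("seed collision: two trials are identical")
    return trains


def generate_eye_movement(head: Trace, params: VORParams | None = None,
                          quick_phase_rate: float = 0.0, seed: int = 0,
                          quick_phase_amplitude: float = 150.0):
    """Model compensatory eye velocity, with optional quick phases.

    Slow-phase eye velocity is the VOR cascade output; quick phases are
    Poisson-timed 40–80 ms half-sine velocity transients of alternating
    sign, added on top and reported in the returned mask.

    Returns ``(eye_velocity, quick_phase_mask)``.
    """
    params = params or VORParams()
    eye = simulate_vor(head, params)
    values = eye.values.copy()
    fs = head.sample_rate
    duration = head.duration
    intervals = []
    if quick_phase_rate > 0:
        rng = substream(seed, "quick_phases")
        n_qp = rng.poisson(quick_phase_rate * duration)
        starts = np.sort(rng.uniform(0, duration, size=n_qp))
        sign = 1.0
        for t0 in starts:
            dur = rng.uniform(0.04, 0.08)
            if t0 + dur >= duration:
                continue
            i0, i1 = int(round(t0 * fs)), int(round((t0 + dur) * fs))
            phase = np.linspace(0, np.pi, i1 - i0, endpoint=False)
            values[i0:i1] += sign * quick_phase_amplitude * np.sin(phase)
            sign = -sign
            if intervals and t0 <= intervals[-1][1]:
                intervals[-1] = (intervals[-1][0], max(intervals[-1][1], t0 + dur))
            else:
                intervals.append((t0, t0 + dur))
    mask = SegmentMask(intervals, label="quick_phase")
    return Trace(values, fs, units="deg/s"), mask
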