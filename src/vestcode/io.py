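"""Plain-text I/O for traces, spike trains, masks, spectra and configs.

Formats: traces as delimited text with a ``time_s,value`` header; spike
trains as one time (seconds) per line; masks as ``start_s,end_s`` pairs;
spectral estimates as ``freq_hz,power`` with a ``# key: value`` metadata
header block.  Configs are YAML/JSON mirroring the spec dataclass fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .containers import SpectralEstimate, Trace
from .spikes import SegmentMask, SpikeTrain
from .synth import NeuronSpec, StimulusSpec


def write_trace(path, trace: Trace) -> None:
    header = f"# sample_rate_hz: {trace.sample_rate}\n# units: {trace.units}\ntime_s,value"
    data = np.column_stack([trace.times, trace.values])
    np.savetxt(path, data, delimiter=",", header=header, comments="",
               fmt="%.9g")


def read_trace(path) -> Trace:
    fs, units = 1000.0, ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("# sample_rate_hz:"):
                fs = float(line.split(":", 1)[1])
            elif line.startswith("# units:"):
                units = line.split(":", 1)[1].strip()
            elif not line.startswith("#"):
                break
    data = np.loadtxt(path, delimiter=",", skiprows=_n_header_lines(path))
    return Trace(np.atleast_2d(data)[:, 1], fs, units=units)


def _n_header_lines(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.strip() == "time_s,value" or \
                    line.strip() == "freq_hz,power" or line.strip() == "start_s,end_s":
                n += 1
            else:
                break
    return n


def write_spiketrain(path, train: SpikeTrain) -> None:
    with open(path, "w") as fh:
        fh.write(f"# duration_s: {train.duration}\n")
        fh.write(f"# sample_rate_hz: {train.sample_rate}\n")
        for t in train.times:
            fh.write(f"{t:.9g}\n")


def read_spiketrain(path, duration: float | None = None) -> SpikeTrain:
    dur, fs = duration, 1000.0
    times = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# duration_s:"):
                dur = float(line.split(":", 1)[1])
            elif line.startswith("# sample_rate_hz:"):
                fs = float(line.split(":", 1)[1])
            elif line and not line.startswith("#"):
                times.append(float(line))
    if dur is None:
        dur = (times[-1] + 1e-3) if times else 1.0
    return SpikeTrain(np.asarray(times), duration=dur, sample_rate=fs)


def write_mask(path, mask: SegmentMask) -> None:
    with open(path, "w") as fh:
        fh.write(f"# label: {mask.label}\nstart_s,end_s\n")
        for a, b in mask.intervals:
            fh.write(f"{a:.9g},{b:.9g}\n")


def read_mask(path) -> SegmentMask:
    label = ""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# label:"):
                label = line.split(":", 1)[1].strip()
            elif line and not line.startswith("#") and line != "start_s,end_s":
                a, b = line.split(",")
                intervals.append((float(a), float(b)))
    return SegmentMask(intervals, label=label)


def write_spectrum(path, est: SpectralEstimate) -> None:
    with open(path, "w") as fh:
        fh.write(f"# scaling: {est.scaling}\n")
        fh.write(f"# n_windows: {est.n_windows}\n")
        fh.write(f"# n_tapers: {est.n_tapers}\n")
        fh.write(f"# resolution_hz: {est.resolution}\n")
        fh.write("freq_hz,power\n")
        for f, p in zip(est.freqs, est.power):
            fh.write(f"{f:.9g},{p:.9g}\n")


def read_spectrum(path) -> SpectralEstimate:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, val = line[1:].split(":", 1)
                meta[key.strip()] = val.strip()
            elif line and line != "freq_hz,power":
                f, p = line.split(",")
                rows.append((float(f), float(p)))
    arr = np.asarray(rows)
    return SpectralEstimate(
        arr[:, 0], arr[:, 1],
        n_windows=int(meta.get("n_windows", 0)),
        n_tapers=int(meta.get("n_tapers", 0)),
        resolution=float(meta.get("resolution_hz", 0.0)),
        scaling=meta.get("scaling", "density"),
    )


def write_ln_model(path, model) -> None:
    """Serialize a fitted LN model to one structured text file.

    Sections: the complex linear stage on its frequency grid, the
    nonlinearity bin table, and the resting-spectrum (P0) reference.
    """
    with open(path, "w") as fh:
        fh.write(f"# base_rate: {model.base_rate}\n")
        fh.write("[linear]\nfreq_hz,h_real,h_imag,valid\n")
        for f, h, v in zip(model.linear.freqs, model.linear.H,
                           model.linear.valid):
            fh.write(f"{f:.9g},{h.real:.9g},{h.imag:.9g},{int(v)}\n")
        fh.write("[nonlinearity]\ndrive_sp_s,rate_sp_s\n")
        for d, r in zip(model.nonlinearity.drive_centers,
                        model.nonlinearity.rate_values):
            fh.write(f"{d:.9g},{r:.9g}\n")
        fh.write("[p0]\nfreq_hz,power\n")
        for f, p in zip(model.p0.freqs, model.p0.power):
            fh.write(f"{f:.9g},{p:.9g}\n")


def read_ln_model(path):
    from .lnmodel import LNModel, Nonlinearity, TransferFunctionEstimate

    base_rate = 0.0
    section = None
    rows = {"linear": [], "nonlinearity": [], "p0": []}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# base_rate:"):
                base_rate = float(line.split(":", 1)[1])
            elif line.startswith("[") and line.endswith("]"):
                section = line[1:-1]
            elif line and not line.startswith("#") and "," in line and \
                    section and not line[0].isalpha():
                rows[section].append([float(x) for x in line.split(",")])
    lin = np.asarray(rows["linear"])
    nl = np.asarray(rows["nonlinearity"])
    p0 = np.asarray(rows["p0"])
    tfe = TransferFunctionEstimate(lin[:, 0], lin[:, 1] + 1j * lin[:, 2],
                                   lin[:, 3].astype(bool))
    return LNModel(linear=tfe,
                   nonlinearity=Nonlinearity(nl[:, 0], nl[:, 1]),
                   p0=SpectralEstimate(p0[:, 0], p0[:, 1], scaling="rate"),
                   base_rate=base_rate)


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def stimulus_spec_from_config(cfg: dict) -> StimulusSpec:
    return StimulusSpec(**cfg)


def neuron_spec_from_config(cfg: dict) -> NeuronSpec:
    cfg = dict(cfg)
    if isinstance(cfg.get("nonlinearity"), list):
        cfg["nonlinearity"] = tuple(cfg["nonlinearity"])
    if isinstance(cfg.get("kernel_corner"), list):
        cfg["kernel_corner"] = tuple(cfg["kernel_corner"])
    return NeuronSpec(**cfg)
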