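import numpy as np
import pytest

import vestcode as vc


@pytest.fixture(scope="session")
def stimulus_120():
    """Shared 120 s naturalistic stimulus (2 Hz knee, 20 Hz cutoff, SD 30)."""
    return vc.generate_naturalistic_stimulus(
        vc.StimulusSpec(duration=120.0, seed=101))


@pytest.fixture(scope="session")
def low_cv_neuron(stimulus_120):
    """A regular (CV 0.1) high-sensitivity model neuron and its response."""
    spec = vc.NeuronSpec(base_rate=60.0, target_cv=0.1, sensitivity=0.5,
                         kernel_shape="identity", seed=7)
    return spec, vc.generate_ln_response(stimulus_120, spec)


@pytest.fixture(scope="session")
def cohort_run():
    """Default 24-neuron cohort (CV 0.1-0.8 x 3 seeds, rate 50 sp/s)."""
    return vc.run_cohort(master_seed=1)


def least_squares_fir(x: np.ndarray, s: np.ndarray, n_lags: int) -> np.ndarray:
    """Brute-force acausal FIR decoder: normal equations on lagged
    regressors of ``x`` (lags -n_lags..n_lags), zero-padded edges.

    Independent oracle for the frequency-domain Wiener kernel.
    """
    x = x - x.mean()
    s = s - s.mean()
    X = np.lib.stride_tricks.sliding_window_view(
        np.pad(x, n_lags), 2 * n_lags + 1)[:s.size][:, ::-1]
    return np.linalg.solve(X.T @ X, X.T @ s)


def least_squares_fir_pair(x1, x2, s, n_lags):
    """Two-train version of :func:`least_squares_fir`."""
    s = s - s.mean()
    cols = []
    for x in (x1, x2):
        x = x - x.mean()
        cols.append(np.lib.stride_tricks.sliding_window_view(
            np.pad(x, n_lags), 2 * n_lags + 1)[:s.size][:, ::-1])
    X = np.hstack(cols)
    h = np.linalg.solve(X.T @ X, X.T @ s)
    return h[:2 * n_lags + 1], h[2 * n_lags + 1:]
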