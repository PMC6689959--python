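import numpy as np
import pytest

from prepercept import simulate as sim


def make_epochs(data: np.ndarray, fs: float = 250.0, t0: float = -1.0, labels=None) -> sim.TrialEpochs:
    n_trials, _, n_samples = data.shape
    if labels is None:
        labels = np.array(["face"] * n_trials)
    time_s = t0 + np.arange(n_samples) / fs
    return sim.TrialEpochs(data, time_s, labels, fs)


@pytest.fixture(scope="session")
def coupled_var():
    """Canonical unidirectionally coupled VAR: FFA -> V1 at lags 2-3."""
    coeffs = sim.default_var_coeffs()
    coeffs[1, 0, 1] += 0.05
    coeffs[2, 0, 1] += 0.05
    return coeffs


@pytest.fixture(scope="session")
def coupled_epochs(coupled_var):
    """500 one-second trials of the canonical coupled VAR."""
    x = sim.var_generate(coupled_var, np.eye(2), 250, seed=11, n_trials=500)
    return make_epochs(x)
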