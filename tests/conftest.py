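import numpy as np
import pytest

import emograph as eg
from emograph.preprocess import WindowSet


@pytest.fixture(scope="session")
def small_cohort_windows():
    """2 participants, 100 windows per participant per class, split 7/2/1."""
    protocol = eg.ProtocolConfig(n_participants=2)
    spectra = eg.ClassSpectrumSpec(seed=7)
    sessions = eg.generate_cohort(protocol, spectra)
    wc = eg.WindowConfig(target_samples_per_class=12_500)
    return eg.sessions_to_windows(sessions, wc, seed=0,
                                  truncate_to_target=True)


@pytest.fixture(scope="session")
def fitted_small_model(small_cohort_windows):
    """DFCGN trained for 30 epochs on the small separable cohort."""
    model = eg.DFCGNModel(small_cohort_windows, seed=0)
    results = model.fit(eg.TrainConfig(epochs=30, seed=0))
    return model, results


@pytest.fixture(scope="session")
def alpha_band_trainset():
    """200 training windows of a single alpha-band class (toy GAN target)."""
    rng = np.random.default_rng(0)
    fs = 500.0
    t = np.arange(125) / fs
    wins = []
    for _ in range(200):
        f = rng.uniform(8, 13, size=(3, 4))
        ph = rng.uniform(0, 2 * np.pi, size=(3, 4))
        wins.append(10 * np.sin(2 * np.pi * f[..., None] * t
                                + ph[..., None]).sum(1) / 2
                    + rng.normal(0, 1, (3, 125)))
    wins = np.array(wins)
    return WindowSet(wins, np.full(200, 2), np.zeros(200), np.full(200, 1))


def random_graph(rng, n):
    """Random symmetric nonnegative adjacency with zero diagonal."""
    W = rng.random((n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return eg.laplacian(W)
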