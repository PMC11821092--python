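import numpy as np
import pytest

import chaosrefine as cr


@pytest.fixture(scope="session")
def lorenz_signal() -> cr.SignalSeries:
    """A 1000-sample Lorenz x1 signal on the attractor (transient discarded)."""
    spec = cr.lorenz()
    config = cr.IntegratorConfig(dt=0.01, n_samples=1000, initial_state=(1.0, 1.0, 1.0),
                                 transient_discard=1000)
    return cr.integrate(spec, config)


@pytest.fixture(scope="session")
def oscillator_signal() -> cr.SignalSeries:
    """A 1000-sample undamped linear-oscillator signal (period = 100 samples)."""
    spec = cr.linear_oscillator()
    config = cr.IntegratorConfig(dt=0.01, n_samples=1000, initial_state=(1.0, 0.0),
                                 transient_discard=1000)
    return cr.integrate(spec, config)


@pytest.fixture(scope="session")
def lorenz_refined(lorenz_signal) -> cr.RefinedSet:
    return cr.refine_signal(lorenz_signal, cr.RefineConfig(seed=1))


@pytest.fixture
def blob_data():
    """Two well-separated isotropic Gaussian blobs and their sample means."""
    rng = np.random.default_rng(42)
    a = rng.normal(loc=(0.0, 0.0), scale=0.5, size=(120, 2))
    b = rng.normal(loc=(10.0, 10.0), scale=0.5, size=(80, 2))
    X = np.vstack([a, b])
    return X, a.mean(axis=0), b.mean(axis=0), 0.5


def make_series(samples, dt=1.0, name="test", label="unknown") -> cr.SignalSeries:
    return cr.SignalSeries(samples=np.asarray(samples, dtype=float), dt=dt,
                           name=name, label=label)
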