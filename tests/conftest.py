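import numpy as np
import pytest

from dcsae.data import apply_minmax, fit_minmax
from dcsae.synth import SynthConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def easy_table():
    """Well-separated 2-class table, normalized: 600 rows, 30 features,
    5 planted informative columns."""
    cfg = SynthConfig(
        n_per_class=300,
        n_classes=2,
        n_features=30,
        informative_indices=(2, 7, 13, 21, 28),
        class_separation=3.0,
        rng_seed=7,
    )
    table, info = generate(cfg)
    norm = apply_minmax(table, fit_minmax(table))
    return norm, info


@pytest.fixture
def small_table():
    """Smaller easy table for fast classifier tests."""
    cfg = SynthConfig(
        n_per_class=150,
        n_classes=2,
        n_features=10,
        informative_indices=(1, 4, 7),
        class_separation=3.0,
        rng_seed=2,
    )
    table, info = generate(cfg)
    norm = apply_minmax(table, fit_minmax(table))
    return norm, info


def oracle_cca(h1, h2, r, n_components):
    """Independent CCA solution via the generalized eigenproblem
    Sigma12 Sigma22^-1 Sigma21 a = rho^2 Sigma11 a (same ridge terms)."""
    from scipy.linalg import eigh

    n = h1.shape[0]
    h1c = h1 - h1.mean(axis=0)
    h2c = h2 - h2.mean(axis=0)
    s11 = h1c.T @ h1c / n + r * np.eye(h1.shape[1])
    s22 = h2c.T @ h2c / n + r * np.eye(h2.shape[1])
    s12 = h1c.T @ h2c / n
    vals, vecs = eigh(s12 @ np.linalg.inv(s22) @ s12.T, s11)
    order = np.argsort(vals)[::-1]
    rho = np.sqrt(np.clip(vals[order], 0.0, None))
    return float(rho[:n_components].sum()), vecs[:, order[:n_components]]
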