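import numpy as np
import pytest

from radbench import DatasetProfile, FeatureTable, SynthSpec, generate


def make_table(X, y, provenance="test"):
    X = np.asarray(X, dtype=float)
    return FeatureTable(
        X, np.asarray(y, dtype=int),
        [f"f{j}" for j in range(X.shape[1])],
        [f"s{i}" for i in range(X.shape[0])],
        provenance,
    )


def random_imbalanced_table(rng, n_min=8, n_maj=18, d=3, spread=2.0):
    """A small two-cluster instance with overlapping classes."""
    n = n_min + n_maj
    X = rng.normal(size=(n, d))
    y = np.zeros(n, dtype=int)
    y[:n_min] = 1
    X[:n_min] += spread * rng.uniform(0, 0.8)
    perm = rng.permutation(n)
    return make_table(X[perm], y[perm])


@pytest.fixture
def rng():
    return np.random.default_rng(20240203)


@pytest.fixture
def imbalanced_table(rng):
    """(30, 10) well-behaved table used by resampler contract tests."""
    X = np.vstack([
        rng.normal(0.0, 1.0, size=(30, 4)),
        rng.normal(2.5, 1.0, size=(10, 4)),
    ])
    y = np.array([0] * 30 + [1] * 10)
    return make_table(X, y)


@pytest.fixture
def signal_table():
    """n=200 synthetic table with one informative block (delta=2, rho=0.8)."""
    prof = DatasetProfile("signal", 200, 60, 60, 140, 2.3)
    spec = SynthSpec(prof, n_informative=1, effect_size=2.0, block_size=10,
                     within_block_corr=0.8, seed=77)
    return generate(spec)
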