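import numpy as np
import pandas as pd
import pytest

from stressnet import synthdata as sd


@pytest.fixture(scope="session")
def small_config():
    return sd.SimConfig(seed=7, genes_per_species=120, n_hogs=40, n_clusters=4)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return sd.generate_dataset(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def planted_module_expr(
    n_modules=5, genes_per_module=50, n_samples=20, effect=2.0, noise=0.3, seed=0
):
    """Expression with planted co-expression modules (log2-unit effects)."""
    g = np.random.default_rng(seed)
    profiles = effect * g.standard_normal((n_modules, n_samples))
    rows, labels = [], []
    for m in range(n_modules):
        for i in range(genes_per_module):
            rows.append(profiles[m] + noise * g.standard_normal(n_samples))
            labels.append(m)
    idx = [f"g{i:04d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx, columns=[f"s{j}" for j in range(n_samples)]), np.array(labels)


def planted_trajectories(n_per_group=20, n_times=10, sep=4.0, noise=0.2, seed=0):
    """Two groups of trajectories with opposite archetype shapes.

    Rows are z-scored downstream, so separation is in shape: the archetypes
    are +/- a sine scaled so their RMS distance over the grid is ``sep``
    noise-sd units.
    """
    g = np.random.default_rng(seed)
    t = np.linspace(0.5, 24, n_times)
    base = np.sin(t / 24 * 2 * np.pi)
    amp = sep * noise / (2 * np.sqrt((base**2).mean()))
    a = amp * base
    b = -a
    rows, labels = [], []
    for i in range(n_per_group):
        rows.append(a + noise * g.standard_normal(n_times))
        labels.append(0)
    for i in range(n_per_group):
        rows.append(b + noise * g.standard_normal(n_times))
        labels.append(1)
    idx = [f"g{i:03d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx, columns=t), np.array(labels)
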