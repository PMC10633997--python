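import numpy as np
import pytest

from moluq.synthetic import MoleculeTable, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_table() -> MoleculeTable:
    """A 1000-molecule table with the default study conditions."""
    return generate_dataset(SyntheticConfig(n_molecules=1000, seed=7))


@pytest.fixture(scope="session")
def medium_split():
    """5000 molecules split 72/8/20 into train/val/test."""
    table = generate_dataset(SyntheticConfig(n_molecules=5000, seed=11))
    order = np.random.default_rng(0).permutation(len(table))
    return (table.subset(order[:3600]), table.subset(order[3600:4000]),
            table.subset(order[4000:]))


def make_linear_table(n=2000, p=8, seed=0, noise=0.0) -> MoleculeTable:
    """Molecule table with a purely linear noiseless (or noisy) target."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    w = rng.normal(size=p)
    y = X @ w + noise * rng.normal(size=n)
    return MoleculeTable(
        ids=[f"lin_{i}" for i in range(n)], X=X, E=X[:, :2].copy(), y=y,
        cluster=np.zeros(n, int), sigma_true=np.full(n, float(noise)))
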