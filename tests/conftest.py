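import numpy as np
import pytest

import odorgraph as og
from odorgraph.training import prepare_features


def random_toy_molecule(rng: np.random.Generator, n_min: int = 2, n_max: int = 12) -> og.Molecule:
    """A geometry-only molecule: random nuclei and well-separated coordinates."""
    n = int(rng.integers(n_min, n_max + 1))
    zs = rng.choice([1, 6, 7, 8, 16, 17], size=n).tolist()
    coords = rng.uniform(-4.0, 4.0, size=(n, 3))
    # enforce pairwise separation so Coulomb entries stay finite
    for _ in range(200):
        diff = coords[:, None] - coords[None, :]
        dist = np.sqrt((diff**2).sum(-1)) + np.eye(n) * 10
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        if dist[i, j] > 0.7:
            break
        coords[i] += rng.uniform(0.5, 1.0, size=3)
    return og.Molecule(f"toy-{rng.integers(1e9)}", "", zs, coords, [])


@pytest.fixture(scope="session")
def toy_rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_synthetic():
    """60 molecules, noise-free labels: quick fixture for structural tests."""
    spec = og.SyntheticSpec(n_molecules=60, noise=0.0, seed=11)
    dataset, clean = og.generate_dataset(spec)
    return spec, dataset, clean


@pytest.fixture(scope="session")
def default_fixture():
    """The package's standard study fixture: 200 molecules, 3 labels, 5% noise."""
    spec = og.SyntheticSpec(seed=0)
    dataset, clean = og.generate_dataset(spec)
    split = og.stratified_split(dataset, seed=0)
    return spec, dataset, clean, split


@pytest.fixture(scope="session")
def trained_lpe(default_fixture):
    """One trained LPE model on the standard fixture, shared across tests."""
    _, dataset, clean, split = default_fixture
    cfg = og.preset("lpe_asym", o=dataset.n_descriptors, seed=0)
    feats = prepare_features(dataset, cfg)
    model, log = og.train(
        dataset, split, cfg,
        og.TrainConfig(batch_size=16, max_epochs=150, patience=30, seed=0),
        features=feats,
    )
    return dataset, clean, split, cfg, feats, model, log
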