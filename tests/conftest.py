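import numpy as np
import pytest

from dtnn import (
    DTNN,
    EnergyScaler,
    GaussianGrid,
    MoleculeGeometry,
    init_params,
)
from dtnn import synthetic


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_grid():
    # 11 centers: -1.0, -0.5, ..., 4.0
    return GaussianGrid(mu_min=-1.0, mu_max=4.0, delta_mu=0.5, sigma=0.5)


@pytest.fixture()
def tiny_params(tiny_grid):
    return init_params([1, 6, 8], tiny_grid.n_features, B=6, F=8, H=4, T=2, seed=0)


@pytest.fixture()
def scaler():
    return EnergyScaler(E_mu=-3.0, E_sigma=2.0)


@pytest.fixture()
def triatomic():
    return MoleculeGeometry(
        Z=[8, 1, 1],
        R=[[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]],
        energy=-12.0,
        id="triatomic",
    )


def random_isometry(rng):
    """A random proper rotation + translation (optionally a reflection)."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.normal(scale=5.0, size=3)
    return Q, t


@pytest.fixture(scope="session")
def small_dataset():
    return synthetic.make_dataset(synthetic.default_spec(n_molecules=60, seed=7))


@pytest.fixture(scope="session")
def fitted(small_dataset):
    """A quickly trained small model shared across interpretation tests."""
    model = DTNN(small_dataset, basis_size=12, n_factors=16, hidden=8, n_passes=2)
    return model.fit(epochs=120, batch_size=16, seed=0)
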