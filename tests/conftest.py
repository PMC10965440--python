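"""Shared fixtures: toy molecule corpus, voxel grids, and trained toy models.

Heavy fixtures (trained models, the end-to-end optimization run) are
session-scoped so the training cost is paid once per pytest session.
"""

import numpy as np
import pytest

from edgen.density_vae import VaeTrainConfig, train_vae
from edgen.esp_net import EspTrainConfig, train_esp_net
from edgen.fixtures import (FixtureSpec, dipole_pairs, make_training_pairs,
                            toy_host, toy_molecule_library)
from edgen.guest_optimizer import OptimizerConfig, optimize_guests
from edgen.vol2smiles import XformerConfig, train_translator
from edgen.voxelize import DensityGrid, GridSpec


@pytest.fixture(scope="session")
def grid16() -> GridSpec:
    return GridSpec(n_voxels=16, step=0.5)


@pytest.fixture(scope="session")
def fixture_mols(grid16):
    """32 embedded toy molecules across all families (1-5 heavy atoms)."""
    spec = FixtureSpec(family="all", size_range=(1, 5), count=32, seed=0, grid=grid16)
    return toy_molecule_library(spec)


@pytest.fixture(scope="session")
def train_pairs(fixture_mols, grid16):
    """32 decorated (volume, SMILES) pairs on the 16^3 grid."""
    pairs, skipped = make_training_pairs(fixture_mols, grid16, decorated=True)
    assert skipped == 0
    return pairs


@pytest.fixture(scope="session")
def ed_grids(train_pairs, grid16):
    """First 16 electron-density grids as DensityGrid objects."""
    return [DensityGrid(spec=grid16, values=p[0][..., 0].astype(np.float64))
            for p in train_pairs[:16]]


@pytest.fixture(scope="session")
def trained_vae(ed_grids):
    """VAE overfit on 16 fixture grids (16^3, latent 32)."""
    return train_vae(ed_grids, VaeTrainConfig(epochs=400, batch_size=8, lr=2e-3,
                                              beta=1e-4, latent_dim=32, seed=0))


@pytest.fixture(scope="session")
def dipole_train_pairs(grid16):
    return dipole_pairs(8, grid16, seed=0)


@pytest.fixture(scope="session")
def trained_esp(dipole_train_pairs):
    """ESP net overfit on idealized diatomic-dipole pairs."""
    return train_esp_net(dipole_train_pairs,
                         EspTrainConfig(epochs=350, batch_size=4, lr=2e-3,
                                        width=12, depth=6, seed=0))


@pytest.fixture(scope="session")
def trained_xformer_strided(train_pairs):
    return train_translator(train_pairs,
                            XformerConfig(strategy="strided", epochs=80,
                                          batch_size=8, seed=0))


@pytest.fixture(scope="session")
def trained_xformer_squeeze(train_pairs):
    return train_translator(train_pairs,
                            XformerConfig(strategy="squeeze", epochs=120,
                                          batch_size=8, seed=0))


@pytest.fixture(scope="session")
def host16(grid16):
    return toy_host("hollow_shell", grid16)


@pytest.fixture(scope="session")
def optimization_run(host16, trained_vae, trained_esp, trained_xformer_strided):
    """One full guest-optimization run against the toy host (seed 1)."""
    cfg = OptimizerConfig(population=16, learning_rate=50.0, max_iter=400,
                          lam=1.0, seed=1)
    results, trace = optimize_guests(host16, trained_vae, trained_esp,
                                     trained_xformer_strided, cfg)
    return {"results": results, "trace": trace, "cfg": cfg}
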