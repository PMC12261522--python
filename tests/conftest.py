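import numpy as np
import pandas as pd
import pytest

from scintigan.gan import Checkpoint, GanConfig, build_generator
from scintigan.optics import CrystalGeometry, EmissionSpectrum, simulate_point
from scintigan.phasespace import build_training_dataset, compute_stats


@pytest.fixture(scope="session")
def geometry():
    return CrystalGeometry()


@pytest.fixture(scope="session")
def spectrum():
    return EmissionSpectrum()


@pytest.fixture(scope="session")
def small_table(geometry, spectrum):
    """Detected phase-space table from the reference emission point."""
    return simulate_point((0.5, 0.5, 1.0), 20_000, geometry, spectrum, seed=101)


@pytest.fixture(scope="session")
def two_point_dataset(geometry, spectrum):
    """Equal-size dataset from two emission points, with statistics."""
    grid = np.array([[0.5, 0.5, 1.0], [1.0, 0.0, 5.0]])
    table = build_training_dataset(grid, 2_000, geometry, spectrum, seed=7)
    return table, compute_stats(table)


@pytest.fixture(scope="session")
def tiny_checkpoint(two_point_dataset):
    """Randomly initialized small generator checkpoint (bookkeeping tests)."""
    _, stats = two_point_dataset
    config = GanConfig(hidden=8, latent_dim=8, batch_size=32, epochs=1, iterations_per_epoch=1, seed=3)
    gen = build_generator(config, np.random.default_rng(3))
    return Checkpoint(epoch=1, generator_params=gen.copy_params(), config=config, stats=stats, similarity=0.5)
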