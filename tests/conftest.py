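import numpy as np
import pytest

from pearlst.diffusion import DiffusionConfig, denoise_and_augment
from pearlst.fixtures import FixtureSpec, make_tissue
from pearlst.neighbors import compute_neighbors
from pearlst.preprocess import preprocess


@pytest.fixture(scope="session")
def small_tissue():
    """A 150-spot, 100-gene, 3-strip tissue, preprocessed."""
    ds, labels, t = make_tissue(FixtureSpec(n_spots=150, n_genes=100, seed=7))
    ds = preprocess(ds, n_top=100)
    return ds, labels, t


@pytest.fixture(scope="session")
def augmented_tissue(small_tissue):
    """Same tissue after neighbor computation and PDE augmentation."""
    ds, labels, t = small_tissue
    nm = compute_neighbors(ds.processed, ds.coords)
    ds = denoise_and_augment(ds, nm.nn_sets, DiffusionConfig())
    return ds, labels, t, nm


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
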