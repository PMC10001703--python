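import numpy as np
import pytest

from sirtboost import DoseGrid, StructureMask


def make_grid(values, spacing=(1.0, 1.0, 1.0)):
    return DoseGrid(np.asarray(values, dtype=float), spacing)


def make_mask(values, spacing=(1.0, 1.0, 1.0), name="m"):
    return StructureMask(np.asarray(values, dtype=bool), spacing, name=name)


def grid_from_flat(doses, spacing=(1.0, 1.0, 1.0)):
    """Put a flat list of doses on a (n,1,1) lattice with an all-true mask."""
    doses = np.asarray(doses, dtype=float).reshape(-1, 1, 1)
    grid = DoseGrid(doses, spacing)
    mask = StructureMask(np.ones_like(doses, dtype=bool), spacing, name="all")
    return grid, mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_instance(rng):
    """One random <=1000-voxel dose/mask instance for oracle comparisons."""
    def _make(seed):
        r = np.random.default_rng(seed)
        shape = tuple(r.integers(3, 11, size=3))
        spacing = tuple(r.uniform(0.5, 3.0, size=3))
        dose = DoseGrid(r.gamma(2.0, 20.0, size=shape), spacing)
        mask_vals = r.random(shape) < 0.6
        if not mask_vals.any():
            mask_vals.flat[0] = True
        return dose, StructureMask(mask_vals, spacing, name="roi")
    return _make
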