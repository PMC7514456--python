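import numpy as np
import pytest

from psishent import CompositionGrid, MultiwayTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_grid(fractions, times=None):
    """Grid from a (rows, cols, times, categories) fraction array."""
    fr = np.asarray(fractions, dtype=float)
    ny, nx, nt, nk = fr.shape
    rows, cols = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    cell_index = np.column_stack([rows.ravel(), cols.ravel()])
    return CompositionGrid(
        cell_index=cell_index,
        cell_ids=[f"r{r}c{c}" for r, c in cell_index],
        times=list(times) if times is not None else list(range(nt)),
        categories=[f"cat{k + 1}" for k in range(nk)],
        fractions=fr.reshape(ny * nx, nt, nk),
    )


def random_table(rng, shape, mode_names=None):
    """Strictly positive random multiway table."""
    vals = rng.random(shape) + 0.05
    names = mode_names or [f"M{i}" for i in range(len(shape))]
    labels = [[f"{n}{j}" for j in range(s)] for n, s in zip(names, shape)]
    return MultiwayTable(names, labels, vals)
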