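import numpy as np
import pytest

from nartscale import ItemResponseMatrix, guttman, load_nart_fixture


@pytest.fixture(scope="session")
def nart_fixture():
    return load_nart_fixture()


@pytest.fixture
def staircase():
    """Perfect Guttman scalogram with every score pattern represented."""
    return guttman(44, 10)


@pytest.fixture
def coherent_scalogram():
    """Perfect scalogram in which every person scores all-0 or all-1."""
    rng = np.random.default_rng(7)
    passed = (rng.random(400) < 0.6).astype(np.int8)
    values = np.repeat(passed[:, None], 6, axis=1)
    return ItemResponseMatrix(values, tuple("abcdef"))


def matrix_from_rows(rows, labels=None):
    rows = np.asarray(rows, dtype=np.int8)
    if labels is None:
        labels = tuple(f"i{k}" for k in range(rows.shape[1]))
    return ItemResponseMatrix(rows, labels)
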