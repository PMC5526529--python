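"""Shared fixtures for the test suite."""

import numpy as np
import pytest

from mitoaudit.simulate import make_arborophila_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """The default seven-taxon synthetic benchmark (seed 0)."""
    return make_arborophila_benchmark(0)


@pytest.fixture(scope="session")
def benchmark_dir(tmp_path_factory):
    """The same benchmark written to disk (GenBank + ledger + trees)."""
    out = tmp_path_factory.mktemp("bench")
    make_arborophila_benchmark(0, out_dir=out)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
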