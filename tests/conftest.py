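import numpy as np
import pandas as pd
import pytest

from rnanet.simulate import SimulationSpec, simulate_counts, write_bundle


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    """Compact study: 120 genes, 2 modules, 24 samples."""
    return SimulationSpec(n_genes=120, n_modules=2, module_size=30, n_deg=30, go_terms=10, seed=11)


@pytest.fixture(scope="session")
def small_data(small_spec):
    return simulate_counts(small_spec)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory, small_spec):
    """A complete on-disk input bundle for pipeline-level tests."""
    out = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(out, small_spec)
    return paths


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_counts() -> pd.DataFrame:
    genes = [f"g{i}" for i in range(1, 7)]
    data = {
        "s1": [250, 0, 30, 120, 5, 95],
        "s2": [260, 0, 28, 115, 7, 90],
        "s3": [240, 1, 33, 130, 4, 92],
    }
    return pd.DataFrame(data, index=genes)
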