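import numpy as np
import pandas as pd
import pytest

from selnet.data import CountMatrix
from selnet.normalize import filter_by_cpm, upper_quartile_normalize
from selnet.simulate import SimulationConfig, simulate_count_dataset


@pytest.fixture
def toy_counts() -> CountMatrix:
    """5 genes x 4 samples with hand-pickable numbers."""
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 5, 100, 0],
            "s2": [20, 0, 10, 200, 0],
            "s3": [8, 2, 6, 90, 0],
            "s4": [12, 1, 4, 110, 0],
        },
        index=[f"g{i}" for i in range(1, 6)],
    )
    meta = pd.DataFrame(
        {"line": ["HIGH", "HIGH", "LOW", "LOW"], "region": ["VMB"] * 4},
        index=counts.columns,
    )
    return CountMatrix(counts, meta)


@pytest.fixture(scope="session")
def reference_sim():
    """The seeded reference simulation: 5 modules x 200 genes, 24+24 samples,
    within-module correlation 0.6, no planted effects."""
    cfg = SimulationConfig(
        n_genes=1000, n_modules=5, module_sizes=[200] * 5,
        within_module_corr=0.6, de_fraction=0.0, dw_gene_fraction=0.0,
        ds_gene_fraction=0.0, seed=1,
    )
    return simulate_count_dataset(cfg)


@pytest.fixture(scope="session")
def reference_norm(reference_sim):
    cm, _ = reference_sim
    return filter_by_cpm(upper_quartile_normalize(cm))


@pytest.fixture(scope="session")
def planted_sim():
    """Smaller simulation with planted DE and DW effects (power surface)."""
    cfg = SimulationConfig(
        n_genes=250, n_modules=5, module_sizes=[50] * 5,
        within_module_corr=0.8, de_fraction=0.1, de_log2fc=2.0,
        dw_gene_fraction=0.1, dw_delta_r=0.7, ds_gene_fraction=0.0, seed=7,
    )
    return simulate_count_dataset(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
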