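import numpy as np
import pandas as pd
import pytest

import lineagedec as ld


def random_signature(rng: np.random.Generator, n_genes: int = 300, k: int = 5
                     ) -> pd.DataFrame:
    """Well-conditioned random signature with log-normal entries."""
    return pd.DataFrame(
        rng.lognormal(0.0, 1.0, (n_genes, k)),
        index=[f"g{i:04d}" for i in range(n_genes)],
        columns=[f"type{j}" for j in range(k)],
    )


def small_sc_config(seed: int = 7, **overrides) -> ld.ScSimConfig:
    """A desk-scale single-cell config where QC keeps most cells."""
    defaults = dict(
        n_types=3, cells_per_type=60, n_genes=300, markers_per_type=10,
        marker_log2fc=2.0, mito_gene_count=5, mito_mean_factor=1.5,
        qc_fail_fraction=0.02, qc_min_features=50, qc_max_features=250,
        qc_max_mito=0.2, seed=seed,
    )
    defaults.update(overrides)
    return ld.ScSimConfig(**defaults)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def sc_dataset():
    """Simulated counts + annotations + truth from the small config."""
    cfg = small_sc_config()
    return ld.simulate_sc(cfg)


@pytest.fixture
def normalized_clusters(sc_dataset):
    """QC-passed, normalized expression with cluster labels."""
    counts, _, truth = sc_dataset
    stats = ld.compute_cell_stats(counts)
    filtered, _ = ld.qc_filter(counts, stats, min_features=50,
                               max_features=250, max_mito=0.2)
    expr = ld.normalize(filtered)
    labels = truth.type_labels.reindex(expr.columns)
    return expr, labels, truth
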