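import numpy as np
import pandas as pd
import pytest

from tissueqtl.synthetic_data import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """Modest bundle with one planted eQTL and one planted fQTL."""
    cfg = SimConfig(
        n_subjects=80,
        paired_fraction=0.5,
        n_snps=6,
        mafs=np.linspace(0.1, 0.5, 6),
        n_genes=120,
        n_gene_sets=8,
        gene_set_size_range=(6, 15),
        noise_sd=1.0,
        planted_eqtl=[("rs900000", "G00000", 1.5)],
        planted_fqtl=[("rs900002", "SET001", 0.6)],
        seed=11,
    )
    return simulate_bundle(cfg)


@pytest.fixture
def tiny_design():
    idx = [f"s{i}" for i in range(8)]
    rng = np.random.default_rng(3)
    return pd.DataFrame(
        {"intercept": 1.0, "x1": rng.normal(size=8), "x2": rng.normal(size=8)},
        index=idx,
    )
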