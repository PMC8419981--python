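import numpy as np
import pandas as pd
import pytest

import sumtune


@pytest.fixture
def toy_sumstats() -> pd.DataFrame:
    """Five well-behaved SNPs with complete fields."""
    rng = np.random.default_rng(0)
    n = 5
    maf = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    beta = rng.normal(0, 0.05, n)
    se = np.full(n, 0.02)
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(1, n + 1)],
            "a1": ["A", "C", "G", "T", "A"],
            "a2": ["G", "T", "A", "C", "G"],
            "beta": beta,
            "se": se,
            "p": 2 * sumtune.gwas_io.sps.norm.sf(np.abs(beta / se)),
            "n": [1000, 1200, 1100, 1000, 1300],
            "maf": maf,
        }
    )


@pytest.fixture(scope="session")
def quant_dataset() -> sumtune.SimDataset:
    """Moderate quantitative-trait simulation shared across tests."""
    cfg = sumtune.SimConfig(n_samples=1500, n_snps=500, h2=0.5, p_causal=0.05, seed=1234)
    return sumtune.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def quant_sumstats(quant_dataset) -> pd.DataFrame:
    return sumtune.marginal_gwas(quant_dataset)
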