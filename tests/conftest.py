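import numpy as np
import pandas as pd
import pytest

from cogpanel import SimulationConfig, simulate_genotypes, simulate_phenotypes
from cogpanel.behavior import summarize_by_strain
from cogpanel.simulate import stream_rngs


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_strains=12, reps_per_strain_age=4, seed=42,
                            n_chromosomes=4, markers_per_chromosome=10)


@pytest.fixture(scope="session")
def small_panel(small_config):
    """A simulated 12-strain panel: (geno, pheno, truth, summaries)."""
    rngs = stream_rngs(small_config.seed)
    geno = simulate_genotypes(small_config, rngs["genotypes"])
    pheno, truth = simulate_phenotypes(small_config, geno, rngs["phenotypes"])
    summaries = summarize_by_strain(pheno)
    return geno, pheno, truth, summaries


@pytest.fixture
def toy_summaries():
    """Hand-built strain summaries: 6 strains x 1 trait x 2 ages."""
    rows = []
    baselines = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]
    for i, b in enumerate(baselines):
        for age, mean in ((6, b), (14, b - 5.0)):
            rows.append({"strain": f"S{i}", "trait": "ymaze_alt",
                         "age_months": age, "n": 4, "mean": mean,
                         "sd": 4.0, "se": 2.0})
    return pd.DataFrame.from_records(rows)
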