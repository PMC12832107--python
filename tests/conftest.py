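import numpy as np
import pandas as pd
import pytest

from rmescope import ClonePanel, SimulationParams, Thresholds, simulate_panel


def make_panel(cast, r129, tpm=None, annotations=None, **kwargs):
    """Build a small ClonePanel from nested lists (genes x clones)."""
    cast = np.asarray(cast)
    genes = [f"g{i}" for i in range(cast.shape[0])]
    clones = [f"c{j}" for j in range(cast.shape[1])]
    if tpm is None:
        tpm = np.full(cast.shape, 50.0)
    return ClonePanel(
        cast=pd.DataFrame(cast, index=genes, columns=clones),
        r129=pd.DataFrame(np.asarray(r129), index=genes, columns=clones),
        tpm=pd.DataFrame(np.asarray(tpm, dtype=float), index=genes, columns=clones),
        annotations=annotations or {},
        **kwargs,
    )


@pytest.fixture
def defaults() -> Thresholds:
    return Thresholds()


@pytest.fixture(scope="session")
def sim_default():
    """One default simulated panel shared across tests (seed fixed)."""
    return simulate_panel(SimulationParams(seed=123))


@pytest.fixture(scope="session")
def sim_clean():
    """Deep, low-overdispersion panel for parameter-recovery checks."""
    params = SimulationParams(
        n_clones=100,
        gene_spec=(
            ("BIALLELIC", 100),
            ("ARME_BALANCED", 40),
            ("ARME_SKEWED", 20),
            ("AME_ONE_ALLELE", 20),
            ("IMPRINTED_LIKE", 12),
            ("X_LIKE", 8),
        ),
        f_me=0.6,
        rho=0.05,
        mean_expression=100.0,
        reads_per_tpm=10.0,
        seed=7,
    )
    return params, simulate_panel(params)
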