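import numpy as np
import pandas as pd
import pytest

from bayesrs import (
    GenotypeMatrix,
    MarkerMap,
    PhenotypeTable,
    SimConfig,
    simulate_study,
    standardize,
)
from bayesrs.mcmc import GibbsConfig, MixtureSpec
from bayesrs.segments import partition


@pytest.fixture(scope="session")
def tiny_study():
    """Small two-population study reused by chain-level tests."""
    cfg = SimConfig(
        n_source=300, n_target=150, n_validation=80,
        m_markers=300, n_chromosomes=3, n_qtl=6, seed=42,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def tiny_fit(tiny_study):
    """One short BayesR fit on the tiny study's source population."""
    from bayesrs.mcmc import fit_bayesr

    st = tiny_study
    W = standardize(st.source)
    y = st.source_pheno.values_for(st.source.sample_ids, "sim")
    mix = MixtureSpec.from_phenotypes(y, st.source_pheno.mean_reliability("sim"))
    part = partition(st.map, 50)
    summary = fit_bayesr(
        W, y, mix, part, cfg=GibbsConfig(n_iter=600, burn_in=300, seed=5)
    )
    return st, W, y, mix, part, summary


@pytest.fixture()
def small_genotypes():
    rng = np.random.default_rng(3)
    X = rng.integers(0, 3, size=(40, 12)).astype(float)
    # guarantee polymorphism
    X[0] = 0
    X[1] = 2
    return GenotypeMatrix(X, [f"s{i}" for i in range(40)], MarkerMap.default(12))


def make_phenotypes(sample_ids, values, trait="t", reliability=0.9):
    return PhenotypeTable(
        pd.DataFrame(
            {
                "sample_id": list(sample_ids),
                "trait": trait,
                "value": values,
                "reliability": reliability,
            }
        )
    )
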