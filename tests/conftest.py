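import numpy as np
import pandas as pd
import pytest

from htlmap import (
    DiallelDesign,
    FounderGenotypeMatrix,
    MarkerDef,
    SimConfig,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic diallel (10 founders, 20 markers) for fast tests."""
    cfg = SimConfig(
        n_founders=10,
        n_markers=20,
        n_planted=1,
        seed=42,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """The full-size synthetic study (19 founders, 85 markers, 3 planted)."""
    return simulate_study(SimConfig(seed=0))


@pytest.fixture
def toy_geno():
    """Six homozygous founders, two markers: one biallelic, one monomorphic."""
    calls = pd.DataFrame(
        {
            "mA": [154, 154, 154, 162, 162, 162],
            "mB": [150, 150, 150, 150, 150, 150],
        },
        index=[f"F{i}" for i in range(1, 7)],
        dtype=float,
    )
    markers = [MarkerDef("mA", "1", 100.0), MarkerDef("mB", "2", 200.0)]
    return FounderGenotypeMatrix(calls, markers=markers)


@pytest.fixture
def toy_design(toy_geno):
    return DiallelDesign.half_diallel(toy_geno.founder_ids)


@pytest.fixture
def toy_pheno(toy_design):
    """Deterministic phenotypes: founders at fixed means, hybrids above."""
    rows = []
    means = {f"F{i}": 80.0 + 5 * i for i in range(1, 7)}
    for f, mu in means.items():
        for r in range(1, 4):
            rows.append(
                {"entry": f, "year": 2010, "replicate": r, "DPW": mu + (r - 2)}
            )
    for _, row in toy_design.crosses.iterrows():
        mu = (means[row["female"]] + means[row["male"]]) / 2 * 1.2
        for r in range(1, 4):
            rows.append(
                {
                    "entry": row["cross_id"],
                    "year": 2010,
                    "replicate": r,
                    "DPW": mu + (r - 2),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
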