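import numpy as np
import pandas as pd
import pytest

from lungsort import (
    AnalysisConfig,
    TaxaCountTable,
    TaxaProfile,
    average_controls,
    make_templates,
)


@pytest.fixture
def small_table() -> TaxaCountTable:
    return TaxaCountTable(
        pd.DataFrame({"s1": [5, 5], "s2": [0, 10]}, index=["TaxA", "TaxB"])
    )


@pytest.fixture
def worked_control():
    """The two-taxon control used by the worked filtering examples."""
    return average_controls([TaxaProfile.from_dict({"X": 0.5, "Y": 0.5})])


@pytest.fixture
def worked_sample() -> TaxaProfile:
    """A pure-A community admixed with the worked control at proportion 0.4."""
    return TaxaProfile.from_dict({"A": 0.6, "X": 0.2, "Y": 0.2})


@pytest.fixture
def three_taxon_profile() -> TaxaProfile:
    return TaxaProfile.from_dict({"A": 0.5, "B": 0.3, "C": 0.2})


@pytest.fixture
def default_template():
    return make_templates(n_taxa=25, overlap=0.3, seed=0)


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig(n_permutations=99, nmds_restarts=4, rng_seed=0)


def random_profile_pair(rng: np.random.Generator, n_taxa: int | None = None):
    """A random (experimental, control) profile pair on a shared taxon set."""
    n = int(n_taxa or rng.integers(5, 51))
    taxa = [f"t{i}" for i in range(n)]
    exp = TaxaProfile(pd.Series(rng.dirichlet(np.full(n, 0.7)), index=taxa))
    cont_support = rng.choice(n, size=max(2, n // 2), replace=False)
    cont = np.zeros(n)
    cont[cont_support] = rng.dirichlet(np.full(len(cont_support), 1.0))
    cont = TaxaProfile(pd.Series(cont, index=taxa))
    return exp, cont
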