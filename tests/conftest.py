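import logging

import numpy as np
import pandas as pd
import pytest

from riverdiv.data import DEFAULT_TRAIT_SCHEMA, CommunityMatrix, Phylogeny, TraitTable
from riverdiv.simulate import ScenarioConfig, generate_bundle

logging.getLogger("riverdiv").setLevel(logging.ERROR)


@pytest.fixture
def toy_community():
    table = pd.DataFrame(
        [[3, 0, 2], [1, 2, 0], [0, 5, 4], [2, 2, 2], [1, 0, 0]],
        index=[f"s{i}" for i in range(1, 6)],
        columns=["A", "B", "C"],
    )
    return CommunityMatrix(table)


@pytest.fixture
def newick_abc():
    return "((A:1,B:1):1,C:2);"


@pytest.fixture
def tree_abc(newick_abc):
    return Phylogeny.from_newick(newick_abc)


@pytest.fixture
def star3():
    return Phylogeny.from_newick("(A:1,B:1,C:1);")


def random_trait_table(n_species, seed=0, schema=DEFAULT_TRAIT_SCHEMA):
    rng = np.random.default_rng(seed)
    width = len(str(n_species))
    names = [f"sp{i + 1:0{width}d}" for i in range(n_species)]
    data = {c: rng.lognormal(0.0, 0.4, n_species) for c in schema.continuous}
    for col, levels in schema.categorical.items():
        data[col] = rng.choice(levels, n_species)
    return TraitTable(pd.DataFrame(data, index=names), schema)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(
        ScenarioConfig(n_species=12, n_sites=6, n_sources=4, n_dams=2, seed=3)
    )


@pytest.fixture(scope="session")
def bundle10():
    return generate_bundle(
        ScenarioConfig(n_species=15, n_sites=10, n_sources=8, n_dams=3, seed=7)
    )
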