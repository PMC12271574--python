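import io

import numpy as np
import pandas as pd
import pytest
import skbio

from plumedpr import core_io, synthetic_data as sd

TOY_NEWICK = "((A:1,B:2):1,C:3);"


@pytest.fixture
def toy_tree():
    return skbio.TreeNode.read(io.StringIO(TOY_NEWICK))


@pytest.fixture
def two_clade_tree():
    """Two deep clades of three close tips each (for dispersion checks)."""
    nwk = ("(((A:0.05,B:0.05):0.05,C:0.1):0.9,"
           "((D:0.05,E:0.05):0.05,F:0.1):0.9);")
    return skbio.TreeNode.read(io.StringIO(nwk))


@pytest.fixture(scope="session")
def fixture_dataset():
    """Small synthetic survey (30 samples x 60 taxa), shared across tests."""
    return sd.simulate_dataset(sd.fixture_config(seed=3))


@pytest.fixture(scope="session")
def fixture_rarefied(fixture_dataset):
    return core_io.rarefy(fixture_dataset["counts"], seed=3)


def random_counts(rng, n_samples=6, n_taxa=8, fill=0.5, max_count=5):
    """Random sparse integer community matrix."""
    mat = rng.integers(1, max_count + 1, (n_samples, n_taxa))
    mat = mat * (rng.random((n_samples, n_taxa)) < fill)
    return pd.DataFrame(
        mat, index=[f"s{i}" for i in range(n_samples)],
        columns=[f"t{j}" for j in range(n_taxa)],
    )
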