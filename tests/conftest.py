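import numpy as np
import pandas as pd
import pytest

import sigvecta as sv
from sigvecta import fixtures as fx


@pytest.fixture(scope="session")
def small_collection():
    """Four-signature collection from planted datasets run through the CD pipeline."""
    collection, truths = fx.make_collection(
        n_signatures=4, n_genes=150, n_planted=15, seed=7
    )
    return collection, truths


@pytest.fixture(scope="session")
def small_library(small_collection):
    collection, truths = small_collection
    background = collection.gene_union()
    planted = frozenset(truths[0].planted_up | truths[0].planted_down)
    library, truth = fx.make_library(
        n_sets=40, set_size_range=(8, 25), background=background,
        planted_genes=planted, seed=7,
    )
    return library, truth


@pytest.fixture(scope="session")
def small_compound_library(small_collection):
    collection, _ = small_collection
    library, truth = fx.make_compound_library(
        collection.signatures[0], n_compounds=60, noise_sd=0.1, seed=7
    )
    return library, truth


@pytest.fixture
def tiny_dataset():
    """4 genes × 4 samples, 2 control vs 2 perturbation."""
    rng = np.random.default_rng(3)
    values = pd.DataFrame(
        rng.normal(8, 1, (4, 4)),
        index=["GA", "GB", "GC", "GD"],
        columns=["c1", "c2", "p1", "p2"],
    )
    labels = pd.Series(
        [sv.CONTROL, sv.CONTROL, sv.PERTURBATION, sv.PERTURBATION],
        index=values.columns,
    )
    return sv.ExpressionDataset(values, labels, "human")
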