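import numpy as np
import pandas as pd
import pytest

from netrank import make_dataset, make_worked_fixture
from netrank.simulate import SyntheticSpec


@pytest.fixture(scope="session")
def worked():
    """Tiny deterministic bundle: dataset + 2-node and 5-node networks."""
    return make_worked_fixture()


@pytest.fixture(scope="session")
def default_dataset():
    """The generator at its default (stated-world) parameters, seed 0."""
    return make_dataset()


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 60-gene dataset for stage-level tests."""
    return make_dataset(
        SyntheticSpec(
            n_genes=60,
            n_samples=120,
            n_cases=40,
            n_biomarkers=6,
            n_modules=6,
            seed=7,
        )
    )


@pytest.fixture
def toy_expr():
    """3 genes x 4 samples with hand-checkable values."""
    return pd.DataFrame(
        [[2.0, 4.0, 6.0, 8.0], [1.0, 1.0, 2.0, 2.0], [5.0, 3.0, 1.0, 7.0]],
        index=pd.Index(["G1", "G2", "G3"], name="gene_id"),
        columns=["S1", "S2", "S3", "S4"],
    )


def random_network(rng, n, density=0.3):
    """Random weighted undirected graph with weights in (0, 1]."""
    import scipy.sparse as sp

    from netrank import GeneNetwork

    upper = np.triu(rng.random((n, n)) < density, k=1)
    w = np.where(upper, rng.uniform(0.05, 1.0, (n, n)), 0.0)
    adj = w + w.T
    return GeneNetwork(pd.Index([f"g{i:03d}" for i in range(n)]), sp.csr_matrix(adj))


def random_prior(rng, node_ids):
    s = rng.uniform(0.0, 1.0, len(node_ids))
    return pd.DataFrame(
        {"raw_r": s, "s": s, "p_value": rng.uniform(0, 1, len(node_ids))},
        index=pd.Index(node_ids, name="gene_id"),
    )
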