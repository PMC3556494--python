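import numpy as np
import pandas as pd
import pytest

import lnskit as lk


def make_dataset(values, gene_ids=None, array_ids=None, dataset_id="test"):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(values.shape[0])]
    array_ids = array_ids or [f"a{i + 1}" for i in range(values.shape[1])]
    return lk.ExpressionDataset(
        dataset_id=dataset_id,
        values=pd.DataFrame(values, index=gene_ids, columns=array_ids),
    )


@pytest.fixture(scope="session")
def default_fixture():
    """Default synthetic two-species compendium with planted divergence."""
    spec = lk.SyntheticSpec()
    ds_a, ds_b, om, truth = lk.generate_compendium(spec)
    return spec, ds_a, ds_b, om, truth


@pytest.fixture(scope="session")
def networks(default_fixture):
    """Aggregated connection matrices of the default fixture, both species."""
    _, ds_a, ds_b, om, truth = default_fixture
    conn_a = lk.build_global_network([lk.preprocess(d) for d in ds_a])
    conn_b = lk.build_global_network([lk.preprocess(d) for d in ds_b])
    return conn_a, conn_b, om, truth


@pytest.fixture(scope="session")
def global_table(networks):
    conn_a, conn_b, om, truth = networks
    return lk.global_lns(conn_a, conn_b, om)


@pytest.fixture(scope="session")
def pooled_null(networks):
    """>= 10,000 pooled null LNS samples (34 permutations x 300 pairs)."""
    conn_a, conn_b, om, _ = networks
    return lk.randomized_null(conn_a, conn_b, om, n_permutations=34, seed=17)
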