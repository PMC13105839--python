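import numpy as np
import pandas as pd
import pytest

from sctrim import (ClusterAssignment, ExpressionMatrix, PlantedParams,
                    gen_planted_dataset, log_normalize)
from sctrim.knn_trim import NeighborDistances


@pytest.fixture(scope="session")
def planted():
    """Default planted dataset: 3 clusters, 10% border cells, inflation x4."""
    return gen_planted_dataset(PlantedParams(seed=1))


@pytest.fixture(scope="session")
def planted_fragile():
    """Planted dataset with a border-only ("fragile") marker in cluster 0."""
    return gen_planted_dataset(PlantedParams(seed=1, fragile_cluster=0))


@pytest.fixture(scope="session")
def planted_norm(planted):
    return log_normalize(planted.counts)


def make_matrix(values, layer="lognorm", gene_prefix="g", cell_prefix="c"):
    values = np.asarray(values, dtype=float)
    d, n = values.shape
    return ExpressionMatrix(values, [f"{gene_prefix}{i}" for i in range(d)],
                            [f"{cell_prefix}{j}" for j in range(n)], layer=layer)


def make_nd(values_by_cluster):
    """NeighborDistances carrying prescribed min_dist values per cluster.

    Lets the quantile-trimming rule be tested directly against enumeration
    oracles without constructing geometry.
    """
    cell_ids, labels, mins = [], [], []
    for cl, vals in values_by_cluster.items():
        for i, v in enumerate(vals):
            cell_ids.append(f"{cl}_{i}")
            labels.append(cl)
            mins.append(float(v))
    return (NeighborDistances(
        k=1, cell_ids=cell_ids,
        cluster_of=pd.Series(labels, index=cell_ids, name="cluster"),
        neighbor_ids=[[] for _ in cell_ids],
        distances=[np.empty(0) for _ in cell_ids],
        min_dist=np.array(mins)),
        ClusterAssignment.from_arrays(cell_ids, labels))
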