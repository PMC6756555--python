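import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from switchnet import RunConfig, SyntheticSpec, generate_dataset, run_pipeline
from switchnet.network import CorrelationNetwork, CommunityAssignment


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset (seed 1) with its planted truth."""
    return generate_dataset(SyntheticSpec())


@pytest.fixture(scope="session")
def default_run(default_dataset):
    """Full pipeline result on the default dataset at default settings."""
    matrix, truth = default_dataset
    return run_pipeline(matrix, RunConfig(seed=1)), truth


@pytest.fixture(scope="session")
def ten_seed_runs():
    """Pipeline results on the default study conditions over seeds 1..10."""
    out = []
    for seed in range(1, 11):
        spec = dataclasses.replace(SyntheticSpec(), seed=seed)
        matrix, truth = generate_dataset(spec)
        out.append((run_pipeline(matrix, RunConfig(seed=seed)), truth))
    return out


def small_network(edges: list[tuple[str, str, float]]) -> CorrelationNetwork:
    """Hand-built signed network for cartography tests."""
    g = nx.Graph()
    g.add_weighted_edges_from(edges)
    return CorrelationNetwork(g, r_threshold=0.5)


def communities(labels: dict[str, int]) -> CommunityAssignment:
    k = len(set(labels.values()))
    return CommunityAssignment(labels, k=k, scree=[], n_replicates=1, seed=0)


def toy_matrix(values: np.ndarray, n_disease: int, n_control: int, gene_prefix="g"):
    """ExpressionMatrix from a raw array, disease columns first."""
    from switchnet.expression import ExpressionMatrix, DISEASE, CONTROL

    n = n_disease + n_control
    assert values.shape[1] == n
    samples = [f"s{i}" for i in range(n)]
    groups = pd.Series([DISEASE] * n_disease + [CONTROL] * n_control, index=samples)
    df = pd.DataFrame(
        values, index=[f"{gene_prefix}{i}" for i in range(values.shape[0])], columns=samples
    )
    return ExpressionMatrix(df, groups)
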