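import pandas as pd
import pytest
from hypothesis import settings

from metanmf import ExpressionDataset, SimulationConfig, simulate_expression

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_dataset():
    """4 probes x 4 samples, hand-checkable values; probes p3/p4 share a gene."""
    matrix = pd.DataFrame(
        [[1.0, 3.0, 5.0, 7.0],
         [2.0, 2.0, 2.0, 2.0],
         [1.0, 3.0, 2.0, 4.0],
         [3.0, 5.0, 4.0, 6.0]],
        index=["p1", "p2", "p3", "p4"],
        columns=["s1", "s2", "s3", "s4"],
    )
    groups = pd.Series(["control", "control", "case", "case"],
                       index=["s1", "s2", "s3", "s4"], name="group")
    annotation = pd.Series(["GA", "GB", "GC", "GC"],
                           index=["p1", "p2", "p3", "p4"], name="gene_symbol")
    return ExpressionDataset(matrix=matrix, groups=groups,
                             annotation=annotation)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale simulation config used across tests."""
    return SimulationConfig(
        n_genes=300, n_probes_per_gene=(1, 3), n_samples_per_group=(5, 6),
        n_de_up=20, n_de_down=40, de_logfc_range=(0.8, 1.5), r_true=5,
        noise_sd=0.2, network_n_nodes=200, network_planted_hub_degree=20,
        n_hubs=4, seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_expression(small_config)
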