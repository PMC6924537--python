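import numpy as np
import pytest

from connectopharm import CohortSpec, generate_cohort
from connectopharm.connectivity import AssociationMatrix, BinaryGraph
from connectopharm.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Small cohort: enough structure for recovery, fast enough for units."""
    return CohortSpec(
        n_controls=8,
        n_patients=6,
        n_nodes=60,
        n_volumes=145,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def demo_config(tmp_path_factory) -> PipelineConfig:
    """The demo configuration: 20 controls, 10 patients, 90 nodes, 145 volumes."""
    return PipelineConfig(
        output_dir=str(tmp_path_factory.mktemp("demo")),
        cohort=CohortSpec(n_controls=20, n_patients=10, n_nodes=90, seed=5),
        densities=[round(0.01 * i, 2) for i in range(3, 11)],
        louvain_restarts=5,
        write_graphs=False,
    )


@pytest.fixture()
def four_node_assoc() -> AssociationMatrix:
    """The worked local-thresholding example."""
    w = np.eye(4)
    for (i, j), v in {
        (0, 1): 0.9,
        (0, 2): 0.8,
        (0, 3): 0.7,
        (2, 3): 0.3,
        (1, 3): 0.2,
        (1, 2): 0.1,
    }.items():
        w[i, j] = w[j, i] = v
    return AssociationMatrix(w)


def make_graph(n: int, edges) -> BinaryGraph:
    pairs = sorted(tuple(sorted(e)) for e in edges)
    return BinaryGraph(n_nodes=n, edges=np.asarray(pairs, dtype=int))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
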