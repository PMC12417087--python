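import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from stagewalk import BackgroundNetwork, ExpressionMatrix, StagePartition

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_expr():
    """5 genes x 6 samples with heterogeneous variability."""
    rng = np.random.default_rng(42)
    values = rng.normal(5.0, 1.0, size=(5, 6))
    values[0] = 5.0  # constant gene
    genes = [f"g{i}" for i in range(5)]
    samples = [f"s{j}" for j in range(6)]
    return ExpressionMatrix(genes, samples, values)


@pytest.fixture
def toy_stages(toy_expr):
    assignment = {s: ("early" if i < 3 else "late") for i, s in enumerate(toy_expr.sample_ids)}
    return StagePartition(["early", "late"], assignment)


@pytest.fixture
def toy_background():
    """5-node weighted path-plus-chord network."""
    genes = [f"g{i}" for i in range(5)]
    edges = [(0, 1, 0.9), (1, 2, 0.5), (2, 3, 0.8), (3, 4, 0.4), (0, 2, 0.3)]
    rows = [i for i, _, _ in edges] + [j for _, j, _ in edges]
    cols = [j for _, j, _ in edges] + [i for i, _, _ in edges]
    w = [w for _, _, w in edges] * 2
    A = sp.coo_matrix((w, (rows, cols)), shape=(5, 5)).tocsr()
    return BackgroundNetwork(genes, A)


def random_instance(rng, n, s):
    """Random multilayer transition + restart pair for solver oracles."""
    from stagewalk import StageNetwork, assemble, column_normalize

    genes = [f"g{i}" for i in range(n)]
    A = rng.random((n, n)) * (rng.random((n, n)) < 0.4)
    A = np.triu(A, 1)
    A = A + A.T
    background = BackgroundNetwork(genes, sp.csr_matrix(A))
    stage_nets = []
    for k in range(s):
        B = rng.random((n, n)) * (rng.random((n, n)) < 0.3)
        B = np.triu(B, 1)
        stage_nets.append(StageNetwork(f"st{k}", sp.csr_matrix(B + B.T)))
    net = assemble(background, stage_nets, delta=0.5, mu=0.5, mode="full")
    raw = rng.random(net.n_nodes)
    prs = raw / raw.sum()
    tlc = column_normalize(net.transition, prs)
    return tlc, prs, net
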