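import numpy as np
import pytest

from edgemix.calling import Network
from edgemix.model import L2NParams
from edgemix.weights import ExpressionMatrix


def make_network(n_nodes: int, edges, signs=None, weights=None) -> Network:
    """Build a Network from a plain edge list [(m, n), ...]."""
    edges = [(min(a, b), max(a, b)) for a, b in edges]
    m = np.array([e[0] for e in edges], dtype=np.int64)
    n = np.array([e[1] for e in edges], dtype=np.int64)
    if signs is None:
        signs = np.ones(len(edges), dtype=np.int8)
    if weights is None:
        weights = np.ones(len(edges))
    return Network(
        gene_ids=[f"g{i}" for i in range(n_nodes)],
        edges_m=m, edges_n=n,
        signs=np.asarray(signs), edge_weights=np.asarray(weights),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_expression(rng) -> ExpressionMatrix:
    """12 genes x 20 samples with two strongly correlated pairs."""
    G, N = 12, 20
    X = rng.standard_normal((G, N))
    X[1] = X[0] + 0.05 * rng.standard_normal(N)       # strong positive pair
    X[3] = -X[2] + 0.05 * rng.standard_normal(N)      # strong negative pair
    return ExpressionMatrix(
        values=X,
        gene_ids=[f"gene{i}" for i in range(G)],
        sample_ids=[f"s{j}" for j in range(N)],
    )


@pytest.fixture
def generic_params() -> L2NParams:
    """A valid parameter set with both non-null components populated."""
    return L2NParams(
        p0=0.90, p1=0.06, p2=0.04,
        sigma2=1.0 / 97.0,
        theta1=-0.25, kappa1sq=0.25,
        theta2=-0.50, kappa2sq=0.16,
        n_samples=100,
    )


def draw_l2n_weights(K, p0, p1, p2, sigma2, theta1, kappa1sq, theta2,
                     kappa2sq, seed):
    """Sample weights (and their true component labels) from the mixture."""
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=K, p=[p0, p1, p2])
    w = rng.normal(0.0, np.sqrt(sigma2), K)
    n1 = int((comp == 1).sum())
    n2 = int((comp == 2).sum())
    w[comp == 1] = rng.lognormal(theta1, np.sqrt(kappa1sq), n1)
    w[comp == 2] = -rng.lognormal(theta2, np.sqrt(kappa2sq), n2)
    return w, comp
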