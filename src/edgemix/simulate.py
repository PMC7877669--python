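"""Synthetic networks and expression data with known ground truth.

Two generation protocols:

* :func:`gen_l2n_graph` — weights are drawn directly from the L2N model
  (null pairs ~ Normal(0, 1/(N-3)), non-null pairs ~ +/- lognormal placed
  according to a chosen clique/band structure), back-transformed to
  correlations with tanh, PSD-repaired, and used as the covariance of a
  zero-mean multivariate normal expression sample.  This tests the method
  on its own turf.
* :func:`gen_structure_graph` — an adjacency matrix of a classic shape
  (random / hub / band / scale-free / overlapped-cluster) is turned into
  a precision matrix Omega = v*A with a diagonal-dominant diagonal
  (mirroring the huge R package's convention: diag = |lambda_min| + 0.1 + u),
  inverted and rescaled to a correlation matrix.  The data are Gaussian
  but NOT generated from the mixture model, so this protocol probes
  robustness to model misspecification.

Both return (TrueGraph, ExpressionMatrix) and are bit-reproducible from
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform

from .weights import ExpressionMatrix, pair_arrays, pair_count, pair_to_index

__all__ = [
    "L2NSimConfig",
    "StructureSimConfig",
    "TrueGraph",
    "gen_l2n_graph",
    "gen_structure_graph",
    "repair_psd",
]

L2N_STRUCTURES = ("complete", "ar", "two_blocks", "neg_blocks")
OTHER_STRUCTURES = ("random", "hub", "band", "scale_free", "overlapped_cluster")


@dataclass
class L2NSimConfig:
    """Configuration for the mixture-model-based generator.

    ``structure`` is one of 'complete' (one S-clique), 'ar' (banded decay
    within the first S genes), 'two_blocks' (two independent S-cliques),
    'neg_blocks' (two S-cliques, positively correlated within and
    negatively across).  theta1/kappa1sq parameterize the positive
    lognormal; theta2/kappa2sq default to mirroring them (used only by
    neg_blocks).
    """

    structure: str
    G: int = 500
    S: int = 100
    N: int = 100
    theta1: float = 0.0
    kappa1sq: float = 0.25
    theta2: float | None = None
    kappa2sq: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.structure not in L2N_STRUCTURES:
            raise ValueError(f"unknown L2N structure: {self.structure!r}")
        if self.theta2 is None:
            self.theta2 = self.theta1
        if self.kappa2sq is None:
            self.kappa2sq = self.kappa1sq
        need = 2 * self.S if self.structure in ("two_blocks", "neg_blocks") else self.S
        if need > self.G:
            raise ValueError(f"structure needs {need} genes but G={self.G}")
        if self.S < 2:
            raise ValueError("block size S must be >= 2")
        if self.N <= 3:
            raise ValueError("need N > 3")


@dataclass
class StructureSimConfig:
    """Configuration for the structure-based (huge-style) generator.

    ``p`` is the Bernoulli edge probability (random / overlapped_cluster);
    ``g`` is the group count (hub, overlapped_cluster) or bandwidth (band).
    ``v`` and ``u`` control the precision-matrix construction; defaults
    follow the huge package (v=0.3, u=0.1).  With ``exact_edge_count``
    (default) the scale-free generator adds one extra random edge to the
    Barabasi-Albert tree so that |E| = G exactly.
    """

    structure: str
    G: int = 1000
    N: int = 70
    p: float | None = None
    g: int | None = None
    v: float = 0.3
    u: float = 0.1
    exact_edge_count: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.structure not in OTHER_STRUCTURES:
            raise ValueError(f"unknown structure: {self.structure!r}")
        if self.structure in ("random", "overlapped_cluster"):
            if self.p is None or not (0.0 < self.p < 1.0):
                raise ValueError(f"{self.structure} needs edge probability p in (0,1)")
        if self.structure in ("hub", "overlapped_cluster"):
            if self.g is None or not (2 <= self.g <= self.G):
                raise ValueError(f"{self.structure} needs group count g in [2, G]")
        if self.structure == "band":
            if self.g is None or not (1 <= self.g <= self.G - 1):
                raise ValueError("band needs bandwidth g in [1, G-1]")
        if self.N <= 3:
            raise ValueError("need N > 3")


@dataclass
class TrueGraph:
    """Ground truth of a simulation: adjacency, covariance, provenance.

    ``edge_mask`` marks true edges over the canonical K-pair ordering;
    ``true_signs`` is +1/-1/0 per pair (sign of the generating weight for
    the L2N protocol, +1 for structure-based edges).
    """

    n_genes: int
    edge_mask: np.ndarray       # (K,) bool
    true_signs: np.ndarray      # (K,) int8
    sigma: np.ndarray           # G x G correlation used for sampling
    config: dict
    gen_weights: np.ndarray | None = None  # (K,) generating z-weights (L2N protocol)

    def __post_init__(self) -> None:
        K = pair_count(self.n_genes)
        if self.edge_mask.shape != (K,):
            raise ValueError("edge_mask must cover all K pairs")

    @property
    def n_edges(self) -> int:
        return int(self.edge_mask.sum())

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_genes, self.n_genes), dtype=np.int8)
        m, n = pair_arrays(self.n_genes)
        A[m[self.edge_mask], n[self.edge_mask]] = 1
        return A + A.T

    def edge_list(self) -> tuple[np.ndarray, np.ndarray]:
        m, n = pair_arrays(self.n_genes)
        return m[self.edge_mask], n[self.edge_mask]


def nearest_correlation(M: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Project a symmetric matrix onto the correlation-matrix cone.

    Higham's alternating-projections method (via statsmodels) finds the
    Frobenius-nearest correlation matrix, which preserves the generating
    signal far better than spectral clipping with diagonal rescaling when
    the input is far from PSD (pairwise-sampled correlation "matrices"
    are): clipping+rescaling shrinks every entry multiplicatively, while
    the nearest-matrix projection spreads the (inherently unavoidable)
    adjustment evenly.  A final eigenvalue clip at ``eps`` guarantees
    strict positive definiteness for the Cholesky sampler.
    """
    import warnings

    from statsmodels.stats.correlation_tools import corr_nearest

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        R = corr_nearest(np.asarray(M, dtype=float), threshold=1e-6, n_fact=0.12)
    return repair_psd(R, eps=eps)


def repair_psd(M: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Nearest-by-clipping PSD repair of a symmetric matrix.

    Eigenvalues below ``eps`` are raised to ``eps``, the matrix is
    reassembled and its diagonal rescaled to 1.  A matrix whose spectrum
    already clears ``eps`` is returned unchanged.
    """
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("repair_psd expects a symmetric matrix")
    vals, vecs = np.linalg.eigh(M)
    if vals[0] >= eps:
        return M
    vals = np.clip(vals, eps, None)
    R = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def _sample_expression(rng, sigma: np.ndarray, N: int) -> np.ndarray:
    """Draw N zero-mean multivariate-normal samples with covariance sigma;
    returns genes x samples."""
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(sigma + 1e-8 * np.eye(sigma.shape[0]))
    return L @ rng.standard_normal((sigma.shape[0], N))


def _as_expression(X: np.ndarray) -> ExpressionMatrix:
    G, N = X.shape
    return ExpressionMatrix(
        values=X,
        gene_ids=[f"g{i:04d}" for i in range(G)],
        sample_ids=[f"s{j:04d}" for j in range(N)],
    )


# ---------------------------------------------------------------------------
# L2N-model-based generation
# ---------------------------------------------------------------------------

def _block_pair_indices(genes: np.ndarray, G: int) -> np.ndarray:
    """Canonical pair indices of all pairs within a set of gene indices."""
    gm, gn = np.triu_indices(genes.size, k=1)
    return pair_to_index(genes[gm], genes[gn], G)


def gen_l2n_graph(cfg: L2NSimConfig) -> tuple[TrueGraph, ExpressionMatrix]:
    """Generate weights from the L2N model, then expression data.

    Null pairs get weights ~ Normal(0, 1/(N-3)); non-null pairs get
    (+/-) LogNormal(theta, kappa^2) draws placed according to the
    structure.  The weight matrix is mapped to correlations with tanh,
    PSD-repaired, and N multivariate-normal samples are drawn.
    """
    rng = np.random.default_rng(cfg.seed)
    G, S, N = cfg.G, cfg.S, cfg.N
    K = pair_count(G)
    null_sd = np.sqrt(1.0 / (N - 3))
    w = rng.normal(0.0, null_sd, size=K)
    signs = np.zeros(K, dtype=np.int8)

    if cfg.structure in ("complete", "ar"):
        blocks = [np.arange(S)]
    else:
        blocks = [np.arange(S), np.arange(S, 2 * S)]

    if cfg.structure == "ar":
        idx = _block_pair_indices(blocks[0], G)
        draws = np.sort(
            rng.lognormal(cfg.theta1, np.sqrt(cfg.kappa1sq), size=idx.size)
        )[::-1]
        # band k (|m-n| = k) receives the k-th largest group of S-k draws,
        # randomly permuted within the band
        m_all, n_all = pair_arrays(G)
        pos = 0
        for band in range(1, S):
            members = np.arange(S - band)
            band_idx = pair_to_index(members, members + band, G)
            vals = draws[pos:pos + band_idx.size]
            pos += band_idx.size
            w[band_idx] = rng.permutation(vals)
            signs[band_idx] = 1
    else:
        for blk in blocks:
            idx = _block_pair_indices(blk, G)
            w[idx] = rng.lognormal(cfg.theta1, np.sqrt(cfg.kappa1sq), size=idx.size)
            signs[idx] = 1
        if cfg.structure == "neg_blocks":
            cross = pair_to_index(
                np.repeat(blocks[0], S), np.tile(blocks[1], S), G
            )
            w[cross] = -rng.lognormal(
                cfg.theta2, np.sqrt(cfg.kappa2sq), size=cross.size
            )
            signs[cross] = -1

    R = squareform(np.tanh(w))
    np.fill_diagonal(R, 1.0)
    R = nearest_correlation(R)
    X = _sample_expression(rng, R, N)

    truth = TrueGraph(
        n_genes=G,
        edge_mask=signs != 0,
        true_signs=signs,
        sigma=R,
        config={"generator": "l2n", **asdict(cfg)},
        gen_weights=w,
    )
    return truth, _as_expression(X)


# ---------------------------------------------------------------------------
# structure-based (huge-style) generation
# ---------------------------------------------------------------------------

def _adjacency_mask(cfg: StructureSimConfig, rng) -> np.ndarray:
    """True-edge mask over the canonical K pairs for each structure."""
    G = cfg.G
    K = pair_count(G)
    m, n = pair_arrays(G)
    mask = np.zeros(K, dtype=bool)

    if cfg.structure == "random":
        mask = rng.random(K) < cfg.p

    elif cfg.structure == "hub":
        # g disjoint groups; members connect only to the group's first node
        for grp in np.array_split(np.arange(G), cfg.g):
            center, leaves = grp[0], grp[1:]
            if leaves.size:
                mask[pair_to_index(np.full(leaves.size, center), leaves, G)] = True

    elif cfg.structure == "band":
        mask = (n - m) <= cfg.g

    elif cfg.structure == "scale_free":
        gr = nx.barabasi_albert_graph(G, 1, seed=int(rng.integers(2**31)))
        em = np.array([min(e) for e in gr.edges()])
        en = np.array([max(e) for e in gr.edges()])
        mask[pair_to_index(em, en, G)] = True
        if cfg.exact_edge_count:
            # one extra random non-edge brings |E| from G-1 up to G
            absent = np.nonzero(~mask)[0]
            mask[rng.choice(absent)] = True

    elif cfg.structure == "overlapped_cluster":
        s = G // cfg.g
        shared = int(np.floor(0.2 * s))
        stride = s - shared
        for i in range(cfg.g):
            grp = np.arange(i * stride, min(i * stride + s, G))
            if grp.size < 2:
                break
            idx = _block_pair_indices(grp, G)
            mask[idx] |= rng.random(idx.size) < cfg.p

    return mask


def gen_structure_graph(cfg: StructureSimConfig) -> tuple[TrueGraph, ExpressionMatrix]:
    """Generate a structured adjacency and Gaussian data (huge convention).

    Omega = v * A with diagonal |lambda_min(vA)| + 0.1 + u (positive
    definite by construction); Sigma = cov2cor(Omega^{-1}); X ~ MVN(0, Sigma).
    """
    rng = np.random.default_rng(cfg.seed)
    G = cfg.G
    mask = _adjacency_mask(cfg, rng)
    m, n = pair_arrays(G)

    A = np.zeros((G, G))
    A[m[mask], n[mask]] = 1.0
    A += A.T
    omega = cfg.v * A
    lam_min = np.linalg.eigvalsh(omega)[0]
    np.fill_diagonal(omega, abs(lam_min) + 0.1 + cfg.u)
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    sigma = sigma / np.outer(d, d)
    np.fill_diagonal(sigma, 1.0)
    X = _sample_expression(rng, sigma, cfg.N)

    truth = TrueGraph(
        n_genes=G,
        edge_mask=mask,
        true_signs=mask.astype(np.int8),
        sigma=sigma,
        config={"generator": "structure", **asdict(cfg)},
    )
    return truth, _as_expression(X)
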