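"""From fitted mixture to edge set: thresholds, error control, adjacency.

An edge is called for pair (m, n) when its weight falls outside an
interval [c2, c1] with c2 < 0 < c1.  Three criteria to choose (c1, c2):

* posterior ratio: smallest w > 0 with p1 f1(w) / (p0 f0(w)) > T, and the
  mirrored quantity on the negative side;
* Type-I control: p0 [F0(c2) + 1 - F0(c1)] <= alpha, with alpha split
  between the tails (proportionally to the fitted non-null masses by
  default);
* FDR control: model-based (mixture-tail) FDR
  p0 (null mass outside [c2, c1]) / (total mixture mass outside [c2, c1])
  <= q, searched over the one-parameter ratio-threshold family so the
  rejection regions are nested in q.

All tail masses use closed-form normal / lognormal CDFs, never
quadrature, so the same code scales to 10^8 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import norm

from .model import L2NParams, posterior
from .weights import WeightVector, pair_arrays

__all__ = [
    "ThresholdPair",
    "Network",
    "thresholds_from_ratio",
    "thresholds_from_alpha",
    "thresholds_from_fdr",
    "type1_estimate",
    "type2_estimate",
    "fdr_estimate",
    "build_network",
    "write_edges",
    "write_adjacency_mtx",
]


@dataclass
class ThresholdPair:
    """A pair of calling thresholds c2 < 0 < c1 with its error estimates."""

    c1: float
    c2: float
    criterion: str                 # 'ratio', 'type1', or 'fdr'
    criterion_value: float
    est_type1: float = float("nan")
    est_type2: float = float("nan")
    est_fdr: float = float("nan")
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.c2 < 0.0 < self.c1):
            raise ValueError(f"need c2 < 0 < c1, got c2={self.c2}, c1={self.c1}")


# ---------------------------------------------------------------------------
# closed-form tail masses
# ---------------------------------------------------------------------------

def _null_tail_mass(params: L2NParams, c1: float, c2: float) -> float:
    """F0(c2) + 1 - F0(c1) for the N(0, sigma2) null (no p0 factor)."""
    s = np.sqrt(params.sigma2)
    return float(norm.cdf(c2, scale=s) + norm.sf(c1, scale=s))


def _lognorm_cdf(x: float, theta: float, kappasq: float) -> float:
    if x <= 0:
        return 0.0
    if np.isinf(x):
        return 1.0
    return float(norm.cdf((np.log(x) - theta) / np.sqrt(kappasq)))


def _nonnull_tail_mass(params: L2NParams, c1: float, c2: float) -> float:
    """p1 (1 - F1(c1)) + p2 (1 - F2(-c2)): non-null mass outside [c2, c1]."""
    m1 = params.p1 * (1.0 - _lognorm_cdf(c1, params.theta1, params.kappa1sq))
    m2 = params.p2 * (1.0 - _lognorm_cdf(-c2, params.theta2, params.kappa2sq))
    return m1 + m2


def type1_estimate(params: L2NParams, c1: float, c2: float) -> float:
    """Model-estimated Type-I error: p0 [F0(c2) + 1 - F0(c1)]."""
    return params.p0 * _null_tail_mass(params, c1, c2)


def type2_estimate(params: L2NParams, c1: float, c2: float) -> float:
    """Model-estimated Type-II error: non-null mass left inside [c2, c1].

    p2 [F2(-c2)] + p1 [F1(c1)], the probability that a truly non-null
    pair's weight falls between the thresholds and the edge is missed.
    """
    if not (c2 < 0.0 < c1):
        raise ValueError("need c2 < 0 < c1")
    miss1 = params.p1 * _lognorm_cdf(c1, params.theta1, params.kappa1sq)
    miss2 = params.p2 * _lognorm_cdf(-c2, params.theta2, params.kappa2sq)
    return miss1 + miss2


def fdr_estimate(params: L2NParams, c1: float, c2: float) -> float:
    """Model-based FDR: null mass outside [c2, c1] over total mass outside."""
    fp = type1_estimate(params, c1, c2)
    total = fp + _nonnull_tail_mass(params, c1, c2)
    if total <= 0.0:
        return 0.0
    return fp / total


def _finish(tp: ThresholdPair, params: L2NParams) -> ThresholdPair:
    c1 = tp.c1 if np.isfinite(tp.c1) else np.inf
    c2 = tp.c2 if np.isfinite(tp.c2) else -np.inf
    tp.est_type1 = type1_estimate(params, c1, c2)
    tp.est_type2 = type2_estimate(params, min(c1, 1e308), max(c2, -1e308))
    tp.est_fdr = fdr_estimate(params, c1, c2)
    return tp


# ---------------------------------------------------------------------------
# ratio thresholds
# ---------------------------------------------------------------------------

def _log_ratio_pos(u: np.ndarray, params: L2NParams) -> np.ndarray:
    """log[p1 f1(w) / (p0 f0(w))] at w = exp(u) (positive side)."""
    w = np.exp(u)
    lf1 = -u - 0.5 * np.log(2 * np.pi * params.kappa1sq) \
        - (u - params.theta1) ** 2 / (2 * params.kappa1sq)
    lf0 = -0.5 * np.log(2 * np.pi * params.sigma2) - w * w / (2 * params.sigma2)
    return np.log(params.p1) + lf1 - np.log(params.p0) - lf0


def _log_ratio_neg(u: np.ndarray, params: L2NParams) -> np.ndarray:
    """log[p2 f2(w) / (p0 f0(w))] at w = -exp(u) (negative side)."""
    w = np.exp(u)
    lf2 = -u - 0.5 * np.log(2 * np.pi * params.kappa2sq) \
        - (u - params.theta2) ** 2 / (2 * params.kappa2sq)
    lf0 = -0.5 * np.log(2 * np.pi * params.sigma2) - w * w / (2 * params.sigma2)
    return np.log(params.p2) + lf2 - np.log(params.p0) - lf0


def _first_upcrossing(fun, logT: float, params: L2NParams) -> float:
    """Smallest |w| > 0 where fun (a log posterior-ratio in u = log|w|)
    exceeds logT; +inf if it never does below |w| = 1e3."""
    u = np.linspace(np.log(1e-8), np.log(1e3), 4096)
    g = fun(u, params) - logT
    above = np.nonzero(g > 0)[0]
    if above.size == 0:
        return np.inf
    i = above[0]
    if i == 0:
        return float(np.exp(u[0]))
    lo, hi = np.exp(u[i - 1]), np.exp(u[i])
    # bisection in w to 1e-8
    for _ in range(200):
        if hi - lo < 1e-8:
            break
        mid = 0.5 * (lo + hi)
        if fun(np.log(np.array([mid])), params)[0] > logT:
            hi = mid
        else:
            lo = mid
    return float(hi)


def thresholds_from_ratio(params: L2NParams, T: float) -> ThresholdPair:
    """Thresholds where the non-null/null posterior ratio first exceeds T.

    c1 is the smallest w > 0 with p1 f1(w) / (p0 f0(w)) > T; c2 is the
    largest w < 0 with p2 f2(w) / (p0 f0(w)) > T.  A side whose ratio
    never exceeds T (e.g. p1 = 0) gets an infinite threshold, flagged —
    no edges of that sign are callable.
    """
    if T <= 1.0:
        raise ValueError("ratio threshold T must exceed 1")
    logT = np.log(T)
    flags = []
    if params.p1 > 0.0 and params.p0 > 0.0:
        c1 = _first_upcrossing(_log_ratio_pos, logT, params)
    else:
        c1 = np.inf
    if params.p2 > 0.0 and params.p0 > 0.0:
        c2 = -_first_upcrossing(_log_ratio_neg, logT, params)
    else:
        c2 = -np.inf
    if np.isinf(c1):
        flags.append("no_positive_edges")
    if np.isinf(c2):
        flags.append("no_negative_edges")
    tp = ThresholdPair(c1=c1, c2=c2, criterion="ratio", criterion_value=T,
                       flags=flags)
    return _finish(tp, params)


# ---------------------------------------------------------------------------
# Type-I control
# ---------------------------------------------------------------------------

def thresholds_from_alpha(
    params: L2NParams, alpha: float, split: str = "proportional"
) -> ThresholdPair:
    """Thresholds controlling the estimated Type-I error at alpha.

    Solves p0 [F0(c2) + 1 - F0(c1)] <= alpha in closed form (normal
    quantiles).  The tail budget is split in proportion to the fitted
    non-null masses p1/(p1+p2) vs p2/(p1+p2) (``split='proportional'``,
    the default, falling back to 50/50 when p1 + p2 = 0) or evenly
    (``split='equal'``).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if split not in ("proportional", "equal"):
        raise ValueError(f"unknown split rule: {split!r}")
    if split == "proportional" and (params.p1 + params.p2) > 0:
        share1 = params.p1 / (params.p1 + params.p2)
    else:
        share1 = 0.5
    s = np.sqrt(params.sigma2)
    # p0 * tail mass per side = alpha * share
    a1 = alpha * share1 / max(params.p0, 1e-300)
    a2 = alpha * (1.0 - share1) / max(params.p0, 1e-300)
    c1 = float(norm.isf(min(a1, 0.5), scale=s)) if a1 > 0 else np.inf
    c2 = float(norm.ppf(min(a2, 0.5), scale=s)) if a2 > 0 else -np.inf
    flags = []
    if np.isinf(c1):
        flags.append("no_positive_edges")
    if np.isinf(c2):
        flags.append("no_negative_edges")
    tp = ThresholdPair(c1=c1, c2=c2, criterion="type1", criterion_value=alpha,
                       flags=flags)
    return _finish(tp, params)


# ---------------------------------------------------------------------------
# FDR control
# ---------------------------------------------------------------------------

def thresholds_from_fdr(params: L2NParams, q: float) -> ThresholdPair:
    """Thresholds controlling the model-based FDR at level q.

    Rejection regions are indexed by a single posterior-ratio parameter t
    (thresholds c1(t), c2(t) from :func:`thresholds_from_ratio`), which
    makes them nested and sign-consistent; t is found by bisection until
    the mixture-tail FDR drops to q.

    Raises
    ------
    ValueError
        If q is unattainable (non-null mass too small), reporting the
        smallest achievable FDR.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    if params.p1 + params.p2 <= 0.0:
        raise ValueError(
            "FDR control impossible: fitted non-null mass p1 + p2 = 0, so any "
            "rejection has FDR 1"
        )

    def fdr_at(logt: float) -> float:
        tp = thresholds_from_ratio(params, float(np.exp(logt)))
        return fdr_estimate(params, tp.c1, tp.c2)

    lo, hi = np.log(1.0 + 1e-9), np.log(1e12)
    f_hi = fdr_at(hi)
    if f_hi > q:
        raise ValueError(
            f"FDR level q={q} unattainable for these parameters; smallest "
            f"achievable model FDR is about {f_hi:.4g} "
            f"(non-null mass p1+p2={params.p1 + params.p2:.4g})"
        )
    if fdr_at(lo) <= q:
        hi = lo
    else:
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if fdr_at(mid) <= q:
                hi = mid
            else:
                lo = mid
            if hi - lo < 1e-10:
                break
    tp = thresholds_from_ratio(params, float(np.exp(hi)))
    tp.criterion = "fdr"
    tp.criterion_value = q
    return _finish(tp, params)


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

@dataclass
class Network:
    """A called co-expression network: signed edge list over G genes."""

    gene_ids: list[str]
    edges_m: np.ndarray    # int, m < n
    edges_n: np.ndarray
    signs: np.ndarray      # +1 / -1
    edge_weights: np.ndarray

    def __post_init__(self) -> None:
        self.edges_m = np.asarray(self.edges_m, dtype=np.int64)
        self.edges_n = np.asarray(self.edges_n, dtype=np.int64)
        self.signs = np.asarray(self.signs, dtype=np.int8)
        self.edge_weights = np.asarray(self.edge_weights, dtype=float)
        if np.any(self.edges_m >= self.edges_n):
            raise ValueError("edges must satisfy m < n (hollow adjacency)")

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return self.edges_m.size

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency (zero diagonal)."""
        G = self.n_nodes
        data = np.ones(self.n_edges, dtype=np.int8)
        a = sp.coo_matrix((data, (self.edges_m, self.edges_n)), shape=(G, G))
        return (a + a.T).tocsr()

    def neighbor_lists(self) -> list[np.ndarray]:
        a = self.adjacency()
        return [a.indices[a.indptr[i]:a.indptr[i + 1]] for i in range(self.n_nodes)]


def build_network(
    weights: WeightVector,
    thresholds: ThresholdPair,
    gene_ids: list[str] | None = None,
) -> Network:
    """Call edges: pair (m, n) is an edge iff w_mn falls outside [c2, c1].

    Sign is + for w > c1 and - for w < c2.
    """
    gene_ids = list(gene_ids) if gene_ids is not None else list(weights.gene_ids)
    if len(gene_ids) != weights.n_genes:
        raise ValueError("gene_ids length does not match the weight vector")
    m, n = pair_arrays(weights.n_genes)
    w = weights.w
    pos = w > thresholds.c1
    neg = w < thresholds.c2
    keep = pos | neg
    return Network(
        gene_ids=gene_ids,
        edges_m=m[keep],
        edges_n=n[keep],
        signs=np.where(pos[keep], 1, -1),
        edge_weights=w[keep],
    )


def write_edges(net: Network, path, params: L2NParams | None = None) -> None:
    """Write the edge list as TSV: gene_m, gene_n, sign, weight, posterior_q0.

    The null posterior q0 column requires the fitted parameters; it is
    left as NaN when ``params`` is None.
    """
    if params is not None and net.n_edges:
        q0 = posterior(net.edge_weights, params)[0]
    else:
        q0 = np.full(net.n_edges, np.nan)
    with open(path, "w") as fh:
        fh.write("gene_m\tgene_n\tsign\tweight\tposterior_q0\n")
        for i in range(net.n_edges):
            fh.write(
                f"{net.gene_ids[net.edges_m[i]]}\t{net.gene_ids[net.edges_n[i]]}\t"
                f"{'+' if net.signs[i] > 0 else '-'}\t"
                f"{net.edge_weights[i]:.6f}\t{q0[i]:.6g}\n"
            )


def read_edges(path, gene_ids: list[str]) -> Network:
    """Read an edge-list TSV written by :func:`write_edges`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene_m": str, "gene_n": str})
    index = {g: i for i, g in enumerate(gene_ids)}
    m = np.array([index[g] for g in df["gene_m"]], dtype=np.int64)
    n = np.array([index[g] for g in df["gene_n"]], dtype=np.int64)
    lo, hi = np.minimum(m, n), np.maximum(m, n)
    return Network(
        gene_ids=list(gene_ids),
        edges_m=lo,
        edges_n=hi,
        signs=np.where(df["sign"].to_numpy() == "+", 1, -1),
        edge_weights=df["weight"].to_numpy(dtype=float),
    )


def write_adjacency_mtx(net: Network, path) -> None:
    """Write the adjacency in Matrix Market coordinate format (pattern,
    symmetric)."""
    from scipy.io import mmwrite

    G = net.n_nodes
    # store lower triangle so the 'symmetric' qualifier is valid
    a = sp.coo_matrix(
        (np.ones(net.n_edges, dtype=np.int8), (net.edges_n, net.edges_m)),
        shape=(G, G),
    )
    mmwrite(str(path), a, field="pattern", symmetry="symmetric")
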