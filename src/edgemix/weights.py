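"""Pairwise correlations and Fisher-z edge weights.

The first step of the pipeline: given a normalized expression matrix
(genes x samples), compute all pairwise Pearson correlations and map them
to Fisher-z weights ``w = arctanh(r)``.  Under the null (uncorrelated
pair) ``w`` is asymptotically normal with mean 0 and variance 1/(N-3),
which is what makes the downstream mixture model tractable.

All modules share one canonical pair ordering: row-major over the strict
upper triangle of the G x G matrix, so pair k corresponds to (m, n) with
m < n, exactly the order produced by ``numpy.triu_indices(G, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "WeightVector",
    "compute_weights",
    "null_variance",
    "read_expression",
    "drop_constant_genes",
    "pair_count",
    "pair_arrays",
    "pair_to_index",
    "index_to_pair",
]

#: default correlation clipping bound; arctanh(0.999999) ~ 7.25, so weights
#: stay finite even for duplicated genes while real data are untouched
DEFAULT_CLIP_R = 0.999999


def pair_count(n_genes: int) -> int:
    """Number of unordered gene pairs K = G(G-1)/2."""
    return n_genes * (n_genes - 1) // 2


def pair_arrays(n_genes: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays (m, n) of the canonical pair ordering (row-major upper triangle)."""
    return np.triu_indices(n_genes, k=1)


def pair_to_index(m, n, n_genes: int):
    """Canonical index k of pair (m, n), m < n, vectorized."""
    m = np.asarray(m)
    n = np.asarray(n)
    if np.any(m >= n):
        raise ValueError("pair_to_index requires m < n")
    return m * (2 * n_genes - m - 1) // 2 + (n - m - 1)


def index_to_pair(k, n_genes: int):
    """Inverse of :func:`pair_to_index`, vectorized."""
    k = np.asarray(k)
    G = n_genes
    # solve m(2G - m - 1)/2 <= k for the largest integer m
    m = (2 * G - 1 - np.sqrt((2 * G - 1) ** 2 - 8 * k)) // 2
    m = m.astype(np.int64)
    n = k - m * (2 * G - m - 1) // 2 + m + 1
    return m, n.astype(np.int64)


def null_variance(n_samples: int) -> float:
    """Asymptotic variance 1/(N-3) of a null Fisher-z weight."""
    if n_samples <= 3:
        raise ValueError(
            f"null variance 1/(N-3) undefined for N={n_samples}; need N > 3"
        )
    return 1.0 / (n_samples - 3)


@dataclass
class ExpressionMatrix:
    """Normalized expression values for G genes across N samples.

    Parameters
    ----------
    values
        Real matrix of shape (G, N), genes in rows.
    gene_ids
        G unique gene identifiers.
    sample_ids
        N unique sample identifiers.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        G, N = self.values.shape
        if G < 2:
            raise ValueError("need at least 2 genes")
        if len(self.gene_ids) != G or len(self.sample_ids) != N:
            raise ValueError("id lengths do not match the value matrix shape")
        if len(set(self.gene_ids)) != G:
            raise ValueError("gene identifiers must be unique")
        if len(set(self.sample_ids)) != N:
            raise ValueError("sample identifiers must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = [self.gene_ids[i] for i in
                   np.unique(np.nonzero(~np.isfinite(self.values))[0])][:10]
            raise ValueError(f"missing/non-finite expression values in genes: {bad}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def constant_genes(self) -> list[str]:
        """Gene ids whose expression has zero variance across samples."""
        flat = np.ptp(self.values, axis=1) == 0.0
        return [g for g, f in zip(self.gene_ids, flat) if f]


@dataclass
class WeightVector:
    """Fisher-z weights for all K = G(G-1)/2 gene pairs, canonical order."""

    w: np.ndarray
    n_genes: int
    n_samples: int
    clip_r: float = DEFAULT_CLIP_R
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (pair_count(self.n_genes),):
            raise ValueError("weight vector length must be G(G-1)/2")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite")
        if not self.gene_ids:
            self.gene_ids = [f"g{i}" for i in range(self.n_genes)]

    def __len__(self) -> int:
        return self.w.size

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        return pair_arrays(self.n_genes)


def compute_weights(X: ExpressionMatrix, clip_r: float = DEFAULT_CLIP_R) -> WeightVector:
    """Pearson correlations of all gene pairs mapped to Fisher-z weights.

    Correlations are clamped to [-clip_r, clip_r] before ``arctanh`` so
    that duplicated genes (|r| = 1) yield a large finite weight instead of
    infinity.

    Raises
    ------
    ValueError
        If N <= 3 (the null variance 1/(N-3) is undefined) or any gene has
        zero variance (its correlations are undefined).
    """
    if not (0.0 < clip_r < 1.0):
        raise ValueError("clip_r must lie in (0, 1)")
    if X.n_samples <= 3:
        raise ValueError(f"need N > 3 samples, got N={X.n_samples}")
    const = X.constant_genes()
    if const:
        raise ValueError(
            "correlation undefined for zero-variance genes: "
            f"{const[:10]}{'...' if len(const) > 10 else ''}; "
            "remove them first (see drop_constant_genes)"
        )
    r = np.corrcoef(X.values)
    iu, ju = pair_arrays(X.n_genes)
    rv = np.clip(r[iu, ju], -clip_r, clip_r)
    return WeightVector(
        w=np.arctanh(rv),
        n_genes=X.n_genes,
        n_samples=X.n_samples,
        clip_r=clip_r,
        gene_ids=list(X.gene_ids),
    )


def drop_constant_genes(X: ExpressionMatrix) -> ExpressionMatrix:
    """Explicit prefilter removing zero-variance genes (never done silently)."""
    const = set(X.constant_genes())
    if not const:
        return X
    keep = [i for i, g in enumerate(X.gene_ids) if g not in const]
    if len(keep) < 2:
        raise ValueError("fewer than 2 genes left after removing constant genes")
    return ExpressionMatrix(
        values=X.values[keep],
        gene_ids=[X.gene_ids[i] for i in keep],
        sample_ids=list(X.sample_ids),
    )


def read_expression(
    path,
    orientation: str = "genes_by_samples",
    sep: str | None = None,
) -> ExpressionMatrix:
    """Load a delimited expression table.

    Expected layout: first column = gene ids, header row = sample ids
    (``orientation='genes_by_samples'``).  Use
    ``orientation='samples_by_genes'`` for the transposed layout.  The
    delimiter is sniffed from the extension when ``sep`` is None
    (.csv -> comma, otherwise tab).

    Rows containing missing values are rejected with an error naming the
    offending genes; silent imputation would corrupt the pair indexing.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "samples_by_genes":
        df = df.T
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()[:10]
        raise ValueError(f"rows with missing values (rejected): {bad}")
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=df.index.tolist(),
        sample_ids=df.columns.tolist(),
    )
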