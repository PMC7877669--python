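"""The L2N mixture model: densities, posteriors, and EM estimation.

Fisher-z weights w are modeled as a three-component mixture:

* C0 (null): w ~ Normal(0, sigma^2), the vast majority of gene pairs.
  sigma^2 = 1/(N-3) + sigma0^2, i.e. the asymptotic variance of
  arctanh(r) plus a random-effect component for extra dispersion among
  uncorrelated pairs; the fitted sigma^2 is therefore floored at 1/(N-3).
* C1 (positive non-null):  w | w > 0 ~ LogNormal(theta1, kappa1^2).
* C2 (negative non-null): -w | w < 0 ~ LogNormal(theta2, kappa2^2).

Because the lognormal components have disjoint support (strictly
positive / strictly negative weights) and vanish at 0, the model does not
suffer the null/non-null identifiability problems of all-normal mixtures,
and every EM M-step has a closed form (responsibility-weighted moments).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .weights import WeightVector, compute_weights, null_variance

__all__ = [
    "L2NParams",
    "PosteriorTable",
    "FitResult",
    "component_densities",
    "posterior",
    "auto_init",
    "log_likelihood",
    "fit_em",
    "subsample_fit",
]

KAPPA_SQ_FLOOR = 1e-4  # prevents degenerate lognormal spikes
_LOG_EPS = -745.0  # below log of smallest positive double

# sentinel parameters for a pinned (empty) non-null component
_SENTINEL_THETA = 0.0
_SENTINEL_KAPPA_SQ = KAPPA_SQ_FLOOR


@dataclass
class L2NParams:
    """The eight L2N parameters plus the sample size N.

    ``p0 + p1 + p2 = 1``; ``sigma2 >= 1/(N-3)``; ``kappa*sq > 0``.
    """

    p0: float
    p1: float
    p2: float
    sigma2: float
    theta1: float
    kappa1sq: float
    theta2: float
    kappa2sq: float
    n_samples: int

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ps = np.array([self.p0, self.p1, self.p2], dtype=float)
        if np.any(ps < 0):
            raise ValueError(f"mixture probabilities must be >= 0, got {ps}")
        if abs(ps.sum() - 1.0) > 1e-10:
            raise ValueError(f"mixture probabilities must sum to 1, got {ps.sum()}")
        floor = null_variance(self.n_samples)
        if self.sigma2 < floor - 1e-12:
            raise ValueError(
                f"sigma2={self.sigma2} below the asymptotic floor 1/(N-3)={floor}"
            )
        if self.kappa1sq <= 0 or self.kappa2sq <= 0:
            raise ValueError("kappa1sq and kappa2sq must be positive")

    # -- serialization ---------------------------------------------------
    _KEYS = ("p0", "p1", "p2", "sigma2", "theta1", "kappa1sq",
             "theta2", "kappa2sq", "n_samples")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self._KEYS}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "L2NParams":
        return cls(**{k: d[k] for k in cls._KEYS})

    @classmethod
    def from_json(cls, path) -> "L2NParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _log_normal_pdf(w: np.ndarray, sigma2: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * sigma2) + w * w / sigma2)


def _log_lognormal_pdf(x: np.ndarray, theta: float, kappasq: float) -> np.ndarray:
    """log pdf of LogNormal(theta, kappasq) on x > 0; -inf elsewhere."""
    out = np.full(np.shape(x), -np.inf, dtype=float)
    x = np.asarray(x, dtype=float)
    pos = x > 0
    lx = np.log(x, where=pos, out=np.zeros_like(x))
    out[pos] = (
        -lx[pos]
        - 0.5 * np.log(2.0 * np.pi * kappasq)
        - (lx[pos] - theta) ** 2 / (2.0 * kappasq)
    )
    return out


def component_log_densities(w, params: L2NParams):
    """(log f0, log f1, log f2) at weight(s) w; -inf where a density is 0."""
    w = np.atleast_1d(np.asarray(w, dtype=float))
    logf0 = _log_normal_pdf(w, params.sigma2)
    logf1 = _log_lognormal_pdf(w, params.theta1, params.kappa1sq)
    logf2 = _log_lognormal_pdf(-w, params.theta2, params.kappa2sq)
    return logf0, logf1, logf2


def component_densities(w, params: L2NParams):
    """Component densities (f0, f1, f2) at weight(s) w.

    f1 is supported on w > 0 and f2 on w < 0; both vanish at w = 0.
    """
    scalar = np.isscalar(w) or np.ndim(w) == 0
    logf0, logf1, logf2 = component_log_densities(w, params)
    f0, f1, f2 = np.exp(logf0), np.exp(logf1), np.exp(logf2)
    if scalar:
        return float(f0[0]), float(f1[0]), float(f2[0])
    return f0, f1, f2


def _log_weighted(w, params: L2NParams) -> np.ndarray:
    """K x 3 matrix of log(p_j f_j(w)); -inf where p_j = 0 or f_j = 0."""
    logf0, logf1, logf2 = component_log_densities(w, params)
    with np.errstate(divide="ignore"):
        logp = np.log(np.array([params.p0, params.p1, params.p2]))
    return np.stack([logp[0] + logf0, logp[1] + logf1, logp[2] + logf2], axis=1)


def _normalize_rows(lw: np.ndarray) -> tuple[np.ndarray, float]:
    """Row-softmax of a K x 3 log matrix and the summed log-normalizer.

    Faster than scipy.special.logsumexp for this fixed tiny width; -inf
    entries (vanished densities) are handled because exp(-inf - m) = 0.
    """
    m = lw.max(axis=1)
    if not np.all(np.isfinite(m)):
        raise ValueError(
            "all mixture terms vanished at some weight; invalid parameters"
        )
    with np.errstate(invalid="ignore"):
        e = np.exp(lw - m[:, None])
    s = e.sum(axis=1)
    return e / s[:, None], float((m + np.log(s)).sum())


def posterior(w, params: L2NParams):
    """Posterior component probabilities (q0, q1, q2) given weight(s) w.

    q_j = p_j f_j(w) / sum_l p_l f_l(w).
    """
    scalar = np.isscalar(w) or np.ndim(w) == 0
    lw = _log_weighted(np.atleast_1d(np.asarray(w, dtype=float)), params)
    q, _ = _normalize_rows(lw)
    if scalar:
        return float(q[0, 0]), float(q[0, 1]), float(q[0, 2])
    return q[:, 0], q[:, 1], q[:, 2]


@dataclass
class PosteriorTable:
    """Per-pair posterior probabilities and hard component labels.

    Labels are the argmax of (q0, q1, q2) with ties broken toward the
    lower-numbered component (null preferred, then positive).
    """

    q: np.ndarray          # K x 3
    labels: np.ndarray     # K, values in {0, 1, 2}

    @classmethod
    def from_weights(cls, weights, params: L2NParams) -> "PosteriorTable":
        w = weights.w if isinstance(weights, WeightVector) else np.asarray(weights)
        q0, q1, q2 = posterior(w, params)
        q = np.stack([q0, q1, q2], axis=1)
        return cls(q=q, labels=np.argmax(q, axis=1))


@dataclass
class FitResult:
    """Outcome of an EM fit."""

    params: L2NParams
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    subsample_gene_ids: list[str] = field(default_factory=list)


def log_likelihood(w: np.ndarray, params: L2NParams) -> float:
    """Observed-data log-likelihood of the weights under the mixture."""
    return _normalize_rows(_log_weighted(w, params))[1]


def auto_init(w: np.ndarray, n_samples: int) -> L2NParams:
    """Deterministic, data-driven starting values.

    p0 starts as the fraction of |w| below twice the asymptotic null sd;
    the non-null locations/scales come from log-moments of the extreme 2%
    of each tail.  Deterministic initialization avoids label switching and
    makes refits reproducible.
    """
    w = np.asarray(w, dtype=float)
    sigma2 = null_variance(n_samples)
    cutoff = 2.0 * np.sqrt(sigma2)
    inside = np.abs(w) <= cutoff
    p0 = float(np.clip(inside.mean(), 0.50, 1.0 - 1e-6))
    n_pos = int((w > cutoff).sum())
    n_neg = int((w < -cutoff).sum())
    if n_pos + n_neg == 0:
        p1 = p2 = (1.0 - p0) / 2.0
    else:
        p1 = (1.0 - p0) * n_pos / (n_pos + n_neg)
        p2 = (1.0 - p0) * n_neg / (n_pos + n_neg)

    def _tail_moments(x: np.ndarray, fallback=(0.0, 0.25)):
        # x: positive magnitudes of one tail
        if x.size < 10:
            return fallback
        top = x[x >= np.quantile(x, 0.98)]
        lx = np.log(top)
        return float(lx.mean()), float(max(lx.var(), 1e-2))

    theta1, kappa1sq = _tail_moments(w[w > 0])
    theta2, kappa2sq = _tail_moments(-w[w < 0])
    return L2NParams(
        p0=p0, p1=p1, p2=p2, sigma2=sigma2,
        theta1=theta1, kappa1sq=kappa1sq,
        theta2=theta2, kappa2sq=kappa2sq,
        n_samples=n_samples,
    )


def fit_em(
    weights: WeightVector | np.ndarray,
    init: L2NParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_samples: int | None = None,
) -> FitResult:
    """Estimate the L2N parameters by EM.

    E-step: posterior responsibilities q_jk per pair (Bayes' rule on the
    three weighted densities).  M-step (closed forms):

    * p_j = mean_k q_jk
    * sigma^2 = max(1/(N-3), sum q0 w^2 / sum q0)
    * theta1 = weighted mean of log w over w > 0 with weights q1;
      kappa1^2 = matching weighted variance (floored at 1e-4);
      mirrored on -w for the negative component.

    Iterates until the observed-data log-likelihood changes by less than
    ``tol`` or ``max_iter`` is reached.  A side with no weights at all has
    its component pinned at p = 0 with sentinel parameters.
    """
    if isinstance(weights, WeightVector):
        w = weights.w
        N = weights.n_samples
    else:
        w = np.asarray(weights, dtype=float)
        if n_samples is None:
            raise ValueError("n_samples required when passing a bare array")
        N = n_samples
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")

    var_floor = null_variance(N)
    pos = w > 0
    neg = w < 0
    have_pos = bool(pos.any())
    have_neg = bool(neg.any())

    params = init if init is not None else auto_init(w, N)
    if not have_pos:
        params = _pin_component(params, side=1)
    if not have_neg:
        params = _pin_component(params, side=2)

    # Each weight can belong to at most two components (the null and the
    # lognormal of its own sign; the opposite lognormal has density 0), so
    # the E-step reduces to two binary softmaxes over the sign strata.
    w_pos = w[pos]
    w_neg = w[neg]
    logw_pos = np.log(w_pos) if have_pos else np.empty(0)
    logw_neg = np.log(-w_neg) if have_neg else np.empty(0)
    wsq = w * w
    sum_wsq = float(wsq.sum())
    wsq_pos = wsq[pos]
    wsq_neg = wsq[neg]
    ll_zero_count = int(w.size - w_pos.size - w_neg.size)
    K = w.size

    def _side_estep(p_side, theta, kappasq, p0, sigma2, logw_side, wsq_side):
        # returns (q_side, loglik contribution) for one sign stratum
        a0 = (np.log(p0) - 0.5 * np.log(2 * np.pi * sigma2)
              - wsq_side / (2 * sigma2))
        if p_side <= 0.0:
            return np.zeros(logw_side.size), float(a0.sum())
        b = (np.log(p_side) - logw_side - 0.5 * np.log(2 * np.pi * kappasq)
             - (logw_side - theta) ** 2 / (2 * kappasq))
        m = np.maximum(a0, b)
        e0 = np.exp(a0 - m)
        e1 = np.exp(b - m)
        s = e0 + e1
        return e1 / s, float((m + np.log(s)).sum())

    trace: list[float] = []
    converged = False
    while True:
        # E-step; the same pass yields the observed-data log-likelihood
        q1, ll_pos = _side_estep(params.p1, params.theta1, params.kappa1sq,
                                 params.p0, params.sigma2, logw_pos, wsq_pos)
        q2, ll_neg = _side_estep(params.p2, params.theta2, params.kappa2sq,
                                 params.p0, params.sigma2, logw_neg, wsq_neg)
        ll = ll_pos + ll_neg + ll_zero_count * (
            np.log(params.p0) - 0.5 * np.log(2 * np.pi * params.sigma2)
        )
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        if len(trace) > max_iter:
            break

        # M-step
        s1 = float(q1.sum())
        s2 = float(q2.sum())
        s0 = K - s1 - s2
        p0, p1, p2 = s0 / K, s1 / K, s2 / K
        null_ssq = sum_wsq - float(q1 @ wsq_pos) - float(q2 @ wsq_neg)
        sigma2 = max(var_floor, null_ssq / s0) if s0 > 0 else var_floor

        theta1, kappa1sq = params.theta1, params.kappa1sq
        if have_pos and s1 > 1e-12:
            theta1 = float((q1 @ logw_pos) / s1)
            kappa1sq = max(float(q1 @ (logw_pos - theta1) ** 2) / s1,
                           KAPPA_SQ_FLOOR)
        theta2, kappa2sq = params.theta2, params.kappa2sq
        if have_neg and s2 > 1e-12:
            theta2 = float((q2 @ logw_neg) / s2)
            kappa2sq = max(float(q2 @ (logw_neg - theta2) ** 2) / s2,
                           KAPPA_SQ_FLOOR)

        # renormalize against tiny floating drift
        tot = p0 + p1 + p2
        params = L2NParams(
            p0=p0 / tot, p1=p1 / tot, p2=p2 / tot, sigma2=sigma2,
            theta1=theta1, kappa1sq=kappa1sq,
            theta2=theta2, kappa2sq=kappa2sq, n_samples=N,
        )

    return FitResult(
        params=params,
        loglik_trace=np.asarray(trace),
        n_iter=len(trace) - 1,
        converged=converged,
    )


def _pin_component(params: L2NParams, side: int) -> L2NParams:
    """Return params with non-null component ``side`` (1 or 2) pinned to p=0."""
    d = params.to_dict()
    freed = d.pop(f"p{side}")
    d[f"p{side}"] = 0.0
    d["p0"] = params.p0 + freed
    d[f"theta{side}"] = _SENTINEL_THETA
    d[f"kappa{side}sq"] = _SENTINEL_KAPPA_SQ
    return L2NParams.from_dict(d)


def subsample_fit(
    X,
    g_prime: int,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    clip_r: float | None = None,
):
    """Fit the mixture on a random subset of G' genes, score all pairs.

    For large G, fitting on all K = G(G-1)/2 pairs is slow and the weights
    sharing a gene are not independent.  Fitting on the K' = G'(G'-1)/2
    pairs of a uniformly sampled gene subset (e.g. G' = 1000) is fast,
    approximately independent, and the fitted parameters are then used to
    score every pair exactly once downstream.

    Returns
    -------
    (FitResult, WeightVector)
        The fit (recording which genes were used) and the weight vector
        over ALL K pairs.
    """
    from .weights import DEFAULT_CLIP_R, ExpressionMatrix  # cycle-free import

    if not isinstance(X, ExpressionMatrix):
        raise TypeError("X must be an ExpressionMatrix")
    if g_prime < 2:
        raise ValueError("g_prime must be >= 2")
    if g_prime > X.n_genes:
        raise ValueError("g_prime cannot exceed the number of genes")
    clip_r = DEFAULT_CLIP_R if clip_r is None else clip_r

    full = compute_weights(X, clip_r=clip_r)
    if g_prime == X.n_genes:
        fit = fit_em(full, tol=tol, max_iter=max_iter)
        fit.subsample_gene_ids = list(X.gene_ids)
        return fit, full

    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(X.n_genes, size=g_prime, replace=False))
    sub = ExpressionMatrix(
        values=X.values[idx],
        gene_ids=[X.gene_ids[i] for i in idx],
        sample_ids=list(X.sample_ids),
    )
    fit = fit_em(compute_weights(sub, clip_r=clip_r), tol=tol, max_iter=max_iter)
    fit.subsample_gene_ids = list(sub.gene_ids)
    return fit, full
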