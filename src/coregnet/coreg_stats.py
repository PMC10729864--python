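"""Beta-binomial significance of per-pair co-regulation.

For a gene pair, co-regulation in each of the K contrasts is a Bernoulli
trial whose success probability P_k varies from contrast to contrast.  With
P_k ~ Beta(alpha, beta), the number of co-regulated contrasts under the
null follows a beta-binomial law

    P(X = n | K, alpha, beta) = C(K, n) * B(n + alpha, K - n + beta) / B(alpha, beta)

where B is the Beta function.  (alpha, beta) are fitted per pair to the
null count vector produced by fixed-margin resampling, and the pair's
p-value is the inclusive upper tail P(X >= n_observed).  Benjamini-Hochberg
FDR is then computed over all retained pairs.

The fit is method-of-moments by default (closed form; with millions of
pairs the per-pair fit is the bottleneck), with maximum-likelihood
refinement available via ``method="mle"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, gammaln
from statsmodels.stats.multitest import multipletests

from .null_model import NullPairCounts

__all__ = [
    "BetaBinomParams",
    "count_coregulation",
    "betabinom_pmf",
    "fit_betabinom",
    "pair_pvalue",
    "compute_fdr",
    "score_pairs",
]

# alpha + beta used when the null vector shows no overdispersion: the
# beta-binomial degenerates toward Binomial(K, m/K) as alpha+beta grows at
# fixed mean, so a large fixed scale reproduces the binomial to float
# precision.
BINOMIAL_LIMIT_SCALE = 1e6

# p-value assigned when the observed count exceeds a degenerate (point-mass)
# null's support: the smallest outcome distinguishable from impossible.
MACHINE_FLOOR = np.finfo(float).tiny


@dataclass(frozen=True)
class BetaBinomParams:
    """Parameters of a beta-binomial null: K trials, Beta(alpha, beta) prior.

    ``degenerate`` marks a null count vector with zero variance (e.g. all
    zeros); the fit is then a point mass at ``point_mass`` and alpha/beta
    are not meaningful.
    """

    alpha: float
    beta: float
    K: int
    degenerate: bool = False
    point_mass: float = 0.0

    def __post_init__(self):
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if not self.degenerate and (self.alpha <= 0 or self.beta <= 0):
            raise ValueError(
                f"alpha and beta must be > 0, got ({self.alpha}, {self.beta})"
            )


def count_coregulation(
    binary: pd.DataFrame, signed: pd.DataFrame, min_obs: int = 2
) -> pd.DataFrame:
    """Observed co-regulation counts for every retained unordered gene pair.

    For a pair, ``n`` is the number of contrasts in which both genes are
    DEGs and ``n_discordant`` the number of those in which they move in
    opposite directions.  Pairs are in canonical order (gene_i before
    gene_j in the matrix row order); pairs with ``n < min_obs`` are dropped.

    Returns a DataFrame with columns gene_i, gene_j, n, n_discordant, K.
    """
    if binary.shape != signed.shape or not binary.index.equals(signed.index):
        raise ValueError("binary and signed matrices are not aligned")
    b = binary.to_numpy(dtype=np.int32)
    s = signed.to_numpy(dtype=np.int32)
    if not ((s != 0) == (b == 1)).all():
        raise ValueError("signed matrix nonzero pattern disagrees with binary matrix")

    pos = (s > 0).astype(np.int32)
    neg = (s < 0).astype(np.int32)
    concordant = pos @ pos.T + neg @ neg.T
    discordant = pos @ neg.T + neg @ pos.T
    n = concordant + discordant

    iu, ju = np.triu_indices(b.shape[0], k=1)
    keep = n[iu, ju] >= min_obs
    iu, ju = iu[keep], ju[keep]
    genes = binary.index.to_numpy(object)
    return pd.DataFrame(
        {
            "gene_i": genes[iu],
            "gene_j": genes[ju],
            "n": n[iu, ju],
            "n_discordant": discordant[iu, ju],
            "K": binary.shape[1],
        }
    )


def betabinom_pmf(n, params: BetaBinomParams) -> np.ndarray | float:
    """Beta-binomial probability mass at ``n`` (scalar or array)."""
    n_arr = np.asarray(n)
    if ((n_arr < 0) | (n_arr > params.K)).any():
        raise ValueError(f"n must be in [0, {params.K}]")
    if params.degenerate:
        out = np.where(n_arr == params.point_mass, 1.0, 0.0)
        return float(out) if np.isscalar(n) else out
    K, a, b = params.K, params.alpha, params.beta
    log_pmf = (
        gammaln(K + 1)
        - gammaln(n_arr + 1)
        - gammaln(K - n_arr + 1)
        + betaln(n_arr + a, K - n_arr + b)
        - betaln(a, b)
    )
    out = np.exp(log_pmf)
    return float(out) if np.isscalar(n) else out


def _moments_to_params(m: float, v: float, K: int) -> tuple[float, float]:
    """Solve the beta-binomial moment identities for (alpha, beta).

    mean = K a/(a+b); var = K p (1-p) (a+b+K)/(a+b+1) with p = a/(a+b).
    When the variance does not exceed the binomial value (no
    overdispersion), fall back to the binomial-matching limit at fixed mean.
    """
    p = m / K
    p = min(max(p, 1e-12), 1 - 1e-12)
    binom_var = K * p * (1 - p)
    theta = None
    if v > binom_var and K > 1:
        c = v / binom_var
        theta = (K - c) / (c - 1)  # a+b
        if theta <= 0:
            # variance at/beyond the beta-binomial maximum (theta -> 0);
            # use a near-zero scale to approach it
            theta = 0.02
    if theta is None:
        theta = BINOMIAL_LIMIT_SCALE
    return p * theta, (1 - p) * theta


def fit_betabinom(
    null_counts: np.ndarray, K: int, method: str = "moments"
) -> BetaBinomParams:
    """Fit a beta-binomial to one pair's null count vector.

    ``method="moments"`` (default) uses the closed-form method of moments;
    ``method="mle"`` refines it by maximizing the likelihood.  A zero-
    variance vector (e.g. all zeros) yields a degenerate point-mass fit.
    """
    x = np.asarray(null_counts, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 null samplings to fit")
    if ((x < 0) | (x > K)).any():
        raise ValueError(f"null counts must lie in [0, {K}]")
    m = x.mean()
    v = x.var(ddof=1)
    if v == 0.0:
        return BetaBinomParams(np.nan, np.nan, K, degenerate=True, point_mass=m)
    a, b = _moments_to_params(m, v, K)
    if method == "mle":
        grid = np.arange(K + 1)
        hist = np.bincount(x.astype(int), minlength=K + 1)

        def nll(log_ab):
            pa, pb = np.exp(log_ab)
            lp = (
                gammaln(K + 1) - gammaln(grid + 1) - gammaln(K - grid + 1)
                + betaln(grid + pa, K - grid + pb) - betaln(pa, pb)
            )
            return -float(hist @ lp)

        res = minimize(nll, np.log([a, b]), method="Nelder-Mead")
        if res.success:
            a, b = np.exp(res.x)
    elif method != "moments":
        raise ValueError(f"unknown fitting method {method!r}")
    return BetaBinomParams(float(a), float(b), K)


def pair_pvalue(n_observed: int, params: BetaBinomParams) -> float:
    """Inclusive upper-tail p-value P(X >= n_observed) under the fitted null."""
    if not 0 <= n_observed <= params.K:
        raise ValueError(f"n_observed must be in [0, {params.K}]")
    if params.degenerate:
        return 1.0 if n_observed <= params.point_mass else MACHINE_FLOOR
    js = np.arange(n_observed, params.K + 1)
    return float(min(betabinom_pmf(js, params).sum(), 1.0))


def compute_fdr(pair_stats: pd.DataFrame) -> pd.DataFrame:
    """Attach Benjamini-Hochberg adjusted values over all retained pairs."""
    out = pair_stats.copy()
    if len(out) == 0:
        out["fdr"] = pd.Series(dtype=float)
        return out
    _, fdr, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
    out["fdr"] = fdr
    return out


def score_pairs(
    pair_stats: pd.DataFrame, null: NullPairCounts, method: str = "moments"
) -> pd.DataFrame:
    """Fit the null, compute p-values and FDR for every pair in the table.

    ``pair_stats`` is the output of :func:`count_coregulation`; ``null`` the
    matching :class:`~coregnet.null_model.NullPairCounts` (same pairs, same
    order).  The moments fit is vectorized across pairs.  Returns the table
    with alpha, beta, p_value, fdr columns added.
    """
    if len(pair_stats) != len(null.pair_i):
        raise ValueError(
            f"{len(pair_stats)} pairs in stats table but {len(null.pair_i)} in null ensemble"
        )
    K = null.n_contrasts
    out = pair_stats.copy()
    n_obs = out["n"].to_numpy()

    if method == "mle" or len(out) == 0:
        fits = [fit_betabinom(null.counts[p], K, method=method) for p in range(len(out))]
        out["alpha"] = [f.alpha for f in fits]
        out["beta"] = [f.beta for f in fits]
        out["p_value"] = [pair_pvalue(int(n_obs[p]), fits[p]) for p in range(len(out))]
        return compute_fdr(out)

    counts = null.counts.astype(float)
    m = counts.mean(axis=1)
    v = counts.var(axis=1, ddof=1)
    alphas = np.empty(len(out))
    betas = np.empty(len(out))
    pvals = np.empty(len(out))

    degen = v == 0.0
    alphas[degen] = np.nan
    betas[degen] = np.nan
    pvals[degen] = np.where(n_obs[degen] <= m[degen], 1.0, MACHINE_FLOOR)

    idx = np.flatnonzero(~degen)
    if idx.size:
        ab = np.array([_moments_to_params(m[p], v[p], K) for p in idx])
        alphas[idx], betas[idx] = ab[:, 0], ab[:, 1]
        # tail sums on a shared 0..K grid, one row per pair
        grid = np.arange(K + 1)[None, :]
        a = alphas[idx][:, None]
        b = betas[idx][:, None]
        log_pmf = (
            gammaln(K + 1) - gammaln(grid + 1) - gammaln(K - grid + 1)
            + betaln(grid + a, K - grid + b) - betaln(a, b)
        )
        pmf = np.exp(log_pmf)
        tail = np.minimum(np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1], 1.0)
        pvals[idx] = tail[np.arange(idx.size), n_obs[idx]]

    out["alpha"] = alphas
    out["beta"] = betas
    out["p_value"] = pvals
    return compute_fdr(out)
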