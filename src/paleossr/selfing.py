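"""Maximum-likelihood selfing-rate estimation from multilocus heterozygosity.

Under partial self-fertilization, an individual last produced by outcrossing
``t`` generations ago (``t ~ Geometric``, P(t) = (1-s) s^t) retains
heterozygosity at a locus with probability ``h_l 2^{-t}``, where ``h_l`` is
the heterozygosity of outcrossed offspring at locus ``l`` (a nuisance
parameter).  Only the pattern of heterozygous/homozygous calls enters the
likelihood, which makes the estimator robust to null-allele-free scoring of
allele identities:

    lnL(s, h) = sum_i ln sum_{t=0..T} (1-s) s^t
                prod_{l in obs(i)} (h_l 2^{-t})^{x_il} (1 - h_l 2^{-t})^{1 - x_il}

with ``x_il = 1`` if individual ``i`` is heterozygous at locus ``l``.  This
is the model behind the RMES program of David et al. (2007).

Estimation is by expectation-maximization over the latent outcrossing age
``t`` with multiple starting values of ``s``; the truncation ``T`` is the
smallest integer with ``s^T < 1e-6``, capped at 200.  The test of ``s = 0``
is a likelihood-ratio test whose null distribution is the boundary mixture
``0.5 chi2_0 + 0.5 chi2_1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import chi2

from .genotypes import MISSING, EmptyDataError, GenotypeDataset

__all__ = ["SelfingFit", "selfing_maximum_likelihood", "compare_selfing"]

_LN2 = np.log(2.0)
_EPS = 1e-9
_S_MAX = 0.999
_T_CAP = 200


@dataclass
class SelfingFit:
    """Result of the maximum-likelihood selfing fit for one sample."""

    s_hat: float
    loglik: float
    p_value: float
    lrt_statistic: float
    h: np.ndarray
    n_iter: int
    converged: bool


def _het_matrix(dataset: GenotypeDataset, group: str):
    """(X, M): heterozygosity indicators and observation mask for a group."""
    rows = dataset.group_rows(group)
    calls = dataset.calls[rows]
    M = calls[..., 0] != MISSING
    X = (calls[..., 0] != calls[..., 1]) & M
    # drop loci with no data in this group
    keep = M.any(axis=0)
    return X[:, keep].astype(float), M[:, keep].astype(float)


def _truncation(s: float) -> int:
    if s <= 0:
        return 0
    T = int(np.ceil(np.log(1e-6) / np.log(s)))
    return min(max(T, 2), _T_CAP)


def _loglik_grid(X, M, h, T):
    """n x (T+1) matrix of per-individual conditional log-likelihoods.

    Entry (i, t) is the log-probability of individual i's het/hom pattern
    given t selfing generations since outcrossing.
    """
    h = np.clip(h, _EPS, 1 - _EPS)
    t = np.arange(T + 1)
    het_base = (X * M) @ np.log(h)  # n
    n_het = (X * M).sum(axis=1)  # n
    # hom part depends on t through 2^{-t}
    q = h[None, :] * (2.0 ** -t)[:, None]  # (T+1) x L
    log1mq = np.log1p(-np.clip(q, None, 1 - _EPS))  # (T+1) x L
    hom = ((1 - X) * M) @ log1mq.T  # n x (T+1)
    return het_base[:, None] - n_het[:, None] * t[None, :] * _LN2 + hom


def _loglik(X, M, h, s) -> float:
    T = _truncation(s)
    A = _loglik_grid(X, M, h, T)
    t = np.arange(T + 1)
    if s <= 0:
        return float(A[:, 0].sum())
    logprior = np.log1p(-s) + t * np.log(s)
    return float(logsumexp(A + logprior[None, :], axis=1).sum())


def _update_h(X, M, W, T):
    """M-step for the per-locus outcrossed heterozygosities.

    ``W`` is the n x (T+1) posterior weight matrix over outcrossing ages.
    Each locus solves a one-dimensional concave score equation by bisection.
    """
    n, L = X.shape
    t = np.arange(T + 1)
    pow2 = 2.0 ** -t
    h_new = np.empty(L)
    for l in range(L):
        obs = M[:, l] > 0
        n_het = float((X[obs, l]).sum())
        hom_w = W[obs][(X[obs, l] == 0)]  # weights of homozygous observed individuals
        g = hom_w.sum(axis=0)  # aggregated weight per t
        if n_het == 0:
            h_new[l] = _EPS
            continue
        if g.sum() == 0:
            h_new[l] = 1 - _EPS
            continue

        def score(h):
            return n_het / h - np.sum(g * pow2 / (1.0 - h * pow2))

        lo, hi = _EPS, 1 - _EPS
        if score(hi) > 0:
            h_new[l] = hi
        else:
            h_new[l] = brentq(score, lo, hi, xtol=1e-10)
    return h_new


def _em(X, M, s0, max_iter=500, tol=1e-8, fixed_s: float | None = None):
    """EM over latent outcrossing ages; returns (s, h, loglik, n_iter, conv)."""
    n, L = X.shape
    # initial h: observed heterozygote frequency, bounded away from 0/1
    with np.errstate(invalid="ignore"):
        h = np.clip((X * M).sum(axis=0) / M.sum(axis=0), 0.02, 0.98)
    s = s0 if fixed_s is None else fixed_s
    prev = -np.inf
    for it in range(1, max_iter + 1):
        T = _truncation(s)
        A = _loglik_grid(X, M, h, T)
        t = np.arange(T + 1)
        if s <= 0:
            logpost = A[:, :1]
        else:
            logpost = A + (np.log1p(-s) + t * np.log(s))[None, :]
        norm = logsumexp(logpost, axis=1)
        ll = float(norm.sum())
        W = np.exp(logpost - norm[:, None])
        if abs(ll - prev) < tol:
            return s, h, ll, it, True
        prev = ll
        # M-step
        if fixed_s is None:
            tbar = float((W @ t).mean())
            s = min(tbar / (1.0 + tbar), _S_MAX)
        h = _update_h(X, M, W, T)
    return s, h, prev, max_iter, False


def _null_loglik(X, M) -> float:
    """Closed-form maximized log-likelihood at s = 0 (h_l = het frequency)."""
    n_het = (X * M).sum(axis=0)
    n_obs = M.sum(axis=0)
    h = np.clip(n_het / n_obs, _EPS, 1 - _EPS)
    return float(np.sum(n_het * np.log(h) + (n_obs - n_het) * np.log1p(-h)))


def selfing_maximum_likelihood(
    dataset: GenotypeDataset,
    group: str,
    starts=(0.1, 0.5, 0.9),
    max_iter: int = 500,
) -> SelfingFit:
    """ML selfing rate, maximized log-likelihood, and LRT p-value for s = 0.

    Runs EM from several starting selfing rates and keeps the best optimum.
    With no heterozygote anywhere the likelihood is monotone in ``s``; the
    estimate is then the upper search bound (0.999) with a warning.
    """
    X, M = _het_matrix(dataset, group)
    if X.size == 0 or M.sum() == 0:
        raise EmptyDataError(f"group {group!r} has no observed calls")
    if (X * M).sum(axis=0).astype(bool).sum() < 2:
        # fewer than 2 loci with any heterozygote: boundary or degenerate fit
        if (X * M).sum() == 0:
            warnings.warn(
                f"group {group!r} has no heterozygous call; selfing estimate set "
                f"to the upper search bound {_S_MAX}"
            )
            ll0 = _null_loglik(X, M)
            return SelfingFit(_S_MAX, ll0, 1.0, 0.0, np.zeros(X.shape[1]), 0, True)
    best = None
    for s0 in starts:
        s, h, ll, it, conv = _em(X, M, s0, max_iter=max_iter)
        if best is None or ll > best[2] + 1e-12:
            best = (s, h, ll, it, conv)
    s, h, ll, it, conv = best
    ll0 = _null_loglik(X, M)
    lam = max(0.0, 2.0 * (ll - ll0))
    # boundary mixture 0.5 chi2_0 + 0.5 chi2_1
    p = 1.0 if lam <= 1e-10 else float(0.5 * chi2.sf(lam, df=1))
    return SelfingFit(float(s), ll, p, lam, h, it, conv)


def _profile_loglik(X, M, s, max_iter=200) -> float:
    """Log-likelihood maximized over h at a fixed selfing rate."""
    _, _, ll, _, _ = _em(X, M, s, max_iter=max_iter, fixed_s=s)
    return ll


def compare_selfing(dataset: GenotypeDataset, group_a: str, group_b: str) -> dict:
    """Likelihood-ratio test of equal selfing rate in two samples.

    Null model: one shared ``s`` with free per-group nuisance ``h``;
    alternative: free ``s`` per group.  The statistic is symmetric in the
    two groups; p-value from chi2 with 1 df.
    """
    Xa, Ma = _het_matrix(dataset, group_a)
    Xb, Mb = _het_matrix(dataset, group_b)
    fit_a = selfing_maximum_likelihood(dataset, group_a)
    fit_b = selfing_maximum_likelihood(dataset, group_b)
    ll_free = fit_a.loglik + fit_b.loglik

    def neg_shared(s):
        return -(_profile_loglik(Xa, Ma, s) + _profile_loglik(Xb, Mb, s))

    res = minimize_scalar(neg_shared, bounds=(0.0, _S_MAX), method="bounded",
                          options={"xatol": 1e-4})
    ll_shared = -res.fun
    lam = max(0.0, 2.0 * (ll_free - ll_shared))
    return {
        "statistic": lam,
        "p_value": float(chi2.sf(lam, df=1)),
        "s_shared": float(res.x),
        "s_a": fit_a.s_hat,
        "s_b": fit_b.s_hat,
    }
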