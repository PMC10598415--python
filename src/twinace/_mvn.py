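"""Full-information ML machinery for multivariate-normal twin-pair data.

Pairs with partially missing phenotypes contribute the marginal normal
likelihood of their observed subvector.  For speed, rows are grouped by
missingness pattern and each pattern is summarised by its sufficient
statistics (count, mean, centred scatter), so a -2lnL evaluation costs a
handful of small Cholesky factorisations regardless of sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

_LOG_2PI = float(np.log(2.0 * np.pi))

#: -2lnL value returned for a non-positive-definite implied covariance.
#: Large but finite so optimizers can recover from bad regions.
NONPD_PENALTY = 1e12


@dataclass(frozen=True)
class PatternStats:
    """Sufficient statistics for one missingness pattern."""

    observed: np.ndarray  # indices of observed variables, shape (k,)
    n: int                # number of rows with this pattern
    mean: np.ndarray      # sample mean of observed variables, shape (k,)
    scatter: np.ndarray   # centred scatter sum_i (x-mean)(x-mean)', (k, k)


def split_patterns(X: np.ndarray) -> list[PatternStats]:
    """Group rows of ``X`` (NaN = missing) by missingness pattern.

    Rows with no observed values are dropped (they carry no likelihood).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (rows x variables)")
    n, p = X.shape
    if n == 0:
        return []
    miss = np.isnan(X)
    codes = miss @ (1 << np.arange(p, dtype=np.int64))
    out: list[PatternStats] = []
    for code in np.unique(codes):
        rows = X[codes == code]
        obs = np.flatnonzero(~miss[np.flatnonzero(codes == code)[0]])
        if obs.size == 0:
            continue
        sub = rows[:, obs]
        m = sub.mean(axis=0)
        d = sub - m
        out.append(PatternStats(observed=obs, n=sub.shape[0], mean=m,
                                scatter=d.T @ d))
    return out


def neg2_loglik(mu: np.ndarray, sigma: np.ndarray,
                patterns: list[PatternStats]) -> float:
    """-2 log-likelihood of iid N(mu, sigma) rows summarised by ``patterns``.

    Returns :data:`NONPD_PENALTY` (plus a slope on the most negative
    eigenvalue) when a required marginal covariance is not positive definite.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    total = 0.0
    for pat in patterns:
        obs = pat.observed
        s = sigma[np.ix_(obs, obs)]
        try:
            cf = linalg.cho_factor(s, lower=True, check_finite=False)
        except linalg.LinAlgError:
            lam = linalg.eigvalsh(s)
            return NONPD_PENALTY * (1.0 + abs(float(lam[0])))
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        d = pat.mean - mu[obs]
        a = pat.scatter + pat.n * np.outer(d, d)
        trace = float(np.trace(linalg.cho_solve(cf, a, check_finite=False)))
        total += pat.n * (obs.size * _LOG_2PI + logdet) + trace
    return total


def neg2_loglik_rows(mu: np.ndarray, sigma: np.ndarray, X: np.ndarray) -> float:
    """Convenience wrapper: -2lnL evaluated directly from a data matrix."""
    return neg2_loglik(mu, sigma, split_patterns(X))


def finite_difference_hessian(fun, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian, used for delta-method fallbacks."""
    x = np.asarray(x, dtype=float)
    k = x.size
    h = np.full(k, step) * np.maximum(1.0, np.abs(x))
    hess = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                hess[i, i] = (fun(xp) - 2.0 * f0 + fun(xm)) / h[i] ** 2
            else:
                xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
                xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
                hess[i, j] = hess[j, i] = (
                    fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)
                ) / (4.0 * h[i] * h[j])
    return hess
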