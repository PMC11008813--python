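"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's vectorized code paths: dense
covariance matrices, explicit inverses, and nested grid search over the
intraclass correlation.
"""

import numpy as np


def dense_gls(X, y, groups, rho):
    """GLS estimates at a fixed intraclass correlation via an explicit
    covariance matrix."""
    groups = np.asarray(groups)
    same = groups[:, None] == groups[None, :]
    C = np.where(same, rho, 0.0)
    np.fill_diagonal(C, 1.0)
    Ci = np.linalg.inv(C)
    XtCiX = X.T @ Ci @ X
    beta = np.linalg.inv(XtCiX) @ (X.T @ Ci @ y)
    r = y - X @ beta
    rss = float(r @ Ci @ r)
    n = len(y)
    _, logdet = np.linalg.slogdet(C)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0) - 0.5 * logdet
    return beta, XtCiX, rss, loglik


def profiled_gls_oracle(X, y, groups, max_rho=0.995):
    """Profile-ML fit by nested grid search over rho (coarse 1e-3 grid, then
    two local refinements to 1e-7).  Returns beta, se, t with the
    residual-df variance scale RSS/(n-p)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape

    def ll(rho):
        return dense_gls(X, y, groups, rho)[3]

    grid = np.arange(0.0, max_rho + 1e-12, 1e-3)
    best = grid[int(np.argmax([ll(r) for r in grid]))]
    for step in (1e-5, 1e-7):
        lo = max(best - 100 * step, 0.0)
        hi = min(best + 100 * step, max_rho)
        local = np.arange(lo, hi + step / 2, step)
        best = local[int(np.argmax([ll(r) for r in local]))]
    beta, XtCiX, rss, _ = dense_gls(X, y, groups, best)
    sigma2 = rss / (n - p)
    se = np.sqrt(np.diag(np.linalg.inv(XtCiX)) * sigma2)
    return beta, se, beta / se, best


def bh_stepup_bruteforce(pvals):
    """Closed-form Benjamini-Hochberg step-up q-values, written naively."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q
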