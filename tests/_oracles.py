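"""Independent oracles for the mixed-model fits.

The brute-force oracle maximizes the marginal Gaussian likelihood directly
over (log sigma_u2, log sigma_e2) with a dense-matrix likelihood (explicit
n x n covariance, Cholesky) and multi-start Nelder-Mead — sharing no code
path with the package's profiled implementation.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def dense_loglik(theta, y, X, Z, reml=False):
    su2, se2 = np.exp(theta)
    n, p = X.shape
    V = se2 * np.eye(n) + su2 * (Z @ Z.T)
    L = np.linalg.cholesky(V)
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    A = X.T @ Vi_X
    beta = np.linalg.solve(A, X.T @ Vi_y)
    r = y - X @ beta
    Vi_r = np.linalg.solve(V, r)
    ld = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (n * np.log(2 * np.pi) + ld + float(r @ Vi_r))
    if reml:
        ll += 0.5 * p * np.log(2 * np.pi) - 0.5 * float(np.linalg.slogdet(A)[1])
    return ll, beta


def brute_force_fit(y, X, groups, reml=False):
    """Maximize over both variance components by direct numeric search."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    codes = np.unique(groups, return_inverse=True)[1]
    Z = (codes[:, None] == np.arange(codes.max() + 1)).astype(float)

    best = None
    for start in [(-2.0, -2.0), (0.0, 0.0), (-6.0, 0.0), (1.0, -1.0)]:
        res = optimize.minimize(
            lambda t: -dense_loglik(t, y, X, Z, reml)[0],
            start,
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    ll, beta = dense_loglik(best.x, y, X, Z, reml)
    su2, se2 = np.exp(best.x)
    return {"loglik": ll, "beta": beta, "sigma_u2": su2, "sigma_e2": se2}


def anova_moment_estimates(y, groups):
    """Closed-form one-way balanced variance components (ML and REML)."""
    y = np.asarray(y, float)
    labels = np.unique(groups)
    J = len(labels)
    sizes = {g: np.sum(groups == g) for g in labels}
    m = next(iter(sizes.values()))
    assert all(v == m for v in sizes.values()), "layout must be balanced"
    ybar_j = np.array([y[groups == g].mean() for g in labels])
    ssb = m * float(((ybar_j - y.mean()) ** 2).sum())
    sse = float(sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum() for g in labels))
    mse = sse / (J * m - J)
    msb = ssb / (J - 1)
    return {
        "ml": {"sigma_e2": mse, "sigma_u2": max(0.0, (ssb / J - mse) / m)},
        "reml": {"sigma_e2": mse, "sigma_u2": max(0.0, (msb - mse) / m)},
    }


def random_small_instance(rng, max_clusters=5, max_n=50):
    """One random small clustered dataset for the oracle-equivalence check."""
    while True:
        J = int(rng.integers(2, max_clusters + 1))
        sizes = rng.integers(2, 11, J)
        groups = np.repeat(np.arange(J), sizes)
        n = len(groups)
        if n > max_n:
            continue
        p = int(rng.integers(1, 4))
        if n <= p + 2:
            continue
        X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p - 1)])
        su = rng.uniform(0.0, 1.5)
        se = rng.uniform(0.3, 1.5)
        y = X @ rng.normal(size=p) + rng.normal(0, su, J)[groups] + rng.normal(0, se, n)
        return y, X, groups
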