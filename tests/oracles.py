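"""Independent oracles used by the test suite.

These deliberately avoid the package's own computational paths: brute-force
grids, alternating least squares and numerical quadrature, run at tiny
problem sizes.
"""
import math

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm


def als_reduced_rank(X, Y, rank, n_starts=20, n_iter=200, seed=0):
    """Multi-start alternating least squares for min ||Y - X U V^T||_F^2.

    Alternately solves the two linear subproblems from random starts and
    returns the best squared residual found.
    """
    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        V = rng.normal(size=(Y.shape[1], rank))
        for _ in range(n_iter):
            U = np.linalg.pinv(X) @ Y @ V @ np.linalg.pinv(V.T @ V)
            fitted_low = X @ U
            V = Y.T @ fitted_low @ np.linalg.pinv(fitted_low.T @ fitted_low)
        best = min(best, float(np.linalg.norm(Y - X @ U @ V.T) ** 2))
    return best


def grid_search_map_coefficient(x, y, sigma2=1.0, lo=-3.0, hi=3.0, step=1e-4):
    """Profile the rank-1 log-link MAP objective over b = u*v.

    For fixed b the best factorization under unit Gaussian priors is
    u = v = +-sqrt(|b|), giving prior penalty -|b|/sigma2; the profiled
    objective is sum(y*b*x - exp(b*x)) - |b|/sigma2, maximized on a grid.
    """
    grid = np.arange(lo, hi, step)
    eta = x.ravel()[:, None] * grid[None, :]
    obj = (y.ravel()[:, None] * eta - np.exp(eta)).sum(axis=0) - np.abs(grid) / sigma2
    return float(grid[np.argmax(obj)])


def quadrature_log_evidence(x, y, half_width=6.0, n_points=501):
    """2-D grid quadrature of the scalar log-link model's marginal likelihood.

    log integral of Poisson(y | exp(x*u*v)) N(u) N(v) du dv on a wide grid;
    only valid for P = Q = R = 1.
    """
    grid = np.linspace(-half_width, half_width, n_points)
    uu, vv = np.meshgrid(grid, grid, indexing="ij")
    eta = x.ravel()[:, None, None] * (uu * vv)[None]
    loglik = (y.ravel()[:, None, None] * eta - np.exp(eta)).sum(axis=0) - sum(
        math.lgamma(int(k) + 1) for k in y.ravel()
    )
    integrand = loglik + norm.logpdf(uu) + norm.logpdf(vv)
    h = grid[1] - grid[0]
    return float(logsumexp(integrand) + 2 * np.log(h))
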