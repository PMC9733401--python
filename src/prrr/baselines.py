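"""Reference models: closed-form Gaussian reduced-rank regression and
full-rank Poisson regression.

Gaussian RRR minimizes ||Y - X U V^T||_F^2 and has a closed form: take the
ridge-stabilized OLS coefficients and project the fitted values onto their
leading R right singular vectors, so X B_rrr is the best rank-R
approximation (Eckart-Young) of X B_ols. Full-rank Poisson regression is
the log-link model fit at R = min(P, Q), exposed separately so benchmark
configurations read cleanly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import PriorConfig
from .results import PRRRResults

__all__ = ["GaussianRRRFit", "fit_gaussian_rrr", "fit_fullrank_poisson"]


def _values(M) -> np.ndarray:
    return np.asarray(M.values if hasattr(M, "values") else M, dtype=float)


@dataclass
class GaussianRRRFit:
    """Closed-form Gaussian reduced-rank regression solution."""

    B_ols: np.ndarray
    B_rrr: np.ndarray
    rank: int
    singular_vectors: np.ndarray  # Q x R right singular vectors of X @ B_ols

    def predict(self, X_new) -> np.ndarray:
        return _values(X_new) @ self.B_rrr


def fit_gaussian_rrr(X, Y, rank: int, ridge: float = 1e-6) -> GaussianRRRFit:
    """Solve min ||Y - X B||_F^2 subject to rank(B) <= R in closed form.

    B_ols = (X^T X + ridge I)^-1 X^T Y; with X B_ols = L D W^T the SVD of
    the fitted values, B_rrr = B_ols W_R W_R^T where W_R holds the leading
    R right singular vectors, so the fitted values of the reduced model are
    the best rank-R approximation of the OLS fitted values.
    """
    Xv, Yv = _values(X), _values(Y)
    if Xv.shape[0] != Yv.shape[0]:
        raise ValueError(f"X has {Xv.shape[0]} rows but Y has {Yv.shape[0]}")
    n, p = Xv.shape
    q = Yv.shape[1]
    if not 1 <= rank <= min(p, q):
        raise ValueError(f"rank must be in [1, {min(p, q)}], got {rank}")
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    G = Xv.T @ Xv + ridge * np.eye(p)
    if ridge == 0:
        # detect a singular normal-equation system before solving
        if np.linalg.matrix_rank(G) < p:
            raise np.linalg.LinAlgError(
                "X^T X is singular (N <= P or collinear columns); "
                "pass ridge > 0 to stabilize the inversion"
            )
    B_ols = np.linalg.solve(G, Xv.T @ Yv)
    fitted = Xv @ B_ols
    _, _, Wt = np.linalg.svd(fitted, full_matrices=False)
    W_r = Wt[:rank].T  # Q x R
    B_rrr = B_ols @ W_r @ W_r.T
    return GaussianRRRFit(B_ols=B_ols, B_rrr=B_rrr, rank=rank, singular_vectors=W_r)


def fit_fullrank_poisson(model, prior: PriorConfig | None = None, options=None) -> PRRRResults:
    """Log-link Poisson regression with an unconstrained coefficient matrix.

    Identical to a MAP fit at R = min(P, Q): the factorization U V^T then
    spans all P x Q matrices, so no rank restriction binds.
    """
    from .inference import fit_map

    rank = min(model.n_covariates, model.n_features)
    return fit_map(model, rank, prior, options)
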