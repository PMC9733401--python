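"""Poisson reduced-rank regression models.

Two related models for mapping N samples' covariates ``X`` (N x P) to count
outcomes ``Y`` (N x Q) through a rank-R coefficient matrix ``B = U V^T``:

* **PoissonRRR** (log link):
  ``y_nq ~ Poisson(exp(x_n U v_q^T))`` with independent N(0, sigma^2)
  priors on the factor entries.

* **NonnegativePoissonRRR** (identity link, additive "parts-based" form):
  ``y_nq ~ Poisson(s_n * x_n U v_q^T)`` with Gamma(alpha, beta) priors on
  the strictly positive factor entries and per-sample size factors
  ``s_n = sum_q y_nq`` absorbing sequencing depth.

Both expose the statsmodels-style surface: construct from data, call
``fit()`` (MAP gradient ascent or stochastic variational inference) and
receive a results object.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import (
    CountMatrix,
    CovariateMatrix,
    FactorPair,
    PriorConfig,
    SizeFactors,
    compute_size_factors,
)

__all__ = [
    "PoissonRRR",
    "NonnegativePoissonRRR",
    "prrr_rates",
    "nnprrr_rates",
    "log_joint",
    "poisson_log_pmf",
]

# Linear predictor clip for the log-link model: exp(30) ~ 1e13 transcript
# counts, far beyond any realistic fit, while exp(700) overflows float64.
LINPRED_CLIP = 30.0
# Rate floor for the identity-link model so log(rate) stays finite when a
# sample's covariate row is all zero.
RATE_FLOOR = 1e-8


def _values(M) -> np.ndarray:
    return M.values if hasattr(M, "values") else np.asarray(M, dtype=float)


def _check_conformable(X: np.ndarray, F: FactorPair) -> None:
    if X.shape[1] != F.U.shape[0]:
        raise ValueError(
            f"covariate dimension mismatch: X is {X.shape[0]}x{X.shape[1]} "
            f"but U is {F.U.shape[0]}x{F.U.shape[1]} (expected X with "
            f"{F.U.shape[0]} columns)"
        )


def prrr_rates(X, F: FactorPair) -> np.ndarray:
    """Poisson rates of the log-link model, exp(X U V^T), entrywise.

    The linear predictor is clipped to [-30, 30] before exponentiation for
    numerical stability; outputs are finite and strictly positive.
    """
    Xv = _values(X)
    _check_conformable(Xv, F)
    eta = np.clip((Xv @ F.U) @ F.V.T, -LINPRED_CLIP, LINPRED_CLIP)
    return np.exp(eta)


def nnprrr_rates(X, F: FactorPair, s: SizeFactors | np.ndarray) -> np.ndarray:
    """Poisson rates of the identity-link model, s_n * (x_n U v_q^T).

    Requires a fully nonnegative decomposition: X >= 0 and U, V > 0.
    A floor of 1e-8 is added so downstream logs are finite even when a
    covariate row is entirely zero.
    """
    Xv = _values(X)
    _check_conformable(Xv, F)
    if np.any(Xv < 0):
        raise ValueError("identity-link model requires nonnegative covariates")
    F.require_positive()
    sv = s.s if isinstance(s, SizeFactors) else np.asarray(s, dtype=float).ravel()
    if sv.size != Xv.shape[0]:
        raise ValueError(
            f"size factor length {sv.size} does not match {Xv.shape[0]} samples"
        )
    if np.any(sv <= 0):
        raise ValueError("size factors must be strictly positive")
    return sv[:, None] * ((Xv @ F.U) @ F.V.T) + RATE_FLOOR


def poisson_log_pmf(y: np.ndarray, rate: np.ndarray) -> np.ndarray:
    """Entrywise log Poisson(y | rate), constants included."""
    return y * np.log(rate) - rate - gammaln(y + 1.0)


def _log_prior(F: FactorPair, prior: PriorConfig) -> float:
    if prior.family == "gaussian":
        lp = -0.5 * (F.U**2).sum() / prior.sigma2_u - 0.5 * F.U.size * np.log(
            2 * np.pi * prior.sigma2_u
        )
        lp += -0.5 * (F.V**2).sum() / prior.sigma2_v - 0.5 * F.V.size * np.log(
            2 * np.pi * prior.sigma2_v
        )
        return float(lp)
    # Gamma(alpha, beta) with rate parameterization
    F.require_positive()

    def block(M, a, b):
        return (
            M.size * (a * np.log(b) - gammaln(a))
            + (a - 1.0) * np.log(M).sum()
            - b * M.sum()
        )

    return float(
        block(F.U, prior.alpha_u, prior.beta_u) + block(F.V, prior.alpha_v, prior.beta_v)
    )


def log_joint(
    X,
    Y,
    F: FactorPair,
    prior: PriorConfig,
    model: str,
    size_factors: SizeFactors | None = None,
) -> float:
    """Unnormalized log posterior log p(U, V) + log p(Y | X, U, V).

    ``model`` selects the likelihood: ``"prrr"`` (log link, Gaussian prior)
    or ``"nnprrr"`` (identity link, Gamma prior, size factors computed from
    the row totals of Y unless given). Constants of the Poisson pmf are
    retained so values are comparable across models.
    """
    if model not in ("prrr", "nnprrr"):
        raise ValueError(f"unknown model {model!r}")
    expected_family = "gaussian" if model == "prrr" else "gamma"
    if prior.family != expected_family:
        raise ValueError(
            f"prior family {prior.family!r} does not match model {model!r} "
            f"(expected {expected_family!r})"
        )
    Yv = Y.values if isinstance(Y, CountMatrix) else np.asarray(Y)
    if model == "prrr":
        rates = prrr_rates(X, F)
    else:
        s = size_factors if size_factors is not None else compute_size_factors(Yv)
        rates = nnprrr_rates(X, F, s)
    return _log_prior(F, prior) + float(poisson_log_pmf(Yv, rates).sum())


def _loglik_and_grad_prrr(Xv, Yv, U, V):
    """Poisson log-likelihood under the log link and its gradients in U, V."""
    eta = (Xv @ U) @ V.T
    clipped = np.clip(eta, -LINPRED_CLIP, LINPRED_CLIP)
    lam = np.exp(clipped)
    ll = float((Yv * clipped - lam - gammaln(Yv + 1.0)).sum())
    # straight-through gradient: at a clipped entry, y - exp(30) still pushes
    # the predictor back inside the window instead of stalling at zero slope
    dl_deta = Yv - lam
    gU = Xv.T @ (dl_deta @ V)
    gV = dl_deta.T @ (Xv @ U)
    return ll, gU, gV


def _loglik_and_grad_nnprrr(Xv, Yv, U, V, s):
    """Poisson log-likelihood under the identity link and gradients in U, V."""
    M = (Xv @ U) @ V.T
    lam = s[:, None] * M + RATE_FLOOR
    ll = float((Yv * np.log(lam) - lam - gammaln(Yv + 1.0)).sum())
    dl_dM = s[:, None] * (Yv / lam - 1.0)
    gU = Xv.T @ (dl_dM @ V)
    gV = dl_dM.T @ (Xv @ U)
    return ll, gU, gV


class _BasePoissonRRR:
    """Shared plumbing for the two reduced-rank Poisson regressions."""

    model_tag: str = ""

    def __init__(self, Y, X, *, sample_ids=None, feature_ids=None, covariate_ids=None):
        if not isinstance(Y, CountMatrix):
            Y = CountMatrix(np.asarray(Y), sample_ids=sample_ids, feature_ids=feature_ids)
        if not isinstance(X, CovariateMatrix):
            X = CovariateMatrix(
                np.asarray(X, dtype=float),
                covariate_ids=covariate_ids,
                sample_ids=sample_ids,
            )
        if Y.n_samples != X.n_samples:
            raise ValueError(
                f"Y has {Y.n_samples} samples but X has {X.n_samples}"
            )
        self.endog = Y
        self.exog = X

    @classmethod
    def from_dataframes(cls, counts: pd.DataFrame, covariates: pd.DataFrame, **kwargs):
        """Build the model from labeled pandas frames (rows = samples)."""
        if not counts.index.equals(covariates.index):
            raise ValueError("counts and covariates must share the same sample index")
        Y = CountMatrix(
            counts.to_numpy(),
            sample_ids=list(counts.index.astype(str)),
            feature_ids=list(counts.columns.astype(str)),
        )
        X = CovariateMatrix(
            covariates.to_numpy(dtype=float),
            covariate_ids=list(covariates.columns.astype(str)),
            sample_ids=list(covariates.index.astype(str)),
            encoding=kwargs.pop("encoding", "raw"),
        )
        return cls(Y, X, **kwargs)

    @property
    def n_samples(self) -> int:
        return self.endog.n_samples

    @property
    def n_covariates(self) -> int:
        return self.exog.n_covariates

    @property
    def n_features(self) -> int:
        return self.endog.n_features

    def default_prior(self) -> PriorConfig:
        return PriorConfig.for_model(self.model_tag)

    def log_joint(self, F: FactorPair, prior: PriorConfig | None = None) -> float:
        prior = prior or self.default_prior()
        return log_joint(
            self.exog,
            self.endog,
            F,
            prior,
            self.model_tag,
            size_factors=getattr(self, "size_factors", None),
        )

    def fit(
        self,
        rank: int,
        method: str = "map",
        prior: PriorConfig | None = None,
        options=None,
        **option_kwargs,
    ):
        """Fit at the given rank; ``method`` is ``"map"`` or ``"vi"``.

        Extra keyword arguments are forwarded to :class:`FitOptions`
        (``max_iter``, ``learning_rate``, ``seed``, ...).
        """
        from .inference import FitOptions, fit_map, fit_vi

        if options is None:
            options = FitOptions(**option_kwargs)
        elif option_kwargs:
            raise TypeError("pass either options or keyword overrides, not both")
        prior = prior or self.default_prior()
        if method == "map":
            return fit_map(self, rank, prior, options)
        if method == "vi":
            return fit_vi(self, rank, prior, options)
        raise ValueError(f"unknown method {method!r}; expected 'map' or 'vi'")

    def select_rank(self, ranks: Sequence[int], restarts: int = 5, prior=None, options=None, **option_kwargs):
        from .inference import FitOptions, select_rank

        if options is None:
            options = FitOptions(**option_kwargs)
        return select_rank(self, list(ranks), restarts, prior or self.default_prior(), options)


class PoissonRRR(_BasePoissonRRR):
    """Reduced-rank Poisson regression with a log link.

    Counts are modeled as ``y_nq ~ Poisson(exp(x_n U v_q^T))`` with
    ``U`` (P x R) and ``V`` (Q x R) carrying independent Gaussian priors.
    Covariates may be real-valued (genotype dosages, one-hot indicators,
    spatial coordinates, arbitrary numeric features).

    Examples
    --------
    >>> model = PoissonRRR(Y, X)
    >>> res = model.fit(rank=3, method="map", seed=0)
    >>> res.coefficients.shape
    (P, Q)
    """

    model_tag = "prrr"

    def rates(self, F: FactorPair, X=None) -> np.ndarray:
        return prrr_rates(self.exog if X is None else X, F)

    def loglik_and_grad(self, U: np.ndarray, V: np.ndarray):
        return _loglik_and_grad_prrr(self.exog.values, self.endog.values, U, V)


class NonnegativePoissonRRR(_BasePoissonRRR):
    """Nonnegative reduced-rank Poisson regression (identity link).

    Counts are modeled as ``y_nq ~ Poisson(s_n * x_n U v_q^T)`` with
    strictly positive factors under Gamma(2, 1) priors and per-sample size
    factors ``s_n``. By default ``s_n`` is the sample's total transcript
    count; pass ``size_factors`` to override (e.g. when the generating
    depths are known). Requires nonnegative covariates; suited to
    parts-based, additive decompositions of e.g. minor-allele counts or
    cell-type indicators.
    """

    model_tag = "nnprrr"

    def __init__(self, Y, X, size_factors: SizeFactors | None = None, **kwargs):
        super().__init__(Y, X, **kwargs)
        if not self.exog.is_nonnegative():
            raise ValueError(
                "nonnegative model requires a nonnegative covariate matrix"
            )
        if size_factors is None:
            size_factors = compute_size_factors(self.endog)
        elif not isinstance(size_factors, SizeFactors):
            size_factors = SizeFactors(np.asarray(size_factors, dtype=float))
        if len(size_factors) != self.n_samples:
            raise ValueError("size factor length does not match sample count")
        self.size_factors = size_factors

    def rates(self, F: FactorPair, X=None, s=None) -> np.ndarray:
        return nnprrr_rates(
            self.exog if X is None else X,
            F,
            self.size_factors if s is None else s,
        )

    def loglik_and_grad(self, U: np.ndarray, V: np.ndarray):
        return _loglik_and_grad_nnprrr(
            self.exog.values, self.endog.values, U, V, self.size_factors.s
        )
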