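"""Gradient-based fitting: MAP ascent and stochastic variational inference.

Both models have closed-form gradients, so optimization runs on plain
numpy with an in-package Adam optimizer:

* **MAP** maximizes the log joint ``log p(U, V) + log p(Y | X, U, V)``
  directly in (U, V) for the log-link model, and in (log U, log V) for the
  nonnegative model so positivity is automatic.
* **SVI** maximizes the evidence lower bound over a mean-field variational
  family — elementwise normal for the log-link model, elementwise
  log-normal for the nonnegative one — using one reparameterized sample
  per step for the likelihood term and closed-form expressions for the
  expected log prior and the entropy (both exist for these
  family/prior pairs, which keeps gradient variance low).

``elbo`` is the plain Monte-Carlo estimator of
``E_q[log p(X, Y, U, V) - log q(U, V)]`` used for reporting and for rank
selection; it is deterministic given its seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import FactorPair, PriorConfig
from .results import PRRRResults, RankSelectionResult

__all__ = [
    "FitOptions",
    "VariationalState",
    "fit_map",
    "fit_vi",
    "elbo",
    "select_rank",
]

# Fixed seed for the final ELBO evaluation so that evaluated ELBOs are a
# common yardstick across fits, restarts and ranks (same Monte-Carlo noise).
ELBO_EVAL_SEED = 20221208

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)
_HALF_LOG_2PIE = 0.5 * np.log(2.0 * np.pi * np.e)


@dataclass
class FitOptions:
    """Optimizer settings shared by MAP and VI fits.

    ``learning_rate`` defaults to Adam's 0.01. Convergence is declared when
    the relative change between successive 50-iteration moving averages of
    the objective falls below ``rel_tol``.
    """

    max_iter: int = 3000
    learning_rate: float = 0.01
    mc_samples_train: int = 1
    mc_samples_eval: int = 64
    rel_tol: float = 1e-6
    window: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_iter, self.mc_samples_train, self.mc_samples_eval, self.window) < 1:
            raise ValueError("iteration and sample counts must be positive")
        if self.learning_rate <= 0 or self.rel_tol <= 0:
            raise ValueError("learning_rate and rel_tol must be positive")


class _Adam:
    """Adam for ascent over a list of numpy arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p += self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _Convergence:
    """Windowed moving-average stopping rule for (possibly noisy) traces."""

    def __init__(self, window: int, rel_tol: float):
        self.window, self.rel_tol = window, rel_tol
        self.prev_mean: float | None = None

    def check(self, trace: list[float], it: int) -> bool:
        if (it + 1) % self.window:
            return False
        mean = float(np.mean(trace[-self.window:]))
        done = False
        if self.prev_mean is not None:
            denom = max(abs(self.prev_mean), 1.0)
            done = abs(mean - self.prev_mean) / denom < self.rel_tol
        self.prev_mean = mean
        return done


def _gaussian_prior_grad(M: np.ndarray, sigma2: float) -> np.ndarray:
    return -M / sigma2


def fit_map(model, rank: int, prior: PriorConfig | None = None, options: FitOptions | None = None) -> PRRRResults:
    """Maximum a posteriori fit by Adam ascent on the log joint.

    The nonnegative model is optimized in log-parameters (log U, log V), a
    smooth unconstrained reparameterization that guarantees positive
    estimates and matches the geometry of the log-normal VI family.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > min(model.n_covariates, model.n_features):
        warnings.warn(
            f"rank {rank} exceeds min(P, Q) = {min(model.n_covariates, model.n_features)}; "
            "the factorization is overcomplete",
            stacklevel=2,
        )
    prior = prior or model.default_prior()
    opts = options or FitOptions()
    rng = np.random.default_rng(opts.seed)
    P, Q = model.n_covariates, model.n_features
    nonneg = model.model_tag == "nnprrr"
    if nonneg and prior.family != "gamma":
        raise ValueError("nonnegative model requires the gamma prior family")
    if not nonneg and prior.family != "gaussian":
        raise ValueError("log-link model requires the gaussian prior family")

    # symmetry-breaking init: small zero-mean normal entries
    # (log-parameters for the nonnegative model)
    pu = rng.normal(0.0, 0.1, size=(P, rank))
    pv = rng.normal(0.0, 0.1, size=(Q, rank))

    def objective_and_grads(pu, pv):
        if nonneg:
            U, V = np.exp(pu), np.exp(pv)
            ll, gU, gV = model.loglik_and_grad(U, V)
            # Gamma(a, b) log prior in log-space: (a-1)*log u - b*u + const;
            # chain rule through u = exp(p) multiplies the u-gradient by u
            au, bu, av, bv = prior.alpha_u, prior.beta_u, prior.alpha_v, prior.beta_v
            lp = (
                U.size * (au * np.log(bu) - gammaln(au)) + (au - 1) * pu.sum() - bu * U.sum()
                + V.size * (av * np.log(bv) - gammaln(av)) + (av - 1) * pv.sum() - bv * V.sum()
            )
            gpu = gU * U + (au - 1) - bu * U
            gpv = gV * V + (av - 1) - bv * V
        else:
            U, V = pu, pv
            ll, gU, gV = model.loglik_and_grad(U, V)
            s2u, s2v = prior.sigma2_u, prior.sigma2_v
            lp = (
                -0.5 * (U**2).sum() / s2u - U.size * (_HALF_LOG_2PI + 0.5 * np.log(s2u))
                - 0.5 * (V**2).sum() / s2v - V.size * (_HALF_LOG_2PI + 0.5 * np.log(s2v))
            )
            gpu = gU + _gaussian_prior_grad(U, s2u)
            gpv = gV + _gaussian_prior_grad(V, s2v)
        return ll + float(lp), gpu, gpv

    obj0, _, _ = objective_and_grads(pu, pv)
    if not np.isfinite(obj0):
        raise FloatingPointError(
            "log joint is non-finite at initialization; check Y for extreme "
            "counts or rescale the covariates"
        )

    adam = _Adam([pu, pv], opts.learning_rate)
    stopper = _Convergence(opts.window, opts.rel_tol)
    trace: list[float] = []
    converged = False
    for it in range(opts.max_iter):
        obj, gpu, gpv = objective_and_grads(pu, pv)
        trace.append(obj)
        adam.step([gpu, gpv])
        if stopper.check(trace, it):
            converged = True
            break

    F = FactorPair(np.exp(pu), np.exp(pv)) if nonneg else FactorPair(pu.copy(), pv.copy())
    return PRRRResults(
        model=model,
        model_tag=model.model_tag,
        method="map",
        rank=rank,
        point_estimate=F,
        prior=prior,
        trace=np.array(trace),
        converged=converged,
        n_iter=len(trace),
        seed=opts.seed,
    )


@dataclass
class VariationalState:
    """Mean-field variational parameters for the factor posteriors.

    Each factor entry gets an independent ``normal`` (log-link model) or
    ``lognormal`` (nonnegative model) variational factor with location
    ``mu`` and scale ``exp(log_sigma)``.
    """

    family: str
    mu_u: np.ndarray
    log_sigma_u: np.ndarray
    mu_v: np.ndarray
    log_sigma_v: np.ndarray

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown variational family {self.family!r}")
        for name in ("mu_u", "log_sigma_u", "mu_v", "log_sigma_v"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.mu_u.shape != self.log_sigma_u.shape or self.mu_v.shape != self.log_sigma_v.shape:
            raise ValueError("location/scale shapes do not match")
        if self.mu_u.shape[1] != self.mu_v.shape[1]:
            raise ValueError("U and V variational blocks disagree on rank")

    @property
    def rank(self) -> int:
        return self.mu_u.shape[1]

    def sample(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """One reparameterized draw (U, V, eps_u, eps_v)."""
        eps_u = rng.standard_normal(self.mu_u.shape)
        eps_v = rng.standard_normal(self.mu_v.shape)
        zu = self.mu_u + np.exp(self.log_sigma_u) * eps_u
        zv = self.mu_v + np.exp(self.log_sigma_v) * eps_v
        if self.family == "lognormal":
            return np.exp(zu), np.exp(zv), eps_u, eps_v
        return zu, zv, eps_u, eps_v

    def log_q(self, U: np.ndarray, V: np.ndarray) -> float:
        """Variational log density evaluated at factor values."""

        def block(val, mu, log_sigma):
            sigma = np.exp(log_sigma)
            if self.family == "lognormal":
                z = np.log(val)
                jac = -z  # d log-normal pdf includes -log(val)
            else:
                z = val
                jac = 0.0
            return np.sum(
                -_HALF_LOG_2PI - log_sigma - 0.5 * ((z - mu) / sigma) ** 2 + jac
            )

        return float(
            block(U, self.mu_u, self.log_sigma_u) + block(V, self.mu_v, self.log_sigma_v)
        )

    def point_estimate(self) -> FactorPair:
        """Variational means mapped through the family."""
        if self.family == "lognormal":
            U = np.exp(self.mu_u + 0.5 * np.exp(2 * self.log_sigma_u))
            V = np.exp(self.mu_v + 0.5 * np.exp(2 * self.log_sigma_v))
        else:
            U, V = self.mu_u.copy(), self.mu_v.copy()
        return FactorPair(U, V)


def elbo(
    model,
    qstate: VariationalState,
    prior: PriorConfig | None = None,
    n_samples: int = 64,
    seed: int = 0,
    include_likelihood: bool = True,
) -> float:
    """Monte-Carlo evidence lower bound E_q[log p(X,Y,U,V) - log q(U,V)].

    Averages ``n_samples`` reparameterized draws; deterministic given
    ``seed``. With ``include_likelihood=False`` the data term is dropped,
    leaving ``-KL(q || prior)`` (zero when q equals the prior).
    """
    prior = prior or model.default_prior()
    expected = "normal" if model.model_tag == "prrr" else "lognormal"
    if qstate.family != expected:
        raise ValueError(
            f"variational family {qstate.family!r} does not match model "
            f"{model.model_tag!r} (expected {expected!r})"
        )
    rng = np.random.default_rng(seed)
    from .model import log_joint

    vals = np.empty(n_samples)
    for i in range(n_samples):
        U, V, _, _ = qstate.sample(rng)
        F = FactorPair(U, V)
        if include_likelihood:
            lp = log_joint(
                model.exog,
                model.endog,
                F,
                prior,
                model.model_tag,
                size_factors=getattr(model, "size_factors", None),
            )
        else:
            from .model import _log_prior

            lp = _log_prior(F, prior)
        vals[i] = lp - qstate.log_q(U, V)
    out = float(vals.mean())
    if not np.isfinite(out):
        raise FloatingPointError(
            "non-finite ELBO estimate; review the rate floor / linear-predictor clipping"
        )
    return out


def fit_vi(model, rank: int, prior: PriorConfig | None = None, options: FitOptions | None = None) -> PRRRResults:
    """Stochastic variational inference with Adam.

    Likelihood gradients use one reparameterized Monte-Carlo sample per
    step; the expected log prior and the entropy enter in closed form.
    The returned ``elbo`` field is evaluated with ``mc_samples_eval``
    draws at a fixed evaluation seed.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    prior = prior or model.default_prior()
    opts = options or FitOptions()
    rng = np.random.default_rng(opts.seed)
    P, Q = model.n_covariates, model.n_features
    nonneg = model.model_tag == "nnprrr"
    family = "lognormal" if nonneg else "normal"
    if nonneg and prior.family != "gamma":
        raise ValueError("nonnegative model requires the gamma prior family")
    if not nonneg and prior.family != "gaussian":
        raise ValueError("log-link model requires the gaussian prior family")

    mu_u = rng.normal(0.0, 0.1, size=(P, rank))
    mu_v = rng.normal(0.0, 0.1, size=(Q, rank))
    ls_u = np.full((P, rank), -2.0)
    ls_v = np.full((Q, rank), -2.0)

    def prior_and_entropy():
        """Closed-form E_q[log p(U,V)] + H[q] and its gradients."""
        su, sv = np.exp(ls_u), np.exp(ls_v)
        if nonneg:
            au, bu, av, bv = prior.alpha_u, prior.beta_u, prior.alpha_v, prior.beta_v
            Eu = np.exp(mu_u + 0.5 * su**2)  # E_q[u] for log-normal q
            Ev = np.exp(mu_v + 0.5 * sv**2)
            val = (
                mu_u.size * (au * np.log(bu) - gammaln(au)) + (au - 1) * mu_u.sum() - bu * Eu.sum()
                + mu_v.size * (av * np.log(bv) - gammaln(av)) + (av - 1) * mu_v.sum() - bv * Ev.sum()
                + (mu_u + _HALF_LOG_2PIE + ls_u).sum()
                + (mu_v + _HALF_LOG_2PIE + ls_v).sum()
            )
            g_mu_u = (au - 1) - bu * Eu + 1.0
            g_mu_v = (av - 1) - bv * Ev + 1.0
            g_ls_u = -bu * Eu * su**2 + 1.0
            g_ls_v = -bv * Ev * sv**2 + 1.0
        else:
            s2u, s2v = prior.sigma2_u, prior.sigma2_v
            val = (
                -0.5 * ((mu_u**2 + su**2).sum()) / s2u
                - mu_u.size * (_HALF_LOG_2PI + 0.5 * np.log(s2u))
                - 0.5 * ((mu_v**2 + sv**2).sum()) / s2v
                - mu_v.size * (_HALF_LOG_2PI + 0.5 * np.log(s2v))
                + (_HALF_LOG_2PIE + ls_u).sum()
                + (_HALF_LOG_2PIE + ls_v).sum()
            )
            g_mu_u = -mu_u / s2u
            g_mu_v = -mu_v / s2v
            g_ls_u = -(su**2) / s2u + 1.0
            g_ls_v = -(sv**2) / s2v + 1.0
        return float(val), g_mu_u, g_ls_u, g_mu_v, g_ls_v

    adam = _Adam([mu_u, ls_u, mu_v, ls_v], opts.learning_rate)
    stopper = _Convergence(opts.window, opts.rel_tol)
    trace: list[float] = []
    converged = False
    first = True
    n_mc = opts.mc_samples_train
    for it in range(opts.max_iter):
        su, sv = np.exp(ls_u), np.exp(ls_v)
        ll = 0.0
        g_mu_u_lik = np.zeros_like(mu_u)
        g_ls_u_lik = np.zeros_like(ls_u)
        g_mu_v_lik = np.zeros_like(mu_v)
        g_ls_v_lik = np.zeros_like(ls_v)
        for _ in range(n_mc):
            eps_u = rng.standard_normal(mu_u.shape)
            eps_v = rng.standard_normal(mu_v.shape)
            zu = mu_u + su * eps_u
            zv = mu_v + sv * eps_v
            if nonneg:
                U, V = np.exp(zu), np.exp(zv)
            else:
                U, V = zu, zv
            ll_s, gU, gV = model.loglik_and_grad(U, V)
            if nonneg:  # pathwise chain rule through u = exp(mu + sigma*eps)
                gU = gU * U
                gV = gV * V
            ll += ll_s / n_mc
            g_mu_u_lik += gU / n_mc
            g_ls_u_lik += gU * su * eps_u / n_mc
            g_mu_v_lik += gV / n_mc
            g_ls_v_lik += gV * sv * eps_v / n_mc
        pe, g_mu_u_pe, g_ls_u_pe, g_mu_v_pe, g_ls_v_pe = prior_and_entropy()
        obj = ll + pe
        if first and not np.isfinite(obj):
            raise FloatingPointError(
                "ELBO estimate non-finite at initialization; check inputs"
            )
        first = False
        trace.append(obj)
        adam.step(
            [
                g_mu_u_lik + g_mu_u_pe,
                g_ls_u_lik + g_ls_u_pe,
                g_mu_v_lik + g_mu_v_pe,
                g_ls_v_lik + g_ls_v_pe,
            ]
        )
        if stopper.check(trace, it):
            converged = True
            break

    qstate = VariationalState(family, mu_u, ls_u, mu_v, ls_v)
    final_elbo = elbo(
        model, qstate, prior, n_samples=opts.mc_samples_eval, seed=ELBO_EVAL_SEED
    )
    return PRRRResults(
        model=model,
        model_tag=model.model_tag,
        method="vi",
        rank=rank,
        point_estimate=qstate.point_estimate(),
        prior=prior,
        trace=np.array(trace),
        converged=converged,
        n_iter=len(trace),
        seed=opts.seed,
        variational=qstate,
        elbo=final_elbo,
    )


def select_rank(
    model,
    ranks: Sequence[int],
    restarts: int = 5,
    prior: PriorConfig | None = None,
    options: FitOptions | None = None,
) -> RankSelectionResult:
    """Fit VI across a rank grid and pick the rank with the best mean ELBO.

    Each rank is fit ``restarts`` times from seeds derived deterministically
    from the top-level seed (seed + restart index, shared across ranks so
    restarts are paired). Ties in the mean evaluated ELBO break toward the
    smaller rank. A failing restart is recorded as missing with a warning;
    a rank with no surviving restart raises.
    """
    ranks = list(ranks)
    if not ranks or any(r < 1 for r in ranks):
        raise ValueError("ranks must be a non-empty list of positive integers")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    prior = prior or model.default_prior()
    opts = options or FitOptions()

    rows = []
    fits: dict[tuple[int, int], PRRRResults] = {}
    for rank in ranks:
        elbos = []
        for i in range(restarts):
            try:
                res = fit_vi(model, rank, prior, replace(opts, seed=opts.seed + i))
            except (FloatingPointError, ValueError) as exc:
                warnings.warn(
                    f"restart {i} at rank {rank} failed ({exc}); recorded as missing",
                    stacklevel=2,
                )
                continue
            fits[(rank, i)] = res
            elbos.append(res.elbo)
        if not elbos:
            raise RuntimeError(f"all {restarts} restarts failed at rank {rank}")
        elbos = np.asarray(elbos, dtype=float)
        se = float(elbos.std(ddof=1) / np.sqrt(len(elbos))) if len(elbos) > 1 else 0.0
        rows.append(
            {
                "rank": rank,
                "mean_elbo": float(elbos.mean()),
                "se_elbo": se,
                "n_restarts": len(elbos),
            }
        )
    table = pd.DataFrame(rows)
    # argmax of mean ELBO; ties toward the smallest rank
    best = int(
        table.sort_values(["mean_elbo", "rank"], ascending=[False, True]).iloc[0]["rank"]
    )
    return RankSelectionResult(best_rank=best, table=table, fits=fits)
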