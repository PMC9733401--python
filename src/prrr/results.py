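"""Results containers returned by the fitting routines."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

from .containers import FactorPair, PriorConfig, SizeFactors

if TYPE_CHECKING:  # pragma: no cover
    from .inference import VariationalState


@dataclass
class PRRRResults:
    """Point estimates (or variational state), traces and fit metadata.

    ``point_estimate`` holds the MAP factors, or for variational fits the
    means of the variational factors mapped through the family (the mean of
    a LogNormal(mu, sigma^2) is exp(mu + sigma^2/2)). ``trace`` is the
    per-iteration objective: the log joint for MAP, a single-sample ELBO
    estimate for VI. ``elbo`` is the final evaluated ELBO (VI only),
    computed with a larger Monte-Carlo budget at a fixed evaluation seed so
    values are comparable across fits.
    """

    model: object
    model_tag: str
    method: str
    rank: int
    point_estimate: FactorPair
    prior: PriorConfig
    trace: np.ndarray
    converged: bool
    n_iter: int
    seed: int
    variational: Optional["VariationalState"] = None
    elbo: Optional[float] = None

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        if self.trace.size == 0:
            raise ValueError("trace must be non-empty")
        F = self.point_estimate
        if F.rank != self.rank:
            raise ValueError(f"point estimate rank {F.rank} != declared rank {self.rank}")
        if self.model_tag == "nnprrr" and (np.any(F.U <= 0) or np.any(F.V <= 0)):
            raise ValueError("nonnegative model produced non-positive point estimates")

    # -- coefficient access -------------------------------------------------
    @property
    def factors(self) -> FactorPair:
        return self.point_estimate

    @property
    def coefficients(self) -> np.ndarray:
        """Full P x Q coefficient matrix B = U V^T."""
        return self.point_estimate.coefficients()

    @property
    def coefficients_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coefficients,
            index=self.model.exog.covariate_ids,
            columns=self.model.endog.feature_ids,
        )

    @property
    def objective(self) -> float:
        """Final value of the optimization trace."""
        return float(self.trace[-1])

    # -- prediction ---------------------------------------------------------
    def predict(self, X_new=None, size_factors=None) -> np.ndarray:
        """Predicted Poisson rates for new covariate rows.

        For the identity-link model, new samples default to the mean
        training size factor (held-out totals are part of the outcome);
        pass ``size_factors`` to use observed totals instead.
        """
        from .model import nnprrr_rates, prrr_rates

        X = self.model.exog if X_new is None else X_new
        if self.model_tag == "prrr":
            return prrr_rates(X, self.point_estimate)
        if size_factors is None:
            if X_new is None:
                size_factors = self.model.size_factors
            else:
                n_new = X.shape[0] if hasattr(X, "shape") else np.asarray(X).shape[0]
                mean_s = float(np.mean(self.model.size_factors.s))
                size_factors = SizeFactors(np.full(n_new, mean_s))
        elif not isinstance(size_factors, SizeFactors):
            size_factors = SizeFactors(np.asarray(size_factors, dtype=float))
        return nnprrr_rates(X, self.point_estimate, size_factors)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of the fit."""
        m = self.model
        name = {"prrr": "Poisson RRR (log link)", "nnprrr": "Nonnegative Poisson RRR"}[
            self.model_tag
        ]
        lines = [
            f"{name}",
            "=" * 58,
            f"  samples:          {m.n_samples}",
            f"  covariates:       {m.n_covariates}",
            f"  genes:            {m.n_features}",
            f"  rank:             {self.rank}",
            f"  method:           {self.method.upper()}",
            f"  iterations:       {self.n_iter} ({'converged' if self.converged else 'max_iter reached'})",
            f"  final objective:  {self.objective:.4f}",
        ]
        if self.elbo is not None:
            lines.append(f"  evaluated ELBO:   {self.elbo:.4f}")
        B = self.coefficients
        flat = np.abs(B).ravel()
        top = np.argsort(flat)[::-1][:5]
        lines.append("  largest |coefficients| (covariate, gene, value):")
        for idx in top:
            i, j = divmod(int(idx), B.shape[1])
            lines.append(
                f"    {m.exog.covariate_ids[i]:<16} {m.endog.feature_ids[j]:<16} {B[i, j]:+.4f}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)


@dataclass
class RankSelectionResult:
    """Outcome of an ELBO-based sweep over candidate ranks.

    ``table`` has one row per rank: mean evaluated ELBO across restarts,
    its standard error, and the restart count. ``best_rank`` maximizes the
    mean ELBO, ties broken toward the smaller rank.
    """

    best_rank: int
    table: pd.DataFrame
    fits: dict = field(default_factory=dict, repr=False)

    def summary(self) -> str:
        lines = ["Rank selection by evaluated ELBO", "=" * 44]
        for _, row in self.table.iterrows():
            marker = " <- best" if int(row["rank"]) == self.best_rank else ""
            lines.append(
                f"  R={int(row['rank']):>3}  mean ELBO {row['mean_elbo']:>14.2f}"
                f"  (se {row['se_elbo']:.2f}, n={int(row['n_restarts'])}){marker}"
            )
        lines.append("=" * 44)
        return "\n".join(lines)
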