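"""Held-out prediction scoring and downstream coefficient analyses.

Covers the association-mapping workflow downstream of a fit: train/test
splitting, predicted-rate scoring with the goodness-of-fit R^2, the full
coefficient matrix B = U V^T, per-factor association tables u_r v_r^T, and
marker-gene extraction (the top-k genes per covariate by coefficient).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FactorPair

__all__ = [
    "SplitIndex",
    "split",
    "predict_rates",
    "goodness_of_fit_r2",
    "full_coefficients",
    "factor_association",
    "top_markers",
]


@dataclass
class SplitIndex:
    """Disjoint, exhaustive train/test row indices."""

    train_rows: np.ndarray
    test_rows: np.ndarray
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        self.train_rows = np.asarray(self.train_rows, dtype=int)
        self.test_rows = np.asarray(self.test_rows, dtype=int)
        if self.train_rows.size == 0 or self.test_rows.size == 0:
            raise ValueError("both sides of the split must be non-empty")
        if np.intersect1d(self.train_rows, self.test_rows).size:
            raise ValueError("train and test rows overlap")


def split(n: int, fraction: float = 0.8, seed: int = 0) -> SplitIndex:
    """Uniform random split: floor(fraction * n) training rows, rest test."""
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    n_train = int(np.floor(fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"fraction {fraction} with n={n} leaves an empty train or test side"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndex(
        train_rows=np.sort(perm[:n_train]),
        test_rows=np.sort(perm[n_train:]),
        fraction=fraction,
        seed=seed,
    )


def predict_rates(fit, X_new, size_factors=None) -> np.ndarray:
    """Predicted Poisson rates for new covariate rows (delegates to the fit)."""
    return fit.predict(X_new, size_factors=size_factors) if fit.model_tag == "nnprrr" else fit.predict(X_new)


def goodness_of_fit_r2(Y_obs, rates_pred) -> float:
    """R^2 = 1 - SSE/SST between observed counts and predicted rates.

    Computed jointly over all matrix entries against the grand mean of the
    observations; can be negative for predictors worse than the grand
    mean. Raises on constant observations (SST = 0).
    """
    y = np.asarray(Y_obs.values if hasattr(Y_obs, "values") else Y_obs, dtype=float).ravel()
    pred = np.asarray(
        rates_pred.values if hasattr(rates_pred, "values") else rates_pred, dtype=float
    ).ravel()
    if y.size != pred.size:
        raise ValueError(f"shape mismatch: {y.size} observations vs {pred.size} predictions")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("observed counts are constant; R^2 is undefined")
    sse = float(((y - pred) ** 2).sum())
    return 1.0 - sse / sst


def goodness_of_fit_r2_per_gene(Y_obs, rates_pred) -> np.ndarray:
    """Non-default per-gene variant: one R^2 per outcome column."""
    y = np.asarray(Y_obs.values if hasattr(Y_obs, "values") else Y_obs, dtype=float)
    pred = np.asarray(
        rates_pred.values if hasattr(rates_pred, "values") else rates_pred, dtype=float
    )
    if y.shape != pred.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {pred.shape}")
    sst = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    sse = ((y - pred) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sst > 0, 1.0 - sse / sst, np.nan)


def full_coefficients(F: FactorPair, covariate_ids=None, feature_ids=None) -> pd.DataFrame:
    """Labeled P x Q coefficient matrix B = U V^T."""
    B = F.coefficients()
    if covariate_ids is None:
        covariate_ids = [f"covariate{i}" for i in range(B.shape[0])]
    if feature_ids is None:
        feature_ids = [f"gene{j}" for j in range(B.shape[1])]
    return pd.DataFrame(B, index=list(covariate_ids), columns=list(feature_ids))


def factor_association(
    F: FactorPair,
    r: int,
    top_k: int = 10,
    covariate_ids=None,
    feature_ids=None,
) -> pd.DataFrame:
    """Strongest (covariate, gene) pairs in factor r's outer product u_r v_r^T.

    Rows are sorted by decreasing |coefficient|, ties broken by
    (covariate_id, gene_id) lexicographic order. ``r`` is zero-based.
    """
    if not 0 <= r < F.rank:
        raise ValueError(f"factor index {r} out of range for rank {F.rank}")
    outer = np.outer(F.U[:, r], F.V[:, r])
    if covariate_ids is None:
        covariate_ids = [f"covariate{i}" for i in range(outer.shape[0])]
    if feature_ids is None:
        feature_ids = [f"gene{j}" for j in range(outer.shape[1])]
    if np.all(outer == 0):
        warnings.warn(f"factor {r} is identically zero (dead factor)", stacklevel=2)
    rows = pd.DataFrame(
        {
            "covariate_id": np.repeat(list(covariate_ids), outer.shape[1]),
            "gene_id": list(feature_ids) * outer.shape[0],
            "factor": r,
            "coefficient": outer.ravel(),
        }
    )
    rows["abs"] = rows["coefficient"].abs()
    rows = rows.sort_values(
        ["abs", "covariate_id", "gene_id"], ascending=[False, True, True]
    ).drop(columns="abs")
    k = min(top_k, len(rows))
    return rows.head(k).reset_index(drop=True)


def top_markers(B: pd.DataFrame, covariate_id: str, k: int = 10) -> list[str]:
    """The k genes with the largest (signed) coefficient for a covariate.

    Descending by coefficient, ties broken lexicographically by gene id —
    the marker-gene rule for e.g. a cell-type indicator column. Use
    ``B.abs()`` upstream for an absolute-value ranking.
    """
    if covariate_id not in B.index:
        raise KeyError(
            f"unknown covariate {covariate_id!r}; available: {list(B.index)}"
        )
    row = B.loc[covariate_id]
    order = sorted(zip(-row.to_numpy(dtype=float), row.index.astype(str)))
    return [gene for _, gene in order[: min(k, len(order))]]
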