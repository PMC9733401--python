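"""Labeled data containers shared by the PRRR models.

The containers validate the structural invariants the models rely on
(nonnegative integer counts, conforming factor shapes, strictly positive
size factors) once, at construction, so the numerical code can assume
clean inputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CountMatrix",
    "CovariateMatrix",
    "FactorPair",
    "PriorConfig",
    "SizeFactors",
    "compute_size_factors",
]

ENCODINGS = ("raw", "one_hot", "genotype", "spatial")


def _as_labels(labels: Sequence[str] | None, n: int, prefix: str) -> list[str]:
    if labels is None:
        return [f"{prefix}{i}" for i in range(n)]
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(
            f"expected {n} {prefix!r} labels, received {len(labels)}"
        )
    return labels


@dataclass
class CountMatrix:
    """N x Q matrix of nonnegative integer outcomes (transcript counts).

    Rows are samples (cells, spots, donors); columns are genes.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    feature_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2 or vals.size == 0:
            raise ValueError(f"counts must be a non-empty 2-D array, got shape {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("counts contain non-finite entries")
        if np.any(vals < 0):
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(f"negative count at ({i}, {j})")
        if not np.all(vals == np.floor(vals)):
            i, j = np.argwhere(vals != np.floor(vals))[0]
            raise ValueError(f"non-integer count {vals[i, j]!r} at ({i}, {j})")
        self.values = vals.astype(np.int64)
        self.sample_ids = _as_labels(self.sample_ids, vals.shape[0], "sample")
        self.feature_ids = _as_labels(self.feature_ids, vals.shape[1], "gene")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class CovariateMatrix:
    """N x P real design matrix with an encoding tag.

    ``encoding`` records how the columns were produced: ``raw`` numeric
    columns, ``one_hot`` indicators (rows sum to 1), ``genotype`` minor
    allele counts in {0, 1, 2}, or ``spatial`` coordinates.
    """

    values: np.ndarray
    covariate_ids: list[str] = field(default=None)  # type: ignore[assignment]
    encoding: str = "raw"
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.size == 0:
            raise ValueError(f"covariates must be a non-empty 2-D array, got shape {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("covariates contain non-finite entries")
        if self.encoding not in ENCODINGS:
            raise ValueError(f"unknown encoding {self.encoding!r}; expected one of {ENCODINGS}")
        if self.encoding == "one_hot":
            row_sums = vals.sum(axis=1)
            if not (np.all(np.isin(vals, (0.0, 1.0))) and np.allclose(row_sums, 1.0)):
                raise ValueError("one_hot covariates must be binary with rows summing to 1")
        if self.encoding == "genotype" and not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"genotype covariates must lie in {{0,1,2}}; found {bad!r}")
        self.values = vals
        self.covariate_ids = _as_labels(self.covariate_ids, vals.shape[1], "covariate")
        self.sample_ids = _as_labels(self.sample_ids, vals.shape[0], "sample")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def is_nonnegative(self) -> bool:
        return bool(np.all(self.values >= 0))


@dataclass
class FactorPair:
    """Low-rank coefficient factors U (P x R) and V (Q x R).

    The regression coefficient matrix is B = U V^T. For the nonnegative
    model all factor entries must be strictly positive.
    """

    U: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        U = np.asarray(self.U, dtype=float)
        V = np.asarray(self.V, dtype=float)
        if U.ndim != 2 or V.ndim != 2:
            raise ValueError("U and V must be 2-D arrays")
        if U.shape[1] != V.shape[1]:
            raise ValueError(
                f"rank mismatch: U has {U.shape[1]} columns, V has {V.shape[1]}"
            )
        if U.shape[1] < 1:
            raise ValueError("rank must be at least 1")
        self.U, self.V = U, V

    @property
    def rank(self) -> int:
        return self.U.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.U.shape[0]

    @property
    def n_features(self) -> int:
        return self.V.shape[0]

    def coefficients(self) -> np.ndarray:
        """Full P x Q coefficient matrix B = U V^T."""
        return self.U @ self.V.T

    def require_positive(self) -> "FactorPair":
        if np.any(self.U <= 0) or np.any(self.V <= 0):
            raise ValueError("nonnegative model requires strictly positive factors")
        return self


@dataclass
class PriorConfig:
    """Prior on the factor entries.

    ``gaussian``: independent N(0, sigma2_u) / N(0, sigma2_v) entries on U / V
    (the log-link model). ``gamma``: independent Gamma(alpha, beta) entries
    (shape/rate; the nonnegative identity-link model). Defaults follow the
    model definitions: unit Gaussian variances, Gamma(2, 1).
    """

    family: str = "gaussian"
    sigma2_u: float = 1.0
    sigma2_v: float = 1.0
    alpha_u: float = 2.0
    beta_u: float = 1.0
    alpha_v: float = 2.0
    beta_v: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "gamma"):
            raise ValueError(f"unknown prior family {self.family!r}")
        for name in ("sigma2_u", "sigma2_v", "alpha_u", "beta_u", "alpha_v", "beta_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def for_model(cls, model: str, **kwargs) -> "PriorConfig":
        family = {"prrr": "gaussian", "nnprrr": "gamma"}.get(model)
        if family is None:
            raise ValueError(f"unknown model {model!r}")
        return cls(family=family, **kwargs)


@dataclass
class SizeFactors:
    """Per-sample positive scale factors (sequencing depth)."""

    s: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float).ravel()
        if s.size == 0:
            raise ValueError("size factors must be non-empty")
        if np.any(s <= 0) or not np.all(np.isfinite(s)):
            raise ValueError("size factors must be strictly positive and finite")
        self.s = s

    def __len__(self) -> int:
        return self.s.size


def compute_size_factors(Y: CountMatrix | np.ndarray) -> SizeFactors:
    """Total transcript count per sample, s_n = sum_q y_nq.

    Raises if any sample has zero total counts: a zero size factor makes the
    nonnegative model's Poisson rate identically zero for that sample, which
    is degenerate under any nonzero observation.
    """
    values = Y.values if isinstance(Y, CountMatrix) else np.asarray(Y)
    totals = values.sum(axis=1).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        if isinstance(Y, CountMatrix):
            name = Y.sample_ids[zero[0]]
        else:
            name = str(zero[0])
        raise ValueError(
            f"sample {name!r} (row {zero[0]}) has zero total counts; "
            "size factors must be positive"
        )
    return SizeFactors(totals)
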