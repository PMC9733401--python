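"""Synthetic data generators.

Draws datasets from the PRRR / nn-PRRR generative models under covariate
schemes emulating the three application regimes the models target:
genotype minor-allele counts in {0, 1, 2}, one-hot cell-type indicators,
and 2-D spatial coordinates, plus plain Gaussian covariates for generic
simulations and a grouped-count scheme (one-hot groups with group-specific
mean shifts) standing in for a single-cell count simulator.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import CountMatrix, CovariateMatrix, FactorPair

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "simulate_genotypes",
    "encode_one_hot",
    "simulate_dataset",
]

COVARIATE_SCHEMES = ("gaussian", "genotype", "one_hot", "spatial")
MODELS = ("prrr", "nnprrr", "grouped")


@dataclass
class SimulationSpec:
    """Settings for one synthetic dataset.

    ``factor_scale`` scales the factor draws (normal entries for the
    log-link model, Gamma(2, 1) entries for the nonnegative one); the 0.5
    default keeps simulated counts in a realistic single-cell range
    (median below ~50). ``maf`` is the minor-allele frequency of the
    genotype scheme; ``n_groups`` drives the one-hot and grouped schemes.
    """

    n_samples: int = 200
    n_covariates: int = 10
    n_genes: int = 50
    true_rank: int = 3
    covariate_scheme: str = "gaussian"
    model: str = "prrr"
    factor_scale: float = 0.5
    maf: float = 0.3
    n_groups: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.covariate_scheme not in COVARIATE_SCHEMES:
            raise ValueError(f"unknown covariate scheme {self.covariate_scheme!r}")
        if not 0 < self.maf < 1:
            raise ValueError("maf must lie in (0, 1)")
        if self.true_rank > min(self.n_covariates, self.n_genes):
            raise ValueError(
                f"true_rank {self.true_rank} exceeds min(P, Q) = "
                f"{min(self.n_covariates, self.n_genes)}"
            )
        if self.factor_scale < 0:
            raise ValueError("factor_scale must be nonnegative")


@dataclass
class SimulatedDataset:
    """A draw from the generative model plus its ground truth."""

    X: CovariateMatrix
    Y: CountMatrix
    true_factors: FactorPair
    true_B: np.ndarray
    spec: SimulationSpec
    size_factors: np.ndarray | None = None
    group_labels: list | None = field(default=None, repr=False)


def simulate_genotypes(n: int, p: int, maf: float = 0.3, seed: int = 0) -> CovariateMatrix:
    """Minor-allele count matrix with entries i.i.d. Binomial(2, maf)."""
    if not 0 < maf < 1:
        raise ValueError("maf must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    values = rng.binomial(2, maf, size=(n, p)).astype(float)
    return CovariateMatrix(
        values,
        covariate_ids=[f"snp{j}" for j in range(p)],
        encoding="genotype",
    )


def encode_one_hot(labels: Sequence) -> CovariateMatrix:
    """One indicator column per distinct label, ordered by first appearance.

    No reference level is dropped: rows are full one-hot vectors, matching
    a cell-type design where each cell carries exactly one indicator.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("label list is empty")
    order: dict = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    values = np.zeros((len(labels), len(order)))
    for i, lab in enumerate(labels):
        values[i, order[lab]] = 1.0
    return CovariateMatrix(
        values,
        covariate_ids=[str(lab) for lab in order],
        encoding="one_hot",
    )


def _draw_covariates(spec: SimulationSpec, rng: np.random.Generator):
    n, p = spec.n_samples, spec.n_covariates
    labels = None
    if spec.covariate_scheme == "gaussian":
        X = CovariateMatrix(rng.standard_normal((n, p)))
    elif spec.covariate_scheme == "genotype":
        X = simulate_genotypes(n, p, spec.maf, seed=int(rng.integers(2**31 - 1)))
    elif spec.covariate_scheme == "one_hot":
        groups = [f"group{g}" for g in range(spec.n_groups)]
        labels = [groups[i % spec.n_groups] for i in range(n)]
        rng.shuffle(labels)
        X = encode_one_hot(labels)
    else:  # spatial: uniform 2-D coordinates
        X = CovariateMatrix(
            rng.uniform(0.0, 1.0, size=(n, 2)),
            covariate_ids=["x", "y"],
            encoding="spatial",
        )
    return X, labels


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Draw (X, U*, V*, Y) from the requested generative model.

    * ``prrr``: U*, V* have N(0, factor_scale^2) entries and
      Y ~ Poisson(exp(X U* V*^T)) entrywise.
    * ``nnprrr``: U*, V* have factor_scale * Gamma(2, 1) entries, size
      factors are drawn uniformly in [500, 2000] and then treated as fixed,
      and Y ~ Poisson(s_n * x_n U* V*^T). Requires a nonnegative scheme.
    * ``grouped``: balanced one-hot group labels with a group-specific
      log-rate vector (a rank-``true_rank`` log-link draw over group
      indicators), emulating grouped single-cell counts.

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    eff = spec
    if spec.model == "grouped":
        # grouped counts = log-link model over one-hot group indicators
        from dataclasses import replace

        eff = replace(
            spec,
            covariate_scheme="one_hot",
            n_covariates=spec.n_groups,
            model="prrr",
        )
    X, labels = _draw_covariates(eff, rng)
    p = X.n_covariates
    q = eff.n_genes
    r = eff.true_rank

    if eff.model == "prrr":
        U = rng.normal(0.0, 1.0, size=(p, r)) * eff.factor_scale
        V = rng.normal(0.0, 1.0, size=(q, r)) * eff.factor_scale
        F = FactorPair(U, V)
        eta = (X.values @ U) @ V.T
        if np.any(eta > 30):
            raise FloatingPointError(
                "simulated linear predictor exceeds 30 (rate overflow); "
                "use a smaller factor_scale"
            )
        rates = np.exp(eta)
        Y = rng.poisson(rates)
        s = None
    else:
        if not X.is_nonnegative():
            raise ValueError("nonnegative model requires a nonnegative covariate scheme")
        U = rng.gamma(2.0, 1.0, size=(p, r)) * eff.factor_scale
        V = rng.gamma(2.0, 1.0, size=(q, r)) * eff.factor_scale
        F = FactorPair(U, V)
        s = rng.uniform(500.0, 2000.0, size=eff.n_samples)
        rates = s[:, None] * ((X.values @ U) @ V.T)
        Y = rng.poisson(rates)

    # guard against an all-zero sample, which has no defined size factor
    zero_rows = np.flatnonzero(Y.sum(axis=1) == 0)
    if zero_rows.size:
        for i in zero_rows:
            Y[i, rng.integers(Y.shape[1])] = 1
    counts = CountMatrix(
        Y,
        sample_ids=X.sample_ids,
        feature_ids=[f"gene{j}" for j in range(q)],
    )
    return SimulatedDataset(
        X=X,
        Y=counts,
        true_factors=F,
        true_B=F.coefficients(),
        spec=spec,
        size_factors=s,
        group_labels=labels,
    )
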