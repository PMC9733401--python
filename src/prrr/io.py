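"""File I/O: dense CSV/TSV and sparse MatrixMarket matrices, run configs.

Counts and covariates travel as labeled CSV/TSV (first column = sample
ids, header = feature/covariate ids) or as MTX with ``samples.txt`` /
``genes.txt`` label files alongside. Fitted factors are persisted as
labeled CSVs so spreadsheet and R users can consume them directly.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CountMatrix, CovariateMatrix, FactorPair
from .simulate import encode_one_hot

__all__ = [
    "read_counts",
    "read_covariates",
    "write_counts",
    "write_covariates",
    "write_factors",
    "read_factors",
    "RunConfig",
    "write_manifest",
]

_SEPS = {"csv": ",", "tsv": "\t"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "tsv", "mtx"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def _read_dense(path: Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no data columns found (malformed header?)")
    return df


def _read_mtx(path: Path, orientation: str | None) -> tuple[np.ndarray, list[str], list[str]]:
    mat = scipy.io.mmread(path)
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    samples_path = path.parent / "samples.txt"
    genes_path = path.parent / "genes.txt"
    if not samples_path.exists() or not genes_path.exists():
        raise FileNotFoundError(
            f"MTX input {path} requires samples.txt and genes.txt alongside it"
        )
    samples = samples_path.read_text().split()
    genes = genes_path.read_text().split()
    n_rows, n_cols = dense.shape
    if orientation is None:
        if n_rows == n_cols:
            raise ValueError(
                f"{path}: square matrix; pass orientation='samples' or 'genes' "
                "to disambiguate which axis is rows"
            )
        if n_rows == len(samples) and n_cols == len(genes):
            orientation = "samples"
        elif n_rows == len(genes) and n_cols == len(samples):
            orientation = "genes"
        else:
            raise ValueError(
                f"{path}: matrix is {n_rows}x{n_cols} but samples.txt has "
                f"{len(samples)} labels and genes.txt has {len(genes)}"
            )
    if orientation == "genes":  # 10x convention: genes on rows
        dense = dense.T
    if dense.shape != (len(samples), len(genes)):
        raise ValueError(
            f"{path}: label counts ({len(samples)} samples, {len(genes)} genes) "
            f"do not match matrix shape {dense.shape}"
        )
    return dense, samples, genes


def read_counts(path, fmt: str | None = None, orientation: str | None = None) -> CountMatrix:
    """Read a count matrix from CSV/TSV (samples x genes) or MTX.

    Fractional or negative entries are rejected with their coordinates.
    MTX files are read with label sidecars ``samples.txt`` / ``genes.txt``;
    orientation is auto-detected from the label counts (genes-as-rows is
    the common sparse convention) and must be given explicitly for square
    matrices.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        dense, samples, genes = _read_mtx(path, orientation)
        return CountMatrix(dense, sample_ids=samples, feature_ids=genes)
    df = _read_dense(path, _SEPS[fmt])
    vals = df.to_numpy()
    try:
        vals = vals.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric count entry ({exc})") from exc
    bad = np.argwhere((vals < 0) | (vals != np.floor(vals)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: entry {vals[i, j]!r} at row {df.index[i]!r}, column "
            f"{df.columns[j]!r} (cell ({i}, {j})) is not a nonnegative integer"
        )
    return CountMatrix(
        vals,
        sample_ids=list(df.index.astype(str)),
        feature_ids=list(df.columns.astype(str)),
    )


def read_covariates(path, fmt: str | None = None, encoding: str = "raw") -> CovariateMatrix:
    """Read covariates from CSV/TSV with an encoding directive.

    ``encoding="one_hot"`` expects a single categorical column and expands
    it through the one-hot encoder; ``"genotype"`` validates entries lie in
    {0, 1, 2}; ``"raw"`` and ``"spatial"`` read numeric columns as-is.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        raise ValueError("covariates must be dense CSV/TSV")
    df = _read_dense(path, _SEPS[fmt])
    if encoding == "one_hot":
        if df.shape[1] != 1:
            raise ValueError(
                f"{path}: one_hot encoding expects a single categorical column, "
                f"found {df.shape[1]}"
            )
        X = encode_one_hot(df.iloc[:, 0].astype(str).tolist())
        X.sample_ids = list(df.index.astype(str))
        return X
    vals = df.to_numpy(dtype=float)
    return CovariateMatrix(
        vals,
        covariate_ids=list(df.columns.astype(str)),
        sample_ids=list(df.index.astype(str)),
        encoding=encoding,
    )


def write_counts(Y: CountMatrix, path, fmt: str | None = None) -> None:
    """Write counts as labeled CSV/TSV or sparse MTX + label sidecars."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(Y.values))
        (path.parent / "samples.txt").write_text("\n".join(Y.sample_ids) + "\n")
        (path.parent / "genes.txt").write_text("\n".join(Y.feature_ids) + "\n")
        return
    pd.DataFrame(Y.values, index=Y.sample_ids, columns=Y.feature_ids).to_csv(
        path, sep=_SEPS[fmt]
    )


def write_covariates(X: CovariateMatrix, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    pd.DataFrame(X.values, index=X.sample_ids, columns=X.covariate_ids).to_csv(
        path, sep=_SEPS[fmt]
    )


def write_factors(F: FactorPair, outdir, covariate_ids=None, feature_ids=None) -> None:
    """Persist U and V as labeled CSVs (U.csv, V.csv) in ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = [f"factor{r}" for r in range(F.rank)]
    if covariate_ids is None:
        covariate_ids = [f"covariate{i}" for i in range(F.U.shape[0])]
    if feature_ids is None:
        feature_ids = [f"gene{j}" for j in range(F.V.shape[0])]
    pd.DataFrame(F.U, index=covariate_ids, columns=cols).to_csv(outdir / "U.csv")
    pd.DataFrame(F.V, index=feature_ids, columns=cols).to_csv(outdir / "V.csv")


def read_factors(outdir) -> FactorPair:
    outdir = Path(outdir)
    U = pd.read_csv(outdir / "U.csv", index_col=0).to_numpy(dtype=float)
    V = pd.read_csv(outdir / "V.csv", index_col=0).to_numpy(dtype=float)
    return FactorPair(U, V)


_RUNCONFIG_KEYS = None  # populated below


@dataclass
class RunConfig:
    """One fitting run: model, rank(s), prior and optimizer settings, paths."""

    model: str = "prrr"
    mode: str = "map"
    rank: int = 3
    ranks: list[int] | None = None
    restarts: int = 5
    encoding: str = "raw"
    sigma2_u: float = 1.0
    sigma2_v: float = 1.0
    alpha: float = 2.0
    beta: float = 1.0
    learning_rate: float = 0.01
    max_iter: int = 3000
    seed: int = 0
    counts_path: str | None = None
    covariates_path: str | None = None
    outdir: str = "prrr_out"
    extra: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        known = set(cls.__dataclass_fields__) - {"extra"}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_json(self, path) -> None:
        d = asdict(self)
        d.pop("extra")
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(outdir, config: RunConfig, inputs: list[str]) -> None:
    """Record config, seed, package version and input checksums for re-runs."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "extra"},
        "input_checksums": {str(p): _checksum(p) for p in inputs if p and Path(p).exists()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
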