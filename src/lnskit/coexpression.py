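"""Per-dataset and aggregated connection matrices.

A species' co-expression network is represented as a *connection matrix*:
all-pairs Pearson correlations of gene expression vectors, variance-
stabilised by the Fisher z-transform ``z = arctanh(rho)`` and standardised so
the off-diagonal entries are ~N(0, 1).  The standardisation makes correlation
structure comparable across datasets whose raw correlation distributions
differ widely.  A global network is the entrywise average of per-dataset
connection matrices, re-standardised (the mean of D independent standard
normals has standard deviation 1/sqrt(D), so a final rescale restores unit
variance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DataError, ExpressionDataset

logger = logging.getLogger(__name__)

DEFAULT_CLIP = 1.0 - 1e-6


@dataclass
class CorrelationMatrix:
    """Symmetric all-pairs Pearson correlation matrix for one dataset."""

    gene_ids: list[str]
    rho: np.ndarray
    zero_variance_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.rho.shape != (n, n):
            raise ValueError("correlation matrix shape does not match gene list")


@dataclass
class ConnectionMatrix:
    """Standardised, Fisher-transformed co-expression weights for one species.

    ``z`` is symmetric with NaN on the diagonal (self-connections are
    excluded from every downstream vector).  ``provenance`` records whether
    the matrix came from a single dataset or is an aggregate, ``n_datasets``
    how many datasets contributed.
    """

    gene_ids: list[str]
    z: np.ndarray
    provenance: str = "single-dataset"
    n_datasets: int = 1

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.z.shape != (n, n):
            raise ValueError("connection matrix shape does not match gene list")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def offdiag_values(self) -> np.ndarray:
        """Finite upper-triangle off-diagonal entries (each pair once)."""
        iu = np.triu_indices(self.n_genes, k=1)
        vals = self.z[iu]
        return vals[np.isfinite(vals)]

    def restrict(self, gene_ids: list[str]) -> np.ndarray:
        """Submatrix aligned to ``gene_ids`` (all must be present)."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in gene_ids], dtype=int)
        return self.z[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.gene_ids, columns=self.gene_ids)

    def to_tsv(self, path) -> None:
        with open(str(path), "w") as fh:
            fh.write(
                f'# {{"provenance": "{self.provenance}", '
                f'"n_datasets": {self.n_datasets}}}\n'
            )
            self.to_frame().to_csv(fh, sep="\t", na_rep="NA")


def read_connection_tsv(path) -> ConnectionMatrix:
    """Read a connection matrix written by :meth:`ConnectionMatrix.to_tsv`."""
    import json

    provenance, n_datasets = "single-dataset", 1
    with open(str(path)) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = json.loads(first.lstrip("# ").strip())
            provenance = meta.get("provenance", provenance)
            n_datasets = int(meta.get("n_datasets", n_datasets))
        df = pd.read_csv(fh, sep="\t", index_col=0, na_values=["NA"])
    z = df.to_numpy(dtype=float)
    if not df.index.equals(df.columns):
        raise DataError(f"{path}: row and column gene ids differ")
    return ConnectionMatrix([str(g) for g in df.index], z, provenance, n_datasets)


def pearson_matrix(ds: ExpressionDataset) -> CorrelationMatrix:
    """All-pairs Pearson correlation of gene expression vectors.

    Requires a complete dataset with at least 3 arrays.  Genes with zero
    variance get correlation 0 to every other gene (flagged and logged)
    rather than being dropped, keeping matrices aligned across datasets.
    """
    if not ds.is_complete():
        raise DataError(f"dataset {ds.dataset_id!r} has missing values; impute first")
    if ds.n_arrays < 3:
        raise DataError(f"dataset {ds.dataset_id!r} has fewer than 3 arrays")
    X = ds.values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    flat = sd == 0
    zero_var = [g for g, f in zip(ds.gene_ids, flat) if f]
    if zero_var:
        logger.warning(
            "pearson_matrix: %d zero-variance gene(s) in %r set to rho=0",
            len(zero_var), ds.dataset_id,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(X)
    rho[flat, :] = 0.0
    rho[:, flat] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    return CorrelationMatrix(list(ds.gene_ids), rho, zero_var)


def fisher_z(c: CorrelationMatrix | np.ndarray, clip: float = DEFAULT_CLIP) -> np.ndarray:
    """Fisher z-transform ``z = 0.5 ln((1+rho)/(1-rho)) = arctanh(rho)``.

    Correlations are clipped to ``[-clip, clip]`` first so that exact +/-1
    (self-correlations, duplicated genes) do not map to infinity.
    """
    rho = c.rho if isinstance(c, CorrelationMatrix) else np.asarray(c, dtype=float)
    return np.arctanh(np.clip(rho, -clip, clip))


def standardize(zmat: np.ndarray, gene_ids: list[str],
                provenance: str = "single-dataset",
                n_datasets: int = 1) -> ConnectionMatrix:
    """Shift/scale a symmetric z-matrix so off-diagonals are mean 0, sd 1.

    Statistics are computed on the finite upper-triangle off-diagonal entries
    only (each unordered pair counted once); the diagonal is set to NaN and
    excluded from all downstream vectors.
    """
    z = np.array(zmat, dtype=float)
    if z.shape[0] != z.shape[1]:
        raise ValueError("z-matrix must be square")
    iu = np.triu_indices(z.shape[0], k=1)
    vals = z[iu]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise DataError("too few gene pairs to standardize")
    mu = vals.mean()
    sd = vals.std()
    if sd == 0:
        raise DataError("degenerate correlation structure: zero variance of z values")
    out = (z - mu) / sd
    np.fill_diagonal(out, np.nan)
    return ConnectionMatrix(list(gene_ids), out, provenance, n_datasets)


def connection_matrix(ds: ExpressionDataset, clip: float = DEFAULT_CLIP) -> ConnectionMatrix:
    """Pearson -> Fisher z -> standardise, for one preprocessed dataset."""
    corr = pearson_matrix(ds)
    return standardize(fisher_z(corr, clip), corr.gene_ids,
                       provenance=f"single-dataset:{ds.dataset_id}")


def aggregate_connection(mats: list[ConnectionMatrix]) -> ConnectionMatrix:
    """Average per-dataset connection matrices into a global network.

    Matrices are aligned on the union of their gene universes; a gene pair's
    average runs over the datasets in which both genes are present (datasets
    missing either gene contribute no term).  The entrywise mean is then
    re-standardised to off-diagonal mean 0, sd 1.  Pairs observed in no
    dataset remain missing and are flagged downstream.
    """
    if not mats:
        raise DataError("aggregate_connection: empty matrix list")
    if len(mats) == 1:
        m = mats[0]
        return ConnectionMatrix(list(m.gene_ids), m.z.copy(),
                                provenance="aggregated-over-1-datasets", n_datasets=1)
    universe: list[str] = []
    seen: set[str] = set()
    for m in mats:
        for g in m.gene_ids:
            if g not in seen:
                seen.add(g)
                universe.append(g)
    shared = set(mats[0].gene_ids)
    for m in mats[1:]:
        shared &= set(m.gene_ids)
    if not shared:
        raise DataError("aggregate_connection: empty gene universe intersection")
    n = len(universe)
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    pos = {g: i for i, g in enumerate(universe)}
    for m in mats:
        idx = np.array([pos[g] for g in m.gene_ids], dtype=int)
        z = m.z
        fin = np.isfinite(z)
        block = np.where(fin, z, 0.0)
        total[np.ix_(idx, idx)] += block
        count[np.ix_(idx, idx)] += fin
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return standardize(mean, universe,
                       provenance=f"aggregated-over-{len(mats)}-datasets",
                       n_datasets=len(mats))


def build_global_network(datasets: list[ExpressionDataset],
                         clip: float = DEFAULT_CLIP) -> ConnectionMatrix:
    """Per-dataset connection matrices for a compendium, then aggregate."""
    return aggregate_connection([connection_matrix(ds, clip) for ds in datasets])
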