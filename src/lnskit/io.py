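"""Reading, validation and preprocessing of expression matrices and ortholog maps.

Expression data are log-ratio (two-channel microarray style) gene x array
tables.  Two tab-delimited dialects are supported:

* ``tsv`` — first column gene IDs, remaining columns arrays.
* ``pcl`` — the yeast-repository PCL dialect: leading ``YORF``/``NAME``/
  ``GWEIGHT`` columns (NAME and GWEIGHT are parsed and dropped) and an
  optional ``EWEIGHT`` row (ignored).

Preprocessing follows the standard compendium recipe: genes present in less
than ``min_fraction`` of a dataset's arrays are removed, remaining missing
values are estimated by K-nearest-neighbour imputation (Euclidean distance,
K = 10 by default), and biological replicates are averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

logger = logging.getLogger(__name__)

#: tokens accepted as a missing cell (compared case-insensitively)
MISSING_TOKENS = frozenset({"", "na", "nan", "null"})


class DataError(ValueError):
    """Raised when an input file or dataset violates a structural invariant."""


@dataclass
class ExpressionDataset:
    """One experiment's gene x array expression matrix.

    Parameters
    ----------
    dataset_id
        Identifier of the experiment (used as context label downstream).
    values
        genes x arrays float DataFrame; ``NaN`` marks a missing measurement.
    replicate_groups
        Optional mapping ``array_id -> group_id``; arrays not listed are
        treated as singleton groups.
    """

    dataset_id: str
    values: pd.DataFrame
    replicate_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise DataError(f"duplicate gene ID {dup!r} in dataset {self.dataset_id!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise DataError(f"duplicate array ID {dup!r} in dataset {self.dataset_id!r}")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def is_complete(self) -> bool:
        return self.n_missing == 0

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "GENE"
        out.to_csv(path, sep="\t", na_rep="NA")


@dataclass
class OrthologMap:
    """Validated one-to-one ortholog mapping between two species.

    ``pairs`` is an ordered list of ``(gene_a, gene_b)``; ``N`` is the number
    of matched ortholog pairs.  Strict one-to-one: no gene appears twice on
    either side.
    """

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise DataError("no ortholog pairs")
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        for side, name in ((a_side, "A"), (b_side, "B")):
            seen: set[str] = set()
            for g in side:
                if g in seen:
                    raise DataError(
                        f"gene {g!r} appears more than once on species-{name} side"
                    )
                seen.add(g)

    @property
    def N(self) -> int:
        return len(self.pairs)

    @property
    def a_ids(self) -> list[str]:
        return [a for a, _ in self.pairs]

    @property
    def b_ids(self) -> list[str]:
        return [b for _, b in self.pairs]

    @classmethod
    def identity(cls, gene_ids) -> "OrthologMap":
        """Self-map used for within-species comparisons."""
        return cls([(g, g) for g in gene_ids])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.pairs, columns=["gene_a", "gene_b"]).to_csv(
            path, sep="\t", index=False
        )


def _parse_cell(token: str) -> float:
    if token.strip().lower() in MISSING_TOKENS:
        return np.nan
    return float(token)


def read_expression_matrix(path, dialect: str = "tsv",
                           dataset_id: str | None = None) -> ExpressionDataset:
    """Read a tab-delimited expression matrix.

    ``dialect='pcl'`` expects ``YORF``/``NAME``/``GWEIGHT`` leading columns
    (NAME and GWEIGHT dropped) and skips an ``EWEIGHT`` row if present.
    Empty fields, ``NA`` and ``nan`` are flagged missing.  Duplicate gene IDs
    and ragged rows are hard errors.
    """
    if dialect not in ("tsv", "pcl"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = str(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise DataError(f"{path}: empty file")
    header = lines[0].split("\t")
    n_meta = 3 if dialect == "pcl" else 1
    if len(header) <= n_meta:
        raise DataError(f"{path}: no array columns found")
    array_ids = header[n_meta:]
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if dialect == "pcl" and fields[0].strip().upper() == "EWEIGHT":
            continue
        if len(fields) != len(header):
            raise DataError(
                f"{path}: ragged row at line {lineno} "
                f"({len(fields)} fields, expected {len(header)})"
            )
        gene_ids.append(fields[0])
        try:
            rows.append([_parse_cell(t) for t in fields[n_meta:]])
        except ValueError as exc:
            raise DataError(f"{path}: line {lineno}: {exc}") from exc
    seen: set[str] = set()
    for g in gene_ids:
        if g in seen:
            raise DataError(f"{path}: duplicate gene ID {g!r}")
        seen.add(g)
    values = pd.DataFrame(rows, index=gene_ids, columns=array_ids, dtype=float)
    if dataset_id is None:
        import os

        dataset_id = os.path.splitext(os.path.basename(path))[0]
    return ExpressionDataset(dataset_id=dataset_id, values=values)


def filter_low_coverage_genes(ds: ExpressionDataset,
                              min_fraction: float = 0.5) -> ExpressionDataset:
    """Remove genes observed in less than ``min_fraction`` of arrays.

    The threshold is inclusive on the kept side: a gene present in exactly
    ``min_fraction`` of the arrays is retained (removal applies to genes
    represented in *less than* the cutoff).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    frac = ds.values.notna().mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        raise DataError(f"no genes survive filter in dataset {ds.dataset_id!r}")
    return replace(ds, values=ds.values.loc[keep])


def knn_impute(ds: ExpressionDataset, k: int = 10) -> ExpressionDataset:
    """Estimate missing values from the k nearest genes (Euclidean distance).

    Distances between gene rows are computed on mutually observed arrays and
    scaled by ``sqrt(n_arrays / n_shared)`` so that sparsely co-observed genes
    are not spuriously near.  A missing cell (gene g, array a) becomes the
    unweighted mean of the values at ``a`` of the k genes nearest to ``g``
    among genes observed at ``a`` (all eligible neighbours if fewer than k).
    If no neighbour is observed at ``a`` the gene's own row mean is used, then
    the column mean; each fallback is logged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if ds.is_complete():
        return ds
    X = ds.values.to_numpy(dtype=float, copy=True)
    observed = np.isfinite(X)
    with np.errstate(invalid="ignore"):
        dist = nan_euclidean_distances(X, X)
    np.fill_diagonal(dist, np.inf)
    dist[~np.isfinite(dist)] = np.inf
    row_means = np.nanmean(np.where(observed, X, np.nan), axis=1)
    col_means = np.nanmean(np.where(observed, X, np.nan), axis=0)
    out = X.copy()
    n_fallback = 0
    for g, a in zip(*np.nonzero(~observed)):
        eligible = observed[:, a] & np.isfinite(dist[g])
        idx = np.nonzero(eligible)[0]
        if idx.size:
            nearest = idx[np.argsort(dist[g, idx], kind="stable")[:k]]
            out[g, a] = X[nearest, a].mean()
        elif np.isfinite(row_means[g]):
            out[g, a] = row_means[g]
            n_fallback += 1
        elif np.isfinite(col_means[a]):
            out[g, a] = col_means[a]
            n_fallback += 1
        else:
            raise DataError(
                f"cannot impute gene {ds.gene_ids[g]!r} at array "
                f"{ds.array_ids[a]!r}: no observed values in row or column"
            )
    if n_fallback:
        logger.warning(
            "knn_impute: %d cell(s) in dataset %r imputed by row/column-mean fallback",
            n_fallback, ds.dataset_id,
        )
    values = pd.DataFrame(out, index=ds.values.index, columns=ds.values.columns)
    return replace(ds, values=values)


def average_replicates(ds: ExpressionDataset,
                       groups: dict[str, str] | None = None) -> ExpressionDataset:
    """Average biological replicates (arithmetic mean per replicate group).

    ``groups`` maps array_id -> group_id; arrays not listed form singleton
    groups under their own name.  Output columns follow the order of first
    appearance of each group.
    """
    if groups is None:
        groups = ds.replicate_groups or {}
    unknown = set(groups) - set(ds.array_ids)
    if unknown:
        raise DataError(f"replicate map references unknown array(s): {sorted(unknown)}")
    order: list[str] = []
    members: dict[str, list[str]] = {}
    for a in ds.array_ids:
        gid = groups.get(a, a)
        if gid not in members:
            members[gid] = []
            order.append(gid)
        members[gid].append(a)
    cols = {gid: ds.values[members[gid]].mean(axis=1) for gid in order}
    values = pd.DataFrame(cols, index=ds.values.index)[order]
    return replace(ds, values=values, replicate_groups=None)


def preprocess(ds: ExpressionDataset, min_fraction: float = 0.5, k: int = 10,
               groups: dict[str, str] | None = None) -> ExpressionDataset:
    """Full chain: coverage filter -> KNN imputation -> replicate averaging."""
    out = filter_low_coverage_genes(ds, min_fraction)
    out = knn_impute(out, k)
    out = average_replicates(out, groups)
    assert out.is_complete(), "preprocessing must leave no missing values"
    return out


def read_replicate_map(path) -> dict[str, str]:
    """Read a two-column (array_id, group_id) TSV sidecar."""
    mapping: dict[str, str] = {}
    with open(str(path)) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip() or ln.startswith("#"):
                continue
            fields = ln.split("\t")
            if len(fields) != 2:
                raise DataError(f"{path}: line {lineno}: expected 2 columns")
            mapping[fields[0]] = fields[1]
    return mapping


_HEADER_HINTS = ("gene", "orf", "id", "ortholog")


def read_ortholog_map(path) -> OrthologMap:
    """Read a two-column TSV of one-to-one ortholog pairs.

    A header row is optional; the first line is treated as a header when both
    fields look like column labels (contain ``gene``, ``orf``, ``id`` or
    ``ortholog``, case-insensitively).  Duplicate genes on either side are a
    hard error: only strictly one-to-one orthologs are supported.
    """
    rows: list[tuple[str, str]] = []
    with open(str(path)) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip() or ln.startswith("#"):
                continue
            fields = ln.split("\t")
            if len(fields) != 2:
                raise DataError(f"{path}: line {lineno}: expected 2 columns")
            rows.append((fields[0].strip(), fields[1].strip()))
    if rows and all(any(h in f.lower() for h in _HEADER_HINTS) for f in rows[0]):
        rows = rows[1:]
    if not rows:
        raise DataError(f"{path}: no ortholog pairs")
    return OrthologMap(rows)
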