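"""Local network similarity (LNS) between two species' co-expression networks.

For each one-to-one ortholog pair (j, j'), the *connection vector* of gene j
collects its standardised co-expression weights to every other matched
ortholog.  LNS is the Pearson correlation between the two species' connection
vectors, aligned by orthology and with the pair's own entries excluded; it
lies in [-1, 1] and measures how well the gene's first-degree co-expression
neighbourhood is preserved.

The null model for zero conservation shuffles the ortholog assignment along
one species' axis, leaving both networks' structure intact; the resulting
LNS distribution is approximately normal and centred at 0, which makes
"diverged" calls (LNS below the null mean) and distribution-level tests
straightforward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import ConnectionMatrix, aggregate_connection, connection_matrix
from .io import DataError, ExpressionDataset, OrthologMap

logger = logging.getLogger(__name__)

DEFAULT_SEED = 17

#: flag values used in LNS tables
FLAG_OK = "ok"
FLAG_CONSTANT = "constant_vector"
FLAG_MISSING = "missing_gene"
FLAG_INSUFFICIENT = "insufficient_overlap"


@dataclass
class NullDistribution:
    """Pooled LNS samples under randomized ortholog matching."""

    samples: np.ndarray
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def sd(self) -> float:
        return float(self.samples.std())

    def summary(self) -> pd.DataFrame:
        qs = np.quantile(self.samples, [0.025, 0.25, 0.5, 0.75, 0.975])
        return pd.DataFrame(
            {
                "n": [self.samples.size],
                "n_permutations": [self.n_permutations],
                "mean": [self.mean],
                "sd": [self.sd],
                "q025": qs[0], "q25": qs[1], "median": qs[2],
                "q75": qs[3], "q975": qs[4],
            }
        )


def lns_pair(wA: np.ndarray, wB: np.ndarray) -> float:
    """Pearson correlation of two aligned connection vectors.

    Positions missing in either vector are dropped (pairwise-complete).
    Returns NaN when fewer than 3 aligned positions remain or either vector
    is constant.
    """
    a = np.asarray(wA, dtype=float)
    b = np.asarray(wB, dtype=float)
    if a.shape != b.shape:
        raise ValueError("connection vectors must have equal length")
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < 3:
        return np.nan
    a, b = a[m], b[m]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _pairwise_lns(ZA: np.ndarray, ZB: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """LNS for every ortholog index given orthology-aligned N x N matrices.

    Row i of ZA/ZB is gene i's connection vector over the N matched
    orthologs; position i (the pair's own entry, a transformed self-
    correlation) is excluded from both vectors.
    """
    n = ZA.shape[0]
    out = np.full(n, np.nan)
    flags = [FLAG_OK] * n
    keep = ~np.eye(n, dtype=bool)
    for i in range(n):
        a = ZA[i, keep[i]]
        b = ZB[i, keep[i]]
        m = np.isfinite(a) & np.isfinite(b)
        nm = int(m.sum())
        if nm < 3:
            flags[i] = FLAG_INSUFFICIENT
            continue
        av, bv = a[m], b[m]
        if av.std() == 0 or bv.std() == 0:
            flags[i] = FLAG_CONSTANT
            continue
        av = av - av.mean()
        bv = bv - bv.mean()
        out[i] = float((av @ bv) / (np.linalg.norm(av) * np.linalg.norm(bv)))
    return np.clip(out, -1.0, 1.0), flags


def _aligned_matrices(connA: ConnectionMatrix, connB: ConnectionMatrix,
                      om: OrthologMap) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Restrict both matrices to mapped orthologs, in map order.

    Returns (ZA, ZB, present) where ``present`` marks pairs whose genes exist
    in both matrices; absent pairs get all-NaN rows/columns so downstream
    rows are emitted with a missing-gene flag.
    """
    inA = set(connA.gene_ids)
    inB = set(connB.gene_ids)
    present = np.array(
        [(a in inA) and (b in inB) for a, b in om.pairs], dtype=bool
    )
    if not present.any():
        raise DataError("no ortholog pair is present in both connection matrices")
    n = om.N
    ZA = np.full((n, n), np.nan)
    ZB = np.full((n, n), np.nan)
    idx = np.nonzero(present)[0]
    a_sub = connA.restrict([om.pairs[i][0] for i in idx])
    b_sub = connB.restrict([om.pairs[i][1] for i in idx])
    ZA[np.ix_(idx, idx)] = a_sub
    ZB[np.ix_(idx, idx)] = b_sub
    return ZA, ZB, present


def _lns_table(lns: np.ndarray, flags: list[str], om: OrthologMap,
               context: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": om.a_ids,
            "gene_b": om.b_ids,
            "context": context,
            "lns": lns,
            "flag": flags,
        }
    )


def global_lns(connA: ConnectionMatrix, connB: ConnectionMatrix,
               om: OrthologMap, context: str = "global") -> pd.DataFrame:
    """LNS per ortholog pair from two aggregated connection matrices.

    Returns a table with one row per pair: gene_a, gene_b, context, lns,
    flag.  Pairs absent from either matrix, or with constant/too-short
    connection vectors, carry a NaN LNS and an explanatory flag.
    """
    ZA, ZB, present = _aligned_matrices(connA, connB, om)
    lns, flags = _pairwise_lns(ZA, ZB)
    flags = [f if p else FLAG_MISSING for f, p in zip(flags, present)]
    return _lns_table(lns, flags, om, context)


def condition_lns(dsA: ExpressionDataset, dsB: ExpressionDataset,
                  om: OrthologMap, context: str | None = None) -> pd.DataFrame:
    """Condition-specific LNS from a single matched dataset pair.

    Each dataset gets its own standardised connection matrix; no alignment of
    time points between species is required (Pearson correlation between
    genes is invariant to any common reordering of a dataset's arrays).
    """
    if context is None:
        context = f"{dsA.dataset_id}|{dsB.dataset_id}"
    return global_lns(connection_matrix(dsA), connection_matrix(dsB), om, context)


def randomized_null(connA: ConnectionMatrix, connB: ConnectionMatrix,
                    om: OrthologMap, n_permutations: int = 50,
                    seed: int = DEFAULT_SEED) -> NullDistribution:
    """LNS null by shuffling the ortholog match along the species-B axis.

    Each permutation draws a uniform random permutation of the B-side
    assignment (self-matches arising by chance are kept), recomputes LNS for
    every pair, and pools the defined values.  Both networks' structure is
    untouched — only the ortholog correspondence is disturbed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    ZA, ZB, _ = _aligned_matrices(connA, connB, om)
    n = om.N
    pooled: list[np.ndarray] = []
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        ZBp = ZB[np.ix_(perm, perm)]
        lns, _flags = _pairwise_lns(ZA, ZBp)
        pooled.append(lns[np.isfinite(lns)])
    samples = np.concatenate(pooled)
    return NullDistribution(samples, n_permutations, seed)


class DivergedResult(NamedTuple):
    count: int
    p_value: float
    cutoff: float
    n_scored: int
    n_missing: int


def count_diverged(table: pd.DataFrame, null: NullDistribution) -> DivergedResult:
    """Count ortholog pairs whose LNS falls below the null mean.

    ``cutoff`` is the mean of the pooled null samples.  The p-value is a
    two-sided Mann–Whitney U comparing the real LNS values against the
    pooled null samples.  Rows with undefined LNS are excluded and counted
    separately.
    """
    if table.empty:
        raise DataError("count_diverged: empty LNS table")
    vals = table["lns"].to_numpy(dtype=float)
    fin = np.isfinite(vals)
    if not fin.any():
        raise DataError("count_diverged: no defined LNS values")
    scored = vals[fin]
    cutoff = null.mean
    count = int((scored < cutoff).sum())
    p = float(stats.mannwhitneyu(scored, null.samples,
                                 alternative="two-sided").pvalue)
    return DivergedResult(count, p, cutoff, int(fin.sum()), int((~fin).sum()))


def within_species_lns(datasets: list[ExpressionDataset],
                       split_seed: int = DEFAULT_SEED) -> pd.DataFrame:
    """Within-species LNS by random split of a compendium into two halves.

    The datasets are shuffled and split into two disjoint halves, each half
    aggregated into its own connection matrix, and every gene correlated
    with itself across the halves (identity ortholog map on the shared gene
    universe).  Acts as the within-species upper reference for the
    between-species comparison.
    """
    if len(datasets) < 2:
        raise DataError("within_species_lns needs at least 2 datasets")
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(len(datasets))
    half = len(datasets) // 2
    first = [datasets[i] for i in order[:half]]
    second = [datasets[i] for i in order[half:]]
    connA = aggregate_connection([connection_matrix(ds) for ds in first])
    connB = aggregate_connection([connection_matrix(ds) for ds in second])
    shared = [g for g in connA.gene_ids if g in set(connB.gene_ids)]
    if not shared:
        raise DataError("no shared genes between the two halves")
    om = OrthologMap.identity(shared)
    return global_lns(connA, connB, om, context="within-species")


def write_lns_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
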