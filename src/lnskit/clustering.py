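"""Clustering of condition-specific LNS profiles and functional enrichment.

Genes are clustered by k-means on their gene x condition matrix of
condition-specific LNS, the number of clusters chosen by the gap statistic
(overridable), cluster centres arranged by average-linkage hierarchical
clustering for display, and each cluster tested for over-representation of
annotation terms by a hypergeometric tail with Bonferroni correction across
all (cluster, term) tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage, optimal_leaf_ordering
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .io import DataError

logger = logging.getLogger(__name__)


@dataclass
class AnnotationTable:
    """Flat term -> gene-set annotation with an explicit gene universe."""

    terms: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for t, genes in self.terms.items():
            extra = genes - self.universe
            if extra:
                raise DataError(
                    f"term {t!r} annotates genes outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    @classmethod
    def from_tsv(cls, path, universe: set[str] | None = None) -> "AnnotationTable":
        """Two-column (term_id, gene_id) TSV; universe defaults to all
        annotated genes."""
        df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"],
                         comment="#", dtype=str)
        terms: dict[str, set[str]] = {}
        for term, sub in df.groupby("term"):
            terms[str(term)] = set(sub["gene"])
        if universe is None:
            universe = set(df["gene"])
        return cls(terms, universe)


def _complete_rows(m: pd.DataFrame) -> pd.DataFrame:
    complete = m.dropna()
    dropped = len(m) - len(complete)
    if dropped:
        logger.info("clustering: dropped %d gene(s) with missing profiles", dropped)
    return complete


def _dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        sub = X[labels == c]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def choose_k(m: pd.DataFrame, k_max: int = 10, seed: int = 17,
             n_refs: int = 10) -> int:
    """Select the cluster count by the gap statistic.

    Compares log within-cluster dispersion against uniform reference data
    drawn over each feature's observed range; returns the smallest k with
    Gap(k) >= Gap(k+1) - s(k+1), falling back to ``k_max``.  Rows with any
    missing value are dropped (logged) first.
    """
    X = _complete_rows(m).to_numpy(dtype=float)
    if X.shape[0] < k_max:
        raise DataError(f"need at least k_max={k_max} complete rows, have {X.shape[0]}")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_w = np.empty(k_max)
    gap = np.empty(k_max)
    s_k = np.empty(k_max)
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        log_w[k - 1] = np.log(_dispersion(X, km.fit_predict(X)))
        ref_logs = np.empty(n_refs)
        for b in range(n_refs):
            ref = rng.uniform(lo, hi, size=X.shape)
            km_ref = KMeans(n_clusters=k, n_init=10,
                            random_state=seed + 1000 + b)
            ref_logs[b] = np.log(_dispersion(ref, km_ref.fit_predict(ref)))
        gap[k - 1] = ref_logs.mean() - log_w[k - 1]
        s_k[k - 1] = ref_logs.std() * np.sqrt(1 + 1 / n_refs)
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - s_k[k]:
            return k
    return k_max


class KMeansResult(NamedTuple):
    assignment: pd.Series  # gene_id -> cluster label
    centers: np.ndarray    # k x n_conditions
    inertia: float


def kmeans_profiles(m: pd.DataFrame, k: int, seed: int = 17,
                    n_restarts: int = 10) -> KMeansResult:
    """k-means (Lloyd, multiple restarts, best SSE kept) on complete rows."""
    if k < 1:
        raise ValueError("k must be >= 1")
    complete = _complete_rows(m)
    if len(complete) < k:
        raise DataError("fewer complete rows than clusters")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(complete.to_numpy(dtype=float))
    return KMeansResult(
        pd.Series(labels, index=complete.index, name="cluster"),
        km.cluster_centers_,
        float(km.inertia_),
    )


def order_clusters(centers: np.ndarray) -> list[int]:
    """Leaf order of average-linkage hierarchical clustering of the centres.

    Optimal leaf ordering is applied so that adjacent leaves are as similar
    as possible (in particular, collinear centres come out monotone).
    """
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 2 or centers.shape[0] < 1:
        raise ValueError("centers must be a non-empty 2-D array")
    if centers.shape[0] == 1:
        return [0]
    d = pdist(centers)
    tree = optimal_leaf_ordering(linkage(d, method="average"), d)
    return [int(i) for i in leaves_list(tree)]


def cluster_enrichment(assignment: pd.Series, ann: AnnotationTable,
                       alpha: float = 0.01) -> pd.DataFrame:
    """Hypergeometric over-representation of terms in each cluster.

    For cluster of size n containing x genes of a term of size K in a
    universe of size M, p = P(X >= x) under Hypergeom(M, K, n).  Bonferroni
    correction is applied jointly across all tested (cluster, term) pairs;
    rows with corrected p < ``alpha`` are returned.  Clustered genes must be
    a subset of the annotation universe; terms empty in the universe are
    skipped with a log message.
    """
    genes = set(assignment.index)
    outside = genes - ann.universe
    if outside:
        raise DataError(
            f"clustered genes outside annotation universe: {sorted(outside)[:5]}"
        )
    M = len(ann.universe)
    tests: list[dict] = []
    for cluster, sub in assignment.groupby(assignment):
        members = set(sub.index)
        n = len(members)
        for term, term_genes in ann.terms.items():
            K = len(term_genes)
            if K == 0:
                logger.info("cluster_enrichment: term %r empty in universe, skipped",
                            term)
                continue
            x = len(members & term_genes)
            p = float(stats.hypergeom.sf(x - 1, M, K, n))
            tests.append({"cluster": cluster, "term": term, "cluster_size": n,
                          "term_size": K, "overlap": x, "p": p})
    if not tests:
        return pd.DataFrame(columns=["cluster", "term", "cluster_size",
                                     "term_size", "overlap", "p", "p_bonferroni"])
    df = pd.DataFrame(tests)
    df["p_bonferroni"] = np.minimum(1.0, df["p"] * len(df))
    hits = df[df["p_bonferroni"] < alpha].sort_values(
        ["cluster", "p_bonferroni"]).reset_index(drop=True)
    return hits


def heatmap_order(assignment: pd.Series, centers: np.ndarray) -> pd.DataFrame:
    """Gene ordering for external heatmap plotting.

    Clusters are laid out in dendrogram leaf order of their centres; genes
    within a cluster keep their input order.  Returns a frame with columns
    gene_id, cluster, position.
    """
    order = order_clusters(centers)
    rows = []
    pos = 0
    for c in order:
        for g in assignment.index[assignment == c]:
            rows.append({"gene_id": g, "cluster": int(c), "position": pos})
            pos += 1
    return pd.DataFrame(rows)
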