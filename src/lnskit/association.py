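"""Association of LNS with sequence-divergence measures and promoter features.

Continuous divergence measures (dN, dN/dS, Ka, Ka/Ks, upstream-sequence
conservation) are brought to an approximately normal scale by log2 transform
followed by z-scoring, then correlated with LNS by Pearson correlation;
significance comes from a permutation test that randomises the gene-to-gene
matching between feature and LNS.  Categorical promoter features (TATA
status) are tested by point-biserial correlation, i.e. Pearson correlation
against a 0/1 indicator.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError

logger = logging.getLogger(__name__)

MIN_ALIGNED = 10


def normalize_feature(values: pd.Series | np.ndarray) -> pd.Series:
    """log2-transform, mean-subtract and scale a divergence measure to sd 1.

    Nonpositive values cannot be log-transformed and are dropped with a
    logged count (no pseudocount is added).  Requires at least 3 usable
    values and nonzero spread.
    """
    s = pd.Series(values, dtype=float)
    usable = s[np.isfinite(s) & (s > 0)]
    dropped = len(s) - len(usable)
    if dropped:
        logger.warning("normalize_feature: dropped %d nonpositive/missing value(s)",
                       dropped)
    if len(usable) < 3:
        raise DataError("normalize_feature: fewer than 3 usable values")
    logged = np.log2(usable)
    sd = logged.std(ddof=0)
    if sd == 0:
        raise DataError("normalize_feature: zero standard deviation")
    return (logged - logged.mean()) / sd


class AssociationResult(NamedTuple):
    r: float
    p_perm: float
    n: int


def _perm_pvalue(x: np.ndarray, y: np.ndarray, r_obs: float,
                 n_perm: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    hits = 0
    for _ in range(n_perm):
        r_perm = (xc @ rng.permutation(yc)) / denom
        if abs(r_perm) >= abs(r_obs) - 1e-15:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _align(lns: pd.DataFrame | pd.Series, feature: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Align an LNS table (or Series) with a feature keyed by species-A gene."""
    if isinstance(lns, pd.DataFrame):
        lns = pd.Series(lns["lns"].to_numpy(), index=lns["gene_a"].to_numpy())
    joined = pd.concat({"lns": lns, "feat": pd.Series(feature, dtype=float)},
                       axis=1, join="inner").dropna()
    return joined["lns"].to_numpy(float), joined["feat"].to_numpy(float)


def correlate_with_lns(lns: pd.DataFrame | pd.Series, feature: pd.Series,
                       n_perm: int = 1000, seed: int = 17) -> AssociationResult:
    """Pearson correlation of LNS with a continuous feature + permutation p.

    ``lns`` is an LNS table (aligned on its ``gene_a`` column) or a Series
    keyed by gene; ``feature`` a Series keyed the same way.  The permutation
    p-value is the add-one-smoothed fraction of random re-matchings whose
    |r| meets or exceeds the observed |r|.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y, x = _align(lns, feature)
    if y.size < MIN_ALIGNED:
        raise DataError(f"fewer than {MIN_ALIGNED} aligned genes")
    if x.std() == 0 or y.std() == 0:
        raise DataError("constant input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    p = _perm_pvalue(x, y, r, n_perm, seed)
    return AssociationResult(r, p, int(y.size))


def point_biserial(lns: pd.DataFrame | pd.Series, binary: pd.Series,
                   n_perm: int = 1000, seed: int = 17) -> AssociationResult:
    """Point-biserial correlation of LNS with a binary feature.

    Equivalent to Pearson correlation with 0/1 coding of the indicator;
    permutation p-value as in :func:`correlate_with_lns`.  Both classes must
    be non-empty.
    """
    ind = pd.Series(binary).dropna().astype(float)
    if not set(np.unique(ind)) <= {0.0, 1.0}:
        raise ValueError("binary feature must be coded 0/1 (or boolean)")
    y, x = _align(lns, ind)
    if y.size < MIN_ALIGNED:
        raise DataError(f"fewer than {MIN_ALIGNED} aligned genes")
    if len(np.unique(x)) < 2:
        raise DataError("single-class input: point-biserial undefined")
    r = float(stats.pointbiserialr(x, y).correlation)
    p = _perm_pvalue(x, y, r, n_perm, seed)
    return AssociationResult(r, p, int(y.size))


def tata_indicator(status: pd.Series, contrast: str = "both_vs_rest") -> pd.Series:
    """Binary coding of the three-level TATA status {both, one, neither}.

    ``both_vs_rest`` codes pairs TATA-containing in both species as 1;
    ``one_vs_neither`` restricts to {one, neither} and codes ``one`` as 1.
    """
    s = pd.Series(status).astype(str).str.lower()
    levels = {"both", "one", "neither"}
    bad = set(s.unique()) - levels
    if bad:
        raise ValueError(f"unknown TATA status level(s): {sorted(bad)}")
    if contrast == "both_vs_rest":
        return (s == "both").astype(float)
    if contrast == "one_vs_neither":
        sub = s[s != "both"]
        return (sub == "one").astype(float)
    raise ValueError(f"unknown contrast {contrast!r}")


def association_report(lns: pd.DataFrame | pd.Series, features: pd.DataFrame,
                       n_perm: int = 1000, seed: int = 17,
                       log_transform: bool = True) -> pd.DataFrame:
    """Correlate LNS with every continuous column of a feature table."""
    rows = []
    for j, col in enumerate(features.columns):
        feat = features[col]
        if log_transform:
            feat = normalize_feature(feat)
        res = correlate_with_lns(lns, feat, n_perm=n_perm, seed=seed + j)
        rows.append({"feature": col, "n": res.n, "r": res.r, "p_perm": res.p_perm})
    return pd.DataFrame(rows)
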