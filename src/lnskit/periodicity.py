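"""Detection of cell-cycle-regulated genes from synchrony time courses.

Each gene's mean-centred time course is Fourier-transformed; the cell-cycle
frequency is the nonzero DFT frequency carrying the most total power across
genes.  A gene's periodicity score is the fraction of its positive-frequency
spectral power concentrated at that frequency, so amplitude scale does not
dominate the ranking; its phase is the position of peak expression within
the cycle, in radians.  The top ``n_top`` scorers are called periodic, and
cross-species agreement of the periodic sets is tested on the one-to-one
ortholog universe with a hypergeometric tail (a label-permutation p-value is
available as a cross-check).

Time points are assumed evenly spaced; resample uneven series upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError, ExpressionDataset, OrthologMap

logger = logging.getLogger(__name__)

MIN_TIMEPOINTS = 8
#: a dominant frequency must carry at least this multiple of the uniform
#: power share before the period call is considered confident
CONFIDENCE_FACTOR = 2.0


def mean_center(ds: ExpressionDataset) -> ExpressionDataset:
    """Centre each gene so its average over the time course is 0."""
    if not ds.is_complete():
        raise DataError("mean_center requires a complete time-course dataset")
    values = ds.values.sub(ds.values.mean(axis=1), axis=0)
    return replace(ds, values=values)


class PeriodCall(NamedTuple):
    """Dominant-frequency call for a time-course dataset.

    ``index`` counts cycles over the sampled window (DFT frequency index);
    ``power_fraction`` is that frequency's share of total positive-frequency
    power; ``low_confidence`` marks spectra with no dominant frequency.
    """

    index: int
    power_fraction: float
    low_confidence: bool


def _positive_spectrum(ds: ExpressionDataset) -> tuple[np.ndarray, int]:
    X = ds.values.to_numpy(dtype=float)
    coef = np.fft.rfft(X, axis=1)
    n_freq = coef.shape[1] - 1  # positive frequencies 1..n//2
    return coef, n_freq


def identify_period(ds: ExpressionDataset) -> PeriodCall:
    """Find the cycle count maximising total spectral power over all genes.

    Requires a centred dataset with at least 8 evenly spaced time points.
    When the winning frequency's share of total power is below
    ``CONFIDENCE_FACTOR`` times the uniform share the call is flagged
    low-confidence (e.g. white noise has no dominant frequency).
    """
    if ds.n_arrays < MIN_TIMEPOINTS:
        raise DataError(
            f"need >= {MIN_TIMEPOINTS} time points, got {ds.n_arrays}"
        )
    coef, n_freq = _positive_spectrum(ds)
    power = (np.abs(coef[:, 1:]) ** 2).sum(axis=0)
    total = power.sum()
    if total == 0:
        raise DataError("all-zero dataset: no spectral power")
    best = int(np.argmax(power))
    frac = float(power[best] / total)
    low = frac < CONFIDENCE_FACTOR / n_freq
    if low:
        logger.warning(
            "identify_period: no dominant frequency (top share %.3f of %d "
            "frequencies); call is low-confidence", frac, n_freq,
        )
    return PeriodCall(best + 1, frac, low)


@dataclass
class PeriodicityResult:
    """Per-gene periodicity score, peak phase and periodic call."""

    gene_id: str
    score: float
    phase: float
    periodic: bool = False


def fourier_score(ds: ExpressionDataset, freq: int) -> list[PeriodicityResult]:
    """Score every gene at the cell-cycle frequency.

    score = |X(freq)|^2 / sum over positive frequencies of |X(f)|^2, in
    [0, 1]; a pure cosine at ``freq`` scores 1, a cosine at any other DFT
    frequency scores 0.  phase = position of peak expression within the
    cycle in [0, 2pi): a gene following ``cos(2*pi*freq*t/T - phi)`` peaks
    at cycle position ``phi``.  All-zero genes get score 0, phase 0.
    """
    coef, n_freq = _positive_spectrum(ds)
    if not 1 <= freq <= n_freq:
        raise ValueError(f"frequency index must be in 1..{n_freq}")
    power = np.abs(coef[:, 1:]) ** 2
    total = power.sum(axis=1)
    at = power[:, freq - 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(total > 0, at / total, 0.0)
    phase = np.where(at > 0, (-np.angle(coef[:, freq])) % (2 * np.pi), 0.0)
    return [
        PeriodicityResult(g, float(s), float(p))
        for g, s, p in zip(ds.gene_ids, score, phase)
    ]


def select_periodic(results: list[PeriodicityResult],
                    n_top: int) -> list[PeriodicityResult]:
    """Flag the ``n_top`` highest-scoring genes as periodic.

    Ties at the boundary are broken by lexical gene-id order (logged).
    Returns new result objects in the input's gene order.
    """
    if n_top > len(results):
        raise ValueError("n_top exceeds gene count")
    ranked = sorted(results, key=lambda r: (-r.score, r.gene_id))
    if 0 < n_top < len(ranked) and ranked[n_top - 1].score == ranked[n_top].score:
        logger.info("select_periodic: score tie at rank %d broken lexically", n_top)
    chosen = {r.gene_id for r in ranked[:n_top]}
    return [
        PeriodicityResult(r.gene_id, r.score, r.phase, r.gene_id in chosen)
        for r in results
    ]


def suggest_n_top(ds: ExpressionDataset, freq: int, fdr: float = 0.01,
                  n_perm: int = 50, seed: int = 17) -> int:
    """Suggest a periodic-call count via an FDR against time-permuted nulls.

    Each permutation shuffles every gene's time points independently and
    rescores; for each candidate score threshold the FDR is estimated as
    (expected null exceedances) / (observed exceedances).  Returns the size
    of the largest top-set with estimated FDR <= ``fdr``.
    """
    rng = np.random.default_rng(seed)
    obs = np.sort([r.score for r in fourier_score(ds, freq)])[::-1]
    X = ds.values.to_numpy(dtype=float)
    null: list[np.ndarray] = []
    for _ in range(n_perm):
        perm = np.array([rng.permutation(X.shape[1]) for _ in range(X.shape[0])])
        Xp = np.take_along_axis(X, perm, axis=1)
        dsp = replace(ds, values=pd.DataFrame(
            Xp, index=ds.values.index, columns=ds.values.columns))
        null.append(np.array([r.score for r in fourier_score(dsp, freq)]))
    pooled = np.sort(np.concatenate(null))
    best = 0
    for i, thr in enumerate(obs, start=1):
        exp_null = (pooled.size - np.searchsorted(pooled, thr, side="left"))
        exp_null = exp_null / n_perm
        if exp_null / i <= fdr:
            best = i
    return best


class OverlapResult(NamedTuple):
    overlap: int
    p_hyper: float
    p_perm: float


def overlap_test(setA: set[str], setB: set[str], om: OrthologMap,
                 n_perm: int = 0, seed: int = 17) -> OverlapResult:
    """Cross-species overlap of periodic calls on the ortholog universe.

    ``setA`` holds species-A gene ids, ``setB`` species-B gene ids; both
    must be subsets of the respective sides of the ortholog map.  The
    overlap is the number of pairs periodic in both species; significance is
    the hypergeometric upper tail P(X >= overlap) over the N-pair universe.
    With ``n_perm`` > 0 a label-permutation p-value (add-one smoothed) is
    also computed as a cross-check; otherwise ``p_perm`` is NaN.
    """
    if om.N == 0:
        raise DataError("empty ortholog universe")
    extraA = setA - set(om.a_ids)
    extraB = setB - set(om.b_ids)
    if extraA or extraB:
        raise DataError(
            f"periodic sets contain genes outside the ortholog universe: "
            f"{sorted(extraA | extraB)[:5]}"
        )
    in_a = np.array([a in setA for a, _ in om.pairs])
    in_b = np.array([b in setB for _, b in om.pairs])
    overlap = int((in_a & in_b).sum())
    N, KA, KB = om.N, int(in_a.sum()), int(in_b.sum())
    if KA == N and KB == N:
        logger.warning("overlap_test: both sets cover the whole universe; "
                       "p-value is degenerate")
    p_hyper = float(stats.hypergeom.sf(overlap - 1, N, KA, KB))
    p_perm = np.nan
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            if int((in_a & rng.permutation(in_b)).sum()) >= overlap:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
    return OverlapResult(overlap, p_hyper, float(p_perm))


def results_to_frame(results: list[PeriodicityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "score": [r.score for r in results],
            "phase": [r.phase for r in results],
            "periodic": [r.periodic for r in results],
        }
    )
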