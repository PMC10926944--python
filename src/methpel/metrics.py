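"""Summary statistics of methylation landscapes: MML, NME, JSD and tracks.

All statistics are functionals of a subregion's methylation-level
distribution p_k = P(level = k/K), computed exactly from the fitted Ising
model (not from the empirical read histogram):

* MML  = sum_k (k/K) p_k, the mean methylation level in [0, 1];
* NME  = H(p) / log2(K+1) with H in bits, in [0, 1] (0 deterministic,
  1 maximally stochastic);
* JSD  = sqrt(JS divergence) between two level distributions, base-2 logs,
  a metric in [0, 1] that is 1 exactly for disjoint-support distributions.

Differential tracks report per-subregion dMML/dNME (test minus reference)
and JSD; genome summaries pair subregions across samples and apply the
two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import wilcoxon

from .io import CpGMap, RegionPartition
from .ising import (
    FitResult,
    LevelDistribution,
    RegionReads,
    fit_parameters,
    level_distribution,
)

logger = logging.getLogger(__name__)

#: default depth filters: informative reads needed to fit an estimation
#: region, and reads overlapping (>= 1 CpG observed) needed to score a
#: subregion
MIN_REGION_READS = 20
MIN_SUBREGION_READS = 5


def mml(dist: LevelDistribution) -> float:
    """Mean methylation level: expectation of k/K under p."""
    return float((dist.levels * dist.p).sum())


def nme(dist: LevelDistribution) -> float:
    """Normalized methylation entropy H(p)/log2(K+1), with 0*log0 = 0."""
    if dist.K < 1:
        raise ValueError("NME undefined for K=0")
    p = dist.p[dist.p > 0]
    return float(-(p * np.log2(p)).sum() / np.log2(dist.K + 1))


def jsd(p: LevelDistribution | np.ndarray, q: LevelDistribution | np.ndarray) -> float:
    """Jensen-Shannon distance (square root of the divergence, base-2 logs)."""
    pv = p.p if isinstance(p, LevelDistribution) else np.asarray(p, dtype=float)
    qv = q.p if isinstance(q, LevelDistribution) else np.asarray(q, dtype=float)
    if pv.shape != qv.shape:
        raise ValueError("JSD requires level distributions over the same K")
    val = float(jensenshannon(pv, qv, base=2))
    return 0.0 if np.isnan(val) else min(max(val, 0.0), 1.0)


def empirical_level_distribution(reads: RegionReads, subset: np.ndarray) -> LevelDistribution | None:
    """Read-level histogram of methylation levels over a subregion (diagnostic).

    Uses reads observing every CpG of the subregion; returns None when no
    read covers it completely.  The model-based distribution is the primary
    route; this mode exists to sanity-check fits.
    """
    subset = np.asarray(subset, dtype=np.int64)
    K = subset.size
    counts = np.zeros(K + 1)
    for r in range(len(reads.starts)):
        s, L = int(reads.starts[r]), int(reads.lengths[r])
        cl = reads.clamps[reads.offsets[r] : reads.offsets[r] + L]
        inside = (subset >= s) & (subset < s + L)
        if not inside.all():
            continue
        vals = cl[subset - s]
        if np.any(vals == 0):
            continue
        counts[int((vals == 1).sum())] += reads.counts[r]
    if counts.sum() == 0:
        return None
    return LevelDistribution(K=K, p=counts / counts.sum())


def fit_sample(
    region_reads: dict[int, RegionReads],
    partition: RegionPartition,
    cmap: CpGMap,
    min_region_reads: int = MIN_REGION_READS,
) -> dict[int, FitResult]:
    """Fit Ising parameters for every estimation region passing the depth filter."""
    fits: dict[int, FitResult] = {}
    for region in partition.regions.itertuples():
        rid = int(region.region_id)
        rr = region_reads.get(rid)
        if rr is None or rr.n_reads < min_region_reads:
            continue
        rho = cmap.rho[region.chrom][int(region.lo) : int(region.hi)]
        d = np.diff(cmap.pos[region.chrom][int(region.lo) : int(region.hi)]).astype(float)
        try:
            fits[rid] = fit_parameters(rr, rho, d)
        except (ValueError, RuntimeError) as err:
            logger.warning("region %d excluded: %s", rid, err)
    return fits


def _subregion_support(rr: RegionReads | None, lo: int, hi: int) -> int:
    """Number of reads with at least one observed call inside [lo, hi)."""
    if rr is None:
        return 0
    n = 0
    for r in range(len(rr.starts)):
        s, L = int(rr.starts[r]), int(rr.lengths[r])
        a, b = max(s, lo), min(s + L, hi)
        if a < b and np.any(rr.clamps[rr.offsets[r] + (a - s) : rr.offsets[r] + (b - s)] != 0):
            n += int(rr.counts[r])
    return n


def landscape_track(
    fits: dict[int, FitResult],
    region_reads: dict[int, RegionReads],
    partition: RegionPartition,
    cmap: CpGMap,
    min_subregion_reads: int = MIN_SUBREGION_READS,
) -> pd.DataFrame:
    """Per-subregion MML/NME from the fitted model; depth-failed entries NaN.

    Returns the subregion table with added columns mml, nme, n_reads.
    """
    out = partition.subregions.copy()
    mml_v = np.full(len(out), np.nan)
    nme_v = np.full(len(out), np.nan)
    support = np.zeros(len(out), dtype=int)
    regions = partition.regions.set_index("region_id")
    dist_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for i, sub in enumerate(out.itertuples()):
        rid = int(sub.region_id)
        if rid not in fits:
            continue
        reg = regions.loc[rid]
        lo = int(reg["lo"])
        rr = region_reads.get(rid)
        support[i] = _subregion_support(rr, int(sub.lo) - lo, int(sub.hi) - lo)
        if support[i] < min_subregion_reads:
            continue
        if rid not in dist_cache:
            chrom = reg["chrom"]
            hi = int(reg["hi"])
            dist_cache[rid] = (
                cmap.rho[chrom][lo:hi],
                np.diff(cmap.pos[chrom][lo:hi]).astype(float),
            )
        rho, d = dist_cache[rid]
        subset = np.arange(int(sub.lo) - lo, int(sub.hi) - lo)
        dist = level_distribution(fits[rid].params, rho, d, subset)
        mml_v[i] = mml(dist)
        nme_v[i] = nme(dist)
    out["mml"] = mml_v
    out["nme"] = nme_v
    out["n_reads"] = support
    return out


def differential_track(
    test_fits: dict[int, FitResult],
    ref_fits: dict[int, FitResult],
    test_reads: dict[int, RegionReads],
    ref_reads: dict[int, RegionReads],
    partition: RegionPartition,
    cmap: CpGMap,
    min_subregion_reads: int = MIN_SUBREGION_READS,
) -> pd.DataFrame:
    """Per-subregion dMML, dNME and JSD between two fitted samples.

    A subregion is scored only if it passes the depth filter in both
    samples; otherwise its values are NaN.
    """
    test = landscape_track(test_fits, test_reads, partition, cmap, min_subregion_reads)
    ref = landscape_track(ref_fits, ref_reads, partition, cmap, min_subregion_reads)
    out = partition.subregions.copy()
    out["dmml"] = test["mml"] - ref["mml"]
    out["dnme"] = test["nme"] - ref["nme"]
    jsd_v = np.full(len(out), np.nan)
    regions = partition.regions.set_index("region_id")
    cov_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    scored = (~test["mml"].isna()) & (~ref["mml"].isna())
    for i, sub in enumerate(out.itertuples()):
        if not scored.iloc[i]:
            continue
        rid = int(sub.region_id)
        if rid not in cov_cache:
            reg = regions.loc[rid]
            lo_, hi_ = int(reg["lo"]), int(reg["hi"])
            cov_cache[rid] = (
                cmap.rho[reg["chrom"]][lo_:hi_],
                np.diff(cmap.pos[reg["chrom"]][lo_:hi_]).astype(float),
                lo_,
            )
        rho, d, lo_ = cov_cache[rid]
        subset = np.arange(int(sub.lo) - lo_, int(sub.hi) - lo_)
        p = level_distribution(test_fits[rid].params, rho, d, subset)
        q = level_distribution(ref_fits[rid].params, rho, d, subset)
        jsd_v[i] = jsd(p, q)
    out["jsd"] = jsd_v
    if not scored.any():
        logger.warning("differential track is empty: no subregion scored in both samples")
    out["test_mml"], out["test_nme"] = test["mml"], test["nme"]
    out["ref_mml"], out["ref_nme"] = ref["mml"], ref["nme"]
    return out


def genome_summary(values_a: pd.Series, values_b: pd.Series) -> dict:
    """Paired comparison of one statistic across two samples' subregions.

    Pairs on the shared index (subregion id), drops pairs with missing
    values, and reports medians, IQRs, the median paired difference, and a
    two-sided Wilcoxon signed-rank p-value (1.0 by convention when every
    paired difference is zero; NaN and a log message below 10 pairs).
    """
    joined = pd.concat([values_a.rename("a"), values_b.rename("b")], axis=1, join="inner").dropna()
    diffs = joined["a"] - joined["b"]
    out = {
        "n": int(len(joined)),
        "median_a": float(joined["a"].median()) if len(joined) else np.nan,
        "median_b": float(joined["b"].median()) if len(joined) else np.nan,
        "iqr_a": float(joined["a"].quantile(0.75) - joined["a"].quantile(0.25)) if len(joined) else np.nan,
        "iqr_b": float(joined["b"].quantile(0.75) - joined["b"].quantile(0.25)) if len(joined) else np.nan,
        "median_diff": float(diffs.median()) if len(joined) else np.nan,
    }
    if len(joined) < 10:
        logger.warning("genome_summary: only %d shared subregions; p undefined", len(joined))
        out["p_value"] = np.nan
    elif (diffs == 0).all():
        out["p_value"] = 1.0
    else:
        out["p_value"] = float(wilcoxon(joined["a"], joined["b"], alternative="two-sided").pvalue)
    return out
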