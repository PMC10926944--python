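"""Gene and feature ranking by methylation discordance (jsGrank-style).

Genes are scored by the largest JSD (or dNME) among analysis subregions
within +/-2 kb of any of their TSSs, or by a CpG-weighted mean JSD over the
gene body.  Significance is assessed by a read-label permutation null: reads
of the two samples in a region are pooled, labels reshuffled preserving
group sizes, both models refit, and the region statistic recomputed;
empirical p-values are (1 + #{null >= observed}) / (1 + n_perm), adjusted
across genes by Benjamini-Hochberg.

Feature summaries assign each scored subregion to the annotation interval
covering its midpoint and report per-label medians and IQRs, mirroring the
CpG-island-class and chromatin-state breakdowns of differential methylation
analyses.  Meta-profiles average a track in signed, strand-aware distance
bins around anchors such as TSSs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests

from .io import CpGMap, RegionPartition
from .ising import RegionReads, fit_parameters, level_distribution, pack_fragments
from .metrics import jsd

logger = logging.getLogger(__name__)

PROMOTER_WINDOW = 2000
RANK_MODES = ("promoter_jsd", "promoter_dnme", "gene_body_jsd")


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (NaNs propagate)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _tss_table(genes: pd.DataFrame) -> pd.DataFrame:
    """One row per gene entry with its strand-aware TSS coordinate."""
    strand = genes["strand"] if "strand" in genes.columns else pd.Series("+", index=genes.index)
    tss = np.where(strand == "-", genes["end"], genes["start"])
    return pd.DataFrame(
        {"chrom": genes["chrom"], "tss": tss, "strand": strand, "label": genes["label"],
         "start": genes["start"], "end": genes["end"]}
    )


def rank_genes(
    diff: pd.DataFrame,
    genes: pd.DataFrame,
    mode: str = "promoter_jsd",
    window: int = PROMOTER_WINDOW,
) -> pd.DataFrame:
    """Rank genes by methylation discordance around their TSS or gene body.

    ``diff`` is a differential track (subregion table with jsd/dnme
    columns); ``genes`` a BED-like frame (chrom, start, end, label[,score,
    strand]).  Promoter modes take the maximum subregion statistic within
    ``window`` bp of any TSS annotated to the gene symbol; gene-body mode a
    CpG-count-weighted mean of JSD over subregions overlapping the body.
    Ties are broken by genomic position (chrom, start).  Genes with no
    scored subregion get rank NaN and scored=False.
    """
    if mode not in RANK_MODES:
        raise ValueError(f"mode must be one of {RANK_MODES}")
    if len(genes) == 0:
        raise ValueError("empty gene table")
    stat_col = "dnme" if mode == "promoter_dnme" else "jsd"
    tss = _tss_table(genes)
    rows = []
    for (name,), grp in tss.groupby(["label"], sort=False):
        values = []
        for g in grp.itertuples():
            sel = diff["chrom"] == g.chrom
            if mode == "gene_body_jsd":
                lo, hi = int(g.start), int(g.end)
            else:
                lo, hi = int(g.tss) - window, int(g.tss) + window
            sel &= (diff["end"] > lo) & (diff["start"] < hi)
            sub = diff.loc[sel, [stat_col, "K"]].dropna(subset=[stat_col])
            if len(sub):
                values.append(sub)
        first = grp.iloc[0]
        if not values:
            rows.append((name, first["chrom"], int(first["start"]), np.nan, False))
            continue
        allv = pd.concat(values).drop_duplicates()
        if mode == "gene_body_jsd":
            stat = float(np.average(allv[stat_col], weights=allv["K"]))
        else:
            stat = float(allv[stat_col].max())
        rows.append((name, first["chrom"], int(first["start"]), stat, True))
    out = pd.DataFrame(rows, columns=["gene", "chrom", "start", "statistic", "scored"])
    scored = out[out["scored"]].sort_values(
        ["statistic", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    )
    out["rank"] = np.nan
    out.loc[scored.index, "rank"] = np.arange(1, len(scored) + 1)
    return out.sort_values(["rank", "chrom", "start"], na_position="last").reset_index(drop=True)


def _region_jsd(
    frags_a: list[tuple[int, str]],
    frags_b: list[tuple[int, str]],
    rho: np.ndarray,
    d: np.ndarray,
    starts: tuple | None,
) -> float:
    n = len(rho)
    kwargs = {} if starts is None else {"starts": starts}
    fit_a = fit_parameters(pack_fragments(frags_a, n), rho, d, **kwargs)
    fit_b = fit_parameters(pack_fragments(frags_b, n), rho, d, **kwargs)
    return jsd(
        level_distribution(fit_a.params, rho, d),
        level_distribution(fit_b.params, rho, d),
    )


def permutation_pvalue(
    frags_a: list[tuple[int, str]],
    frags_b: list[tuple[int, str]],
    rho: np.ndarray,
    d: np.ndarray,
    n_perm: int = 199,
    seed: int = 0,
    min_reads: int = 5,
    starts: tuple | None = None,
) -> float:
    """Read-label permutation p-value for one region's JSD.

    Pools the fragments of both samples, reassigns sample labels uniformly
    at random preserving group sizes, refits both Ising models and
    recomputes the region-level JSD; p = (1 + #{null >= observed}) /
    (1 + n_perm).  ``starts`` optionally overrides the optimizer start grid
    (the observed statistic always uses the same grid as the null).
    Returns NaN when either group is smaller than ``min_reads``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    n_a, n_b = len(frags_a), len(frags_b)
    if min(n_a, n_b) < min_reads:
        logger.warning("permutation test undefined: group sizes %d/%d", n_a, n_b)
        return float("nan")
    observed = _region_jsd(frags_a, frags_b, rho, d, starts)
    pool = list(frags_a) + list(frags_b)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        idx = rng.permutation(len(pool))
        null_a = [pool[i] for i in idx[:n_a]]
        null_b = [pool[i] for i in idx[n_a:]]
        try:
            null_stat = _region_jsd(null_a, null_b, rho, d, starts)
        except (ValueError, RuntimeError):
            null_stat = np.inf  # conservative: counts against the observed
        if null_stat >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def region_fragments(region_reads: dict[int, RegionReads], region_id: int) -> list[tuple[int, str]]:
    """Unpack a region's deduplicated fragments back to an explicit list."""
    rr = region_reads.get(region_id)
    if rr is None:
        return []
    code = {-1: "U", 0: ".", 1: "M"}
    out = []
    for r in range(len(rr.starts)):
        cl = rr.clamps[rr.offsets[r] : rr.offsets[r] + rr.lengths[r]]
        calls = "".join(code[int(c)] for c in cl)
        out.extend([(int(rr.starts[r]), calls)] * int(rr.counts[r]))
    return out


def write_top_genes(ranking: pd.DataFrame, path, n: int = 1000) -> pd.DataFrame:
    """Write the top-n scored genes (by rank) as TSV for downstream
    enrichment tools; returns the emitted frame."""
    top = ranking[ranking["scored"]].sort_values("rank").head(n)
    top.to_csv(path, sep="\t", index=False)
    return top


def feature_summary(diff: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Median/IQR of dMML, dNME, JSD per annotation label.

    Each scored subregion is assigned to the interval covering its midpoint
    (label "none" when uncovered); ``annotations`` is a frame with chrom,
    start, end, label.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in annotations.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(r.start), int(r.end), r.label) for r in grp.itertuples() if r.end > r.start
        )
    mid = ((diff["start"] + diff["end"]) // 2).astype(int)
    labels = []
    for chrom, m in zip(diff["chrom"], mid):
        hits = trees[chrom][m] if chrom in trees else None
        labels.append(sorted(hits)[0].data if hits else "none")
    scored = diff.assign(label=labels).dropna(subset=["jsd"])
    rows = []
    for label, grp in scored.groupby("label"):
        row = {"label": label, "n": len(grp)}
        for col in ("dmml", "dnme", "jsd"):
            row[f"median_{col}"] = float(grp[col].median())
            row[f"iqr_{col}"] = float(grp[col].quantile(0.75) - grp[col].quantile(0.25))
        rows.append(row)
    return pd.DataFrame(rows).sort_values("label").reset_index(drop=True)


def meta_profile(
    track: pd.DataFrame,
    value_col: str,
    anchors: pd.DataFrame,
    window: int = 2000,
    n_bins: int = 40,
    sub_span: int | None = None,
) -> pd.DataFrame:
    """Mean track value in signed distance bins around anchors.

    ``anchors`` needs chrom, tss (or start) and optionally strand; distances
    are midpoint-to-anchor, sign-flipped for minus-strand anchors so
    positive always means downstream.  Returns bin center, mean, n.
    """
    if len(anchors) == 0:
        raise ValueError("no anchors supplied")
    span = sub_span if sub_span is not None else int((track["end"] - track["start"]).max())
    if window < span:
        raise ValueError("meta-profile window must be at least the subregion span")
    acol = "tss" if "tss" in anchors.columns else "start"
    strand = anchors["strand"] if "strand" in anchors.columns else pd.Series("+", index=anchors.index)
    edges = np.linspace(-window, window, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    scored = track.dropna(subset=[value_col])
    by_chrom = {chrom: grp for chrom, grp in scored.groupby("chrom")}
    for anchor, s, chrom in zip(anchors[acol], strand, anchors["chrom"]):
        grp = by_chrom.get(chrom)
        if grp is None:
            continue
        mid = (grp["start"] + grp["end"]).to_numpy() / 2.0
        dist = mid - float(anchor)
        if s == "-":
            dist = -dist
        inside = (dist >= -window) & (dist < window)
        idx = np.minimum(((dist[inside] + window) / (2 * window) * n_bins).astype(int), n_bins - 1)
        np.add.at(sums, idx, grp[value_col].to_numpy()[inside])
        np.add.at(counts, idx, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return pd.DataFrame({"bin_center": centers, "mean": means, "n": counts})


def rank_with_significance(
    ranking: pd.DataFrame,
    diff: pd.DataFrame,
    genes: pd.DataFrame,
    test_reads: dict[int, RegionReads],
    ref_reads: dict[int, RegionReads],
    partition: RegionPartition,
    cmap: CpGMap,
    n_perm: int = 199,
    seed: int = 0,
    window: int = PROMOTER_WINDOW,
    top: int | None = None,
    starts: tuple | None = None,
) -> pd.DataFrame:
    """Attach permutation p-values and BH q-values to a gene ranking.

    For each (top-``top``) scored gene, tests the estimation region
    containing the maximal promoter subregion.  Unscored genes keep NaN.
    """
    tss = _tss_table(genes).set_index("label")
    regions = partition.regions.set_index("region_id")
    pvals = np.full(len(ranking), np.nan)
    todo = ranking.index[ranking["scored"]]
    if top is not None:
        todo = todo[:top]
    for i in todo:
        gene = ranking.loc[i, "gene"]
        entries = tss.loc[[gene]]
        best = None
        for g in entries.itertuples():
            lo, hi = int(g.tss) - window, int(g.tss) + window
            sel = (diff["chrom"] == g.chrom) & (diff["end"] > lo) & (diff["start"] < hi)
            sub = diff.loc[sel].dropna(subset=["jsd"])
            if len(sub) and (best is None or sub["jsd"].max() > best[0]):
                j = sub["jsd"].idxmax()
                best = (float(sub.loc[j, "jsd"]), int(sub.loc[j, "region_id"]))
        if best is None:
            continue
        rid = best[1]
        reg = regions.loc[rid]
        rho = cmap.rho[reg["chrom"]][int(reg["lo"]) : int(reg["hi"])]
        d = np.diff(cmap.pos[reg["chrom"]][int(reg["lo"]) : int(reg["hi"])]).astype(float)
        frags_a = region_fragments(test_reads, rid)
        frags_b = region_fragments(ref_reads, rid)
        pvals[i] = permutation_pvalue(frags_a, frags_b, rho, d, n_perm=n_perm, seed=seed + i, starts=starts)
    out = ranking.copy()
    out["p_value"] = pvals
    out["q_value"] = bh_adjust(pvals)
    return out
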