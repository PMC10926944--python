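"""Synthetic CpG maps and read-level bisulfite data with known ground truth.

The generator emulates the coarse structure of a mammalian methylome that
the downstream statistics are sensitive to: dense CpG islands (with shores
and shelves as fixed-width flanks) embedded in sparse open sea, a subset of
islands designated bivalent promoters, and heterochromatin blocks in the
open sea.  Reads are exact draws from per-region Ising distributions, so
every simulated dataset carries the true parameters and the exact MML/NME
of every subregion for parameter-recovery and directionality tests.

The paired tumor/normal generator plants the qualitative methylome
reorganisation reported for H3 K27M glioma: global hypomethylation with
globally elevated methylation entropy, but focal hypermethylation at
bivalent promoters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _dp
from .io import CpGMap, ReadSet, RegionPartition, cpg_density, partition_genome
from .ising import IsingParameters, level_distribution

logger = logging.getLogger(__name__)

SPIN_TO_CALL = {1: "M", -1: "U"}

#: mean inter-CpG gap (bp) inside islands / in open sea; shore and shelf
#: widths flanking each island (bp)
ISLAND_GAP_MEAN = 20
OPEN_SEA_GAP_MEAN = 120
SHORE_BP = 2000
SHELF_BP = 2000
MEAN_ISLAND_BP = 1000

#: per-feature Ising fields of the sample profiles.  Normal: open sea (and
#: heterochromatin) strongly methylated, islands strongly unmethylated, high
#: cooperativity c (ordered, low-entropy landscapes).  Tumor: fields shrunk
#: toward 0 and cooperativity reduced (hypomethylation + higher entropy),
#: except bivalent promoters whose field flips positive (focal
#: hypermethylation).
NORMAL_FIELD = {
    "open_sea": 2.5,
    "heterochromatin": 2.5,
    "none": 2.5,
    "island": -3.0,
    "bivalent_promoter": -3.0,
    "shore": 1.0,
    "shelf": 2.0,
}
NORMAL_COUPLING = 4.0
TUMOR_FIELD_SHRINK = 0.4
TUMOR_COUPLING = 1.0
TUMOR_BIVALENT_FIELD = 2.0


@dataclass
class SimulationTruth:
    """Ground truth of a simulated sample.

    ``regions``:    region_id, a, b, c (true generating parameters)
    ``subregions``: sub_id, region_id, mml, nme (exact model values, not
    read-derived).
    """

    regions: pd.DataFrame
    subregions: pd.DataFrame


def _geometric_gaps(rng: np.random.Generator, mean_gap: float, n: int) -> np.ndarray:
    """Inter-CpG gaps >= 2 bp with the requested mean."""
    return 2 + rng.geometric(1.0 / (mean_gap - 1.0), size=n)


def generate_cpg_map(
    n_chrom: int = 1,
    chrom_length: int = 1_000_000,
    island_fraction: float = 0.15,
    seed: int = 0,
    bivalent_fraction: float = 0.1,
    heterochromatin_fraction: float = 0.2,
) -> CpGMap:
    """Generate a CpG map with two spacing regimes and feature labels.

    Islands (exponential lengths, mean 1 kb) cover ``island_fraction`` of
    each chromosome in expectation; CpG gaps are geometric with mean 20 bp
    inside islands and 120 bp outside.  Shores are the 2 kb flanks of each
    island and shelves the next 2 kb.  A ``bivalent_fraction`` of islands is
    relabeled ``bivalent_promoter``; a ``heterochromatin_fraction`` of
    inter-island sea segments is relabeled ``heterochromatin``.
    Deterministic for a fixed seed.
    """
    if n_chrom < 1 or chrom_length <= 0:
        raise ValueError("n_chrom must be >= 1 and chrom_length positive")
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be at least 10 kb")
    if not 0.0 <= island_fraction <= 1.0:
        raise ValueError("island_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lengths, pos, rho, feature = {}, {}, {}, {}
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        islands: list[tuple[int, int, str]] = []  # (start0, end0, island|bivalent_promoter)
        if island_fraction > 0:
            mean_gap = (
                MEAN_ISLAND_BP * (1.0 - island_fraction) / island_fraction
                if island_fraction < 1.0
                else 0.0
            )
            # every 1/bivalent_fraction-th island (deterministic phase) is
            # relabeled bivalent, so small genomes still carry the class
            period = max(1, round(1.0 / bivalent_fraction)) if bivalent_fraction > 0 else 0
            cursor = 0
            idx = 0
            while cursor < chrom_length:
                cursor += int(rng.exponential(mean_gap)) if mean_gap > 0 else 0
                ilen = max(200, int(rng.exponential(MEAN_ISLAND_BP)))
                if cursor >= chrom_length:
                    break
                end = min(cursor + ilen, chrom_length)
                lab = "bivalent_promoter" if period and idx % period == period // 2 else "island"
                islands.append((cursor, end, lab))
                idx += 1
                cursor = end
                if island_fraction >= 1.0:
                    cursor = chrom_length
        # heterochromatin: the middle of the longest sea gaps (clear of the
        # shore/shelf flanks), as many as the requested fraction allows
        het: list[tuple[int, int]] = []
        pad = SHORE_BP + SHELF_BP
        sea_bounds = [0] + [b for s, e, _ in islands for b in (s, e)] + [chrom_length]
        gaps = [
            (s, e) for s, e in zip(sea_bounds[::2], sea_bounds[1::2]) if e - s > 2 * pad + 500
        ]
        gaps.sort(key=lambda g: g[1] - g[0], reverse=True)
        n_het = max(1, round(heterochromatin_fraction * max(len(gaps), 1))) if heterochromatin_fraction > 0 else 0
        for s, e in gaps[:n_het]:
            het.append((s + pad, e - pad))
        # place CpGs segment by segment
        positions: list[int] = []
        labels: list[str] = []
        cursor = 1  # 1-based
        segments: list[tuple[int, int, str | None]] = []
        prev = 0
        for s, e, lab in islands:
            if s > prev:
                segments.append((prev, s, None))
            segments.append((s, e, lab))
            prev = e
        if prev < chrom_length:
            segments.append((prev, chrom_length, None))
        for s, e, lab in segments:
            mean = ISLAND_GAP_MEAN if lab else OPEN_SEA_GAP_MEAN
            span = e - s
            n_draw = max(8, int(2.5 * span / mean))
            gaps = _geometric_gaps(rng, mean, n_draw)
            pts = s + 1 + np.cumsum(gaps)  # 1-based positions
            pts = pts[pts <= e]
            while len(gaps) and (len(pts) == 0 or pts[-1] < e - 3 * mean):
                extra = _geometric_gaps(rng, mean, n_draw)
                base = pts[-1] if len(pts) else s + 1
                more = base + np.cumsum(extra)
                pts = np.concatenate([pts, more[more <= e]])
                if len(more) and more[-1] > e:
                    break
            positions.extend(int(p) for p in pts)
            labels.extend([lab or "open_sea"] * len(pts))
        p_arr = np.array(positions, dtype=np.int64)
        lab_arr = np.array(labels, dtype=object)
        order = np.argsort(p_arr, kind="stable")
        p_arr, lab_arr = p_arr[order], lab_arr[order]
        keep = np.concatenate([[True], np.diff(p_arr) >= 2])
        p_arr, lab_arr = p_arr[keep], lab_arr[keep]
        # shores/shelves: fixed-width flanks of islands, overriding sea labels
        for s, e, _ in islands:
            for flank_lo, flank_hi, lab in (
                (s - SHORE_BP, s, "shore"),
                (e, e + SHORE_BP, "shore"),
                (s - SHORE_BP - SHELF_BP, s - SHORE_BP, "shelf"),
                (e + SHORE_BP, e + SHORE_BP + SHELF_BP, "shelf"),
            ):
                sel = (p_arr - 1 >= flank_lo) & (p_arr - 1 < flank_hi) & (lab_arr == "open_sea")
                lab_arr[sel] = lab
        for s, e in het:
            sel = (p_arr - 1 >= s) & (p_arr - 1 < e) & (lab_arr == "open_sea")
            lab_arr[sel] = "heterochromatin"
        lengths[chrom] = chrom_length
        pos[chrom] = p_arr
        rho[chrom] = cpg_density(p_arr)
        feature[chrom] = lab_arr
    cmap = CpGMap(lengths=lengths, pos=pos, rho=rho, feature=feature)
    cmap.validate()
    return cmap


def feature_annotations(cmap: CpGMap) -> pd.DataFrame:
    """Per-chromosome feature intervals tiling [0, length) from site labels.

    Boundaries between runs of equally-labeled CpGs are drawn halfway between
    the flanking sites, so every base (hence every subregion midpoint) gets
    the label of its nearest CpG run.
    """
    rows = []
    for chrom in cmap.chroms:
        p0 = cmap.pos[chrom] - 1
        lab = cmap.feature[chrom]
        if len(p0) == 0:
            rows.append((chrom, 0, cmap.lengths[chrom], "none"))
            continue
        run_start = 0
        bounds = [0]
        run_labels = []
        for i in range(1, len(p0)):
            if lab[i] != lab[i - 1]:
                bounds.append(int((p0[i - 1] + p0[i]) // 2 + 1))
                run_labels.append(lab[run_start])
                run_start = i
        bounds.append(cmap.lengths[chrom])
        run_labels.append(lab[run_start])
        for s, e, l in zip(bounds[:-1], bounds[1:], run_labels):
            rows.append((chrom, s, e, l))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def simulate_reads(
    cmap: CpGMap,
    partition: RegionPartition,
    params_by_region: dict[int, IsingParameters],
    depth: float = 10.0,
    read_span: int = 10,
    miss_rate: float = 0.05,
    seed: int = 0,
    read_prefix: str = "r",
) -> tuple[ReadSet, SimulationTruth]:
    """Draw reads exactly from each region's Ising distribution.

    ``depth`` is the expected number of observed reads per CpG; each read
    covers ``read_span`` consecutive CpGs (clipped to the region), and each
    covered site is independently masked unobserved at ``miss_rate``.  The
    returned truth holds the generating parameters and the exact MML/NME of
    every subregion, computed from the model rather than from reads.
    """
    if depth < 1 or read_span < 1 or not 0.0 <= miss_rate < 1.0:
        raise ValueError("need depth >= 1, read_span >= 1, miss_rate in [0, 1)")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, int, str]] = []
    truth_regions, truth_subs = [], []
    subs_by_region = dict(tuple(partition.subregions.groupby("region_id")))
    for region in partition.regions.itertuples():
        rid = int(region.region_id)
        if rid not in params_by_region:
            continue
        params = params_by_region[rid]
        n = int(region.hi - region.lo)
        if n == 0:
            logger.warning("region %d has no CpGs; skipped", rid)
            continue
        lo, hi = int(region.lo), int(region.hi)
        rho = cmap.rho[region.chrom][lo:hi]
        dgap = np.diff(cmap.pos[region.chrom][lo:hi]).astype(float)
        alpha = params.alpha(rho)
        beta = params.beta(dgap) if n > 1 else np.empty(0)
        f = _dp.forward_messages(alpha, beta)
        b = _dp.backward_messages(alpha, beta)
        width = min(read_span, n)
        n_reads = max(1, int(round(depth * n / width)))
        starts = rng.integers(0, n - width + 1, size=n_reads).astype(np.int64)
        unif = rng.random((n_reads, width))
        spins = _dp.sample_windows(alpha, beta, f, b, starts, width, unif)
        miss = rng.random((n_reads, width)) < miss_rate
        for i in range(n_reads):
            calls = "".join(
                "." if miss[i, m] else SPIN_TO_CALL[int(spins[i, m])] for m in range(width)
            )
            stripped = calls.lstrip(".")
            lead = width - len(stripped)
            stripped = stripped.rstrip(".")
            if not stripped:
                continue
            rows.append(
                (region.chrom, f"{read_prefix}{rid}_{i}", int(region.lo + starts[i] + lead), stripped)
            )
        truth_regions.append((rid, params.a, params.b, params.c))
        for sub in subs_by_region.get(rid, pd.DataFrame()).itertuples():
            subset = np.arange(int(sub.lo - region.lo), int(sub.hi - region.lo))
            dist = level_distribution(params, rho, dgap, subset)
            lv = dist.levels
            mml = float((lv * dist.p).sum())
            pk = dist.p[dist.p > 0]
            nme = float(-(pk * np.log2(pk)).sum() / np.log2(dist.K + 1)) if dist.K >= 1 else np.nan
            truth_subs.append((int(sub.sub_id), rid, mml, nme))
    reads = ReadSet(pd.DataFrame(rows, columns=["chrom", "read_id", "start", "calls"]))
    truth = SimulationTruth(
        regions=pd.DataFrame(truth_regions, columns=["region_id", "a", "b", "c"]),
        subregions=pd.DataFrame(truth_subs, columns=["sub_id", "region_id", "mml", "nme"]),
    )
    return reads, truth


def _mode_label(labels: np.ndarray) -> str:
    vals, counts = np.unique(labels.astype(str), return_counts=True)
    order = np.lexsort((vals, -counts))  # most frequent, ties alphabetical
    return str(vals[order[0]])


def region_labels(cmap: CpGMap, partition: RegionPartition, level: str = "subregions") -> pd.Series:
    """Majority feature label of each (sub)region's CpG sites."""
    frame = partition.subregions if level == "subregions" else partition.regions
    key = "sub_id" if level == "subregions" else "region_id"
    out = {}
    for row in frame.itertuples():
        lab = cmap.feature[row.chrom][int(row.lo) : int(row.hi)]
        out[int(getattr(row, key))] = _mode_label(lab)
    return pd.Series(out, name="label")


@dataclass
class TumorNormalPair:
    """Paired synthetic samples with planted differential structure."""

    normal: ReadSet
    tumor: ReadSet
    normal_truth: SimulationTruth
    tumor_truth: SimulationTruth
    partition: RegionPartition
    subregion_labels: pd.Series
    config: dict = field(default_factory=dict)


def profile_parameters(label: str, sample: str) -> IsingParameters:
    """Ising parameters assigned to a region of majority feature ``label``."""
    a = NORMAL_FIELD[label]
    if sample == "normal":
        return IsingParameters(a=a, b=0.0, c=NORMAL_COUPLING)
    if sample == "tumor":
        if label == "bivalent_promoter":
            return IsingParameters(a=TUMOR_BIVALENT_FIELD, b=0.0, c=TUMOR_COUPLING)
        return IsingParameters(a=a * TUMOR_FIELD_SHRINK, b=0.0, c=TUMOR_COUPLING)
    raise ValueError(f"unknown sample profile {sample!r}")


def make_tumor_normal_pair(
    cmap: CpGMap,
    seed: int = 0,
    depth: float = 10.0,
    read_span: int = 10,
    miss_rate: float = 0.05,
    est_span: int = 3000,
    sub_span: int = 150,
) -> TumorNormalPair:
    """Simulate a paired normal/tumor dataset with planted differences.

    Normal: strongly methylated open sea, strongly unmethylated islands,
    high cooperativity.  Tumor: all fields shrunk toward zero and
    cooperativity reduced (global hypomethylation, globally higher entropy),
    except bivalent-promoter regions whose field flips positive (focal
    hypermethylation).  All profile constants are recorded in ``config``.
    """
    partition = partition_genome(cmap, est_span=est_span, sub_span=sub_span)
    reg_labels = region_labels(cmap, partition, level="regions")
    present = set(region_labels(cmap, partition, level="subregions").unique())
    required = {"island", "shore", "shelf", "open_sea", "bivalent_promoter", "heterochromatin"}
    missing = required - present
    if missing:
        raise ValueError(f"map lacks subregions of feature class(es): {sorted(missing)}")
    normal_params = {rid: profile_parameters(lab, "normal") for rid, lab in reg_labels.items()}
    tumor_params = {rid: profile_parameters(lab, "tumor") for rid, lab in reg_labels.items()}
    normal, normal_truth = simulate_reads(
        cmap, partition, normal_params, depth, read_span, miss_rate, seed=seed * 2 + 1, read_prefix="n"
    )
    tumor, tumor_truth = simulate_reads(
        cmap, partition, tumor_params, depth, read_span, miss_rate, seed=seed * 2 + 2, read_prefix="t"
    )
    config = {
        "seed": seed,
        "depth": depth,
        "read_span": read_span,
        "miss_rate": miss_rate,
        "est_span": est_span,
        "sub_span": sub_span,
        "normal_field": dict(NORMAL_FIELD),
        "normal_coupling": NORMAL_COUPLING,
        "tumor_field_shrink": TUMOR_FIELD_SHRINK,
        "tumor_coupling": TUMOR_COUPLING,
        "tumor_bivalent_field": TUMOR_BIVALENT_FIELD,
    }
    return TumorNormalPair(
        normal=normal,
        tumor=tumor,
        normal_truth=normal_truth,
        tumor_truth=tumor_truth,
        partition=partition,
        subregion_labels=region_labels(cmap, partition, level="subregions"),
        config=config,
    )


def make_gene_table(partition: RegionPartition, seed: int = 0, body_bp: int = 2000) -> pd.DataFrame:
    """One synthetic gene per estimation region, TSS at the region center.

    Strand alternates deterministically with the region index; for '+'
    genes the body runs downstream of the TSS, for '-' genes upstream, so
    strand-aware promoter windows and meta-profiles are exercised.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, region in enumerate(partition.regions.itertuples()):
        mid = int((region.start + region.end) // 2)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            s, e = mid, mid + body_bp
        else:
            s, e = max(0, mid - body_bp), mid
        rows.append((region.chrom, s, e, f"g{i:04d}", 0, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "score", "strand"])
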