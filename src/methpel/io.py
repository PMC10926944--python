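"""File formats, genome partitioning, and per-region read assembly.

Formats
-------
* **Epiread TSV** — one read per line: ``chrom  read_id  first_cpg_index
  calls`` where ``calls`` is a string over {M, U, .} covering consecutive
  CpG units (index is the 0-based ordinal of the CpG on its chromosome).
* **CpG map TSV** — BED-like: ``chrom  start  end  rho  feature`` per CpG
  dinucleotide (0-based half-open, end = start + 2), preceded by
  ``#length <chrom> <bp>`` header lines.
* **BED** — annotations and genes (0-based half-open; label in column 4,
  strand in column 6 when present).
* **bedGraph** — one value per analysis subregion, 6-decimal formatting.

Coordinates: CpG positions are 1-based internally (position of the C);
every file on disk is 0-based half-open.  CpGs are strand-collapsed, one
unit per CpG dinucleotide, matching the symmetric-methylation convention
of bisulfite analysis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ising import RegionReads, pack_fragments

logger = logging.getLogger(__name__)

CALL_RE = re.compile(r"^[MU](?:[MU.]*[MU])?$")
FEATURE_VOCAB = ("island", "shore", "shelf", "open_sea", "bivalent_promoter", "heterochromatin", "none")

#: window half-width (bp) for the local CpG density covariate rho_n
DENSITY_HALF_WINDOW = 500


@dataclass
class CpGMap:
    """Strand-collapsed CpG coordinates with density/spacing covariates.

    ``pos`` holds 1-based positions, strictly increasing per chromosome;
    ``rho`` the local CpG density in [0, 1]; ``feature`` a per-site label
    from :data:`FEATURE_VOCAB`.
    """

    lengths: dict[str, int]
    pos: dict[str, np.ndarray]
    rho: dict[str, np.ndarray]
    feature: dict[str, np.ndarray]

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    @property
    def n_sites(self) -> int:
        return sum(len(p) for p in self.pos.values())

    def spacing(self, chrom: str) -> np.ndarray:
        """d_n = distance (bp) between consecutive CpGs; length N - 1."""
        return np.diff(self.pos[chrom]).astype(float)

    def validate(self) -> None:
        for chrom in self.chroms:
            p = self.pos[chrom]
            if len(p) and (np.any(np.diff(p) < 2) or p[0] < 1 or p[-1] > self.lengths[chrom]):
                raise ValueError(f"{chrom}: CpG positions must be strictly increasing (gap >= 2) and in range")
            if np.any(self.rho[chrom] < 0) or np.any(self.rho[chrom] > 1):
                raise ValueError(f"{chrom}: rho outside [0, 1]")


def cpg_density(pos: np.ndarray) -> np.ndarray:
    """rho_n = (# CpGs within +/-500 bp of site n) / 500, clipped to [0, 1]."""
    pos = np.asarray(pos, dtype=np.int64)
    hi = np.searchsorted(pos, pos + DENSITY_HALF_WINDOW, side="right")
    lo = np.searchsorted(pos, pos - DENSITY_HALF_WINDOW, side="left")
    return np.clip((hi - lo) / DENSITY_HALF_WINDOW, 0.0, 1.0)


def write_cpg_map(cmap: CpGMap, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in cmap.lengths.items():
            fh.write(f"#length\t{chrom}\t{length}\n")
        for chrom in cmap.chroms:
            for p, r, lab in zip(cmap.pos[chrom], cmap.rho[chrom], cmap.feature[chrom]):
                fh.write(f"{chrom}\t{p - 1}\t{p + 1}\t{r:.6f}\t{lab}\n")


def read_cpg_map(path) -> CpGMap:
    lengths: dict[str, int] = {}
    rows: dict[str, list[tuple[int, float, str]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#length"):
                _, chrom, length = line.rstrip("\n").split("\t")
                lengths[chrom] = int(length)
                continue
            chrom, start, _end, rho, lab = line.rstrip("\n").split("\t")
            rows.setdefault(chrom, []).append((int(start) + 1, float(rho), lab))
    cmap = CpGMap(
        lengths=lengths,
        pos={c: np.array([r[0] for r in v], dtype=np.int64) for c, v in rows.items()},
        rho={c: np.array([r[1] for r in v]) for c, v in rows.items()},
        feature={c: np.array([r[2] for r in v], dtype=object) for c, v in rows.items()},
    )
    cmap.validate()
    return cmap


@dataclass
class ReadSet:
    """Read-level methylation calls, one row per read.

    Columns: ``chrom``, ``read_id``, ``start`` (0-based CpG ordinal on the
    chromosome), ``calls`` (string over {M, U, .}; first/last characters are
    observed calls).
    """

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "read_id", "start", "calls"])
    )

    @property
    def n_reads(self) -> int:
        return len(self.df)

    @property
    def n_calls(self) -> int:
        """Total observed (M + U) calls."""
        return int(self.df["calls"].str.count("[MU]").sum()) if len(self.df) else 0


def read_epireads(path) -> ReadSet:
    """Parse an epiread TSV, rejecting malformed rows (hard error above 10%)."""
    rows, bad = [], 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4 or not CALL_RE.match(parts[3]) or not parts[2].lstrip("-").isdigit() or int(parts[2]) < 0:
                bad += 1
                logger.debug("rejected epiread row %d: %r", ln, line)
                continue
            rows.append((parts[0], parts[1], int(parts[2]), parts[3]))
    total = len(rows) + bad
    if bad:
        logger.warning("rejected %d/%d malformed epiread rows in %s", bad, total, path)
    if total and bad / total > 0.10:
        raise ValueError(f"{path}: {bad}/{total} malformed rows exceeds the 10% tolerance")
    if not rows:
        logger.warning("empty epiread file: %s", path)
        return ReadSet()
    return ReadSet(pd.DataFrame(rows, columns=["chrom", "read_id", "start", "calls"]))


def write_epireads(reads: ReadSet, path) -> None:
    reads.df.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class RegionPartition:
    """Estimation regions tiling the genome, with nested analysis subregions.

    ``regions``:    region_id, chrom, start, end, lo, hi
    ``subregions``: sub_id, region_id, chrom, start, end, lo, hi, K
    where [start, end) is 0-based genomic and [lo, hi) the chromosome-level
    CpG ordinal range.  Every CpG belongs to exactly one region and one
    subregion; CpG-free windows are dropped.
    """

    regions: pd.DataFrame
    subregions: pd.DataFrame
    est_span: int
    sub_span: int


def partition_genome(cmap: CpGMap, est_span: int = 3000, sub_span: int = 150) -> RegionPartition:
    """Tile each chromosome into estimation regions and analysis subregions."""
    if est_span % sub_span != 0:
        raise ValueError("est_span must be a multiple of sub_span")
    cmap.validate()
    regions, subs = [], []
    rid = sid = 0
    for chrom in cmap.chroms:
        pos0 = cmap.pos[chrom] - 1  # 0-based
        length = cmap.lengths[chrom]
        for w_start in range(0, length, est_span):
            w_end = min(w_start + est_span, length)
            lo = int(np.searchsorted(pos0, w_start, side="left"))
            hi = int(np.searchsorted(pos0, w_end, side="left"))
            if hi == lo:
                continue
            regions.append((rid, chrom, w_start, w_end, lo, hi))
            for s_start in range(w_start, w_end, sub_span):
                s_end = min(s_start + sub_span, w_end)
                slo = int(np.searchsorted(pos0, s_start, side="left"))
                shi = int(np.searchsorted(pos0, s_end, side="left"))
                if shi == slo:
                    continue
                subs.append((sid, rid, chrom, s_start, s_end, slo, shi, shi - slo))
                sid += 1
            rid += 1
    return RegionPartition(
        regions=pd.DataFrame(regions, columns=["region_id", "chrom", "start", "end", "lo", "hi"]),
        subregions=pd.DataFrame(
            subs, columns=["sub_id", "region_id", "chrom", "start", "end", "lo", "hi", "K"]
        ),
        est_span=est_span,
        sub_span=sub_span,
    )


def region_covariates(cmap: CpGMap, region: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """(rho, d) slices of one estimation region's chain."""
    chrom, lo, hi = region["chrom"], int(region["lo"]), int(region["hi"])
    rho = cmap.rho[chrom][lo:hi]
    d = np.diff(cmap.pos[chrom][lo:hi]).astype(float)
    return rho, d


def assemble_region_reads(reads: ReadSet, partition: RegionPartition, cmap: CpGMap) -> dict[int, RegionReads]:
    """Split reads at estimation-region boundaries and pack them per region.

    A read spanning a boundary is split into independent fragments, one per
    region, so each region's likelihood stays self-contained.  Returns a dict
    region_id -> :class:`RegionReads` (regions without reads are absent).
    """
    frags: dict[int, list[tuple[int, str]]] = {}
    n_sites = {int(r.region_id): int(r.hi - r.lo) for r in partition.regions.itertuples()}
    for chrom, grp in reads.df.groupby("chrom", sort=False):
        if chrom not in cmap.pos:
            raise ValueError(f"reads reference unknown chromosome {chrom}")
        n_cpg = len(cmap.pos[chrom])
        regs = partition.regions[partition.regions["chrom"] == chrom]
        reg_lo = regs["lo"].to_numpy()
        reg_hi = regs["hi"].to_numpy()
        reg_ids = regs["region_id"].to_numpy()
        starts = grp["start"].to_numpy(dtype=np.int64)
        lens = grp["calls"].str.len().to_numpy(dtype=np.int64)
        if np.any(starts < 0) or np.any(starts + lens > n_cpg):
            raise ValueError(f"{chrom}: read CpG indices outside the map bounds")
        for start, calls in zip(starts, grp["calls"]):
            end = start + len(calls)
            i = int(np.searchsorted(reg_hi, start, side="right"))
            while i < len(reg_ids) and reg_lo[i] < end:
                a, b = max(start, reg_lo[i]), min(end, reg_hi[i])
                if a < b:
                    frags.setdefault(int(reg_ids[i]), []).append(
                        (int(a - reg_lo[i]), calls[a - start : b - start])
                    )
                i += 1
    packed = {}
    for rid, lst in frags.items():
        rr = pack_fragments(lst, n_sites[rid])
        if rr.n_reads:
            packed[rid] = rr
    return packed


def write_track(subregions: pd.DataFrame, values: np.ndarray, path, name: str = "track") -> None:
    """Write one value per subregion as bedGraph; NaN intervals are omitted."""
    values = np.asarray(values, dtype=float)
    if len(values) != len(subregions):
        raise ValueError("need exactly one value per subregion")
    n_nan = int(np.isnan(values).sum())
    if n_nan:
        logger.info("write_track(%s): omitting %d NaN intervals", name, n_nan)
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name={name}\n")
        for (_, row), v in zip(subregions.iterrows(), values):
            if np.isnan(v):
                continue
            fh.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t{v:.6f}\n")


def read_track(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, start, end, value = line.rstrip("\n").split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_params_table(fits: dict, partition: RegionPartition, path) -> None:
    """Per-region Ising parameter table (TSV), one row per fitted region."""
    rows = []
    for region in partition.regions.itertuples():
        rid = int(region.region_id)
        if rid not in fits:
            continue
        fit = fits[rid]
        rows.append(
            (
                region.chrom, int(region.start), int(region.end), rid,
                fit.params.a, fit.params.b, fit.params.c,
                fit.log_likelihood, fit.n_reads, int(fit.converged),
            )
        )
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "region_id", "a", "b", "c", "log_likelihood", "n_reads", "converged"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_params_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass
class AnnotationSet:
    """Named interval tracks (0-based half-open after ingestion)."""

    tracks: dict[str, pd.DataFrame] = field(default_factory=dict)

    def add(self, name: str, df: pd.DataFrame) -> None:
        required = {"chrom", "start", "end", "label"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation track needs columns {sorted(required)}")
        self.tracks[name] = df.reset_index(drop=True)


def read_bed(path, track_name: str | None = None) -> pd.DataFrame:
    """Read BED (>= 4 columns); column 4 becomes ``label``, 6 ``strand``."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "label", "score", "strand"][: df.shape[1]]
    df.columns = names
    if "label" not in df.columns:
        df["label"] = track_name or "interval"
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "label", "score", "strand"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
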