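"""Gene ranking, permutation significance, feature summaries, meta-profiles."""

import numpy as np
import pandas as pd
import pytest

from methpel.ranking import (
    bh_adjust,
    feature_summary,
    meta_profile,
    permutation_pvalue,
    rank_genes,
)
from oracles import direct_bh


def toy_diff(n=20, span=150):
    return pd.DataFrame(
        {
            "sub_id": range(n),
            "region_id": [i // 5 for i in range(n)],
            "chrom": "chr1",
            "start": np.arange(n) * span,
            "end": (np.arange(n) + 1) * span,
            "K": 2,
            "jsd": 0.0,
            "dnme": 0.0,
            "dmml": 0.0,
        }
    )


def gene_row(name, start, end, strand="+"):
    return {"chrom": "chr1", "start": start, "end": end, "label": name, "score": 0, "strand": strand}


class TestBH:
    def test_matches_direct_construction(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            p = rng.uniform(0, 1, int(rng.integers(1, 60)))
            assert bh_adjust(p) == pytest.approx(direct_bh(p), abs=1e-12)

    def test_monotone_with_p(self):
        p = np.array([0.001, 0.2, 0.04, 0.9, 0.04])
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestRankGenes:
    def test_planted_max_gene_ranks_first(self):
        diff = toy_diff()
        diff.loc[7, "jsd"] = 0.9  # subregion [1050, 1200)
        genes = pd.DataFrame([gene_row("hit", 1000, 3000), gene_row("cold", 10_000, 12_000)])
        out = rank_genes(diff, genes, mode="promoter_jsd", window=500)
        assert out.loc[out["gene"] == "hit", "rank"].iloc[0] == 1

    def test_all_zero_ties_resolved_positionally(self):
        diff = toy_diff()
        genes = pd.DataFrame(
            [gene_row("b", 1500, 2500), gene_row("a", 100, 600), gene_row("c", 2600, 2900)]
        )
        out = rank_genes(diff, genes, mode="promoter_jsd", window=300)
        ranked = out.sort_values("rank")
        assert list(ranked["gene"]) == ["a", "b", "c"]  # genomic order
        assert (out["statistic"].dropna() == 0).all()

    def test_input_order_invariance(self):
        diff = toy_diff()
        diff.loc[3, "jsd"] = 0.5
        diff.loc[12, "jsd"] = 0.8
        genes = pd.DataFrame(
            [gene_row("g1", 300, 700), gene_row("g2", 1700, 2100), gene_row("g3", 2500, 2800)]
        )
        out_fwd = rank_genes(diff, genes, window=400)
        out_rev = rank_genes(diff, genes.iloc[::-1].reset_index(drop=True), window=400)
        merged = out_fwd.merge(out_rev, on="gene", suffixes=("_f", "_r"))
        assert (merged["rank_f"] == merged["rank_r"]).all()

    def test_unscored_genes_reported_separately(self):
        diff = toy_diff()
        diff["jsd"] = np.nan
        genes = pd.DataFrame([gene_row("g1", 100, 600)])
        out = rank_genes(diff, genes)
        assert not out["scored"].iloc[0]
        assert np.isnan(out["rank"].iloc[0])

    def test_empty_gene_table_rejected(self):
        with pytest.raises(ValueError):
            rank_genes(toy_diff(), pd.DataFrame(columns=["chrom", "start", "end", "label"]))


class TestPermutation:
    def region(self):
        rho = np.full(6, 0.02)
        d = np.full(5, 40.0)
        return rho, d

    def reads_from(self, a, c, n, seed):
        from methpel import _dp
        from methpel.ising import IsingParameters

        rho, d = self.region()
        params = IsingParameters(a, 0, c)
        alpha, beta = params.alpha(rho), params.beta(d)
        f = _dp.forward_messages(alpha, beta)
        b = _dp.backward_messages(alpha, beta)
        rng = np.random.default_rng(seed)
        spins = _dp.sample_windows(alpha, beta, f, b, np.zeros(n, dtype=np.int64), 6, rng.random((n, 6)))
        return [(0, "".join("M" if s == 1 else "U" for s in row)) for row in spins]

    def test_low_n_perm_rejected(self):
        rho, d = self.region()
        with pytest.raises(ValueError):
            permutation_pvalue([(0, "MMM")] * 10, [(0, "UUU")] * 10, rho, d, n_perm=0)

    def test_strong_difference_attains_minimum_p(self):
        rho, d = self.region()
        frags_a = self.reads_from(2.5, 2.0, 40, seed=1)
        frags_b = self.reads_from(-2.5, 2.0, 40, seed=2)
        p = permutation_pvalue(frags_a, frags_b, rho, d, n_perm=199, seed=3, starts=((0.0, 0.0, 0.0),))
        assert p == pytest.approx(1 / 200)

    def test_tiny_groups_undefined(self):
        rho, d = self.region()
        p = permutation_pvalue([(0, "MUMUMU")] * 2, [(0, "UMUMUM")] * 30, rho, d, n_perm=100)
        assert np.isnan(p)


class TestFeatureSummary:
    def test_single_label_equals_genome_wide(self):
        diff = toy_diff()
        rng = np.random.default_rng(41)
        diff["jsd"] = rng.uniform(0, 1, len(diff))
        diff["dmml"] = rng.uniform(-1, 1, len(diff))
        diff["dnme"] = rng.uniform(-1, 1, len(diff))
        ann = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 10_000, "label": "everything"}])
        out = feature_summary(diff, ann)
        assert len(out) == 1
        assert out["n"].iloc[0] == len(diff)
        assert out["median_jsd"].iloc[0] == pytest.approx(diff["jsd"].median())

    def test_uncovered_subregions_labelled_none(self):
        diff = toy_diff()
        ann = pd.DataFrame(columns=["chrom", "start", "end", "label"])
        out = feature_summary(diff, ann)
        assert list(out["label"]) == ["none"]
        assert out["n"].iloc[0] == len(diff)

    def test_counts_partition_subregions(self):
        diff = toy_diff()
        ann = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 0, "end": 1500, "label": "left"},
                {"chrom": "chr1", "start": 1500, "end": 3000, "label": "right"},
            ]
        )
        out = feature_summary(diff, ann)
        assert out["n"].sum() == len(diff)


class TestMetaProfile:
    def test_constant_track(self):
        diff = toy_diff()
        diff["jsd"] = 0.42
        anchors = pd.DataFrame([{"chrom": "chr1", "tss": 1500, "strand": "+"}])
        prof = meta_profile(diff, "jsd", anchors, window=1500, n_bins=10, sub_span=150)
        filled = prof.dropna(subset=["mean"])
        assert filled["mean"].to_numpy() == pytest.approx(0.42)
        assert filled["n"].sum() > 0

    def test_minus_strand_flips_sign(self):
        diff = toy_diff()
        diff.loc[12, "jsd"] = 1.0  # midpoint 1875, downstream of TSS at 1500
        anchors = pd.DataFrame([{"chrom": "chr1", "tss": 1500, "strand": "-"}])
        prof = meta_profile(diff, "jsd", anchors, window=1000, n_bins=4, sub_span=150)
        hot = prof.loc[prof["mean"].idxmax()]
        assert hot["mean"] > 0
        assert hot["bin_center"] < 0  # genomically above the minus-strand TSS = upstream

    def test_window_smaller_than_span_rejected(self):
        diff = toy_diff()
        anchors = pd.DataFrame([{"chrom": "chr1", "tss": 1500}])
        with pytest.raises(ValueError):
            meta_profile(diff, "jsd", anchors, window=100, n_bins=4, sub_span=150)

    def test_empty_anchors_rejected(self):
        with pytest.raises(ValueError):
            meta_profile(toy_diff(), "jsd", pd.DataFrame(columns=["chrom", "tss"]), window=1000)
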