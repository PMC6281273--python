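import numpy as np
import pandas as pd
import pytest

from longmeth import integration as integ
from oracles import binom_two_sided, fisher_one_sided


def gene(gene_id="g1", chrom="chr1", start=10_000, end=30_000, strand="+"):
    tss = start if strand == "+" else end - 1
    return pd.Series(
        {"gene_id": gene_id, "chrom": chrom, "start": start, "end": end,
         "strand": strand, "tss": tss}
    )


class TestPromoterRegion:
    def test_plus_strand(self):
        assert integ.promoter_region(gene(start=10_000)) == (5_000, 10_100)

    def test_minus_strand_mirror(self):
        g = gene(start=0, end=10_001, strand="-")  # tss = 10,000
        assert integ.promoter_region(g) == (9_900, 15_001)

    def test_clipped_at_chromosome_start(self):
        assert integ.promoter_region(gene(start=1_000, end=20_000)) == (0, 1_100)


class TestUiDmrRegion:
    def test_plus_strand(self):
        assert integ.uidmr_region(gene(start=10_000, end=30_000)) == (10_300, 18_000)

    def test_short_gene_excluded(self):
        assert integ.uidmr_region(gene(start=10_000, end=22_000)) is None

    def test_minus_strand_mirror(self):
        g = gene(start=10_000, end=30_001, strand="-")  # tss = 30,000
        start, end = integ.uidmr_region(g)
        assert (start, end) == (22_001, 29_701)
        assert end - start == 18_000 - 10_300

    def test_never_overlaps_promoter_same_gene(self):
        for strand in "+-":
            g = gene(start=50_000, end=80_000, strand=strand)
            ps, pe = integ.promoter_region(g)
            us, ue = integ.uidmr_region(g)
            assert ue <= ps or us >= pe


class TestClassifyCgis:
    def _setup(self):
        genes = pd.DataFrame([gene(start=10_000, end=30_000)]).reset_index(drop=True)
        promoters = integ.promoter_track(genes)
        return genes, promoters

    def test_promoter_precedence(self):
        genes, promoters = self._setup()
        # CGI spanning the TSS overlaps both promoter and gene body
        cgis = pd.DataFrame({"chrom": ["chr1"], "start": [9_500], "end": [10_500]})
        assert integ.classify_cgis(cgis, promoters, genes).tolist() == ["promoter"]

    def test_gene_body_only(self):
        genes, promoters = self._setup()
        cgis = pd.DataFrame({"chrom": ["chr1"], "start": [20_000], "end": [20_500]})
        assert integ.classify_cgis(cgis, promoters, genes).tolist() == ["gene"]

    def test_gene_desert(self):
        genes, promoters = self._setup()
        cgis = pd.DataFrame({"chrom": ["chr1"], "start": [90_000], "end": [90_500]})
        assert integ.classify_cgis(cgis, promoters, genes).tolist() == ["intergenic"]

    def test_labels_partition_cgi_set(self):
        genes, promoters = self._setup()
        rng = np.random.default_rng(2)
        starts = rng.integers(0, 100_000, 50)
        cgis = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 300})
        labels = integ.classify_cgis(cgis, promoters, genes)
        assert len(labels) == 50
        assert set(labels) <= {"promoter", "gene", "intergenic"}


def gene_calls(rows):
    """rows: (gene_id, n_dmrs, avg_delta)."""
    df = pd.DataFrame(rows, columns=["gene_id", "n_dmrs", "avg_delta_pp"])
    df["retained"] = (df["n_dmrs"] >= 2) & (df["avg_delta_pp"].abs() >= 10)
    df["direction"] = np.where(df["avg_delta_pp"] >= 0, "hyper", "hypo")
    return df


def expression(rows):
    """rows: (gene_id, log2fc, is_de)."""
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "is_de"])
    df["p_adj"] = np.where(df["is_de"], 0.01, 0.5)
    df["is_expressed"] = True
    return df


class TestQuadrants:
    def test_nine_of_ten_down_matches_exact_binomial(self):
        calls = gene_calls([(f"g{i}", 2, 25.0) for i in range(10)])
        expr = expression(
            [(f"g{i}", -1.0, True) for i in range(9)] + [("g9", 1.0, True)]
        )
        res = integ.methylation_expression_quadrants(calls, expr)
        assert (res["n_hyper_down"], res["n_hyper_up"]) == (9, 1)
        assert res["binomial_p"] == pytest.approx(22 / 1024, rel=1e-12)
        assert res["binomial_p"] == pytest.approx(binom_two_sided(9, 10), rel=1e-12)

    def test_balanced_split_p_one(self):
        calls = gene_calls([(f"g{i}", 2, 25.0) for i in range(10)])
        expr = expression(
            [(f"g{i}", -1.0, True) for i in range(5)]
            + [(f"g{i}", 1.0, True) for i in range(5, 10)]
        )
        res = integ.methylation_expression_quadrants(calls, expr)
        assert res["binomial_p"] == pytest.approx(1.0)

    def test_below_cutoff_genes_excluded_from_quadrants(self):
        calls = gene_calls([("g1", 2, 25.0), ("g2", 2, 5.0)])
        expr = expression([("g1", -1.0, True), ("g2", -1.0, True)])
        res = integ.methylation_expression_quadrants(calls, expr)
        assert sum(res["quadrants"].values()) == 1

    def test_no_hyper_de_genes_flagged_undefined(self):
        calls = gene_calls([("g1", 2, -25.0)])
        expr = expression([("g1", -1.0, True)])
        res = integ.methylation_expression_quadrants(calls, expr)
        assert res["binomial_undefined"] and np.isnan(res["binomial_p"])

    def test_type_i_control_under_null_coupling(self):
        """With P(down|hyper) = 0.5 the binomial quadrant test rejects at
        about the nominal rate (exact test, hence conservative)."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_sims = 400
        calls = gene_calls([(f"g{i}", 2, 25.0) for i in range(60)])
        for _ in range(n_sims):
            expr = expression(
                [(f"g{i}", float(rng.choice([-1.0, 1.0])), True) for i in range(60)]
            )
            res = integ.methylation_expression_quadrants(calls, expr)
            rejections += res["binomial_p"] < 0.05
        assert rejections / n_sims <= 0.055 + 3 * np.sqrt(0.05 * 0.95 / n_sims)


class TestUiDmrVariant:
    def test_single_dmr_on_uidmr_suffices(self):
        genes = pd.DataFrame([gene(start=10_000, end=30_000)])
        dmrs = pd.DataFrame(
            [(0, "chr1", 11_000, 11_800, 22.0, True)],
            columns=["window_id", "chrom", "start", "end", "delta_pp", "is_dmr"],
        )
        out = integ.genes_with_uidmr_dmrs(dmrs, genes)
        assert out.iloc[0]["n_dmrs"] == 1 and out.iloc[0]["retained"]

    def test_dmr_outside_uidmr_ignored(self):
        genes = pd.DataFrame([gene(start=10_000, end=30_000)])
        dmrs = pd.DataFrame(
            [(0, "chr1", 25_000, 26_000, 22.0, True)],  # inside gene, past +8 kb
            columns=["window_id", "chrom", "start", "end", "delta_pp", "is_dmr"],
        )
        out = integ.genes_with_uidmr_dmrs(dmrs, genes)
        assert out.iloc[0]["n_dmrs"] == 0

    def test_short_genes_absent_from_output(self):
        genes = pd.DataFrame([gene(start=10_000, end=20_000)])
        dmrs = pd.DataFrame(
            columns=["window_id", "chrom", "start", "end", "delta_pp", "is_dmr"]
        )
        assert len(integ.genes_with_uidmr_dmrs(dmrs, genes)) == 0


class TestTranscriptomeConcordance:
    def test_perfect_concordance_matches_enumeration(self):
        ids = [f"g{i}" for i in range(30)]
        a = pd.Series([1.0] * 15 + [-1.0] * 15, index=ids)
        b = pd.Series([0.5] * 15 + [-0.5] * 15, index=ids)
        res = integ.transcriptome_concordance(a, b)
        assert res["p_directionality"] == pytest.approx(1 / 155117520, rel=1e-9)

    def test_anticoncordant_p_near_one(self):
        ids = [f"g{i}" for i in range(30)]
        a = pd.Series([1.0] * 15 + [-1.0] * 15, index=ids)
        b = pd.Series([-0.5] * 15 + [0.5] * 15, index=ids)
        res = integ.transcriptome_concordance(a, b)
        assert res["p_directionality"] == pytest.approx(1.0)

    def test_overlap_test_uses_expressed_universe(self):
        a = pd.Series([1.0] * 10, index=[f"g{i}" for i in range(10)])
        b = pd.Series([1.0] * 10, index=[f"g{i}" for i in range(5, 15)])
        res = integ.transcriptome_concordance(a, b, universe_size=100)
        oracle = fisher_one_sided([[5, 5], [5, 85]])
        assert res["p_overlap"] == pytest.approx(oracle, rel=1e-9)

    def test_empty_intersection_rejected(self):
        a = pd.Series([1.0], index=["g1"])
        b = pd.Series([1.0], index=["g2"])
        with pytest.raises(ValueError, match="shared"):
            integ.transcriptome_concordance(a, b)

    def test_independent_signs_give_unremarkable_p(self):
        rng = np.random.default_rng(31)
        ps = []
        ids = [f"g{i}" for i in range(80)]
        for _ in range(200):
            a = pd.Series(rng.choice([-1.0, 1.0], 80), index=ids)
            b = pd.Series(rng.choice([-1.0, 1.0], 80), index=ids)
            ps.append(integ.transcriptome_concordance(a, b)["p_directionality"])
        assert np.mean(np.array(ps) < 0.05) < 0.1
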