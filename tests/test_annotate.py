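"""Annotation analyses: contexts, islands, profiles, preference, metaplots."""

import numpy as np
import pytest

import bsmeth as b
from bsmeth.annotate import (
    classify_context,
    context_preference_matrix,
    expression_methylation_curves,
    find_methylated_islands,
    gene_methylation_classes,
    genic_region_profile,
    island_region_stats,
    te_methylation_profile,
)
from bsmeth.types import CytosineSite, GeneModel, Genome, GenomicInterval


def cg_site(chrom, pos, m, n, strand="+", context="CG", called=True):
    return CytosineSite(chrom, pos, strand, context, m, n, 0.001, 0.001, called)


class TestClassifyContext:
    def test_examples(self):
        g = Genome({"c": "ACGTACAGTACTAT"})
        assert classify_context(g, "c", 1, "+") == "CG"
        assert classify_context(g, "c", 5, "+") == "CHG"
        assert classify_context(g, "c", 10, "+") == "CHH"

    def test_non_cytosine_rejected(self):
        g = Genome({"c": "ACGT"})
        with pytest.raises(ValueError, match="not a cytosine"):
            classify_context(g, "c", 0, "+")
        with pytest.raises(ValueError):
            classify_context(g, "c", 1, "-")  # C on Watson is not Crick C


class TestGenicProfile:
    @pytest.fixture
    def gene(self):
        exons = (
            GenomicInterval("c", 5000, 5200),
            GenomicInterval("c", 5400, 5600),
            GenomicInterval("c", 5800, 6000),
            GenomicInterval("c", 6200, 6400),
        )
        return GeneModel("g1", "c", "+", exons)

    def test_upstream_assignment(self, gene):
        res = genic_region_profile([cg_site("c", 4900, 5, 5)], [gene], flank_len=2000)
        assert res.genic.iloc[0]["region"] == "upstream"
        assert res.n_unassigned == 0

    def test_exon_intron_labels(self, gene):
        sites = [
            cg_site("c", 5100, 5, 5),   # first exon
            cg_site("c", 5300, 5, 5),   # first intron
            cg_site("c", 5500, 5, 5),   # internal exon
            cg_site("c", 5700, 5, 5),   # internal intron
            cg_site("c", 6300, 5, 5),   # last exon
            cg_site("c", 6500, 5, 5),   # downstream
        ]
        res = genic_region_profile(sites, [gene], flank_len=2000)
        got = dict(zip(res.genic["region"], res.genic["n_sites"]))
        assert got == {
            "first exon": 1, "first intron": 1, "internal exons": 1,
            "internal introns": 1, "last exon": 1, "downstream": 1,
        }

    def test_single_exon_gene_all_first_exon(self):
        gene = GeneModel("g", "c", "+", (GenomicInterval("c", 100, 400),))
        sites = [cg_site("c", p, 5, 5) for p in (150, 250, 350)]
        res = genic_region_profile(sites, [gene])
        assert list(res.genic["region"]) == ["first exon"]
        assert res.genic.iloc[0]["n_sites"] == 3

    def test_unassigned_counted(self, gene):
        sites = [cg_site("c", 100, 5, 5), cg_site("c", 5100, 5, 5)]
        res = genic_region_profile(sites, [gene], flank_len=2000)
        assert res.n_unassigned == 1
        assert res.genic["n_sites"].sum() + res.n_unassigned == 2

    def test_minus_strand_orientation(self):
        exons = (GenomicInterval("c", 1000, 1200), GenomicInterval("c", 1400, 1600))
        gene = GeneModel("g", "c", "-", exons)
        # 5'-most exon of a minus gene is the genomically last one
        res = genic_region_profile([cg_site("c", 1500, 5, 5)], [gene])
        assert res.genic.iloc[0]["region"] == "first exon"

    def test_repeat_tally(self, gene):
        tes = [GenomicInterval("c", 5050, 5150, ".", "TE1")]
        res = genic_region_profile([cg_site("c", 5100, 5, 5)], [gene], repeats=tes)
        assert res.repeats.iloc[0]["n_sites"] == 1


def _island_fixture(methylated: bool):
    """AT-rich background with one 300-bp CpG-rich block at [1000, 1300)."""
    rng = np.random.default_rng(31)
    bg = rng.choice(list("AT"), size=2300)
    block = "".join(rng.choice(["CG", "GC", "CA", "TG"], size=150, p=[0.45, 0.25, 0.15, 0.15]))
    seq = "".join(bg[:1000]) + block + "".join(bg[1000:])
    g = Genome({"c": seq})
    sites = []
    for pos in range(1000, 1300):
        if seq[pos] == "C" and b.context_of(seq, pos, "+") == "CG":
            m = 10 if methylated else 0
            sites.append(CytosineSite("c", pos, "+", "CG", m, 10))
    return g, sites


class TestIslands:
    def test_methylated_block_gives_one_island(self):
        g, sites = _island_fixture(methylated=True)
        islands = find_methylated_islands(g, sites)
        assert len(islands) == 1
        isl = islands[0]
        # the island covers the designed block up to window slack
        assert isl.interval.start <= 1050 and isl.interval.end >= 1250
        # all four printed thresholds hold on the reported interval
        assert isl.interval.length >= 200
        assert isl.gc_frac > 0.5
        assert isl.obs_exp_cpg > 0.6
        assert isl.level > 0.7

    def test_unmethylated_block_gives_none(self):
        g, sites = _island_fixture(methylated=False)
        assert find_methylated_islands(g, sites) == []

    def test_at_only_genome_gives_none(self):
        g = Genome({"c": "AT" * 500})
        assert find_methylated_islands(g, []) == []

    def test_chromosome_order_invariant(self):
        g1, sites = _island_fixture(methylated=True)
        g_fwd = Genome({"a": "AT" * 300, "c": g1["c"]})
        g_rev = Genome({"c": g1["c"], "a": "AT" * 300})
        i1 = find_methylated_islands(g_fwd, sites)
        i2 = find_methylated_islands(g_rev, sites)
        assert [(i.interval.start, i.interval.end) for i in i1] == [
            (i.interval.start, i.interval.end) for i in i2
        ]


class TestIslandRegionStats:
    GENES = [
        GeneModel("g1", "c", "+", (GenomicInterval("c", 10_000, 12_000),)),
    ]

    def _island(self, start, end, chrom="c"):
        from bsmeth.annotate import MethylatedIsland

        return MethylatedIsland(GenomicInterval(chrom, start, end), 0.6, 0.8, 0.9)

    def test_promoter_by_midpoint(self):
        df = island_region_stats([self._island(9_400, 9_600)], self.GENES, 2000)
        assert df.set_index("region").loc["promoter", "n_islands"] == 1

    def test_gene_free_contig_intergenic(self):
        df = island_region_stats([self._island(100, 400, "other")], self.GENES)
        assert df.set_index("region").loc["intergenic", "n_islands"] == 1

    def test_percentages_sum_to_100(self):
        islands = [
            self._island(9_400, 9_600),     # promoter
            self._island(10_500, 10_800),   # gene body
            self._island(12_100, 12_400),   # downstream
            self._island(50_000, 50_300),   # intergenic
        ]
        df = island_region_stats(islands, self.GENES, 2000)
        assert list(df["percent"]) == [25.0, 25.0, 25.0, 25.0]


class TestGeneClasses:
    GENES = [
        GeneModel("hi", "c", "+", (GenomicInterval("c", 0, 100),)),
        GeneModel("mid", "c", "+", (GenomicInterval("c", 200, 300),)),
        GeneModel("lo", "c", "+", (GenomicInterval("c", 400, 500),)),
        GeneModel("bare", "c", "+", (GenomicInterval("c", 600, 700),)),
    ]
    SITES = [
        cg_site("c", 50, 8, 10),    # 0.8 -> high
        cg_site("c", 250, 7, 10),   # exactly 0.7 -> neither (strict >)
        cg_site("c", 450, 2, 10),   # 0.2 -> low
    ]

    def test_thresholds_strict(self):
        res = gene_methylation_classes(self.GENES, self.SITES)
        assert res.high_genes == ["hi"]
        assert res.low_genes == ["lo"]
        assert res.uncovered_genes == ["bare"]

    def test_class_histogram(self):
        cmap = {"hi": "X", "lo": "X", "mid": "Y"}
        res = gene_methylation_classes(self.GENES, self.SITES, cmap)
        row = res.histogram.set_index("class").loc["X"]
        assert (row["n_high"], row["n_low"]) == (1, 1)


class TestTeProfile:
    def test_fully_methylated_mass_in_top_bin(self):
        tes = [GenomicInterval("c", i * 100, i * 100 + 50, ".", f"t{i}") for i in range(3)]
        sites = [cg_site("c", i * 100 + 10, 10, 10) for i in range(3)]
        prof = te_methylation_profile(sites, tes, n_bins=10)
        assert prof.counts[-1] == 3 and prof.counts[:-1].sum() == 0

    def test_uncovered_tallied(self):
        tes = [GenomicInterval("c", 0, 50), GenomicInterval("c", 100, 150)]
        sites = [cg_site("c", 10, 5, 10)]
        prof = te_methylation_profile(sites, tes)
        assert prof.n_uncovered == 1

    def test_histogram_matches_direct_computation(self):
        rng = np.random.default_rng(7)
        tes, sites = [], []
        for i in range(20):
            start = i * 200
            tes.append(GenomicInterval("c", start, start + 100, ".", f"t{i}"))
            for j in range(3):
                m = int(rng.integers(0, 11))
                sites.append(cg_site("c", start + 10 + j * 20, m, 10))
        prof = te_methylation_profile(sites, tes, n_bins=5)
        direct = []
        for te in tes:
            sub = [s for s in sites if te.start <= s.pos < te.end]
            direct.append(sum(s.m for s in sub) / sum(s.n for s in sub))
        want, _ = np.histogram(direct, bins=5, range=(0, 1))
        assert (prof.counts == want).all()


class TestPreferenceMatrix:
    def test_single_site_counts(self):
        g = Genome({"c": "AAACGAAA"})
        sites = [cg_site("c", 3, 5, 5)]
        mats = context_preference_matrix(sites, g, k=2)
        m = mats["mCG"].counts
        assert m.loc["A", -2] == 1 and m.loc["A", -1] == 1
        assert m.loc["C", 0] == 1 and m.loc["G", 1] == 1 and m.loc["A", 2] == 1
        assert (m.sum(axis=0) == 1).all()

    def test_no_called_sites_zero_matrix(self):
        g = Genome({"c": "AAACGAAA"})
        mats = context_preference_matrix([], g, k=2)
        assert (mats["mCG"].counts.values == 0).all()

    def test_edge_sites_skipped(self):
        g = Genome({"c": "CGAAAAAA"})
        mats = context_preference_matrix([cg_site("c", 0, 5, 5)], g, k=3)
        assert mats["mCG"].n_skipped == 1 and mats["mCG"].n_sites == 0

    def test_minus_strand_oriented(self):
        # Crick C at Watson G pos 4 of TTTCGTTT; Crick flank around it
        g = Genome({"c": "TTTCGTTT"})
        sites = [cg_site("c", 4, 5, 5, strand="-")]
        m = context_preference_matrix(sites, g, k=2)["mCG"].counts
        # Crick 5'->3' around the C: revcomp("TCGTT") = "AACGA"
        assert m.loc["A", -2] == 1 and m.loc["A", -1] == 1
        assert m.loc["C", 0] == 1 and m.loc["G", 1] == 1 and m.loc["A", 2] == 1

    def test_planted_dinucleotide_preference_recovered(self):
        """mCHH sites planted only after TA show T/A enrichment at -2/-1."""
        rng = np.random.default_rng(8)
        seq = []
        sites = []
        pos = 0
        for i in range(200):
            filler = "".join(rng.choice(list("GT"), size=6))
            seq.append(filler + "TACTT")  # C at offset +2 after TA, context CHH
            sites.append(cg_site("c", pos + len(filler) + 2, 5, 5, context="CHH"))
            pos += len(filler) + 5
        g = Genome({"c": "".join(seq)})
        m = context_preference_matrix(sites, g, k=2)["mCHH"].counts
        n = m.sum(axis=0)[-1]
        assert m.loc["T", -2] / n > 0.9
        assert m.loc["A", -1] / n > 0.9


class TestExpressionCurves:
    def _uniform_sites(self, length, level_num, level_den, chrom="c"):
        return [
            cg_site(chrom, p, level_num, level_den)
            for p in range(0, length, 25)
        ]

    def _genes(self, n, span=2000, gap=6000):
        return [
            GeneModel(f"g{i}", "c", "+",
                      (GenomicInterval("c", 4000 + i * gap, 4000 + i * gap + span),))
            for i in range(n)
        ]

    def test_constant_methylation_constant_curves(self):
        genes = self._genes(5)
        sites = self._uniform_sites(40_000, 1, 2)
        expr = {g.gene_id: float(i) for i, g in enumerate(genes)}
        curves = expression_methylation_curves(genes, expr, sites, promoter_len=2000)
        df = curves[("gene_body", "CG")]
        assert np.allclose(df.values[~np.isnan(df.values)], 0.5)

    def test_group_split_equal(self):
        genes = self._genes(10)
        sites = self._uniform_sites(70_000, 1, 2)
        expr = {g.gene_id: float(i) for i, g in enumerate(genes)}
        curves = expression_methylation_curves(genes, expr, sites)
        assert curves[("promoter", "CG")].shape == (5, 20)

    def test_too_few_genes_is_an_error(self):
        genes = self._genes(4)
        with pytest.raises(ValueError, match="at least 5"):
            expression_methylation_curves(genes, {g.gene_id: 1.0 for g in genes}, [])

    def test_planted_promoter_signal(self):
        """High-expression genes with unmethylated promoters: the top group's
        promoter curve sits below the bottom group's at every covered bin."""
        genes = self._genes(10)
        expr = {g.gene_id: float(i) for i, g in enumerate(genes)}
        sites = []
        for i, g in enumerate(genes):
            prom = g.promoter(2000)
            level = (9, 10) if i < 5 else (1, 10)  # low expr methylated, high not
            for p in range(prom.start, prom.end, 25):
                sites.append(cg_site("c", p, *level))
        curves = expression_methylation_curves(genes, expr, sites, promoter_len=2000)
        df = curves[("promoter", "CG")]
        g1, g5 = df.iloc[0].values, df.iloc[4].values
        ok = ~(np.isnan(g1) | np.isnan(g5))
        assert ok.any()
        assert (g5[ok] < g1[ok]).all()

    def test_minus_strand_bins_oriented(self):
        """A 5'-biased methylation gradient appears in early bins for a
        minus-strand gene as well."""
        gene = GeneModel("g", "c", "-", (GenomicInterval("c", 10_000, 12_000),))
        genes = [gene] + self._genes(4)
        expr = {g.gene_id: float(i) for i, g in enumerate(genes)}
        sites = []
        # methylate only the gene's 5' half (genomic right half for '-')
        for p in range(11_000, 12_000, 20):
            sites.append(cg_site("c", p, 10, 10))
        for p in range(10_000, 11_000, 20):
            sites.append(cg_site("c", p, 0, 10))
        curves = expression_methylation_curves(genes, expr, sites)
        row = curves[("gene_body", "CG")].iloc[0].values
        assert np.nanmean(row[:10]) > np.nanmean(row[10:])
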