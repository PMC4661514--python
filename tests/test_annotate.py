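"""Region classification, enrichment chi-squared, MAF and ratio tests."""

import numpy as np
import pytest
from scipy import stats

from cistag.annotate import (
    CATEGORIES,
    RegionClassifier,
    category_counts,
    classify_region,
    enrichment_test,
    maf_compare,
    ratio_compare,
    regulatory_overlap,
)
from cistag.model import GeneModel, Variant


def _gene(start=100_000, end=110_000, strand="+", biotype="coding",
          gene_id="G1", chrom="1"):
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        tss=start if strand == "+" else end,
        tes=end if strand == "+" else start,
        exons=[(start, start + 2_000), (start + 5_000, start + 7_000),
               (end - 2_000, end)],
        cds=None if biotype == "ncRNA" else (start + 500, end - 2_500),
        biotype=biotype,
    )


def _var(pos, chrom="1"):
    return Variant(chrom=chrom, pos=pos, vid=f"v{pos}", ref="A", alt="G")


class TestClassifyRegion:
    def test_upstream_of_tss_within_flank(self):
        ann = classify_region(_var(95_000), [_gene()])
        assert ann.category == "TSS10K"
        assert ann.tss_distance == -5_000

    def test_intron_beyond_flank(self):
        gene = _gene(start=100_000, end=200_000)
        ann = classify_region(_var(150_000), [gene])  # 50 kb from TSS
        assert ann.category == "INTRON"

    def test_intergenic_far_from_genes(self):
        ann = classify_region(_var(5_000_000), [_gene()])
        assert ann.category == "INTERGENIC"
        assert ann.anchor_gene is None

    def test_utr3_is_exonic_past_cds_end(self):
        gene = _gene(start=100_000, end=200_000)  # CDS ends at 197,500
        ann = classify_region(_var(198_000), [gene])
        # exonic (last exon), 3' of the CDS end, beyond the TSS flank
        assert ann.category == "UTR3"

    def test_exon_within_cds(self):
        gene = _gene(start=100_000, end=200_000)
        ann = classify_region(_var(106_000), [gene])
        # exonic... but within 10 kb of the TSS: precedence gives TSS10K
        assert ann.category == "TSS10K"
        ann = classify_region(_var(106_000), [gene], tss_flank=1_000)
        assert ann.category == "EXON"

    def test_ncrna_exon(self):
        gene = _gene(start=100_000, end=200_000, biotype="ncRNA")
        ann = classify_region(_var(198_500), [gene], tss_flank=1_000)
        assert ann.category == "NCRNA"

    def test_strand_flip_negates_tss_distance(self):
        """Reversing a gene's strand (same TSS coordinate) negates the
        signed TSS distance of a fixed variant."""
        fwd = _gene(strand="+")
        rev_same_tss = GeneModel(
            gene_id="G1", chrom="1", strand="-", tss=fwd.tss, tes=fwd.tes,
            exons=fwd.exons, cds=fwd.cds, biotype="coding",
        )
        v = _var(95_000)
        d_fwd = classify_region(v, [fwd]).tss_distance
        d_rev = classify_region(v, [rev_same_tss]).tss_distance
        assert d_rev == -d_fwd

    def test_partition_property(self, demo):
        """Category counts over any variant set sum to the set size."""
        clf = RegionClassifier(demo["genes"])
        anns = clf.classify_all(demo["gm"].variants)
        counts = category_counts(anns)
        assert sum(counts.values()) == len(demo["gm"].variants)
        assert set(counts) == set(CATEGORIES)


class TestEnrichment:
    def test_identical_proportions_null(self):
        res = enrichment_test(90, 1000, 90, 1000)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_textbook_chi2(self):
        """Hand-rolled 2x2 chi-squared oracle on (90/1000 vs 50/1000)."""
        res = enrichment_test(90, 1000, 50, 1000)
        table = np.array([[90, 910], [50, 950]])
        n = table.sum()
        row = table.sum(axis=1)
        col = table.sum(axis=0)
        expected = np.outer(row, col) / n
        chi2 = ((table - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, 1)
        assert res.chi2 == pytest.approx(chi2, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-12)
        assert res.df == 1

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            enrichment_test(0, 0, 10, 100)

    def test_low_expected_flagged(self):
        res = enrichment_test(1, 20, 2, 20)
        assert res.low_expected

    def test_same_distribution_pools_uniform_p(self, demo):
        """Drawing both pools from one annotation stream yields uniform
        enrichment p-values (KS p > 0.01 over 200 repetitions)."""
        clf = RegionClassifier(demo["genes"])
        anns = clf.classify_all(demo["gm"].variants)
        in_cat = np.array([a.category == "TSS10K" for a in anns])
        rng = np.random.default_rng(21)
        ps = []
        for _ in range(200):
            a = rng.choice(in_cat, size=600, replace=True)
            b = rng.choice(in_cat, size=600, replace=True)
            res = enrichment_test(int(a.sum()), 600, int(b.sum()), 600)
            ps.append(res.p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestMafCompare:
    def test_identical_groups(self):
        g = [0.1, 0.2, 0.3, 0.4]
        t, p = maf_compare(g, g)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_power_at_separated_means(self):
        """N(0.3, 0.05) vs N(0.2, 0.05), n=200: p < 1e-4 in >= 99% of
        seeded replicates."""
        rng = np.random.default_rng(8)
        hits = 0
        reps = 100
        for _ in range(reps):
            a = rng.normal(0.3, 0.05, 200)
            b = rng.normal(0.2, 0.05, 200)
            _, p = maf_compare(a, b)
            hits += p < 1e-4
        assert hits >= 99

    def test_single_element_group_errors(self):
        with pytest.raises(ValueError):
            maf_compare([0.1], [0.2, 0.3])


class TestRatioCompare:
    def test_identical_vectors(self):
        r = [0.09, 0.10, 0.11, 0.10, 0.09, 0.10]
        t, p = ratio_compare(r, r)
        assert p == pytest.approx(1.0)

    def test_matches_paired_t_oracle(self, rng):
        """Closed-form paired t on six-population ratio vectors."""
        a = rng.normal(0.097, 0.003, 6)
        b = rng.normal(0.091, 0.003, 6)
        t, p = ratio_compare(a, b, paired=True)
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), len(d) - 1)
        assert t == pytest.approx(t_oracle, abs=1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_unequal_sets_rejected_when_paired(self):
        with pytest.raises(ValueError):
            ratio_compare([0.1, 0.2, 0.3], [0.1, 0.2], paired=True)


class TestRegulatoryOverlap:
    def test_bed_boundary_conversion(self):
        v = _var(100)
        # BED [99, 100) covers exactly 1-based base 100 -> overlap
        assert regulatory_overlap([v], [("1", 99, 100, "F1")])["v100"] == ["F1"]
        # BED [100, 101) covers base 101 -> no overlap
        assert regulatory_overlap([v], [("1", 100, 101, "F2")])["v100"] == []

    def test_long_deletion_spans_feature(self):
        v = Variant(chrom="1", pos=100, vid="del", ref="A" * 30_000, alt="A")
        hits = regulatory_overlap([v], [("1", 20_000, 20_400, "F")])
        assert hits["del"] == ["F"]

    def test_matches_brute_force_double_loop(self, rng):
        variants = [
            Variant(chrom="1", pos=int(p), vid=f"v{i}", ref="AC", alt="A")
            for i, p in enumerate(rng.integers(1, 100_000, size=1000))
        ]
        intervals = []
        for j in range(50):
            s = int(rng.integers(0, 99_000))
            intervals.append(("1", s, s + int(rng.integers(1, 500)), f"F{j}"))
        fast = regulatory_overlap(variants, intervals)
        for v in variants:
            expected = sorted(
                name for chrom, s0, e0, name in intervals
                if chrom == v.chrom and not (v.end <= s0 or v.pos - 1 >= e0)
            )
            assert fast[v.vid] == expected
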