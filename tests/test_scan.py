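"""cis windowing, scanning, sharing classification, peak reduction."""

import numpy as np
import pytest

from cistag.model import GeneModel, Variant
from cistag.scan import (
    EqtlDatabase,
    CisEqtlRecord,
    cis_pairs,
    classify_sharing,
    peak_reduce,
    percent,
    scan,
    sharing_summary,
)
from cistag.model import VariantClass


def _gene(gene_id="G1", start=1_000_000, end=1_010_000, strand="+", chrom="1"):
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        tss=start if strand == "+" else end,
        tes=end if strand == "+" else start,
        exons=[(start, end)], cds=(start + 10, end - 10), biotype="coding",
    )


def _var(pos, vid=None, chrom="1", ref="A", alt="G"):
    return Variant(chrom=chrom, pos=pos, vid=vid or f"v{pos}", ref=ref, alt=alt)


def _rec(vid, probe, pop, min_p, pos=100, vclass=VariantClass.SNP):
    ref, alt = ("A", "G") if vclass == VariantClass.SNP else ("A", "AT")
    return CisEqtlRecord(
        variant=_var(pos, vid=vid, ref=ref, alt=alt), probe=probe,
        population=pop, p_by_model={}, min_p=min_p, best_model="ADD",
        vclass=vclass, maf=0.3, tss_distance=0,
    )


class TestCisPairs:
    def test_window_boundary_is_closed(self):
        gene = _gene()
        inside = _var(800_000)  # exactly window bp upstream of span start
        outside = _var(799_999)
        pairs = cis_pairs([gene], [inside, outside], window=200_000)
        assert [v.vid for v, _, _ in pairs] == ["v800000"]

    def test_variant_outside_window_excluded(self):
        pairs = cis_pairs([_gene()], [_var(805_000 - 10_000)], window=200_000)
        assert pairs == []

    def test_matches_brute_force_interval_scan(self, rng):
        gene = _gene(start=500_000, end=510_000)
        variants = [_var(int(p), vid=f"v{i}")
                    for i, p in enumerate(rng.integers(1, 1_000_000, size=100))]
        window = 200_000
        pairs = cis_pairs([gene], variants, window=window)
        expected = {
            v.vid for v in variants
            if gene.start - window <= v.pos <= gene.end + window
        }
        assert {v.vid for v, _, _ in pairs} == expected

    def test_chromosome_mismatch_raises(self):
        with pytest.raises(ValueError, match="chromosome"):
            cis_pairs([_gene(chrom="chr1")], [_var(100, chrom="1")], 1000)


class TestScan:
    def test_planted_effects_recovered(self, demo, demo_db):
        """At the strict cutoff the scan recovers >= 90% of the 20
        planted effects and labels sharing exactly as planted."""
        m = demo["manifest"]
        pairs = demo_db.pairs()
        recovered = [p for p in m.planted_eqtls if (p.vid, p.probe) in pairs]
        assert len(recovered) >= 18
        for p in recovered:
            label, _ = demo_db.sharing[(p.vid, p.probe)]
            truth = ("population-shared" if len(p.populations) >= 2
                     else "population-specific")
            assert label == truth, p

    def test_far_effect_never_reported(self, demo):
        """No record's variant sits outside the cis window of its
        probe's gene."""
        genes = {g.gene_id: g for g in demo["genes"]}
        em = demo["em"]
        recs = scan(demo["gm"], em, demo["genes"], demo["panel"], "CEU",
                    window=200_000, cutoff=1e-2)
        for r in recs:
            g = genes[em.probe2gene[r.probe]]
            assert g.start - 200_000 <= r.variant.pos <= g.end + 200_000

    def test_null_pass_count_within_envelope(self):
        """No planted effects: passing count at 1e-4 stays within the
        Bonferroni-bounded binomial envelope."""
        from cistag.simulate import (
            null_manifest, simulate_haplotypes, simulate_expression,
            genes_from_manifest,
        )
        from cistag.scan import scan_with_stats

        m = null_manifest(11)
        gm, panel = simulate_haplotypes(m)
        em = simulate_expression(gm, m, panel)
        recs, n_tests = scan_with_stats(
            gm, em, genes_from_manifest(m), panel, "CEU", cutoff=1e-4)
        assert n_tests >= 1000
        # 99% binomial envelope at rate 5e-4 (upper Bonferroni bound)
        upper = 5e-4 * n_tests + 3 * np.sqrt(5e-4 * n_tests)
        assert len(recs) <= upper

    def test_zero_shared_samples_errors(self, demo):
        em = demo["em"].subset_samples(demo["em"].samples[:5])
        with pytest.raises(ValueError):
            scan(demo["gm"], em, demo["genes"], demo["panel"], "CEU")


class TestSharing:
    def test_two_population_pair_is_shared(self):
        db = EqtlDatabase(records=[
            _rec("v1", "P1", "CHB", 1e-5), _rec("v1", "P1", "JPT", 1e-5),
            _rec("v2", "P1", "YRI", 1e-5),
        ])
        classify_sharing(db, 1e-4)
        assert db.sharing[("v1", "P1")][0] == "population-shared"
        assert db.sharing[("v2", "P1")][0] == "population-specific"

    def test_cutoff_respected(self):
        db = EqtlDatabase(records=[
            _rec("v1", "P1", "CHB", 1e-5), _rec("v1", "P1", "JPT", 1e-3),
        ])
        classify_sharing(db, 1e-4)
        assert db.sharing[("v1", "P1")] == ("population-specific", ["CHB"])


class TestPeakReduce:
    def test_smallest_p_flagged(self):
        db = EqtlDatabase(records=[
            _rec("a", "P1", "CEU", 1e-5, pos=100),
            _rec("b", "P1", "CEU", 1e-7, pos=200),
            _rec("c", "P1", "CEU", 1e-6, pos=300),
        ])
        peak_reduce(db)
        peaks = [r.variant.vid for r in db.records if r.is_peak]
        assert peaks == ["b"]

    def test_one_peak_per_variant_class(self):
        db = EqtlDatabase(records=[
            _rec("s", "P1", "CEU", 1e-5, pos=100, vclass=VariantClass.SNP),
            _rec("i", "P1", "CEU", 1e-4, pos=200, vclass=VariantClass.INDEL),
        ])
        peak_reduce(db)
        assert all(r.is_peak for r in db.records)

    def test_matches_brute_force_argmin_and_idempotent(self, demo_db):
        peak_reduce(demo_db)
        first = {(r.variant.vid, r.probe, r.population) for r in
                 demo_db.records if r.is_peak}
        groups = {}
        for r in demo_db.records:
            groups.setdefault((r.probe, r.population, r.vclass), []).append(r)
        expected = set()
        for grp in groups.values():
            best = min(grp, key=lambda r: (r.min_p, r.variant.pos))
            expected.add((best.variant.vid, best.probe, best.population))
        assert first == expected
        peak_reduce(demo_db)
        second = {(r.variant.vid, r.probe, r.population) for r in
                  demo_db.records if r.is_peak}
        assert first == second


class TestSharingSummary:
    def test_percentages_recompute_from_counts(self):
        # arithmetic helper used for all summary percentages
        assert round(percent(4976, 21841), 1) == 22.8
        assert round(percent(53926, 228743), 1) == 23.6
        assert np.isnan(percent(1, 0))

    def test_shared_plus_specific_is_total(self, demo_db):
        summary = sharing_summary(demo_db, cutoff=1e-4)
        for vc, row in summary["by_vclass"].items():
            assert row["shared"] + row["specific"] == row["total"]
            if row["total"]:
                assert row["shared_pct"] + row["specific_pct"] == (
                    pytest.approx(100.0))

    def test_specific_ratio_small_db(self):
        recs = [_rec(f"i{k}", f"P{k}", "CEU", 1e-5,
                     vclass=VariantClass.INDEL) for k in range(10)]
        recs += [_rec(f"s{k}", f"Q{k}", "CEU", 1e-5) for k in range(100)]
        db = EqtlDatabase(records=recs)
        summary = sharing_summary(db, cutoff=1e-4)
        ratio = summary["by_population"]["CEU"]["specific"]["indel_snp_ratio"]
        assert ratio == pytest.approx(0.100)

    def test_detection_rate_monotone_in_effect_size(self):
        """Planted detection at 1e-4 is monotone in beta (n=80)."""
        from cistag.association import batch_min_p

        rng = np.random.default_rng(33)
        rates = []
        for beta in (0.25, 0.5, 1.0):
            hits = 0
            reps = 150
            G = rng.binomial(2, 0.3, size=(reps, 80))
            for i in range(reps):
                y = beta * G[i] + rng.normal(size=80)
                mp, _, _ = batch_min_p(y, G[i:i + 1])
                hits += bool(np.isfinite(mp[0]) and mp[0] < 1e-4)
            rates.append(hits / reps)
        assert rates == sorted(rates)
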