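"""Genomic-region classification and real-vs-null enrichment tests.

Variants are assigned to exactly one of six mutually exclusive
categories relative to the gene models, with a fixed precedence when
several apply:

    TSS10K > UTR3 > EXON > NCRNA > INTRON > INTERGENIC

* TSS10K     — within a flank (default +-10 kb) of any TSS.
* UTR3       — exonic sequence of a coding gene 3' of the CDS end
               (strand-aware).
* EXON       — other exonic sequence of a coding gene (5'UTR folds in).
* NCRNA      — exonic in a non-coding gene.
* INTRON     — inside a gene span but not exonic.
* INTERGENIC — none of the above.

Enrichment of real cis-eQTLs against permutation-generated fake
cis-eQTLs is tested per category with a 2x2 chi-squared test (no
continuity correction by default).  MAF contrasts use a two-sample
t-test; per-population indel/SNP ratio contrasts use a paired t-test
over populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .model import GeneModel, Variant

CATEGORIES = ("TSS10K", "UTR3", "EXON", "NCRNA", "INTRON", "INTERGENIC")


@dataclass
class RegionAnnotation:
    variant: Variant
    category: str
    anchor_gene: Optional[str]
    tss_distance: Optional[int]


@dataclass
class EnrichmentResult:
    category: str
    real_count: int
    real_total: int
    fake_count: int
    fake_total: int
    chi2: float
    df: int
    p: float
    low_expected: bool = False


class RegionClassifier:
    """Classifies variants against a fixed gene-model set.

    Builds per-chromosome interval indexes once; precedence is
    configurable but defaults to the order in ``CATEGORIES``.
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        tss_flank: int = 10_000,
        precedence: Sequence[str] = CATEGORIES,
    ):
        if set(precedence) != set(CATEGORIES):
            raise ValueError("precedence must be a permutation of the six categories")
        self.tss_flank = tss_flank
        self.precedence = tuple(precedence)
        self._span: dict[str, IntervalTree] = {}
        self._genes = {g.gene_id: g for g in genes}
        for g in genes:
            tree = self._span.setdefault(g.chrom, IntervalTree())
            lo = min(g.start, g.tss - tss_flank)
            hi = max(g.end, g.tss + tss_flank)
            tree.addi(lo, hi + 1, g.gene_id)  # half-open on 1-based closed

    def _categories_for(self, variant: Variant, gene: GeneModel) -> set[str]:
        pos = variant.pos
        cats: set[str] = set()
        if abs(pos - gene.tss) <= self.tss_flank:
            cats.add("TSS10K")
        in_gene = gene.start <= pos <= gene.end
        in_exon = any(s <= pos <= e for s, e in gene.exons)
        if in_exon:
            if gene.biotype == "ncRNA":
                cats.add("NCRNA")
            else:
                assert gene.cds is not None
                if gene.strand == "+":
                    utr3 = pos > gene.cds[1]
                else:
                    utr3 = pos < gene.cds[0]
                cats.add("UTR3" if utr3 else "EXON")
        elif in_gene:
            cats.add("INTRON")
        return cats

    def classify(self, variant: Variant) -> RegionAnnotation:
        tree = self._span.get(variant.chrom)
        hits = tree[variant.pos] if tree is not None else set()
        cats: set[str] = set()
        candidates: list[GeneModel] = []
        for iv in hits:
            gene = self._genes[iv.data]
            candidates.append(gene)
            cats |= self._categories_for(variant, gene)
        if not cats:
            return RegionAnnotation(variant, "INTERGENIC", None, None)
        for cat in self.precedence:
            if cat in cats:
                category = cat
                break
        anchor = min(candidates, key=lambda g: abs(variant.pos - g.tss))
        return RegionAnnotation(
            variant, category, anchor.gene_id, anchor.tss_distance(variant.pos)
        )

    def classify_all(self, variants: Sequence[Variant]) -> list[RegionAnnotation]:
        return [self.classify(v) for v in variants]


def classify_region(
    variant: Variant, genes: Sequence[GeneModel], tss_flank: int = 10_000
) -> RegionAnnotation:
    """One-off classification (builds a classifier per call; use
    :class:`RegionClassifier` for batches)."""
    return RegionClassifier(genes, tss_flank=tss_flank).classify(variant)


def category_counts(annotations: Sequence[RegionAnnotation]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for a in annotations:
        counts[a.category] += 1
    return counts


def enrichment_test(
    real_count: int, real_total: int,
    fake_count: int, fake_total: int,
    category: str = "",
    yates: bool = False,
) -> EnrichmentResult:
    """2x2 chi-squared: in-category vs not, real vs fake.

    No continuity correction by default (large-count regime).  Results
    with any expected cell below 5 carry a ``low_expected`` flag but
    are still computed.
    """
    if real_total <= 0 or fake_total <= 0:
        raise ValueError("both totals must be positive")
    if real_count > real_total or fake_count > fake_total:
        raise ValueError("counts cannot exceed totals")
    table = np.array(
        [
            [real_count, real_total - real_count],
            [fake_count, fake_total - fake_count],
        ]
    )
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        # no variation across the category split
        return EnrichmentResult(category, real_count, real_total, fake_count,
                                fake_total, 0.0, 1, 1.0)
    chi2, p, df, expected = stats.chi2_contingency(table, correction=yates)
    return EnrichmentResult(
        category=category,
        real_count=real_count, real_total=real_total,
        fake_count=fake_count, fake_total=fake_total,
        chi2=float(chi2), df=int(df), p=float(p),
        low_expected=bool((expected < 5).any()),
    )


def maf_compare(
    group1: Sequence[float], group2: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample t-test of MAF distributions (equal-variance default,
    Welch optional).  Returns (t, two-sided p); NA when both groups are
    constant."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("both groups need n >= 2")
    if np.var(g1) == 0 and np.var(g2) == 0:
        return float("nan"), float("nan")
    t, p = stats.ttest_ind(g1, g2, equal_var=equal_var)
    return float(t), float(p)


def ratio_compare(
    specific_ratios: Sequence[float],
    shared_ratios: Sequence[float],
    paired: bool = True,
) -> tuple[float, float]:
    """t-test of per-population indel/SNP ratios, specific vs shared.

    Paired by default: the same populations contribute one ratio to
    each group, as in a six-population panel.
    """
    a = np.asarray(specific_ratios, dtype=float)
    b = np.asarray(shared_ratios, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need ratios from at least two populations per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal population sets")
        if np.all(a == b):  # degenerate: zero difference everywhere
            return 0.0, 1.0
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def regulatory_overlap(
    variants: Sequence[Variant],
    intervals: Sequence[tuple[str, int, int, str]],
) -> dict[str, list[str]]:
    """Map variants to overlapping regulatory features.

    ``intervals`` are BED-convention (chrom, start0, end0, name).  A
    variant overlaps a feature iff any affected reference base (POS
    through POS + len(ref) - 1, 1-based closed) lies inside the
    interval.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, s0, e0, name in intervals:
        if e0 > s0:
            trees.setdefault(chrom, IntervalTree()).addi(s0, e0, name)
    out: dict[str, list[str]] = {}
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            out[v.vid] = []
            continue
        # 1-based closed [pos, end] -> 0-based half-open [pos-1, end)
        hits = tree.overlap(v.pos - 1, v.end)
        out[v.vid] = sorted(iv.data for iv in hits)
    return out
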