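"""Core in-memory data model.

Coordinates are 1-based closed throughout the internal model (VCF
convention); BED input/output converts at the boundary.  Genotypes are
coded as alt-allele counts in {0, 1, 2} with ``MISSING`` (-1) for
uncalled or half-called genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

MISSING: int = -1


class VariantClass(str, Enum):
    SNP = "SNP"
    INDEL = "INDEL"


def classify_variant(ref: str, alt: str) -> VariantClass:
    """Classify a biallelic variant as SNP or INDEL.

    A SNP has single-base ref and alt; any length difference (or any
    multi-base allele) makes the variant an indel.  Multiallelic alt
    strings (comma-separated) are rejected.
    """
    if not ref or not alt:
        raise ValueError("alleles must be nonempty")
    if ref == alt:
        raise ValueError("ref and alt alleles must differ")
    if "," in alt:
        raise ValueError(f"multiallelic alt string not supported: {alt!r}")
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNP
    return VariantClass.INDEL


@dataclass(frozen=True)
class Variant:
    """A biallelic variant at a 1-based position."""

    chrom: str
    pos: int
    vid: str
    ref: str
    alt: str
    vclass: VariantClass = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        vclass = classify_variant(self.ref, self.alt)
        if self.vclass is None:
            object.__setattr__(self, "vclass", vclass)
        elif self.vclass != vclass:
            raise ValueError(
                f"declared class {self.vclass} inconsistent with alleles "
                f"{self.ref}>{self.alt}"
            )

    @property
    def end(self) -> int:
        """Last reference base affected (1-based, inclusive)."""
        return self.pos + len(self.ref) - 1


def make_vid(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class GenotypeMatrix:
    """Variant x sample alt-allele dosage matrix, optionally phased.

    ``codes`` is int8 with values {0, 1, 2, MISSING}.  When ``phased``,
    ``haplotypes`` is a variant x (2*n_samples) int8 array of alleles
    (0 = ref, 1 = alt, MISSING) with sample i owning columns 2i, 2i+1,
    and codes equal the haplotype sums wherever not missing.
    """

    variants: list[Variant]
    samples: list[str]
    codes: np.ndarray
    phased: bool = False
    haplotypes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        if self.phased:
            if self.haplotypes is None:
                raise ValueError("phased matrix requires haplotypes")
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (len(self.variants), 2 * len(self.samples)):
                raise ValueError("haplotype array shape mismatch")
        self._vid_index = {v.vid: i for i, v in enumerate(self.variants)}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def index_of(self, vid: str) -> int:
        try:
            return self._vid_index[vid]
        except KeyError:
            raise KeyError(f"variant {vid!r} not present in genotype matrix")

    def __contains__(self, vid: str) -> bool:
        return vid in self._vid_index

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        """Return a new matrix restricted to ``sample_ids`` (order kept)."""
        idx = []
        for s in sample_ids:
            try:
                idx.append(self.samples.index(s))
            except ValueError:
                raise KeyError(f"sample {s!r} not in genotype matrix")
        codes = self.codes[:, idx]
        haps = None
        if self.phased and self.haplotypes is not None:
            hap_idx = np.ravel([[2 * i, 2 * i + 1] for i in idx])
            haps = self.haplotypes[:, hap_idx]
        return GenotypeMatrix(
            variants=list(self.variants),
            samples=[self.samples[i] for i in idx],
            codes=codes,
            phased=self.phased,
            haplotypes=haps,
        )

    def subset_variants(self, indices: Sequence[int]) -> "GenotypeMatrix":
        indices = list(indices)
        haps = None
        if self.phased and self.haplotypes is not None:
            haps = self.haplotypes[indices, :]
        return GenotypeMatrix(
            variants=[self.variants[i] for i in indices],
            samples=list(self.samples),
            codes=self.codes[indices, :],
            phased=self.phased,
            haplotypes=haps,
        )

    def maf(self) -> np.ndarray:
        """Folded minor allele frequency per variant over non-missing calls."""
        codes = self.codes
        called = codes != MISSING
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called, codes, 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        return np.minimum(freq, 1.0 - freq)

    def missing_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.full(self.n_variants, np.nan)
        return (self.codes == MISSING).sum(axis=1) / self.n_samples


@dataclass
class PopulationPanel:
    """Sample -> population assignment, with optional super-populations."""

    assignments: dict[str, str]
    super_population: Optional[dict[str, str]] = None

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def samples_for(self, population: str) -> list[str]:
        if population == "ALL":
            return list(self.assignments)
        pops = {population}
        if self.super_population is not None:
            pops |= {
                p for p, sp in self.super_population.items() if sp == population
            }
        return [s for s, p in self.assignments.items() if p in pops]


@dataclass
class ExpressionMatrix:
    """Probe x sample continuous expression with a probe -> gene map."""

    probes: list[str]
    samples: list[str]
    values: np.ndarray
    probe2gene: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probes), len(self.samples)):
            raise ValueError("expression values shape mismatch")
        self._probe_index = {p: i for i, p in enumerate(self.probes)}

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def row(self, probe: str) -> np.ndarray:
        return self.values[self._probe_index[probe], :]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return ExpressionMatrix(
            probes=list(self.probes),
            samples=[self.samples[i] for i in idx],
            values=self.values[:, idx],
            probe2gene=dict(self.probe2gene),
        )


@dataclass
class GeneModel:
    """A gene with strand-aware TSS and exon structure.

    ``tss`` is the 5' end respecting strand; ``tes`` the 3' end.  Exons
    are 1-based closed, sorted, non-overlapping.  ``cds`` is None for
    non-coding genes; ``biotype`` is "coding" or "ncRNA".
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: list[tuple[int, int]]
    cds: Optional[tuple[int, int]] = None
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.biotype == "coding" and self.cds is None:
            raise ValueError(f"coding gene {self.gene_id} lacks a CDS")
        exons = sorted(self.exons)
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")
        self.exons = exons

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate of the gene span."""
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)

    def tss_distance(self, pos: int) -> int:
        """Signed distance from TSS; negative = upstream of the gene."""
        return pos - self.tss if self.strand == "+" else self.tss - pos
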