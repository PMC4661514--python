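"""Readers and writers for the standard file formats.

VCF parsing uses cyvcf2.  Variant filters follow the study design:
biallelic records only (multiallelic records are skipped with a
warning), per-population folded MAF >= ``maf_min`` and missing rate
< ``miss_max`` computed on the selected samples.  Half-calls are
treated as missing.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    MISSING,
    ExpressionMatrix,
    GeneModel,
    GenotypeMatrix,
    PopulationPanel,
    Variant,
    classify_variant,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


def load_panel(path: PathLike) -> PopulationPanel:
    """Read a sample panel TSV with columns sample, population
    [, super_population]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns or "population" not in df.columns:
        raise ValueError(f"panel {path} must have 'sample' and 'population' columns")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate samples in panel: {dups}")
    assignments = dict(zip(df["sample"], df["population"]))
    superpop = None
    if "super_population" in df.columns:
        superpop = dict(
            zip(df["population"], df["super_population"])
        )
    return PopulationPanel(assignments=assignments, super_population=superpop)


def load_vcf(
    path: PathLike,
    maf_min: float = 0.01,
    miss_max: float = 0.2,
    panel: Optional[PopulationPanel] = None,
    population: str = "ALL",
) -> GenotypeMatrix:
    """Load biallelic variants from a VCF into a GenotypeMatrix.

    Only records with exactly one alt allele are retained; others are
    skipped with a logged warning.  Filtering (MAF, missingness) is
    applied on the samples of the selected population.  The matrix is
    marked phased iff every retained non-missing genotype call is
    phased.
    """
    vcf = VCF(str(path))
    all_samples = list(vcf.samples)
    if panel is not None:
        wanted = set(panel.samples_for(population))
        samples = [s for s in all_samples if s in wanted]
    else:
        samples = all_samples
    if not samples:
        raise ValueError(
            f"no samples remain after intersecting VCF with panel "
            f"population {population!r}"
        )
    sample_idx = [all_samples.index(s) for s in samples]
    n = len(samples)

    variants: list[Variant] = []
    code_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    all_phased = True

    for rec in vcf:
        if len(rec.ALT) != 1:
            log.warning(
                "skipping multiallelic record %s:%d (%s>%s)",
                rec.CHROM, rec.POS, rec.REF, ",".join(rec.ALT),
            )
            continue
        ref, alt = rec.REF, rec.ALT[0]
        gts = rec.genotypes  # [a0, a1, phased] per sample
        codes = np.full(n, MISSING, dtype=np.int8)
        haps = np.full(2 * n, MISSING, dtype=np.int8)
        rec_phased = True
        for j, si in enumerate(sample_idx):
            a0, a1 = gts[si][0], gts[si][1]
            ph = bool(gts[si][2])
            if a0 < 0 or a1 < 0:  # missing or half-call
                continue
            codes[j] = a0 + a1
            haps[2 * j] = a0
            haps[2 * j + 1] = a1
            if not ph:
                rec_phased = False

        called = codes != MISSING
        n_called = int(called.sum())
        miss_rate = (n - n_called) / n  # exact at threshold boundaries
        if miss_rate >= miss_max:
            continue
        if n_called == 0:
            continue
        freq = codes[called].sum() / (2 * n_called)
        maf = min(freq, 1.0 - freq)
        if maf < maf_min:
            continue

        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{ref}:{alt}"
        variants.append(
            Variant(chrom=rec.CHROM, pos=rec.POS, vid=vid, ref=ref, alt=alt,
                    vclass=classify_variant(ref, alt))
        )
        code_rows.append(codes)
        hap_rows.append(haps)
        if not rec_phased:
            all_phased = False

    if not variants:
        log.warning("no variants retained from %s after filtering", path)
        return GenotypeMatrix(
            variants=[], samples=samples,
            codes=np.zeros((0, n), dtype=np.int8), phased=False,
        )
    phased = all_phased
    return GenotypeMatrix(
        variants=variants,
        samples=samples,
        codes=np.vstack(code_rows),
        phased=phased,
        haplotypes=np.vstack(hap_rows) if phased else None,
    )


def write_vcf(gm: GenotypeMatrix, path: PathLike) -> None:
    """Write a GenotypeMatrix back to a plain-text VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples) + "\n"
        )
        sep = "|" if gm.phased else "/"
        for i, v in enumerate(gm.variants):
            fields = [v.chrom, str(v.pos), v.vid, v.ref, v.alt, ".", "PASS", ".", "GT"]
            for j in range(gm.n_samples):
                if gm.codes[i, j] == MISSING:
                    fields.append("./.")
                elif gm.phased and gm.haplotypes is not None:
                    a0, a1 = gm.haplotypes[i, 2 * j], gm.haplotypes[i, 2 * j + 1]
                    fields.append(f"{a0}{sep}{a1}")
                else:
                    g = int(gm.codes[i, j])
                    fields.append(["0/0", "0/1", "1/1"][g])
            fh.write("\t".join(fields) + "\n")


def load_expression(path: PathLike, probe2gene_path: PathLike) -> ExpressionMatrix:
    """Read a probe x sample expression TSV plus a probe -> gene map.

    Probes with any unparsable cell are dropped with a warning naming
    the probe; probes missing from the map are excluded (logged) since
    they cannot be placed in cis of any gene.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate probe IDs in {path}: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    for probe in df.index[bad]:
        log.warning("probe %s has unparsable expression values; dropped", probe)
    numeric = numeric.loc[~bad]

    pmap = pd.read_csv(probe2gene_path, sep="\t", dtype=str)
    if "probe" not in pmap.columns or "gene" not in pmap.columns:
        raise ValueError("probe map must have 'probe' and 'gene' columns")
    probe2gene = dict(zip(pmap["probe"], pmap["gene"]))

    keep = []
    for probe in numeric.index:
        if probe in probe2gene:
            keep.append(probe)
        else:
            log.warning("probe %s absent from probe->gene map; excluded", probe)
    numeric = numeric.loc[keep]
    return ExpressionMatrix(
        probes=list(numeric.index),
        samples=[str(c) for c in numeric.columns],
        values=numeric.to_numpy(dtype=float),
        probe2gene={p: probe2gene[p] for p in numeric.index},
    )


def load_genes_bed12(path: PathLike) -> list[GeneModel]:
    """Read gene models from BED12.

    name = gene ID; thickStart/thickEnd delimit the CDS (equal when the
    gene is non-coding, giving biotype ncRNA); block fields give exons.
    BED is 0-based half-open; the internal model is 1-based closed.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: BED12 requires 12 fields, got {len(f)}")
            chrom = f[0]
            start0, end0 = int(f[1]), int(f[2])
            gene_id, strand = f[3], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"{path}:{ln}: block count mismatch")
            exons = [
                (start0 + off + 1, start0 + off + sz)  # to 1-based closed
                for off, sz in zip(offsets, sizes)
            ]
            coding = thick_e > thick_s
            cds = (thick_s + 1, thick_e) if coding else None
            tss = start0 + 1 if strand == "+" else end0
            tes = end0 if strand == "+" else start0 + 1
            genes.append(
                GeneModel(
                    gene_id=gene_id, chrom=chrom, strand=strand,
                    tss=tss, tes=tes, exons=exons, cds=cds,
                    biotype="coding" if coding else "ncRNA",
                )
            )
    return genes


def write_genes_bed12(genes: list[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start0, end0 = g.start - 1, g.end
            if g.cds is not None:
                thick_s, thick_e = g.cds[0] - 1, g.cds[1]
            else:
                thick_s = thick_e = start0
            sizes = ",".join(str(e - s + 1) for s, e in g.exons)
            offsets = ",".join(str(s - 1 - start0) for s, _ in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom, str(start0), str(end0), g.gene_id, "0", g.strand,
                        str(thick_s), str(thick_e), "0",
                        str(len(g.exons)), sizes, offsets,
                    ]
                )
                + "\n"
            )


def load_bed_intervals(path: PathLike) -> list[tuple[str, int, int, str]]:
    """Read a BED3+ interval file.

    Returns (chrom, start0, end0, name) tuples in BED convention
    (0-based half-open).  Malformed lines raise with a line number.
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: BED line needs >= 3 fields")
            try:
                start0, end0 = int(f[1]), int(f[2])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer BED coordinates")
            if end0 < start0:
                raise ValueError(f"{path}:{ln}: end < start")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            out.append((f[0], start0, end0, name))
    return out


def load_gwas_catalog(path: PathLike) -> pd.DataFrame:
    """Read a GWAS catalog snapshot TSV with columns rsid, trait."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "rsid" not in df.columns or "trait" not in df.columns:
        raise ValueError("GWAS catalog must have 'rsid' and 'trait' columns")
    if df.empty:
        raise ValueError("GWAS catalog is empty")
    return df
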