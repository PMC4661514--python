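"""Seeded synthetic fixtures: genotypes with LD blocks, planted cis
effects, and companion annotation files.

The generator emulates the study conditions of a multi-population
LCL cis-eQTL panel: six populations (CEU, CHB, JPT, LWK, MEX, YRI) of
80 individuals each, phased genotypes mixing SNPs and indels arranged
in LD blocks, genes with multiple expression probes, and expression
with planted cis effects under any of the genetic models.  Haplotypes
use a copy-with-mutation construction: the first variant of each block
is drawn from its population allele frequency, each subsequent variant
copies the previous column and flips alleles with a probability tuned
to the target pairwise r^2 ( flip probability m = (1 - sqrt(r2))/2 ).
Perfect taggers are exact haplotype copies under indel alleles.

All randomness flows from one user seed through named substreams
(layout / haplotypes / expression), so a manifest plus its seed fully
determines every emitted file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_genes_bed12, write_vcf
from .model import (
    ExpressionMatrix,
    GeneModel,
    GenotypeMatrix,
    PopulationPanel,
    Variant,
    VariantClass,
)

DEFAULT_POPULATIONS = {
    "CEU": 80, "CHB": 80, "JPT": 80, "LWK": 80, "MEX": 80, "YRI": 80,
}
SUPER_POPULATION = {
    "CEU": "EUR", "CHB": "EAS", "JPT": "EAS",
    "LWK": "AFR", "YRI": "AFR", "MEX": "AMR",
}

_SNP_ALLELES = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))
_INDEL_ALLELES = (("A", "AT"), ("TAC", "T"), ("G", "GCC"), ("CTTG", "C"))


@dataclass(frozen=True)
class PlantedEqtl:
    vid: str
    probe: str
    populations: tuple[str, ...]
    model: str  # ADD / DOM / REC / DOMDEV
    beta: float
    freq: float  # alt-allele frequency forced at this variant


@dataclass(frozen=True)
class PlantedTagger:
    snp_vid: str
    indel_vid: str
    target_r2: float


@dataclass
class SimManifest:
    seed: int
    populations: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_POPULATIONS)
    )
    chrom: str = "1"
    n_variants: int = 2000
    n_genes: int = 80
    gene_spacing: int = 100_000
    gene_span: int = 10_000
    n_extra_probes: int = 20
    block_size: int = 8
    block_r2: float = 0.8
    indel_fraction: float = 0.15
    maf_range: tuple[float, float] = (0.05, 0.5)
    pop_freq_jitter: float = 0.05
    planted_freq: float = 0.3
    noise_sd: float = 1.0
    positions: list[int] = field(default_factory=list)
    vclass: list[str] = field(default_factory=list)
    planted_eqtls: list[PlantedEqtl] = field(default_factory=list)
    planted_taggers: list[PlantedTagger] = field(default_factory=list)

    @property
    def variant_ids(self) -> list[str]:
        return [f"rs{i + 1:06d}" for i in range(len(self.positions))]

    @property
    def region_end(self) -> int:
        return self.n_genes * self.gene_spacing + 40_000

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path) -> "SimManifest":
        with open(path) as fh:
            d = json.load(fh)
        d["planted_eqtls"] = [
            PlantedEqtl(**{**e, "populations": tuple(e["populations"])})
            for e in d["planted_eqtls"]
        ]
        d["planted_taggers"] = [PlantedTagger(**t) for t in d["planted_taggers"]]
        d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


def genes_from_manifest(m: SimManifest) -> list[GeneModel]:
    """Deterministic gene layout: one gene per spacing slot, alternating
    strand, every tenth gene non-coding."""
    genes = []
    for i in range(m.n_genes):
        start = 20_000 + i * m.gene_spacing
        end = start + m.gene_span
        strand = "+" if i % 2 == 0 else "-"
        exons = [
            (start, start + 1_000),
            (start + 4_000, start + 5_500),
            (start + 8_500, end),
        ]
        ncrna = i % 10 == 9
        genes.append(
            GeneModel(
                gene_id=f"GENE{i + 1:04d}",
                chrom=m.chrom,
                strand=strand,
                tss=start if strand == "+" else end,
                tes=end if strand == "+" else start,
                exons=exons,
                cds=None if ncrna else (start + 500, start + 9_200),
                biotype="ncRNA" if ncrna else "coding",
            )
        )
    return genes


def probe_map_from_manifest(m: SimManifest) -> dict[str, str]:
    """Probe -> gene map: one probe per gene plus extra probes on the
    first genes (several probes may map to one gene)."""
    probes = {}
    for i in range(m.n_genes):
        probes[f"PROBE{i + 1:04d}_1"] = f"GENE{i + 1:04d}"
    for i in range(m.n_extra_probes):
        probes[f"PROBE{i + 1:04d}_2"] = f"GENE{i + 1:04d}"
    return probes


def demo_manifest(seed: int) -> SimManifest:
    """The default demo: 6 populations x 80 samples, 2,000 variants,
    100 probes over 80 genes, 20 planted cis effects (beta = 1.5) and
    5 planted SNP-indel taggers (3 perfect)."""
    m = SimManifest(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    m.positions = _draw_positions(rng, m.n_variants, m.region_end)
    is_indel = rng.random(m.n_variants) < m.indel_fraction
    m.vclass = ["INDEL" if x else "SNP" for x in is_indel]

    genes = genes_from_manifest(m)
    pops = list(m.populations)
    positions = np.asarray(m.positions)

    # 20 planted effects on evenly spaced coding genes
    target_gene_idx = [2 + 4 * k for k in range(20)]  # genes 3,7,...,79 (1-based)
    # weaker-coded models (REC, DOMDEV) go to the six-population group,
    # where a single under-powered population cannot flip the sharing
    # label; the specific and two-population groups get ADD/DOM
    models = (
        ["REC"] * 3 + ["DOMDEV"] * 3 + ["ADD"] * 2  # k 0-7: all six
        + ["DOM"] * 3 + ["ADD"] * 3                 # k 8-13: specific
        + ["ADD"] * 6                               # k 14-19: two pops
    )
    planted = []
    used_variant_idx = []
    for k, gi in enumerate(target_gene_idx):
        gene = genes[gi]
        lo, hi = gene.start - 50_000, gene.end + 50_000
        cand = np.nonzero((positions >= lo) & (positions <= hi))[0]
        cand = [c for c in cand if c not in used_variant_idx]
        if not cand:
            raise ValueError(f"no candidate variant near gene {gene.gene_id}")
        vi = int(cand[len(cand) // 2])
        used_variant_idx.append(vi)
        # a quarter of the planted effects sit on indels
        m.vclass[vi] = "INDEL" if k % 4 == 3 else "SNP"
        model = models[k]
        if k < 8:
            pop_set = tuple(pops)  # shared across all six
        elif k < 14:
            pop_set = (pops[k % 6],)  # population-specific
        else:
            pop_set = (pops[k % 6], pops[(k + 1) % 6])  # shared in two
        # recessive effects need a commoner alt allele for adequate
        # noncentrality; dominance-deviation effects are planted at 0.5
        # where the het indicator is orthogonal to dosage
        freq = 0.5 if model in ("REC", "DOMDEV") else m.planted_freq
        planted.append(
            PlantedEqtl(
                vid=f"rs{vi + 1:06d}",
                probe=f"PROBE{gi + 1:04d}_1",
                populations=pop_set,
                model=model,
                beta=1.5,
                freq=freq,
            )
        )
    m.planted_eqtls = planted

    # taggers: 3 perfect copies of planted SNP eQTLs, 2 at r2 = 0.8
    taggers = []
    snp_plantings = [
        (p, int(p.vid[2:]) - 1) for p in planted
        if m.vclass[int(p.vid[2:]) - 1] == "SNP"
    ]
    for j, (p, vi) in enumerate(snp_plantings[:5]):
        partner = vi + 1
        if partner >= m.n_variants or partner in used_variant_idx:
            partner = vi - 1
        m.vclass[partner] = "INDEL"
        used_variant_idx.append(partner)
        taggers.append(
            PlantedTagger(
                snp_vid=p.vid,
                indel_vid=f"rs{partner + 1:06d}",
                target_r2=1.0 if j < 3 else 0.8,
            )
        )
    m.planted_taggers = taggers
    return m


def null_manifest(seed: int, n_samples: int = 100) -> SimManifest:
    """A no-effect fixture with independent variants, used to measure
    the null behaviour of the min-P statistic."""
    m = SimManifest(
        seed=seed,
        populations={"CEU": n_samples},
        n_variants=500,
        n_genes=40,
        n_extra_probes=0,
        block_size=1,  # every variant an anchor: no LD
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    m.positions = _draw_positions(rng, m.n_variants, m.region_end)
    is_indel = rng.random(m.n_variants) < m.indel_fraction
    m.vclass = ["INDEL" if x else "SNP" for x in is_indel]
    return m


def _draw_positions(rng, n: int, region_end: int) -> list[int]:
    pos: np.ndarray = np.unique(rng.integers(1, region_end, size=2 * n))
    while pos.size < n:
        pos = np.unique(
            np.concatenate([pos, rng.integers(1, region_end, size=n)])
        )
    idx = np.sort(rng.choice(pos.size, size=n, replace=False))
    return [int(x) for x in pos[idx]]


def _flip_prob(target_r2: float) -> float:
    if not 0.0 < target_r2 <= 1.0:
        raise ValueError(
            f"target r2 must be in (0, 1], got {target_r2}"
        )
    return (1.0 - np.sqrt(target_r2)) / 2.0


def simulate_haplotypes(
    m: SimManifest,
) -> tuple[GenotypeMatrix, PopulationPanel]:
    """Draw phased haplotypes per population under the manifest's block
    structure, then install planted taggers by haplotype copy."""
    for pop, n in m.populations.items():
        if n < 2:
            raise ValueError(f"population {pop} needs >= 2 samples, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence([m.seed, 1]))
    n_var = m.n_variants
    vids = m.variant_ids
    vid_idx = {v: i for i, v in enumerate(vids)}

    forced_freq: dict[int, float] = {}
    for p in m.planted_eqtls:
        forced_freq[vid_idx[p.vid]] = p.freq
    for t in m.planted_taggers:
        _flip_prob(t.target_r2)  # validates feasibility
        forced_freq.setdefault(vid_idx[t.snp_vid], m.planted_freq)

    base_freq = rng.uniform(*m.maf_range, size=n_var)
    flip_m = _flip_prob(m.block_r2) if m.block_size > 1 else 0.0

    hap_blocks = []
    samples: list[str] = []
    assignments: dict[str, str] = {}
    for pop, n in m.populations.items():
        names = [f"{pop}{i + 1:03d}" for i in range(n)]
        samples.extend(names)
        for s in names:
            assignments[s] = pop
        freqs = np.clip(
            base_freq + rng.normal(0.0, m.pop_freq_jitter, size=n_var),
            0.02, 0.98,
        )
        for vi, f in forced_freq.items():
            freqs[vi] = f  # identical frequency in every population
        H = np.empty((n_var, 2 * n), dtype=np.int8)
        for j in range(n_var):
            anchor = (j % m.block_size == 0) or (j in forced_freq)
            if anchor or j == 0:
                H[j] = rng.random(2 * n) < freqs[j]
            else:
                flips = rng.random(2 * n) < flip_m
                H[j] = H[j - 1] ^ flips
        for t in m.planted_taggers:
            si, ii = vid_idx[t.snp_vid], vid_idx[t.indel_vid]
            if t.target_r2 >= 1.0:
                H[ii] = H[si]
            else:
                flips = rng.random(2 * n) < _flip_prob(t.target_r2)
                H[ii] = H[si] ^ flips
        hap_blocks.append(H)

    H_all = np.concatenate(hap_blocks, axis=1)
    variants = []
    for i, (pos, vc) in enumerate(zip(m.positions, m.vclass)):
        if vc == "SNP":
            ref, alt = _SNP_ALLELES[i % len(_SNP_ALLELES)]
        else:
            ref, alt = _INDEL_ALLELES[i % len(_INDEL_ALLELES)]
        variants.append(
            Variant(chrom=m.chrom, pos=pos, vid=vids[i], ref=ref, alt=alt,
                    vclass=VariantClass(vc))
        )
    codes = H_all[:, 0::2] + H_all[:, 1::2]
    gm = GenotypeMatrix(
        variants=variants, samples=samples, codes=codes,
        phased=True, haplotypes=H_all,
    )
    panel = PopulationPanel(
        assignments=assignments,
        super_population={
            p: SUPER_POPULATION.get(p, "NA") for p in m.populations
        },
    )
    return gm, panel


def _encode_vec(g: np.ndarray, model: str) -> np.ndarray:
    if model == "ADD":
        return g.astype(float)
    if model == "DOM":
        return (g >= 1).astype(float)
    if model == "REC":
        return (g == 2).astype(float)
    if model == "DOMDEV":
        return (g == 1).astype(float)
    raise ValueError(f"unsupported planted model {model!r}")


def simulate_expression(
    gm: GenotypeMatrix, m: SimManifest, panel: PopulationPanel
) -> ExpressionMatrix:
    """Gaussian noise per probe plus the planted genetic effects:
    y = beta * encode(g, model) + N(0, noise_sd^2), applied only to the
    samples of the planted populations."""
    probe2gene = probe_map_from_manifest(m)
    probes = list(probe2gene)
    rng = np.random.default_rng(np.random.SeedSequence([m.seed, 2]))
    values = rng.normal(0.0, m.noise_sd, size=(len(probes), gm.n_samples))
    probe_idx = {p: i for i, p in enumerate(probes)}
    pop_of = [panel.assignments[s] for s in gm.samples]
    for p in m.planted_eqtls:
        if p.probe not in probe_idx:
            raise ValueError(f"planted probe {p.probe} has no gene assignment")
        g = gm.codes[gm.index_of(p.vid), :].astype(float)
        effect = p.beta * _encode_vec(g, p.model)
        mask = np.array([pop in p.populations for pop in pop_of])
        values[probe_idx[p.probe], mask] += effect[mask]
    return ExpressionMatrix(
        probes=probes, samples=list(gm.samples), values=values,
        probe2gene=probe2gene,
    )


def regulatory_from_manifest(m: SimManifest) -> list[tuple[str, int, int, str]]:
    """Regulatory intervals covering each perfect tagger indel plus a
    few background features."""
    vid_pos = dict(zip(m.variant_ids, m.positions))
    out = []
    k = 0
    for t in m.planted_taggers:
        if t.target_r2 >= 1.0:
            pos = vid_pos[t.indel_vid]
            k += 1
            out.append((m.chrom, max(pos - 200, 0), pos + 200, f"REG{k:04d}"))
    step = max(m.region_end // 6, 1)
    for j in range(5):
        k += 1
        s = 10_000 + j * step
        out.append((m.chrom, s, s + 400, f"REG{k:04d}"))
    out.sort(key=lambda iv: iv[1])
    return out


def catalog_from_manifest(m: SimManifest) -> pd.DataFrame:
    """Toy GWAS catalog: planted SNP eQTLs as association SNPs (one
    trait each) plus two rsIDs absent from the panel."""
    rows = []
    k = 0
    for p in m.planted_eqtls:
        vi = int(p.vid[2:]) - 1
        if m.vclass[vi] == "SNP":
            k += 1
            rows.append({"rsid": p.vid, "trait": f"trait_{k:02d}"})
    rows.append({"rsid": "rs99999901", "trait": "trait_absent_1"})
    rows.append({"rsid": "rs99999902", "trait": "trait_absent_2"})
    return pd.DataFrame(rows)


def write_fixture(m: SimManifest, outdir) -> dict[str, Path]:
    """Simulate everything and emit the full text fixture set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm, panel = simulate_haplotypes(m)
    em = simulate_expression(gm, m, panel)
    genes = genes_from_manifest(m)

    paths = {
        "vcf": outdir / "genotypes.vcf",
        "panel": outdir / "panel.tsv",
        "expression": outdir / "expression.tsv",
        "probe_map": outdir / "probe_map.tsv",
        "genes": outdir / "genes.bed",
        "regulatory": outdir / "regulatory.bed",
        "catalog": outdir / "gwas_catalog.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_vcf(gm, paths["vcf"])
    pd.DataFrame(
        {
            "sample": list(panel.assignments),
            "population": [panel.assignments[s] for s in panel.assignments],
            "super_population": [
                (panel.super_population or {}).get(panel.assignments[s], "NA")
                for s in panel.assignments
            ],
        }
    ).to_csv(paths["panel"], sep="\t", index=False)
    expr = pd.DataFrame(em.values, index=em.probes, columns=em.samples)
    expr.to_csv(paths["expression"], sep="\t", float_format="%.6g")
    pd.DataFrame(
        {"probe": list(em.probe2gene), "gene": list(em.probe2gene.values())}
    ).to_csv(paths["probe_map"], sep="\t", index=False)
    write_genes_bed12(genes, paths["genes"])
    with open(paths["regulatory"], "w") as fh:
        for chrom, s0, e0, name in regulatory_from_manifest(m):
            fh.write(f"{chrom}\t{s0}\t{e0}\t{name}\n")
    catalog_from_manifest(m).to_csv(paths["catalog"], sep="\t", index=False)
    m.to_json(paths["manifest"])
    return paths
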