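"""cis-eQTL scanning, sharing classification, and peak reduction.

A cis-eQTL is a (variant, probe) pair: the variant lies within a fixed
window of the probe's gene (default 200 kb beyond the gene span, with a
TSS-anchored alternative) and the min-P statistic over the five genetic
models falls below the cutoff.  Two cutoffs are in routine use:
1e-2 for the database / GWAS intersection and 1e-4 for the
distribution analyses.

A pair passing the cutoff in at least two populations is
population-shared; passing in exactly one, population-specific.  Peak
reduction keeps, per (probe, population, variant class), the record
with the smallest min-P so that LD-induced redundancy among eQTLs of
the same probe does not inflate class ratios.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import MODEL_ORDER, batch_min_p
from .model import (
    ExpressionMatrix,
    GeneModel,
    GenotypeMatrix,
    PopulationPanel,
    Variant,
    VariantClass,
)

RELAXED_CUTOFF = 1e-2
STRICT_CUTOFF = 1e-4


@dataclass
class CisEqtlRecord:
    variant: Variant
    probe: str
    population: str
    p_by_model: dict[str, float]
    min_p: float
    best_model: str
    vclass: VariantClass
    maf: float
    tss_distance: int
    passes_relaxed: bool = field(init=False)
    passes_strict: bool = field(init=False)
    is_peak: bool = False

    def __post_init__(self) -> None:
        self.passes_relaxed = self.min_p < RELAXED_CUTOFF
        self.passes_strict = self.min_p < STRICT_CUTOFF


@dataclass
class EqtlDatabase:
    """All cis-eQTL records across populations, keyed by (vid, probe)."""

    records: list[CisEqtlRecord]
    sharing: dict[tuple[str, str], tuple[str, list[str]]] = field(
        default_factory=dict
    )

    def pairs(self) -> set[tuple[str, str]]:
        return {(r.variant.vid, r.probe) for r in self.records}

    def records_for(self, vid: str) -> list[CisEqtlRecord]:
        return [r for r in self.records if r.variant.vid == vid]


def percent(numerator: float, denominator: float) -> float:
    """Percentage of a count over a total; NaN on a zero denominator."""
    if denominator == 0:
        return float("nan")
    return 100.0 * numerator / denominator


def _gene_interval(gene: GeneModel, window: int, anchor: str) -> tuple[int, int]:
    if anchor == "span":
        return gene.start - window, gene.end + window
    if anchor == "tss":
        return gene.tss - window, gene.tss + window
    raise ValueError(f"anchor must be 'span' or 'tss', got {anchor!r}")


def cis_pairs(
    genes: Sequence[GeneModel],
    variants: Sequence[Variant],
    window: int = 200_000,
    anchor: str = "span",
    probe2gene: Optional[dict[str, str]] = None,
) -> list[tuple[Variant, GeneModel, Optional[str]]]:
    """Enumerate (variant, gene[, probe]) pairs inside the cis window.

    The window is a closed interval: a variant exactly ``window`` bp
    from the gene boundary is included.  Raises when the two inputs
    share no chromosome names (a likely naming mismatch).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    gene_chroms = {g.chrom for g in genes}
    var_chroms = {v.chrom for v in variants}
    if genes and variants and not (gene_chroms & var_chroms):
        raise ValueError(
            f"no shared chromosome names between gene models {sorted(gene_chroms)} "
            f"and variants {sorted(var_chroms)}"
        )
    by_chrom: dict[str, list[tuple[int, Variant]]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append((v.pos, v))
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t[0])

    gene_probes: dict[str, list[str]] = {}
    if probe2gene is not None:
        for probe, gid in probe2gene.items():
            gene_probes.setdefault(gid, []).append(probe)

    out: list[tuple[Variant, GeneModel, Optional[str]]] = []
    for gene in genes:
        lst = by_chrom.get(gene.chrom, [])
        if not lst:
            continue
        lo, hi = _gene_interval(gene, window, anchor)
        positions = [p for p, _ in lst]
        i0 = bisect_left(positions, lo)
        i1 = bisect_right(positions, hi)
        for _, v in lst[i0:i1]:
            if probe2gene is None:
                out.append((v, gene, None))
            else:
                for probe in gene_probes.get(gene.gene_id, []):
                    out.append((v, gene, probe))
    return out


def scan_with_stats(
    gm: GenotypeMatrix,
    em: ExpressionMatrix,
    genes: Sequence[GeneModel],
    panel: PopulationPanel,
    population: str,
    window: int = 200_000,
    cutoff: float = RELAXED_CUTOFF,
    anchor: str = "span",
    min_samples: int = 10,
    inverse_normal: bool = False,
) -> tuple[list[CisEqtlRecord], int]:
    """Run the cis scan for one population.

    Returns (passing records, number of variant-probe tests attempted).
    Zero-variance probes are skipped.  Expression may optionally be
    rank inverse-normal transformed per probe before testing.
    """
    pop_samples = [s for s in panel.samples_for(population) if s in gm.samples]
    shared = [s for s in pop_samples if s in em.samples]
    if not shared:
        raise ValueError(
            f"no shared samples between genotypes and expression for "
            f"population {population!r}"
        )
    if len(shared) < min_samples:
        raise ValueError(
            f"only {len(shared)} shared samples for population {population!r}; "
            f"minimum is {min_samples}"
        )
    gm_pop = gm.subset_samples(shared)
    em_pop = em.subset_samples(shared)
    mafs = gm_pop.maf()

    pairs = cis_pairs(genes, gm_pop.variants, window=window, anchor=anchor,
                      probe2gene=em.probe2gene)
    # group by probe for vectorized fitting
    by_probe: dict[str, list[tuple[Variant, GeneModel]]] = {}
    for v, gene, probe in pairs:
        if probe is None:
            continue
        by_probe.setdefault(probe, []).append((v, gene))

    vidx = {v.vid: i for i, v in enumerate(gm_pop.variants)}
    records: list[CisEqtlRecord] = []
    n_tests = 0
    for probe, vg in by_probe.items():
        if probe not in em_pop._probe_index:
            continue
        y = em_pop.row(probe)
        finite = y[np.isfinite(y)]
        if finite.size < 2 or np.ptp(finite) == 0:
            continue  # zero-variance probes are never scanned
        if inverse_normal:
            y = _rank_inverse_normal(y)
        rows = [vidx[v.vid] for v, _ in vg]
        G = gm_pop.codes[rows, :]
        min_p, best_idx, p_by_model = batch_min_p(y, G)
        n_tests += int(np.isfinite(min_p).sum())
        hits = np.nonzero(np.isfinite(min_p) & (min_p < cutoff))[0]
        for k in hits:
            v, gene = vg[k]
            records.append(
                CisEqtlRecord(
                    variant=v,
                    probe=probe,
                    population=population,
                    p_by_model={m: float(p_by_model[m][k]) for m in MODEL_ORDER},
                    min_p=float(min_p[k]),
                    best_model=MODEL_ORDER[int(best_idx[k])],
                    vclass=v.vclass,
                    maf=float(mafs[vidx[v.vid]]),
                    tss_distance=gene.tss_distance(v.pos),
                )
            )
    records.sort(key=lambda r: (r.variant.chrom, r.variant.pos, r.probe))
    return records, n_tests


def scan(
    gm: GenotypeMatrix,
    em: ExpressionMatrix,
    genes: Sequence[GeneModel],
    panel: PopulationPanel,
    population: str,
    window: int = 200_000,
    cutoff: float = RELAXED_CUTOFF,
    anchor: str = "span",
    min_samples: int = 10,
    inverse_normal: bool = False,
) -> list[CisEqtlRecord]:
    records, _ = scan_with_stats(
        gm, em, genes, panel, population, window=window, cutoff=cutoff,
        anchor=anchor, min_samples=min_samples, inverse_normal=inverse_normal,
    )
    return records


def _rank_inverse_normal(y: np.ndarray) -> np.ndarray:
    from scipy import stats as _st

    out = np.full_like(y, np.nan, dtype=float)
    ok = np.isfinite(y)
    ranks = _st.rankdata(y[ok])
    out[ok] = _st.norm.ppf((ranks - 0.5) / ok.sum())
    return out


def classify_sharing(db: EqtlDatabase, cutoff: float) -> EqtlDatabase:
    """Label every passing (variant, probe) pair shared or specific.

    Shared = passes the cutoff in >= 2 populations; specific = exactly 1.
    The population list is attached per pair.
    """
    pops_by_pair: dict[tuple[str, str], set[str]] = {}
    for r in db.records:
        if r.min_p < cutoff:
            pops_by_pair.setdefault((r.variant.vid, r.probe), set()).add(
                r.population
            )
    db.sharing = {
        key: ("population-shared" if len(pops) >= 2 else "population-specific",
              sorted(pops))
        for key, pops in pops_by_pair.items()
    }
    return db


def peak_reduce(db: EqtlDatabase) -> EqtlDatabase:
    """Flag the smallest-p record per (probe, population, variant class).

    Ties in min-P go to the smaller genomic position.  Idempotent.
    """
    best: dict[tuple[str, str, VariantClass], CisEqtlRecord] = {}
    for r in db.records:
        r.is_peak = False
        key = (r.probe, r.population, r.vclass)
        cur = best.get(key)
        if (
            cur is None
            or r.min_p < cur.min_p
            or (r.min_p == cur.min_p and r.variant.pos < cur.variant.pos)
        ):
            best[key] = r
    for r in best.values():
        r.is_peak = True
    return db


def sharing_summary(db: EqtlDatabase, cutoff: float) -> dict:
    """Summarize sharing per variant class and per population.

    Returns a dict with, per variant class: total distinct pairs, shared
    count and shared percentage; per population: specific/shared pair
    counts and indel/SNP ratios (all-records and peak-only); and the
    exclusive two-population sharing counts.
    """
    classify_sharing(db, cutoff)
    vclass_by_pair: dict[tuple[str, str], VariantClass] = {}
    peak_pairs: set[tuple[str, str, str]] = set()
    pop_pairs: dict[str, set[tuple[str, str]]] = {}
    for r in db.records:
        if r.min_p >= cutoff:
            continue
        key = (r.variant.vid, r.probe)
        vclass_by_pair[key] = r.vclass
        pop_pairs.setdefault(r.population, set()).add(key)
        if r.is_peak:
            peak_pairs.add((r.variant.vid, r.probe, r.population))

    out: dict = {"by_vclass": {}, "by_population": {}, "pairwise_exclusive": {}}
    for vc in (VariantClass.INDEL, VariantClass.SNP):
        pairs = [k for k, v in vclass_by_pair.items() if v == vc]
        shared = [k for k in pairs if db.sharing[k][0] == "population-shared"]
        out["by_vclass"][vc.value] = {
            "total": len(pairs),
            "shared": len(shared),
            "shared_pct": percent(len(shared), len(pairs)),
            "specific": len(pairs) - len(shared),
            "specific_pct": percent(len(pairs) - len(shared), len(pairs)),
        }

    peak_by_pop: dict[str, set[tuple[str, str]]] = {}
    for vid, probe, pop in peak_pairs:
        peak_by_pop.setdefault(pop, set()).add((vid, probe))
    for pop, pairs in sorted(pop_pairs.items()):
        row: dict = {}
        for label in ("population-shared", "population-specific"):
            sub = [k for k in pairs if db.sharing[k][0] == label]
            n_indel = sum(
                1 for k in sub if vclass_by_pair[k] == VariantClass.INDEL
            )
            n_snp = len(sub) - n_indel
            peak_sub = [k for k in sub if k in peak_by_pop.get(pop, set())]
            pk_indel = sum(
                1 for k in peak_sub if vclass_by_pair[k] == VariantClass.INDEL
            )
            pk_snp = len(peak_sub) - pk_indel
            short = "shared" if label == "population-shared" else "specific"
            row[short] = {
                "n": len(sub),
                "pct": percent(len(sub), len(pairs)),
                "indel": n_indel,
                "snp": n_snp,
                "indel_snp_ratio": (n_indel / n_snp) if n_snp else float("nan"),
                "peak_indel_snp_ratio": (
                    (pk_indel / pk_snp) if pk_snp else float("nan")
                ),
            }
        out["by_population"][pop] = row

    # pairs passing in exactly two populations
    from collections import Counter

    pair_counts: Counter = Counter()
    for key, (_, pops) in db.sharing.items():
        if len(pops) == 2:
            pair_counts[(tuple(pops), vclass_by_pair[key].value)] += 1
    out["pairwise_exclusive"] = {
        f"{a}+{b}:{vc}": c for ((a, b), vc), c in sorted(pair_counts.items())
    }
    return out


def db_to_frame(db: EqtlDatabase) -> pd.DataFrame:
    """Flatten an EqtlDatabase to a tidy DataFrame (one row per record)."""
    rows = []
    for r in db.records:
        sharing = db.sharing.get((r.variant.vid, r.probe))
        rows.append(
            {
                "chrom": r.variant.chrom,
                "pos": r.variant.pos,
                "vid": r.variant.vid,
                "ref": r.variant.ref,
                "alt": r.variant.alt,
                "vclass": r.vclass.value,
                "probe": r.probe,
                "population": r.population,
                "min_p": r.min_p,
                "best_model": r.best_model,
                "maf": r.maf,
                "tss_distance": r.tss_distance,
                "is_peak": r.is_peak,
                "sharing": sharing[0] if sharing else "",
                **{f"p_{m}": r.p_by_model.get(m, float("nan")) for m in MODEL_ORDER},
            }
        )
    return pd.DataFrame(rows)
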