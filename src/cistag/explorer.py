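"""GWAS-catalog intersection, indel tagging, and per-SNP reports.

The explorer answers, for a catalog of GWAS association SNPs: which
are present in the genotype panel, which are themselves cis-eQTLs
(eSNPs), which indel cis-eQTLs tag them through high LD (r^2 >= 0.7
in a 1 Mb window by default, perfect taggers at r^2 = 1), and what
genomic/regulatory context each proxy sits in.  A proxy that is both a
cis-eQTL and inside a regulatory feature is the prioritization target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .annotate import RegionAnnotation, RegionClassifier, regulatory_overlap
from .ld import LdResult, proxy_search
from .model import GeneModel, GenotypeMatrix, PopulationPanel, VariantClass
from .scan import RELAXED_CUTOFF, CisEqtlRecord, EqtlDatabase, percent


@dataclass
class TagReport:
    query: str
    found_in_panel: bool
    traits: list[str] = field(default_factory=list)
    eqtl_hits: list[CisEqtlRecord] = field(default_factory=list)
    proxies: list[LdResult] = field(default_factory=list)
    indel_taggers: list[LdResult] = field(default_factory=list)
    perfect_taggers: list[LdResult] = field(default_factory=list)
    regions: dict[str, RegionAnnotation] = field(default_factory=dict)
    regulatory: dict[str, list[str]] = field(default_factory=dict)

    @property
    def prioritized(self) -> list[str]:
        """Proxy IDs that are eQTL indel taggers inside a regulatory
        feature — the candidates worth carrying forward."""
        return [
            r.vid_b for r in self.indel_taggers if self.regulatory.get(r.vid_b)
        ]


def _passing_pairs(db: EqtlDatabase, cutoff: float) -> dict[str, list[CisEqtlRecord]]:
    out: dict[str, list[CisEqtlRecord]] = {}
    for r in db.records:
        if r.min_p < cutoff:
            out.setdefault(r.variant.vid, []).append(r)
    return out


def catalog_intersect(
    catalog: pd.DataFrame,
    db: EqtlDatabase,
    gm: GenotypeMatrix,
    cutoff: float = RELAXED_CUTOFF,
) -> dict:
    """Intersect a GWAS catalog with the eQTL database.

    Returns panel coverage, the eSNP rate among covered SNPs, and the
    fraction of traits with at least one eSNP, plus per-SNP hits.
    """
    if catalog.empty:
        raise ValueError("GWAS catalog is empty")
    if catalog["rsid"].duplicated().any():
        catalog = catalog.drop_duplicates(subset="rsid")
    rsids = list(dict.fromkeys(catalog["rsid"]))
    traits_by_rsid: dict[str, list[str]] = {}
    for _, row in catalog.iterrows():
        traits_by_rsid.setdefault(row["rsid"], []).append(row["trait"])

    in_panel = [r for r in rsids if r in gm]
    eqtls = _passing_pairs(db, cutoff)
    esnps = [
        r for r in in_panel
        if r in eqtls and any(
            h.vclass == VariantClass.SNP for h in eqtls[r]
        )
    ]
    all_traits = sorted({t for ts in traits_by_rsid.values() for t in ts})
    esnp_traits = sorted(
        {t for r in esnps for t in traits_by_rsid.get(r, [])}
    )
    return {
        "n_catalog": len(rsids),
        "n_in_panel": len(in_panel),
        "coverage_pct": percent(len(in_panel), len(rsids)),
        "n_esnp": len(esnps),
        "esnp_pct": percent(len(esnps), len(in_panel)),
        "n_traits": len(all_traits),
        "n_traits_with_esnp": len(esnp_traits),
        "traits_with_esnp_pct": percent(len(esnp_traits), len(all_traits)),
        "esnps": esnps,
        "hits": {r: eqtls[r] for r in esnps},
    }


def find_indel_taggers(
    esnps: Sequence[str],
    db: EqtlDatabase,
    gm: GenotypeMatrix,
    panel: Optional[PopulationPanel] = None,
    window: int = 1_000_000,
    r2_min: float = 0.7,
    cutoff: float = RELAXED_CUTOFF,
) -> dict:
    """Per eSNP, indel cis-eQTL proxies at r^2 >= ``r2_min``.

    LD is computed per population (any-population aggregation) when a
    panel is supplied, else on the full matrix.  The summary reports
    how many eSNPs are tagged and how many distinct indel taggers
    exist, both at ``r2_min`` and at perfect LD (r^2 = 1).
    """
    eqtls = _passing_pairs(db, cutoff)
    indel_eqtl_ids = {
        vid for vid, recs in eqtls.items()
        if any(r.vclass == VariantClass.INDEL for r in recs)
    }
    matrices: list[GenotypeMatrix]
    if panel is not None:
        matrices = []
        for pop in panel.populations:
            samples = [s for s in panel.samples_for(pop) if s in gm.samples]
            if samples:
                matrices.append(gm.subset_samples(samples))
    else:
        matrices = [gm]

    rows = []
    for rsid in esnps:
        if rsid not in gm:
            raise KeyError(f"eSNP {rsid!r} not in genotype panel")
        best: dict[str, float] = {}
        for sub in matrices:
            for res in proxy_search(rsid, sub, window=window, r2_min=r2_min):
                if res.vid_b == rsid or res.vid_b not in indel_eqtl_ids:
                    continue
                best[res.vid_b] = max(best.get(res.vid_b, 0.0), res.r2)
        for indel_id, r2 in sorted(best.items(), key=lambda kv: -kv[1]):
            rows.append({"esnp": rsid, "indel": indel_id, "r2": r2})

    table = pd.DataFrame(rows, columns=["esnp", "indel", "r2"])
    tagged = table["esnp"].nunique() if not table.empty else 0
    taggers = table["indel"].nunique() if not table.empty else 0
    perfect = table[table["r2"] >= 1.0] if not table.empty else table
    return {
        "table": table,
        "n_esnps_tagged": int(tagged),
        "n_indel_taggers": int(taggers),
        "n_esnps_perfect": int(perfect["esnp"].nunique()) if not table.empty else 0,
        "n_indel_perfect": int(perfect["indel"].nunique()) if not table.empty else 0,
    }


def explore(
    queries: Sequence[str],
    gm: GenotypeMatrix,
    db: EqtlDatabase,
    genes: Sequence[GeneModel],
    regbed: Sequence[tuple[str, int, int, str]] = (),
    catalog: Optional[pd.DataFrame] = None,
    window: int = 1_000_000,
    r2_min: float = 0.7,
    cutoff: float = RELAXED_CUTOFF,
) -> list[TagReport]:
    """Full per-query report: proxies, eQTL hits, regions, regulatory
    overlaps.  Queries are rsIDs or ``chrom:start-end`` ranges; a query
    absent from the panel yields a flagged (not fatal) empty report.
    """
    resolved: list[tuple[str, list[str]]] = []  # (label, variant ids)
    any_ok = False
    for q in queries:
        if ":" in q and "-" in q.split(":", 1)[1]:
            chrom, rng = q.split(":", 1)
            lo, hi = (int(x) for x in rng.split("-", 1))
            vids = [v.vid for v in gm.variants
                    if v.chrom == chrom and lo <= v.pos <= hi]
            resolved.append((q, vids))
            any_ok = any_ok or bool(vids)
        elif q in gm:
            resolved.append((q, [q]))
            any_ok = True
        else:
            resolved.append((q, []))
    if not any_ok:
        raise ValueError(f"no query resolvable in the panel: {list(queries)}")

    classifier = RegionClassifier(genes) if genes else None
    eqtls = _passing_pairs(db, cutoff)
    traits_by_rsid: dict[str, list[str]] = {}
    if catalog is not None:
        for _, row in catalog.iterrows():
            traits_by_rsid.setdefault(row["rsid"], []).append(row["trait"])

    reports: list[TagReport] = []
    for label, vids in resolved:
        if not vids:
            reports.append(TagReport(query=label, found_in_panel=False,
                                     traits=traits_by_rsid.get(label, [])))
            continue
        for vid in vids:
            proxies = proxy_search(vid, gm, window=window, r2_min=r2_min)
            proxy_variants = [gm.variants[gm.index_of(p.vid_b)] for p in proxies]
            indel_taggers = [
                p for p in proxies
                if gm.variants[gm.index_of(p.vid_b)].vclass == VariantClass.INDEL
                and p.vid_b in eqtls
            ]
            regions = {}
            if classifier is not None:
                regions = {v.vid: classifier.classify(v) for v in proxy_variants}
            regulatory = regulatory_overlap(proxy_variants, regbed) if regbed else {}
            reports.append(
                TagReport(
                    query=vid,
                    found_in_panel=True,
                    traits=traits_by_rsid.get(vid, []),
                    eqtl_hits=eqtls.get(vid, []),
                    proxies=proxies,
                    indel_taggers=indel_taggers,
                    perfect_taggers=[p for p in indel_taggers if p.r2 >= 1.0],
                    regions=regions,
                    regulatory=regulatory,
                )
            )
    return reports


_TRACK_COLORS = {
    "eqtl_regulatory": "255,0,0",
    "eqtl": "255,165,0",
    "regulatory": "0,0,255",
    "neither": "128,128,128",
}


def export_track(
    reports: Sequence[TagReport], gm: GenotypeMatrix, path,
    track_name: str = "cistag_proxies",
) -> None:
    """Write proxies as a BED9 custom track (0-based half-open).

    Item color encodes the proxy class: eQTL+regulatory (red), eQTL
    (orange), regulatory (blue), neither (grey).
    """
    if not reports:
        raise ValueError("no reports to export")
    with open(path, "w") as fh:
        fh.write(
            f'track name="{track_name}" description="high-LD proxies" '
            'itemRgb="On"\n'
        )
        seen = set()
        for rep in reports:
            eqtl_ids = {p.vid_b for p in rep.indel_taggers} | (
                {rep.query} if rep.eqtl_hits else set()
            )
            for p in rep.proxies:
                v = gm.variants[gm.index_of(p.vid_b)]
                if v.vid in seen:
                    continue
                seen.add(v.vid)
                is_eqtl = p.vid_b in eqtl_ids
                is_reg = bool(rep.regulatory.get(p.vid_b))
                if is_eqtl and is_reg:
                    color = _TRACK_COLORS["eqtl_regulatory"]
                elif is_eqtl:
                    color = _TRACK_COLORS["eqtl"]
                elif is_reg:
                    color = _TRACK_COLORS["regulatory"]
                else:
                    color = _TRACK_COLORS["neither"]
                start0 = v.pos - 1
                end0 = v.pos - 1 + len(v.ref)
                fh.write(
                    "\t".join(
                        [
                            v.chrom, str(start0), str(end0), v.vid, "0", ".",
                            str(start0), str(end0), color,
                        ]
                    )
                    + "\n"
                )
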