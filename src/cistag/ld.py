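"""Pairwise linkage disequilibrium: r-squared and D-prime.

With phased haplotypes LD is computed by direct counting of the four
two-locus haplotypes.  With unphased genotypes the haplotype
frequencies are estimated by EM over the double-heterozygote phase
ambiguity (the classical two-locus gametic-phase algorithm),
initialized at linkage equilibrium.

Definitions, with p_A, p_B the alt-allele (coded-allele) frequencies
and p_AB the AB haplotype frequency:

    D   = p_AB - p_A * p_B
    r^2 = D^2 / (p_A (1-p_A) p_B (1-p_B))
    D'  = |D| / D_max,
          D_max = min(p_A (1-p_B), (1-p_A) p_B)       if D > 0
                = min(p_A p_B, (1-p_A) (1-p_B))       if D < 0

D' is reported as an absolute value in [0, 1]; the sign of D is
recoverable from the haplotype frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import MISSING, GenotypeMatrix

HapFreqs = tuple[float, float, float, float]  # (p_AB, p_Ab, p_aB, p_ab)


@dataclass
class LdResult:
    vid_a: str
    vid_b: str
    r2: float
    dprime: float
    hap_freqs: HapFreqs
    n_hap: int
    method: str  # "phased" or "EM"
    converged: bool = True
    ambiguous: bool = False

    @property
    def estimable(self) -> bool:
        return np.isfinite(self.r2)


def ld_from_freqs(
    hap_freqs: HapFreqs, n_hap: int = 0,
    vid_a: str = "A", vid_b: str = "B", method: str = "phased",
    converged: bool = True, ambiguous: bool = False,
) -> LdResult:
    """LD statistics from the four two-locus haplotype frequencies."""
    p_ab_, p_aB_, p_Ab_, p_AB_ = hap_freqs[3], hap_freqs[2], hap_freqs[1], hap_freqs[0]
    total = sum(hap_freqs)
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"haplotype frequencies must sum to 1, got {total}")
    pA = p_AB_ + p_Ab_
    pB = p_AB_ + p_aB_
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return LdResult(vid_a, vid_b, np.nan, np.nan, hap_freqs, n_hap, method,
                        converged, ambiguous)
    D = p_AB_ - pA * pB
    # grouped so the expression is exactly symmetric in A <-> B
    denom = (pA * (1 - pA)) * (pB * (1 - pB))
    r2 = D * D / denom
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        dmax = 0.0
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    return LdResult(vid_a, vid_b, float(r2), float(dprime), hap_freqs, n_hap,
                    method, converged, ambiguous)


def ld_phased(
    hapA: np.ndarray, hapB: np.ndarray,
    vid_a: str = "A", vid_b: str = "B",
) -> LdResult:
    """LD by direct haplotype counting on two phased allele vectors.

    Haplotype slots missing at either site are dropped.  Returns NA
    statistics when either site is monomorphic in the retained
    haplotypes.
    """
    hapA = np.asarray(hapA)
    hapB = np.asarray(hapB)
    if hapA.shape != hapB.shape:
        raise ValueError("haplotype vectors must have equal length")
    keep = (hapA != MISSING) & (hapB != MISSING)
    a = hapA[keep].astype(int)
    b = hapB[keep].astype(int)
    n = a.size
    if n == 0:
        return LdResult(vid_a, vid_b, np.nan, np.nan, (np.nan,) * 4, 0, "phased")
    n_AB = int(np.sum((a == 1) & (b == 1)))
    n_Ab = int(np.sum((a == 1) & (b == 0)))
    n_aB = int(np.sum((a == 0) & (b == 1)))
    n_ab = n - n_AB - n_Ab - n_aB
    freqs = (n_AB / n, n_Ab / n, n_aB / n, n_ab / n)
    return ld_from_freqs(freqs, n_hap=n, vid_a=vid_a, vid_b=vid_b, method="phased")


def ld_em(
    gA: np.ndarray, gB: np.ndarray,
    tol: float = 1e-8, max_iter: int = 1000,
    vid_a: str = "A", vid_b: str = "B",
) -> LdResult:
    """LD from unphased genotypes via EM haplotype-frequency estimation.

    Individuals missing either genotype are dropped.  Only the double
    heterozygote carries phase ambiguity; its AB/ab vs Ab/aB split is
    iterated to the maximum-likelihood haplotype frequencies starting
    from linkage equilibrium.  A result computed on all-double-het data
    is flagged ambiguous (the likelihood is symmetric in phase).
    """
    gA = np.asarray(gA)
    gB = np.asarray(gB)
    keep = (gA != MISSING) & (gB != MISSING)
    a = gA[keep].astype(int)
    b = gB[keep].astype(int)
    n = a.size
    if n == 0:
        return LdResult(vid_a, vid_b, np.nan, np.nan, (np.nan,) * 4, 0, "EM")
    if a.sum() in (0, 2 * n) or b.sum() in (0, 2 * n):  # monomorphic
        return LdResult(vid_a, vid_b, np.nan, np.nan, (np.nan,) * 4, 2 * n, "EM")

    counts = np.zeros((3, 3))
    for ga, gb in zip(a, b):
        counts[ga, gb] += 1
    n_dd = counts[1, 1]  # double heterozygotes
    n_hap = 2 * n

    pA = a.sum() / n_hap
    pB = b.sum() / n_hap
    # order: f[0]=AB, f[1]=Ab, f[2]=aB, f[3]=ab
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])

    # haplotype contributions from unambiguous genotype cells
    base = np.zeros(4)
    base[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    base[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    base[2] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    base[3] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]

    converged = False
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        new = base.copy()
        new[0] += n_dd * w
        new[3] += n_dd * w
        new[1] += n_dd * (1 - w)
        new[2] += n_dd * (1 - w)
        new /= n_hap
        if np.max(np.abs(new - f)) < tol:
            f = new
            converged = True
            break
        f = new

    ambiguous = bool(n_dd == n)
    res = ld_from_freqs(
        (f[0], f[1], f[2], f[3]), n_hap=int(n_hap), vid_a=vid_a, vid_b=vid_b,
        method="EM", converged=converged, ambiguous=ambiguous,
    )
    return res


def ld_pair(
    gm: GenotypeMatrix, vid_a: str, vid_b: str, **em_kwargs
) -> LdResult:
    """LD between two variants of a matrix: phased counting when the
    matrix is phased, EM otherwise."""
    ia, ib = gm.index_of(vid_a), gm.index_of(vid_b)
    if gm.phased and gm.haplotypes is not None:
        return ld_phased(gm.haplotypes[ia], gm.haplotypes[ib], vid_a, vid_b)
    return ld_em(gm.codes[ia], gm.codes[ib], vid_a=vid_a, vid_b=vid_b, **em_kwargs)


def proxy_search(
    query: str,
    gm: GenotypeMatrix,
    window: int = 1_000_000,
    r2_min: float = 0.7,
    window_mode: str = "total",
) -> list[LdResult]:
    """Find high-LD proxies of a query variant within a genomic window.

    ``window`` is the total span centered on the query (+- window/2)
    when ``window_mode`` is "total", or the flank on each side when
    "flank".  Results with r^2 >= ``r2_min`` are returned sorted by
    descending r^2; the query itself leads the list with r^2 = 1.
    """
    if query not in gm:
        raise KeyError(f"query variant {query!r} not found in the panel")
    iq = gm.index_of(query)
    qv = gm.variants[iq]
    half = window // 2 if window_mode == "total" else window
    lo, hi = qv.pos - half, qv.pos + half

    results: list[LdResult] = []
    for i, v in enumerate(gm.variants):
        if v.chrom != qv.chrom or not (lo <= v.pos <= hi):
            continue
        if i == iq:
            res = ld_pair(gm, query, query)
            res = LdResult(query, query, 1.0, 1.0, res.hap_freqs, res.n_hap,
                           res.method)
            results.append(res)
            continue
        res = ld_pair(gm, query, v.vid)
        if res.estimable and res.r2 >= r2_min:
            results.append(res)
    # descending r2; the query leads any r2 == 1 tie
    results.sort(key=lambda r: (-r.r2, 0 if r.vid_b == query else 1))
    return results


def export_haploview(
    gm: GenotypeMatrix, ped_path, info_path, variant_ids: Optional[list[str]] = None
) -> None:
    """Export genotypes in linkage PED + marker INFO format for external
    LD plotting tools."""
    if variant_ids is None:
        idx = list(range(gm.n_variants))
    else:
        idx = [gm.index_of(v) for v in variant_ids]
    with open(info_path, "w") as fh:
        for i in idx:
            v = gm.variants[i]
            fh.write(f"{v.vid}\t{v.pos}\n")
    with open(ped_path, "w") as fh:
        for j, sample in enumerate(gm.samples):
            fields = [sample, sample, "0", "0", "0", "0"]
            for i in idx:
                c = gm.codes[i, j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif gm.phased and gm.haplotypes is not None:
                    fields += [
                        str(gm.haplotypes[i, 2 * j] + 1),
                        str(gm.haplotypes[i, 2 * j + 1] + 1),
                    ]
                else:
                    fields += [["1", "1"], ["1", "2"], ["2", "2"]][int(c)]
            fh.write(" ".join(fields) + "\n")
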