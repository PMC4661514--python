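"""LD-preserving permutation null for the cis scan.

Each permutation shuffles the expression sample labels while leaving
the genotype matrix untouched, so the genotype-phenotype link is
broken but LD between variants (and, with the default joint shuffle,
the covariance between probes) is preserved.  Records passing the
cutoff in permuted data are "fake cis-eQTLs": the empirical null for
the enrichment analyses.

The per-permutation counts mirror the study's bookkeeping: the
smallest min-P across probes is assigned to each variant before
counting, so a variant tied to many probes of one gene is not counted
repeatedly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import ExpressionMatrix, GeneModel, GenotypeMatrix, PopulationPanel
from .scan import STRICT_CUTOFF, CisEqtlRecord, scan_with_stats


@dataclass
class PermutationRun:
    seed: int
    n_perm: int
    cutoff: float
    fake_records: list[list[CisEqtlRecord]]  # one list per permutation
    per_perm_counts: list[tuple[int, int]]  # (indel, SNP) per permutation
    n_tests: int  # total variant-probe tests across permutations

    @property
    def pooled(self) -> list[CisEqtlRecord]:
        return [r for perm in self.fake_records for r in perm]

    @property
    def exceedance_rate(self) -> float:
        """Fraction of permuted variant-probe tests below the cutoff."""
        if self.n_tests == 0:
            return float("nan")
        return sum(len(perm) for perm in self.fake_records) / self.n_tests


def permute_expression(
    em: ExpressionMatrix, seed: int, per_probe: bool = False
) -> ExpressionMatrix:
    """Return an expression matrix with sample labels shuffled.

    The default applies one joint permutation of the sample axis to all
    probes, preserving probe-probe covariance; ``per_probe`` shuffles
    each probe independently (a weaker null).
    """
    if len(em.samples) < 2:
        raise ValueError("permutation requires at least two samples")
    rng = np.random.default_rng(seed)
    if per_probe:
        values = np.empty_like(em.values)
        for i in range(em.values.shape[0]):
            values[i] = em.values[i, rng.permutation(len(em.samples))]
    else:
        perm = rng.permutation(len(em.samples))
        values = em.values[:, perm]
    return ExpressionMatrix(
        probes=list(em.probes),
        samples=list(em.samples),
        values=values,
        probe2gene=dict(em.probe2gene),
    )


def _per_variant_counts(records: list[CisEqtlRecord]) -> tuple[int, int]:
    """(indel, SNP) counts after assigning the best p per variant."""
    best: dict[str, CisEqtlRecord] = {}
    for r in records:
        cur = best.get(r.variant.vid)
        if cur is None or r.min_p < cur.min_p:
            best[r.variant.vid] = r
    n_indel = sum(1 for r in best.values() if r.vclass.value == "INDEL")
    return n_indel, len(best) - n_indel


def run_null(
    gm: GenotypeMatrix,
    em: ExpressionMatrix,
    genes: Sequence[GeneModel],
    panel: PopulationPanel,
    population: str,
    window: int = 200_000,
    cutoff: float = STRICT_CUTOFF,
    n_perm: int = 100,
    seed: int = 0,
    per_probe: bool = False,
    anchor: str = "span",
    min_samples: int = 10,
) -> PermutationRun:
    """Rerun the full cis scan on ``n_perm`` permuted expression matrices.

    Per-permutation RNG substreams are derived deterministically from
    the master seed, so identical (seed, inputs) give byte-identical
    fake records.  The genotype matrix is never modified.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    master = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   master.spawn(n_perm)]
    fake_records: list[list[CisEqtlRecord]] = []
    per_perm_counts: list[tuple[int, int]] = []
    n_tests = 0
    for perm_seed in child_seeds:
        em_perm = permute_expression(em, perm_seed, per_probe=per_probe)
        records, tests = scan_with_stats(
            gm, em_perm, genes, panel, population,
            window=window, cutoff=cutoff, anchor=anchor,
            min_samples=min_samples,
        )
        fake_records.append(records)
        per_perm_counts.append(_per_variant_counts(records))
        n_tests += tests
    return PermutationRun(
        seed=seed, n_perm=n_perm, cutoff=cutoff,
        fake_records=fake_records, per_perm_counts=per_perm_counts,
        n_tests=n_tests,
    )
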