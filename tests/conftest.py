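import numpy as np
import pytest

from cistag.scan import EqtlDatabase, classify_sharing, peak_reduce, scan_with_stats
from cistag.simulate import (
    demo_manifest,
    genes_from_manifest,
    simulate_expression,
    simulate_haplotypes,
)

DEMO_SEED = 1


@pytest.fixture(scope="session")
def demo():
    """Demo fixture: 6 populations x 80 samples, 2,000 variants, 100
    probes, 20 planted cis effects, 5 planted taggers."""
    m = demo_manifest(DEMO_SEED)
    gm, panel = simulate_haplotypes(m)
    em = simulate_expression(gm, m, panel)
    genes = genes_from_manifest(m)
    return {"manifest": m, "gm": gm, "panel": panel, "em": em, "genes": genes}


@pytest.fixture(scope="session")
def demo_db(demo):
    """Full six-population scan of the demo at the strict cutoff."""
    records = []
    n_tests = 0
    for pop in demo["panel"].populations:
        recs, nt = scan_with_stats(
            demo["gm"], demo["em"], demo["genes"], demo["panel"], pop,
            cutoff=1e-4,
        )
        records.extend(recs)
        n_tests += nt
    db = EqtlDatabase(records=records)
    classify_sharing(db, 1e-4)
    peak_reduce(db)
    db.n_tests = n_tests
    return db


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
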