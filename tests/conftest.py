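import numpy as np
import pandas as pd
import pytest

from mrmediate import RunConfig, SummaryStatTable, build_scenario, run_two_step, simulate_cohort
from mrmediate.synthetic import screening_fixture


def make_table(rows, trait_id="trait", trait_type="continuous"):
    """Build a SummaryStatTable from a list of per-SNP dicts with defaults."""
    defaults = dict(
        chrom="1", pos=1, effect_allele="A", other_allele="G",
        eaf=0.3, beta=0.1, se=0.02, pval=1e-9, n=10_000,
    )
    recs = []
    for i, row in enumerate(rows):
        rec = dict(defaults, snp=f"rs{i + 1}", pos=1 + i * 10**6)
        rec.update(row)
        recs.append(rec)
    cols = ["snp", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pval", "n"]
    df = pd.DataFrame(recs, columns=cols)[cols]
    return SummaryStatTable(trait_id=trait_id, trait_type=trait_type, records=df)


def make_harmonized(bx, sx, by, sy, n_exp=10_000, n_out=10_000):
    """Harmonized-record frame from effect/SE arrays."""
    bx, sx, by, sy = map(np.atleast_1d, (bx, sx, by, sy))
    k = len(bx)
    return pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(k)],
            "beta_exp": bx, "se_exp": np.broadcast_to(sx, (k,)),
            "pval_exp": 1e-9, "n_exp": float(n_exp),
            "beta_out": by, "se_out": np.broadcast_to(sy, (k,)),
            "pval_out": 0.5, "n_out": float(n_out),
            "eaf": 0.3, "flipped": False, "palindromic": False,
        }
    )


@pytest.fixture(scope="session")
def small_mediated_cohort():
    """A compact mediated-scenario cohort shared across tests."""
    cfg = build_scenario("mediated", n_per_cohort=4000, n_snps=20, n_own_snps=15, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def screening_cohort():
    """The packaged deterministic 10-mediator screening fixture."""
    return screening_fixture()


@pytest.fixture(scope="session")
def screening_tables(screening_cohort):
    c = screening_cohort
    exposure = c.gwas("exposure", trait_id="exposure")
    outcome = c.gwas("outcome", trait_id="outcome")
    mediators = [c.gwas(name, trait_id=name) for name in c.mediator_names]
    return exposure, mediators, outcome


@pytest.fixture(scope="session")
def screening_report(screening_cohort, screening_tables):
    exposure, mediators, outcome = screening_tables
    config = RunConfig(n_boot=200, seed=1)
    return run_two_step(
        exposure, mediators, outcome, config,
        cohort=screening_cohort, bidirectional=False,
    )
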