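import numpy as np
import pandas as pd
import pytest

from summr.sumstats import CANONICAL_COLUMNS, SummaryStatsTable


def make_table(rows, trait_name="trait", trait_type="continuous", case_fraction=None):
    """Build a SummaryStatsTable from a list of per-variant dicts; unspecified
    fields get innocuous defaults."""
    defaults = {"chrom": "1", "effect_allele": "A", "other_allele": "G",
                "eaf": 0.3, "beta": 0.01, "se": 0.005, "pvalue": 1e-9, "n": 10000}
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults, snp_id=f"rs{i + 1}", pos=1_000_000 * (i + 1))
        r.update(row)
        full.append(r)
    df = pd.DataFrame(full, columns=CANONICAL_COLUMNS)
    return SummaryStatsTable(trait_name, trait_type, df, case_fraction)


@pytest.fixture
def two_snp_table():
    return make_table([
        {"snp_id": "rs1", "beta": 0.02, "pvalue": 1e-12},
        {"snp_id": "rs2", "beta": -0.015, "pvalue": 1e-9},
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20230901)
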